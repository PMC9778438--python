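"""Observed/expected normalization of a small intra-chromosomal matrix.

Builds a random 12-bin contact matrix with a 1/(d+1) distance decay, computes
the per-distance expected counts and the O/E map, and verifies the
normalization identity.
"""

import numpy as np

from hicplaid import bin_genome
from hicplaid.contacts import (
    ContactMatrix,
    expected_by_distance,
    normalize_observed_expected,
)

rng = np.random.default_rng(0)
n, res = 12, 1_000_000
bins = bin_genome({"chr1": n * res}, res)

idx = np.arange(n)
lam = 50.0 / (np.abs(idx[:, None] - idx[None, :]) + 1.0)
upper = np.triu(rng.poisson(lam))
counts = (upper + np.triu(upper, 1).T).astype(float)
cm = ContactMatrix(bins, "chr1", counts)

expected = expected_by_distance(cm)
norm = normalize_observed_expected(cm)

print("distance (bins) | expected count | mean O/E at that distance")
for d in range(6):
    diag = np.diagonal(norm.values, d)
    print(f"{d:15d} | {expected[d]:14.2f} | {np.nanmean(diag):.6f}")
print()
print("Expected counts fall with genomic separation (distance decay); after")
print("dividing each cell by the expected count at its separation the mean")
print("O/E at every distance is exactly 1, so remaining structure in the O/E")
print("map reflects compartments and domains rather than linear distance.")
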