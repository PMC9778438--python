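"""Directionality-index TAD calling on a simulated 50 Mb chromosome.

Simulates contacts at 40 kb bins with planted 1-5 Mb domains, computes the DI
track (2 Mb windows), segments it with the 3-state HMM, calls domains and
boundaries, and checks boundary recovery against the planted truth.
"""

import numpy as np

from hicplaid.simulate import SimConfig, generate_truth, simulate_hic
from hicplaid.tads import call_tads, directionality_index, fit_di_hmm, tad_summary

cfg = SimConfig(seed=7, chrom_sizes={"chr1": 50_000_000})
truth = generate_truth(cfg)
raw = simulate_hic(truth, cfg, 1, truth.tad_bins)

track = directionality_index(raw, truth.tad_bins, window=2_000_000)
hmm = fit_di_hmm(track, seed=7)
tads = call_tads(hmm, truth.tad_bins)
summary = tad_summary(tads)

print(f"planted domains: {len(truth.domains[1])}")
print(f"called domains:  {summary['count']}")
print(f"median domain size: {summary['median_size'] / 1e6:.2f} Mb")
print(f"boundaries (gaps <= 400 kb): {summary['boundary_count']}")

planted = truth.boundaries[1]["center"].to_numpy()
called = tads.boundaries["center"].to_numpy()
res = truth.tad_bins.resolution
recovery = np.mean([np.min(np.abs(called - p)) <= res for p in planted])
print(f"planted boundaries recovered within one 40 kb bin: {100 * recovery:.0f}%")
print()
print("DI is strongly positive where contacts point downstream (domain")
print("starts) and negative at domain ends; the HMM turns that into")
print("down/none/up runs, and each down->up motif is one domain.  Extra")
print("boundaries beyond the planted domain edges sit at compartment-block")
print("edges, which the plaid intensity also makes real contact boundaries.")
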