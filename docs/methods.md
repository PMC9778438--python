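# Methods

## Coordinate system and matrices

All analyses run on fixed-width genomic bins (0-based half-open intervals)
tiling each chromosome; the last bin of a chromosome may be shorter than the
nominal resolution.  Compartment analysis defaults to 500 kb bins, TAD
analysis to 40 kb.  Intra-chromosomal contact matrices are dense, square and
symmetric per chromosome; interchromosomal contacts are kept as per-pair
aggregate counts rather than matrices, since the enrichment statistic only
needs pair totals.

## Expected model and O/E normalization

The expected count at bin separation d is estimated per chromosome as the
mean observed count over all pairs at that separation (including d = 0, the
diagonal, which is stored once).  Per-chromosome rather than genome-wide
estimation was chosen because distance-decay profiles differ between
chromosomes and the per-chromosome mean is the simplest estimator that makes
the per-distance mean of the O/E map exactly 1.  Cells with expected count 0
are flagged missing (NaN), not set to 0: a 0/0 cell carries no information,
and downstream correlation/PCA drops missing entries instead of being biased
by imputed zeros.

## Compartment calling

The O/E map's Pearson row-correlation matrix is computed over pairwise
complete observations; rows that are entirely missing are dropped, and any
residual undefined correlation (two rows sharing fewer than two finite
entries) is set to 0 (uncorrelated).  Chromosomes with fewer than 3 usable
bins are skipped with a warning.  E1 is the leading right singular vector of
the column-centered correlation matrix, unit-norm per chromosome, computed
on the correlation matrix rather than raw counts because raw-count PCA is
dominated by distance decay.  The eigenvector sign is fixed deterministically
(largest-magnitude entry positive) and then oriented by requiring a
non-negative Pearson correlation with per-bin gene density, since compartment
A is the active, gene-rich state; zero-variance gene density leaves the
orientation unchanged with a warning.  Labels follow the strict sign rule
(E1 > 0 → A, E1 < 0 → B, exactly 0 or missing → no call).  PCA is per
chromosome, avoiding interchromosomal artifacts.  A majority-vote
aggregation utility reports labels at coarser resolution (e.g. 1 Mb from
500 kb bins); ties aggregate to missing.

Switch detection requires identical bin systems and classifies each bin as
stable_A/stable_B/A_to_B/B_to_A/missing; the switched fraction is reported
both as a bin fraction and as a base-pair fraction (the two differ only
through short terminal bins).  Genes map to bins by TSS position — a single
deterministic coordinate per gene, consistent with the TSS-centric boundary
profiles — rather than by gene-body overlap, which would need a tie-break
for genes spanning bin borders.

## TAD calling

DI uses raw counts by default.  The chi-square form of DI is count-based,
and O/E ratios destroy its sampling interpretation; `use_normalized`-style
input is nevertheless possible by passing normalized matrices, since the
formula applies to any nonnegative track.  Windows truncate at chromosome
ends and the affected bins are flagged.  DI is 0 when the upstream and
downstream sums are equal or both zero.

The 3-state Gaussian HMM is initialized deterministically: state means at
the 10%/50%/90% DI quantiles, shared variance equal to the track variance,
uniform start probabilities, sticky transitions (0.8 self, 0.1 cross).  EM
runs to tolerance 1e-4 or 500 iterations; non-convergence returns the
best-so-far fit with a warning.  Decoding is by most-probable (Viterbi)
path per chromosome, and states are relabeled canonically by emission mean
(lowest = upstream-biased, highest = downstream-biased), which makes domain
calls invariant to state-label permutation.  A single Gaussian per state on
raw DI is used rather than a mixture on transformed DI: on the synthetic
study conditions the three DI modes are well separated and the simpler
emission model decodes the planted segmentation exactly.  A perfectly flat
DI track short-circuits to an all-"none" path.

A domain opens at the first bin of a maximal downstream-biased run and
closes at the last bin of the next upstream-biased run; intervening bins of
any state are interior.  A chromosome with no complete down→up motif yields
no domains.  Inter-domain gaps of length ≤ 400 kb are boundaries (equality
counts as boundary, taking "a distance of 400 kb between two adjacent TADs"
as the boundary criterion); longer gaps are unorganized chromatin.  The
boundary center is the integer midpoint of the gap, so adjacent domains
(gap 0) get a boundary at their junction.

TSS profiles count TSS in half-open 10 kb windows at offsets −span..+span
from each boundary center (span ±500 kb by default, configurable; the
window width is the analysis-defining 10 kb).

## Boundary conservation

Boundary centers from the two samples are matched greedily by increasing
distance within a tolerance (ties broken by position for determinism), each
center used at most once, matched position = pair midpoint.  Observed
windows are ±10 bins including the center (21 values); because the null is
defined on 20-bin windows, the observed correlation is also computed on the
20 non-center bins for strict comparability, and both are reported.  Windows
crossing a chromosome edge exclude that center with a warning.

The null draws one contiguous 20-bin window position per sample per
repetition, uniformly over all valid starts pooled across chromosomes (so
chromosomes are weighted by usable length), independently in the two samples
(a shared-position variant is available behind a flag).  Draws where both
samples land on the identical genomic window are redrawn: the null models
the correlation of unrelated windows, and a window compared with itself is
the signal under test, not background; for genuinely distinct samples such
collisions are rare and carry no information either way.  Constant
(zero-variance) windows are also redrawn.  Empirical p uses the
(1 + #{null ≥ ρ}) / (n_rand + 1) estimator so no p-value is exactly zero.

## Expression and enrichment

FPKM = count · 1e9 / (length · library size).  The library size defaults to
the sum of counted reads over the annotated genes and can be overridden with
a mapped-read total.  Gene length is taken from the annotation as given
(the generator draws a single transcript span per gene); when exon structure
is available upstream, a union-exon length should be supplied in the length
column.  The compartment comparison is descriptive — per-label counts,
median and quartile FPKM, and a one-sided rank-sum statistic for A > B — not
a differential-expression model.

Enrichment is the one-sided hypergeometric (Fisher exact upper tail), the
default of standard over-representation tools.  Raw p-values with the
p < 0.05 rule are reported by default, matching the convention of reporting
uncorrected pathway p-values; Benjamini–Hochberg adjustment is available
behind a flag.  The background universe must be passed explicitly; the
pipeline uses all genes with a bin assignment.

## Synthetic data: what it emulates and what it does not

The generator plants, per chromosome: alternating A/B blocks with lengths
uniform on 2–8 Mb; a set of contiguous switched runs (2–4 bins each by
default) totalling exactly the configured 5% of compartment bins, flipped in
condition 2; domains tiling the chromosome with sizes uniform on 1–5 Mb,
shared between conditions except a configurable 20% of boundaries shifted by
2–5 bins; genes placed by a Poisson process at 10/Mb in A blocks versus 3/Mb
in B (A gene-rich), with uniform TSS, random strand and 1–50 kb spans; and
negative-binomial expression with log-means 5 (A) and 3 (B) — a 2-unit
log-scale effect — and dispersion 0.3.  Contact counts are independent
Poisson draws around (d+1)^(−γ) · (1 + α e_i e_j) · β^{same domain}, γ = 1,
α = 0.4, β = 3, scaled so each chromosome's expected total is 2 × 10⁶ read
pairs.  One planted pathway draws 60% of its 20 members from switched-bin
genes among 20 uniform decoys of the same size.

Poisson rather than negative-binomial contact counts were chosen because the
recovery analyses depend on the mean structure, not on overdispersion.  The
generator does not emulate: restriction-fragment structure or ligation
artifacts, coverage biases (GC, mappability) and hence the need for matrix
balancing, overdispersed or correlated contact noise, sub-compartments,
nested/hierarchical domains, or loops.  Passing recovery tests on this data
therefore demonstrates the correctness of the statistical machinery under
the model's assumptions, not robustness to real-data artifacts — on real
maps, upstream balancing and quality filtering remain the user's
responsibility.

Note one deliberate consequence of planting compartments and domains
independently: compartment-block edges are themselves genuine contact
boundaries (the plaid factor changes across them), so the TAD caller
legitimately reports boundaries there in addition to the planted domain
edges; recovery statistics count false calls against the union of planted
structure.

## Problem sizes and determinism

The shipped tests and the reproduction script use two 50 Mb chromosomes at
500 kb bins (200 bins) for compartment analyses, one 50 Mb chromosome at
40 kb bins (1,250 bins) for TAD and boundary analyses, 10,000 null
randomizations, and 20 seeded replicates for the enrichment positive
control — sizes at which every recovery property is measurable with
comfortable margins while a full run completes in well under a minute.  All
stochastic steps take explicit seeds; fixed seeds give bit-identical truth,
matrices, HMM fits, TAD sets and null distributions across runs.

## Known limitations

- The expected model is the plain per-distance mean; no smoothing or
  monotone regression, so E(d) is noisy at large d where few pairs exist
  (those cells are exactly where O/E is least informative).
- The HMM's single-Gaussian emissions can under-segment real DI tracks whose
  state distributions are heavy-tailed; the quantile initialization assumes
  both biased states are populated.
- Greedy boundary matching is not globally optimal for pathological center
  configurations (it is optimal for well-separated boundaries, the realistic
  case).
- Interchromosomal analysis operates on chromosome-pair totals only; no
  binned trans maps.
- No iterative/matrix balancing (ICE/KR), sub-compartment calling,
  insulation-score or arrowhead TADs, loop calling, or GO-graph-aware
  enrichment.
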