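# hicplaid

Comparative analysis of binned Hi-C contact maps between two samples:
distance-decay (observed/expected) normalization, A/B compartment calling and
switch detection, directionality-index + HMM TAD and boundary calling,
boundary-conservation testing against a randomized null, integration of gene
expression with compartment labels, and hypergeometric pathway enrichment of
switched-compartment genes.  A synthetic-data generator with planted ground
truth (plaid compartments, contiguous domains, compartment switches,
compartment-correlated expression) makes every stage testable end to end.

The package is aimed at genome-organization studies that compare chromatin
architecture between two conditions — tissues, cell types, or populations
adapted to different environments — and ask which genomic regions change
compartment, whether domain boundaries are conserved, and what the genes in
switched regions do.

## The statistics at the core

**O/E normalization.** For an intra-chromosomal count matrix *O*, the
expected count at bin separation *d* is the per-chromosome mean
E(d) = mean{ O(i,j) : |i−j| = d }, and the normalized map is
N(i,j) = O(i,j)/E(|i−j|) (cells with E = 0 are flagged missing).  By
construction the mean of *N* at every separation is 1.

**A/B compartments.** E1 is the first principal component of the Pearson
row-correlation matrix of the O/E map, computed per chromosome and oriented
so that it correlates positively with gene density.  Bins with E1 > 0 are
compartment A (active, gene-rich), E1 < 0 are B.  Bins whose label differs
between two samples are compartment switches; genes whose TSS falls in a
switched bin are switched-compartment genes (SCGs).

**Interchromosomal enrichment.** With T total interchromosomal reads and
f_i the fraction of them with one end on chromosome *i*, the expected count
for pair (i,j) is f_i · f_j · T and the enrichment is observed/expected.

**TADs.** The directionality index at each 40 kb bin contrasts the contact
sum A to the 2 Mb upstream window with the sum B to the 2 Mb downstream
window:

    DI = sign(B − A) · ((A − E)² / E + (B − E)² / E),   E = (A + B) / 2.

A 3-state Gaussian HMM segments the DI track into downstream-biased / none /
upstream-biased runs; a domain spans from the first bin of a downstream run
to the last bin of the next upstream run.  Inter-domain gaps ≤ 400 kb are
topological boundaries; longer gaps are unorganized chromatin.

**Boundary conservation.** At each matched boundary center the DI values
±10 bins around the center are extracted in both samples and their Spearman
correlation computed; the null draws random 20-bin windows independently in
each sample 10,000 times.  Empirical p = (1 + #{null ≥ ρ}) / (n_rand + 1).

**Expression and enrichment.** FPKM = count · 10⁹ / (gene length · library
size).  SCG over-representation per pathway uses the upper-tail
hypergeometric probability P(X ≥ k) with universe N, pathway size K, list
size n and overlap k (significant at p < 0.05; optional Benjamini–Hochberg).

## Worked example

`examples/` contains one narrative script per capability.  For instance:

```sh
$ python examples/02_call_compartments.py
condition 1: 95 A bins, 105 B bins, label accuracy vs planted truth 100.0%
condition 2: 93 A bins, 107 B bins, label accuracy vs planted truth 100.0%
switched fraction: 5.0% of bins
planted switched blocks recovered exactly: True
```

Two 50 Mb chromosomes are simulated at 500 kb bins in two conditions that
share compartment structure except for a planted 5% of switched bins; the
compartment caller recovers every planted label, and the detected switch set
equals the planted one.  Similarly:

```sh
$ python examples/03_call_tads.py
planted domains: 17
called domains:  22
median domain size: 2.12 Mb
boundaries (gaps <= 400 kb): 21
planted boundaries recovered within one 40 kb bin: 100%
```

The extra called boundaries sit at compartment-block edges, which the plaid
intensity makes genuine contact boundaries in the simulation.
`examples/05_expression_enrichment.py` closes the loop: compartment A holds
more genes at higher FPKM than B, and the pathway seeded with switched-bin
genes ranks first in the hypergeometric test (p ≈ 2 × 10⁻¹³ against 20
decoys with seed 7).

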