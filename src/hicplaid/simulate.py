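"""Two-condition synthetic Hi-C data with planted ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: power-law distance decay, a plaid (checkerboard) compartment
pattern, contiguous contact-enriched domains, compartment switches between
the two conditions, gene placement biased toward A blocks, and
compartment-correlated expression.  Contact counts are independent Poisson
draws around the intensity

    lambda(i, j) ∝ (|i - j| + 1)^(-gamma) * (1 + alpha * e_i * e_j) * B(i, j)

with e the planted compartment sign (+1 for A, -1 for B) and B(i, j) = beta
when i and j fall in the same planted domain, else 1, scaled so the expected
total per chromosome equals the configured sequencing depth.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .enrichment import PathwayCollection
from .genome import GenomeBins, bin_genome

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "generate_truth",
    "expected_intensity",
    "simulate_hic",
    "simulate_expression",
    "simulate_pathways",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the two-condition simulation.

    Defaults reflect the comparative design the analysis targets: a 5%
    compartment-switch rate, plaid strength ``alpha`` 0.4, within-domain
    enrichment ``beta`` 3, distance-decay exponent ``gamma`` 1 and 2e6 read
    pairs per chromosome; compartment blocks of 2-8 Mb at 500 kb bins and
    domains of 1-5 Mb at 40 kb bins; gene density 10/Mb in A blocks versus
    3/Mb in B blocks; expression log-means 5 (A) versus 3 (B) with negative
    binomial dispersion 0.3; one planted pathway of 20 genes, 60% drawn from
    switched-bin genes, among 20 uniform decoys of the same size.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    comp_resolution: int = 500_000
    tad_resolution: int = 40_000
    comp_block_range: tuple[int, int] = (2_000_000, 8_000_000)  # bp
    alpha: float = 0.4  # plaid strength, in [0, 1)
    switch_fraction: float = 0.05  # fraction of compartment bins flipped in cond 2
    switch_block_bins: tuple[int, int] = (2, 4)  # contiguous switched-run length
    domain_size_range: tuple[int, int] = (1_000_000, 5_000_000)  # bp
    beta: float = 3.0  # within-domain contact enrichment, >= 1
    boundary_shift_frac: float = 0.2  # cond-2 boundaries moved by >= 2 bins
    boundary_shift_bins: tuple[int, int] = (2, 5)
    gamma: float = 1.0  # distance-decay exponent, > 0
    depth: float = 2_000_000.0  # expected read pairs per chromosome
    genes_per_mb_a: float = 10.0
    genes_per_mb_b: float = 3.0
    gene_length_range: tuple[int, int] = (1_000, 50_000)  # bp
    tss_boundary_frac: float = 0.0  # genes relocated to within 50 kb of a boundary
    mu_a: float = 5.0  # natural-log expression mean, A-bin genes
    mu_b: float = 3.0
    dispersion: float = 0.3  # NB dispersion; 0 -> Poisson
    pathway_size: int = 20
    n_decoys: int = 20
    planted_frac: float = 0.6  # planted pathway members drawn from switched genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must be in [0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """The simulator's ground truth used for recovery testing."""

    comp_bins: GenomeBins
    tad_bins: GenomeBins
    labels: dict[int, np.ndarray]  # condition -> per-comp-bin 'A'/'B'
    switched_bins: np.ndarray  # global comp-bin ids flipped in condition 2
    domains: dict[int, pd.DataFrame]  # condition -> (chrom, start, end)
    boundaries: dict[int, pd.DataFrame]  # condition -> (chrom, center)
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, length
    pathway_id: str = "planted_pathway"

    def gene_labels(self, condition: int) -> pd.Series:
        """Compartment label of each gene's TSS bin under one condition."""
        bins = self.comp_bins
        labs = self.labels[condition]
        idx = [
            labs[bins.bin_index(c, int(t))]
            for c, t in zip(self.genes["chrom"], self.genes["tss"])
        ]
        return pd.Series(idx, index=self.genes["gene_id"].to_numpy(), name="label")

    def scg_ids(self) -> set[str]:
        """Genes whose TSS falls in a planted switched bin."""
        bins = self.comp_bins
        switched = set(self.switched_bins.tolist())
        return {
            g
            for g, c, t in zip(
                self.genes["gene_id"], self.genes["chrom"], self.genes["tss"]
            )
            if bins.bin_index(c, int(t)) in switched
        }


# --------------------------------------------------------------------- truth


def _compartment_blocks(rng, size: int, res: int, block_range) -> np.ndarray:
    """Alternating A/B label array for one chromosome at compartment bins."""
    n = -(-size // res)
    lo = max(1, block_range[0] // res)
    hi = max(lo, block_range[1] // res)
    labels = np.empty(n, dtype="<U1")
    current = rng.choice(["A", "B"])
    pos = 0
    while pos < n:
        length = int(rng.integers(lo, hi + 1))
        labels[pos : pos + length] = current
        current = "A" if current == "B" else "B"
        pos += length
    return labels


def _plant_switch_runs(rng, n_bins: int, target: int, run_range) -> np.ndarray:
    """Non-overlapping contiguous runs of bins totalling exactly ``target``."""
    taken = np.zeros(n_bins, dtype=bool)
    chosen: list[int] = []
    remaining = target
    attempts = 0
    while remaining > 0 and attempts < 10_000:
        attempts += 1
        length = int(rng.integers(run_range[0], run_range[1] + 1))
        length = min(length, remaining)
        start = int(rng.integers(0, n_bins - length + 1))
        # keep one-bin spacing so planted runs stay distinct blocks
        lo = max(0, start - 1)
        hi = min(n_bins, start + length + 1)
        if taken[lo:hi].any():
            continue
        taken[start : start + length] = True
        chosen.extend(range(start, start + length))
        remaining -= length
    if remaining > 0:
        warnings.warn("could not place all requested switch bins; fraction reduced")
    return np.array(sorted(chosen), dtype=int)


def _tile_domains(rng, size: int, res: int, size_range) -> list[tuple[int, int]]:
    """Tile [0, size) with domains of random size (multiples of ``res``)."""
    lo = max(res, (size_range[0] // res) * res)
    hi = max(lo, (size_range[1] // res) * res)
    spans = []
    pos = 0
    while pos < size:
        length = int(rng.integers(lo // res, hi // res + 1)) * res
        end = min(pos + length, size)
        if size - end < lo:  # absorb a too-short remainder into the last domain
            end = size
        spans.append((pos, end))
        pos = end
    return spans


def generate_truth(config: SimConfig) -> PlantedTruth:
    """Draw the planted two-condition ground truth (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    comp_bins = bin_genome(config.chrom_sizes, config.comp_resolution)
    tad_bins = bin_genome(config.chrom_sizes, config.tad_resolution)

    # --- compartment labels, condition 1
    labels1 = np.empty(comp_bins.n_bins, dtype="<U1")
    for chrom, size in config.chrom_sizes.items():
        labels1[comp_bins.chrom_slice(chrom)] = _compartment_blocks(
            rng, size, config.comp_resolution, config.comp_block_range
        )

    # --- planted switches (contiguous runs, condition 2 = flipped labels)
    target = int(round(config.switch_fraction * comp_bins.n_bins))
    switched = _plant_switch_runs(
        rng, comp_bins.n_bins, target, config.switch_block_bins
    )
    labels2 = labels1.copy()
    labels2[switched] = np.where(labels1[switched] == "A", "B", "A")

    # --- domains: shared scaffold, a fraction of cond-2 boundaries shifted
    res = config.tad_resolution
    domains: dict[int, list] = {1: [], 2: []}
    for chrom, size in config.chrom_sizes.items():
        spans1 = _tile_domains(rng, size, res, config.domain_size_range)
        edges1 = [e for _, e in spans1[:-1]]  # internal boundaries
        edges2 = []
        prev = 0
        for i, e in enumerate(edges1):
            nxt = edges1[i + 1] if i + 1 < len(edges1) else size
            if rng.random() < config.boundary_shift_frac:
                shift = int(
                    rng.integers(
                        config.boundary_shift_bins[0], config.boundary_shift_bins[1] + 1
                    )
                ) * res * (1 if rng.random() < 0.5 else -1)
                e2 = int(np.clip(e + shift, prev + res, nxt - res))
            else:
                e2 = e
            edges2.append(e2)
            prev = e2
        spans2 = list(zip([0] + edges2, edges2 + [size]))
        domains[1].extend((chrom, s, e) for s, e in spans1)
        domains[2].extend((chrom, s, e) for s, e in spans2)
    dom_df = {
        cond: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for cond, rows in domains.items()
    }
    boundaries = {}
    for cond, df in dom_df.items():
        rows = []
        for chrom, grp in df.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()
            rows.extend((chrom, int(e)) for e in ends[:-1])
        boundaries[cond] = pd.DataFrame(rows, columns=["chrom", "center"])

    # --- genes: Poisson placement per compartment bin, A-rich (condition 1)
    gene_rows = []
    gid = 0
    for chrom in comp_bins.chroms:
        sl = comp_bins.chrom_slice(chrom)
        sub = comp_bins.table.iloc[sl]
        for start, end, lab in zip(
            sub["start"], sub["end"], labels1[sl]
        ):
            rate_mb = config.genes_per_mb_a if lab == "A" else config.genes_per_mb_b
            n_genes = rng.poisson(rate_mb * (end - start) / 1e6)
            for _ in range(n_genes):
                tss = int(rng.integers(start, end))
                length = int(rng.integers(*config.gene_length_range))
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((f"g{gid:05d}", chrom, tss, strand, length))
                gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand", "length"]
    )

    # optionally concentrate a fraction of TSS near condition-1 boundaries
    if config.tss_boundary_frac > 0 and len(genes) and len(boundaries[1]):
        b1 = boundaries[1]
        move = rng.random(len(genes)) < config.tss_boundary_frac
        for i in np.flatnonzero(move):
            row = b1.iloc[int(rng.integers(len(b1)))]
            chrom = row["chrom"]
            pos = int(row["center"] + rng.integers(-50_000, 50_001))
            pos = int(np.clip(pos, 0, config.chrom_sizes[chrom] - 1))
            genes.loc[genes.index[i], ["chrom", "tss"]] = [chrom, pos]

    return PlantedTruth(
        comp_bins=comp_bins,
        tad_bins=tad_bins,
        labels={1: labels1, 2: labels2},
        switched_bins=switched,
        domains=dom_df,
        boundaries=boundaries,
        genes=genes,
    )


# ------------------------------------------------------------------ contacts


def _bin_signs(truth: PlantedTruth, condition: int, bins: GenomeBins, chrom: str):
    """Compartment sign (+1 A / -1 B) per bin of an arbitrary bin system."""
    mids = bins.midpoints(chrom)
    comp = truth.comp_bins
    labs = truth.labels[condition]
    idx = comp.chrom_offset(chrom) + np.minimum(
        mids // comp.resolution, comp.chrom_n_bins(chrom) - 1
    )
    return np.where(labs[idx] == "A", 1.0, -1.0)


def _domain_ids(truth: PlantedTruth, condition: int, bins: GenomeBins, chrom: str):
    mids = bins.midpoints(chrom)
    dom = truth.domains[condition]
    dom = dom[dom["chrom"] == chrom]
    starts = dom["start"].to_numpy()
    return np.searchsorted(starts, mids, side="right") - 1


def expected_intensity(
    truth: PlantedTruth, config: SimConfig, condition: int, bins: GenomeBins, chrom: str
) -> np.ndarray:
    """Noiseless contact intensity matrix (scaled to the configured depth)."""
    n = bins.chrom_n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    e = _bin_signs(truth, condition, bins, chrom)
    dom = _domain_ids(truth, condition, bins, chrom)
    lam = (d + 1.0) ** (-config.gamma) * (1.0 + config.alpha * np.outer(e, e))
    lam *= np.where(dom[:, None] == dom[None, :], config.beta, 1.0)
    upper_mass = np.triu(lam).sum()
    return lam * (config.depth / upper_mass)


def simulate_hic(
    truth: PlantedTruth,
    config: SimConfig,
    condition: int,
    bins: GenomeBins,
    seed: int | None = None,
) -> dict[str, ContactMatrix]:
    """Draw Poisson contact counts per chromosome at the given bin system.

    The expected count summed over unique (i <= j) pairs equals the
    configured per-chromosome depth.  Returns raw symmetric matrices.
    """
    if config.depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if seed is None:
        seed = config.seed
    out = {}
    for ci, chrom in enumerate(bins.chroms):
        rng = np.random.default_rng([seed, condition, ci])
        lam = expected_intensity(truth, config, condition, bins, chrom)
        upper = np.triu(rng.poisson(np.triu(lam)).astype(float))
        counts = upper + np.triu(upper, 1).T
        out[chrom] = ContactMatrix(bins, chrom, counts, kind="raw")
    return out


# ---------------------------------------------------------------- expression


def simulate_expression(
    truth: PlantedTruth,
    config: SimConfig,
    condition: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial gene counts with compartment-dependent means.

    A-bin genes draw counts with mean exp(mu_a), B-bin genes exp(mu_b), with
    the configured dispersion (0 falls back to Poisson).  Returns a
    DataFrame (gene_id, count).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 100 + condition])
    if truth.genes.empty:
        return pd.DataFrame(columns=["gene_id", "count"])
    labs = truth.gene_labels(condition)
    mean = np.where(labs.to_numpy() == "A", np.exp(config.mu_a), np.exp(config.mu_b))
    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mean)
    return pd.DataFrame({"gene_id": labs.index, "count": counts.astype(int)})


# ------------------------------------------------------------------ pathways


def simulate_pathways(
    truth: PlantedTruth,
    config: SimConfig,
    seed: int | None = None,
) -> PathwayCollection:
    """Decoy pathways plus one pathway enriched for switched-bin genes.

    Decoys draw members uniformly from all genes; the planted pathway draws
    ``planted_frac`` of its members from switched-bin genes (the rest
    uniformly from the remaining genes).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 999])
    all_genes = truth.genes["gene_id"].to_numpy()
    if config.pathway_size > all_genes.size:
        raise ValueError("requested pathway size exceeds the number of genes")
    scgs = np.array(sorted(truth.scg_ids()))
    pathways: dict[str, set[str]] = {}
    n_from_scg = min(int(round(config.planted_frac * config.pathway_size)), scgs.size)
    members = set(rng.choice(scgs, size=n_from_scg, replace=False)) if n_from_scg else set()
    rest_pool = np.array(sorted(set(all_genes) - members))
    extra = config.pathway_size - len(members)
    members |= set(rng.choice(rest_pool, size=extra, replace=False))
    pathways[truth.pathway_id] = members
    for i in range(config.n_decoys):
        pathways[f"decoy_{i:02d}"] = set(
            rng.choice(all_genes, size=config.pathway_size, replace=False)
        )
    descriptions = {name: "synthetic gene set" for name in pathways}
    return PathwayCollection(pathways, descriptions)
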