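"""A/B compartment calling from O/E contact maps.

The per-chromosome O/E matrix is turned into a row-correlation matrix; its
first principal component (E1) separates bins into the two large-scale
chromatin compartments.  After orienting E1 so that it correlates positively
with gene density, bins with E1 > 0 are compartment A (active, gene-rich) and
bins with E1 < 0 are compartment B.  Comparing two samples bin-by-bin yields
stable/switched calls and the switched-compartment gene (SCG) list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMatrix
from .genome import GenomeBins

__all__ = [
    "CompartmentProfile",
    "SwitchCall",
    "correlation_matrix",
    "compute_e1",
    "orient_e1",
    "call_compartments",
    "call_profile",
    "detect_switches",
    "extract_scgs",
    "aggregate_labels",
]

MISSING = ""  # label value for bins without a compartment call


@dataclass
class CompartmentProfile:
    """Per-bin E1 value and A/B label for one sample.

    ``e1`` has one entry per global bin (NaN = missing); it has unit
    Euclidean norm within each chromosome over its non-missing bins.
    """

    bins: GenomeBins
    e1: np.ndarray
    labels: np.ndarray  # 'A' | 'B' | '' per bin

    def label_counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


@dataclass
class SwitchCall:
    """Bin-wise compartment comparison between two samples."""

    bins: GenomeBins
    classes: np.ndarray  # stable_A | stable_B | A_to_B | B_to_A | missing
    switched_fraction: float  # of non-missing bins
    switched_bp_fraction: float  # of non-missing base pairs

    @property
    def switched_bins(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.classes, ["A_to_B", "B_to_A"]))


def correlation_matrix(norm: ContactMatrix) -> tuple[np.ndarray, np.ndarray] | None:
    """Pearson row-correlation matrix of an O/E map.

    Bins whose row is entirely missing are dropped; correlations between the
    remaining rows are computed over mutually non-missing entries (pairwise
    complete observations).  Returns ``(corr, kept)`` where ``kept`` holds the
    local indices of retained bins, or ``None`` for chromosomes with fewer
    than 3 usable bins.
    """
    if norm.kind != "normalized":
        raise ValueError("correlation_matrix expects a normalized (O/E) matrix")
    v = norm.values
    kept = np.flatnonzero(np.isfinite(v).any(axis=1))
    if kept.size < 3:
        warnings.warn(
            f"{norm.chrom}: only {kept.size} usable bins, skipping compartment call"
        )
        return None
    sub = v[np.ix_(kept, kept)]
    corr = pd.DataFrame(sub.T).corr(min_periods=2).to_numpy()
    np.fill_diagonal(corr, 1.0)
    corr[~np.isfinite(corr)] = 0.0  # row pairs with <2 shared finite entries
    corr = (corr + corr.T) / 2
    return corr, kept


def compute_e1(corr: np.ndarray) -> np.ndarray:
    """First principal component of a correlation matrix (unit norm).

    The matrix is column-centered and the leading right singular vector
    returned; the overall sign is fixed deterministically (largest-magnitude
    entry positive) but carries no meaning until :func:`orient_e1`.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.isfinite(c).all():
        raise ValueError("correlation matrix contains non-finite entries")
    centered = c - c.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    e1 = vt[0]
    pivot = int(np.argmax(np.abs(e1)))
    if e1[pivot] < 0:
        e1 = -e1
    return e1


def orient_e1(e1: np.ndarray, gene_density: np.ndarray) -> np.ndarray:
    """Flip E1, if needed, so it correlates non-negatively with gene density.

    Compartment A is the active, gene-rich state; the eigenvector sign is
    arbitrary, so gene density anchors the orientation.  Zero-variance gene
    density leaves the input unchanged with a warning.
    """
    e1 = np.asarray(e1, dtype=float)
    gd = np.asarray(gene_density, dtype=float)
    if e1.shape != gd.shape:
        raise ValueError("e1 and gene_density must have the same length")
    ok = np.isfinite(e1) & np.isfinite(gd)
    if ok.sum() < 2 or np.std(gd[ok]) == 0 or np.std(e1[ok]) == 0:
        warnings.warn("gene density has zero variance; E1 orientation unchanged")
        return e1.copy()
    r, _ = stats.pearsonr(e1[ok], gd[ok])
    return -e1 if r < 0 else e1.copy()


def call_compartments(bins: GenomeBins, e1: np.ndarray) -> CompartmentProfile:
    """Label bins from an oriented E1: > 0 -> A, < 0 -> B, 0 or NaN -> missing."""
    e1 = np.asarray(e1, dtype=float)
    if e1.shape != (bins.n_bins,):
        raise ValueError("e1 length does not match bin system")
    labels = np.full(bins.n_bins, MISSING, dtype="<U1")
    labels[np.nan_to_num(e1) > 0] = "A"
    labels[np.nan_to_num(e1) < 0] = "B"
    labels[~np.isfinite(e1)] = MISSING
    return CompartmentProfile(bins, e1, labels)


def call_profile(
    norm_by_chrom: dict[str, ContactMatrix],
    bins: GenomeBins,
    gene_density: np.ndarray,
) -> CompartmentProfile:
    """Full per-chromosome pipeline: correlation -> E1 -> orientation -> labels.

    ``gene_density`` is the per-global-bin gene count used to orient each
    chromosome's eigenvector.
    """
    e1_full = np.full(bins.n_bins, np.nan)
    for chrom, norm in norm_by_chrom.items():
        result = correlation_matrix(norm)
        if result is None:
            continue
        corr, kept = result
        e1 = compute_e1(corr)
        sl = bins.chrom_slice(chrom)
        gd = np.asarray(gene_density, dtype=float)[sl][kept]
        e1_full[np.arange(sl.start, sl.stop)[kept]] = orient_e1(e1, gd)
    return call_compartments(bins, e1_full)


def detect_switches(p1: CompartmentProfile, p2: CompartmentProfile) -> SwitchCall:
    """Classify each bin as stable, switched (A->B / B->A) or missing."""
    if not p1.bins.same_system(p2.bins):
        raise ValueError("profiles are on different bin systems")
    l1, l2 = p1.labels, p2.labels
    classes = np.full(l1.shape, "missing", dtype="<U8")
    classes[(l1 == "A") & (l2 == "A")] = "stable_A"
    classes[(l1 == "B") & (l2 == "B")] = "stable_B"
    classes[(l1 == "A") & (l2 == "B")] = "A_to_B"
    classes[(l1 == "B") & (l2 == "A")] = "B_to_A"
    non_missing = classes != "missing"
    switched = np.isin(classes, ["A_to_B", "B_to_A"])
    frac = switched.sum() / non_missing.sum() if non_missing.any() else 0.0
    widths = (p1.bins.table["end"] - p1.bins.table["start"]).to_numpy()
    bp_non = widths[non_missing].sum()
    bp_frac = widths[switched].sum() / bp_non if bp_non else 0.0
    return SwitchCall(p1.bins, classes, float(frac), float(bp_frac))


def extract_scgs(switches: SwitchCall, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes whose TSS bin switched compartment, tagged with direction.

    ``genes`` needs columns gene_id, chrom, tss.  Genes whose TSS falls
    outside the binned genome are skipped with a warning.  Returns a
    DataFrame (gene_id, direction, bin_id).
    """
    bins = switches.bins
    rows = []
    skipped = 0
    for gene_id, chrom, tss in genes[["gene_id", "chrom", "tss"]].itertuples(index=False):
        try:
            b = bins.bin_index(chrom, int(tss))
        except (KeyError, ValueError):
            skipped += 1
            continue
        cls = switches.classes[b]
        if cls in ("A_to_B", "B_to_A"):
            rows.append((gene_id, cls, b))
    if skipped:
        warnings.warn(f"{skipped} gene(s) with TSS outside the binned genome skipped")
    return pd.DataFrame(rows, columns=["gene_id", "direction", "bin_id"])


def aggregate_labels(profile: CompartmentProfile, factor: int) -> pd.DataFrame:
    """Majority-vote compartment label over blocks of ``factor`` bins.

    Reports the call at a coarser resolution (e.g. 1 Mb from 500 kb bins);
    ties and all-missing blocks yield a missing label.
    """
    rows = []
    tbl = profile.bins.table
    for chrom in profile.bins.chroms:
        sl = profile.bins.chrom_slice(chrom)
        labs = profile.labels[sl]
        starts = tbl["start"].to_numpy()[sl]
        ends = tbl["end"].to_numpy()[sl]
        for lo in range(0, labs.size, factor):
            block = labs[lo : lo + factor]
            n_a = int((block == "A").sum())
            n_b = int((block == "B").sum())
            lab = "A" if n_a > n_b else "B" if n_b > n_a else MISSING
            rows.append((chrom, int(starts[lo]), int(ends[min(lo + factor, labs.size) - 1]), lab))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
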