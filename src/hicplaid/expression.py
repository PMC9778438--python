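"""Gene expression integration with compartment calls.

FPKM = count * 1e9 / (gene length in bp * library size), the standard
length- and depth-normalized expression unit.  Genes are assigned to
compartment bins by TSS position; per-compartment gene counts and FPKM
distributions quantify the expectation that compartment A is gene-rich and
more highly expressed than compartment B.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentProfile

__all__ = ["compute_fpkm", "compartment_expression", "e1_distribution", "gene_density"]


def compute_fpkm(counts, lengths, library_size: float | None = None) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped reads.

    ``library_size`` defaults to the sum of the supplied counts (override
    with the mapped-read total when available).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must be parallel arrays")
    if np.any(counts < 0):
        raise ValueError("negative read count")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if library_size is None:
        library_size = float(counts.sum())
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return counts * 1e9 / (lengths * library_size)


def _gene_bins(profile: CompartmentProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate genes with their TSS bin and compartment label; skip genes
    whose TSS falls outside the binned genome."""
    rows = []
    skipped = 0
    for t in genes.itertuples(index=False):
        try:
            b = profile.bins.bin_index(t.chrom, int(t.tss))
        except (KeyError, ValueError):
            skipped += 1
            continue
        rows.append((t.gene_id, b, profile.e1[b], profile.labels[b]))
    if skipped:
        warnings.warn(f"{skipped} gene(s) with TSS outside the binned genome skipped")
    return pd.DataFrame(rows, columns=["gene_id", "bin_id", "e1", "label"])


def compartment_expression(
    profile: CompartmentProfile,
    genes: pd.DataFrame,
    fpkm: pd.Series,
) -> dict:
    """Per-compartment gene counts and FPKM distribution summaries.

    ``genes`` needs columns (gene_id, chrom, tss); ``fpkm`` is indexed by
    gene_id.  Returns a dict with per-label counts, median/quartile FPKM,
    and a one-sided rank-sum comparison A > B (descriptive; NaN when either
    compartment is empty).
    """
    mapped = _gene_bins(profile, genes)
    mapped = mapped[mapped["gene_id"].isin(fpkm.index)]
    out: dict = {"per_label": {}, "gene_table": mapped}
    for label in ("A", "B"):
        vals = fpkm.loc[mapped.loc[mapped["label"] == label, "gene_id"]].to_numpy()
        if vals.size == 0:
            warnings.warn(f"no genes in compartment {label}")
            out["per_label"][label] = {
                "count": 0,
                "median": np.nan,
                "q1": np.nan,
                "q3": np.nan,
            }
        else:
            out["per_label"][label] = {
                "count": int(vals.size),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            }
    a = fpkm.loc[mapped.loc[mapped["label"] == "A", "gene_id"]].to_numpy()
    b = fpkm.loc[mapped.loc[mapped["label"] == "B", "gene_id"]].to_numpy()
    if a.size and b.size:
        stat, p = stats.mannwhitneyu(a, b, alternative="greater")
        out["ranksum_A_gt_B"] = {"statistic": float(stat), "p": float(p)}
    else:
        out["ranksum_A_gt_B"] = {"statistic": np.nan, "p": np.nan}
    return out


def e1_distribution(profile: CompartmentProfile, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-bin table (bin_id, e1, n_genes) for export and plotting."""
    counts = np.zeros(profile.bins.n_bins, dtype=int)
    if len(genes):
        mapped = _gene_bins(profile, genes)
        np.add.at(counts, mapped["bin_id"].to_numpy(), 1)
    return pd.DataFrame(
        {
            "bin_id": np.arange(profile.bins.n_bins),
            "e1": profile.e1,
            "n_genes": counts,
        }
    )


def gene_density(genes: pd.DataFrame, bins) -> np.ndarray:
    """Per-global-bin gene count from TSS positions (genes off-genome skipped)."""
    counts = np.zeros(bins.n_bins, dtype=float)
    for t in genes.itertuples(index=False):
        try:
            counts[bins.bin_index(t.chrom, int(t.tss))] += 1
        except (KeyError, ValueError):
            continue
    return counts
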