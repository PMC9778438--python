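"""Binned Hi-C contact matrices and their normalization.

Intra-chromosomal matrices are dense, square and symmetric per chromosome.
Distance-decay normalization divides each observed count O(i, j) by the
expected count E(d) at the same bin separation d = |i - j|, where E(d) is the
per-chromosome mean of observed counts over all pairs at that separation.
Cells with E(d) = 0 carry no information and are flagged missing (NaN).

Interchromosomal contacts are aggregated per chromosome pair; the expected
count for pair (i, j) is f_i * f_j * T where T is the total interchromosomal
read count and f_i the fraction of those reads with one end on chromosome i
(each read contributes to exactly two chromosomes' numerators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins

__all__ = [
    "ContactMatrix",
    "ContactSet",
    "InterchromTable",
    "load_contacts",
    "expected_by_distance",
    "normalize_observed_expected",
    "interchrom_expected",
]

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Square symmetric contact matrix for one chromosome.

    ``kind`` is ``"raw"`` (nonnegative counts) or ``"normalized"``
    (nonnegative O/E ratios with NaN marking missing cells).
    """

    bins: GenomeBins
    chrom: str
    values: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        n = self.bins.chrom_n_bins(self.chrom)
        if v.shape[0] != n:
            raise ValueError(
                f"{self.chrom}: matrix has {v.shape[0]} bins, bin table has {n}"
            )
        finite = np.isfinite(v)
        if self.kind == "raw" and not finite.all():
            raise ValueError("raw matrix contains non-finite entries")
        if np.nanmin(v, initial=0.0, where=finite) < 0:
            raise ValueError("contact matrix contains negative entries")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T), initial=0.0)
        if asym > _SYM_TOL * max(1.0, np.nanmax(np.abs(v), initial=1.0)):
            raise ValueError(f"{self.chrom}: matrix not symmetric (max |A-A^T| = {asym:g})")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class InterchromTable:
    """Observed interchromosomal read counts per chromosome pair (i < j)."""

    pair_counts: dict[tuple[str, str], float]
    chroms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), c in self.pair_counts.items():
            if a == b:
                raise ValueError(f"intra pair ({a}, {b}) in interchromosomal table")
            if c < 0:
                raise ValueError(f"negative count for pair ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            canon[key] = canon.get(key, 0.0) + float(c)
        self.pair_counts = canon
        if not self.chroms:
            seen: list[str] = []
            for a, b in canon:
                for c in (a, b):
                    if c not in seen:
                        seen.append(c)
            self.chroms = sorted(seen)

    @property
    def total(self) -> float:
        return float(sum(self.pair_counts.values()))

    @property
    def fractions(self) -> dict[str, float]:
        """f_i = (interchromosomal reads with one end on i) / T."""
        t = self.total
        f = {c: 0.0 for c in self.chroms}
        for (a, b), c in self.pair_counts.items():
            f[a] += c
            f[b] += c
        if t > 0:
            f = {k: v / t for k, v in f.items()}
        return f


@dataclass
class ContactSet:
    """All matrices loaded from one sample: intra per chromosome + inter table."""

    bins: GenomeBins
    intra: dict[str, ContactMatrix]
    inter: InterchromTable


def load_contacts(triplet_file, bins: GenomeBins) -> ContactSet:
    """Load sparse triplets (bin1_id, bin2_id, count) into per-scope matrices.

    Intra-chromosomal counts are mirrored into both (i, j) and (j, i) for
    off-diagonal pairs; diagonal counts are stored once.  Interchromosomal
    counts are aggregated per chromosome pair.  Total read mass over unique
    pairs is conserved.
    """
    df = pd.read_csv(
        triplet_file,
        sep="\t",
        comment="#",
        header=None,
        names=["bin1", "bin2", "count"],
        dtype={"bin1": "Int64", "bin2": "Int64", "count": float},
    )
    n = bins.n_bins
    if len(df):
        bad = (
            df["bin1"].isna()
            | df["bin2"].isna()
            | (df["bin1"] < 0)
            | (df["bin1"] >= n)
            | (df["bin2"] < 0)
            | (df["bin2"] >= n)
        )
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{triplet_file}: invalid bin id at line {line}")
        if (df["count"] < 0).any():
            line = int(np.flatnonzero((df["count"] < 0).to_numpy())[0]) + 1
            raise ValueError(f"{triplet_file}: negative count at line {line}")

    mats = {
        chrom: np.zeros((bins.chrom_n_bins(chrom),) * 2)
        for chrom in bins.chroms
    }
    pair_counts: dict[tuple[str, str], float] = {}

    if len(df):
        b1 = df["bin1"].to_numpy(dtype=int)
        b2 = df["bin2"].to_numpy(dtype=int)
        cnt = df["count"].to_numpy(dtype=float)
        offsets = np.array([bins.chrom_offset(c) for c in bins.chroms])
        chrom_idx1 = np.searchsorted(offsets, b1, side="right") - 1
        chrom_idx2 = np.searchsorted(offsets, b2, side="right") - 1
        intra_mask = chrom_idx1 == chrom_idx2
        chrom_names = np.array(bins.chroms)

        for ci in np.unique(chrom_idx1[intra_mask]):
            chrom = chrom_names[ci]
            sel = intra_mask & (chrom_idx1 == ci)
            i = b1[sel] - offsets[ci]
            j = b2[sel] - offsets[ci]
            m = mats[chrom]
            np.add.at(m, (i, j), cnt[sel])
            off = i != j
            np.add.at(m, (j[off], i[off]), cnt[sel][off])

        for ci, cj, c in zip(
            chrom_idx1[~intra_mask], chrom_idx2[~intra_mask], cnt[~intra_mask]
        ):
            a, b = sorted((chrom_names[ci], chrom_names[cj]))
            pair_counts[(a, b)] = pair_counts.get((a, b), 0.0) + c

    intra = {
        chrom: ContactMatrix(bins, chrom, m, kind="raw") for chrom, m in mats.items()
    }
    return ContactSet(bins, intra, InterchromTable(pair_counts, chroms=bins.chroms))


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean observed count per bin separation d = 0..n-1 on one chromosome."""
    v = matrix.values
    n = matrix.n
    return np.array([float(np.mean(np.diagonal(v, d))) for d in range(n)])


def normalize_observed_expected(matrix: ContactMatrix) -> ContactMatrix:
    """O/E map: N(i, j) = O(i, j) / E(|i - j|); cells with E = 0 become NaN.

    For every separation d with E(d) > 0 the mean of N over pairs at distance
    d is exactly 1, so normalization removes the distance-decay trend.
    """
    e = expected_by_distance(matrix)
    idx = np.arange(matrix.n)
    d = np.abs(idx[:, None] - idx[None, :])
    ed = e[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(ed > 0, matrix.values / ed, np.nan)
    return ContactMatrix(matrix.bins, matrix.chrom, norm, kind="normalized")


def interchrom_expected(table: InterchromTable) -> pd.DataFrame:
    """Expected and enrichment per chromosome pair: expected = f_i * f_j * T.

    Returns a DataFrame (chrom_i, chrom_j, observed, expected, enrichment)
    over all pairs with an observed entry; enrichment is NaN where the
    expected count is 0 (including the degenerate T = 0 case).
    """
    t = table.total
    f = table.fractions
    rows = []
    if t == 0:
        warnings.warn("interchromosomal total is 0; all expected values undefined")
    for (a, b), obs in sorted(table.pair_counts.items()):
        exp = f[a] * f[b] * t if t > 0 else np.nan
        enr = obs / exp if exp and np.isfinite(exp) and exp > 0 else np.nan
        rows.append((a, b, obs, exp, enr))
    return pd.DataFrame(
        rows, columns=["chrom_i", "chrom_j", "observed", "expected", "enrichment"]
    )
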