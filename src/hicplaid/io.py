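"""Plain-text I/O for the interchange formats the pipeline uses.

All formats are tab-separated text (optionally gzip for triplets via pandas'
transparent compression): two-column chromosome sizes, four-column bin
tables, contact triplets (bin1_id, bin2_id, count over unique pairs),
bedGraph tracks and BED intervals.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, ContactSet
from .genome import GenomeBins, bin_genome

__all__ = [
    "read_chrom_sizes",
    "write_bin_table",
    "read_bin_table",
    "write_contacts",
    "write_bedgraph",
    "write_bed",
    "write_expected",
]


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_bin_table(bins: GenomeBins, path) -> None:
    out = bins.table.copy()
    out["bin_id"] = out.index
    out.to_csv(path, sep="\t", index=False)


def read_bin_table(path) -> GenomeBins:
    """Rebuild a GenomeBins from its exported table (resolution inferred)."""
    df = pd.read_csv(path, sep="\t")
    sizes = df.groupby("chrom", sort=False)["end"].max().astype(int).to_dict()
    resolution = int((df["end"] - df["start"]).max())
    bins = bin_genome(sizes, resolution)
    if not bins.table[["chrom", "start", "end"]].equals(
        df[["chrom", "start", "end"]].astype(bins.table[["chrom", "start", "end"]].dtypes)
    ):
        raise ValueError(f"{path}: bin table is not a uniform tiling")
    return bins


def write_contacts(cset: ContactSet, path) -> None:
    """Write unique-pair triplets (i <= j intra; all inter pairs) as TSV."""
    rows = []
    for chrom, cm in cset.intra.items():
        off = cset.bins.chrom_offset(chrom)
        iu, ju = np.triu_indices(cm.n)
        vals = cm.values[iu, ju]
        nz = vals != 0
        rows.append(
            pd.DataFrame({"bin1": iu[nz] + off, "bin2": ju[nz] + off, "count": vals[nz]})
        )
    # interchromosomal mass is stored per pair; emit one triplet per pair on
    # the first bin of each chromosome (aggregate representation)
    for (a, b), c in cset.inter.pair_counts.items():
        rows.append(
            pd.DataFrame(
                {
                    "bin1": [cset.bins.chrom_offset(a)],
                    "bin2": [cset.bins.chrom_offset(b)],
                    "count": [c],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["bin1", "bin2", "count"]
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(bins: GenomeBins, values: np.ndarray, path) -> None:
    out = bins.table.copy()
    out["value"] = values
    out.dropna(subset=["value"]).to_csv(path, sep="\t", index=False, header=False)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = ["chrom", "start", "end"]
    out = intervals[cols].copy()
    if name_col is not None:
        out["name"] = intervals[name_col]
    out.to_csv(path, sep="\t", index=False, header=False)


def write_expected(expected: np.ndarray, path) -> None:
    pd.DataFrame({"distance": np.arange(len(expected)), "expected": expected}).to_csv(
        path, sep="\t", index=False
    )


def contact_matrix_from_dense(bins: GenomeBins, chrom: str, values) -> ContactMatrix:
    """Convenience constructor for tests and examples."""
    return ContactMatrix(bins, chrom, np.asarray(values, dtype=float), kind="raw")
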