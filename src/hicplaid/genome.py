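"""Fixed-width genomic bins: the coordinate system shared by all matrices.

Bins tile each chromosome left to right without gaps or overlaps; the last
bin of a chromosome may be shorter than the nominal resolution.  Global bin
ids are dense ``0..N-1`` in (chromosome order, start) order, where the
chromosome order is the insertion order of the ``chrom_sizes`` mapping.
All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "bin_genome"]


@dataclass(frozen=True)
class GenomeBins:
    """Ordered fixed-width genomic intervals over a set of chromosomes."""

    chrom_sizes: dict[str, int]
    resolution: int
    table: pd.DataFrame = field(repr=False)  # columns chrom, start, end; index = bin_id

    def __post_init__(self) -> None:
        offsets: dict[str, int] = {}
        counts: dict[str, int] = {}
        pos = 0
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // self.resolution)  # ceil division
            offsets[chrom] = pos
            counts[chrom] = n
            pos += n
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_counts", counts)

    # ------------------------------------------------------------------ basics
    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_n_bins(self, chrom: str) -> int:
        return self._counts[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._counts[chrom])

    # ------------------------------------------------------------- coordinates
    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin id containing position ``pos`` on ``chrom``.

        Raises ``KeyError`` for an unknown chromosome and ``ValueError`` for a
        position outside ``[0, chrom_size)``.
        """
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < size):
            raise ValueError(f"position {pos} outside [0, {size}) on {chrom}")
        return self._offsets[chrom] + int(pos) // self.resolution

    def bin_indices(self, chroms, positions) -> np.ndarray:
        """Vectorized :meth:`bin_index` over parallel chrom/position arrays."""
        return np.array(
            [self.bin_index(c, p) for c, p in zip(chroms, positions)], dtype=int
        )

    def starts(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.chrom_slice(chrom), "start"].to_numpy()

    def midpoints(self, chrom: str) -> np.ndarray:
        sub = self.table.iloc[self.chrom_slice(chrom)]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(int)

    def same_system(self, other: "GenomeBins") -> bool:
        return (
            self.resolution == other.resolution
            and self.chrom_sizes == other.chrom_sizes
        )


def bin_genome(chrom_sizes: dict[str, int], resolution: int) -> GenomeBins:
    """Tile each chromosome into ``resolution``-wide bins.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp; order defines bin-id order.
    resolution
        Bin width in bp.

    Returns
    -------
    GenomeBins with ``ceil(size / resolution)`` bins per chromosome and dense
    global ids.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has nonpositive size {size}")

    records = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, resolution, dtype=int)
        ends = np.minimum(starts + resolution, size)
        records.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    table = pd.concat(records, ignore_index=True)
    table.index.name = "bin_id"
    return GenomeBins(dict(chrom_sizes), int(resolution), table)
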