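"""Genome bin tables.

All genomic coordinates in this package are 0-based, half-open. Within a
chromosome, bins are contiguous, non-overlapping and sorted; the last bin of a
chromosome may be shorter than the nominal bin size. Bin indices are global
(concatenated over chromosomes in input order) and monotone in
(chromosome order, start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinTable:
    """Fixed binning of a genome at a single resolution.

    Parameters
    ----------
    chromsizes
        Ordered mapping of chromosome name to length in bp.
    bin_size
        Nominal bin width in bp (> 0).
    """

    chromsizes: dict[str, int]
    bin_size: int
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromsizes:
            raise ValueError("empty genome: no chromosomes given")
        if len(set(self.chromsizes)) != len(self.chromsizes):
            raise ValueError("duplicate chromosome name")
        offsets: dict[str, int] = {}
        total = 0
        for name, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            offsets[name] = total
            total += self.n_bins_of(name)
        object.__setattr__(self, "_offsets", offsets)

    # -- sizes ------------------------------------------------------------
    def n_bins_of(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chromsizes)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromsizes)

    def offset(self, chrom: str) -> int:
        """Global index of the first bin of ``chrom``."""
        return self._offsets[chrom]

    # -- index <-> coordinate ---------------------------------------------
    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of genomic position ``pos`` on ``chrom``."""
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with global index ``index``."""
        if not 0 <= index < self.n_bins:
            raise IndexError(index)
        for chrom in self.chromsizes:
            n = self.n_bins_of(chrom)
            off = self._offsets[chrom]
            if index < off + n:
                local = index - off
                start = local * self.bin_size
                end = min(start + self.bin_size, self.chromsizes[chrom])
                return chrom, start, end
        raise IndexError(index)  # pragma: no cover

    def to_frame(self) -> pd.DataFrame:
        """Bin table as a DataFrame with columns chrom, start, end."""
        rows = []
        for chrom, length in self.chromsizes.items():
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self.n_bins_of(chrom))


def make_bins(chromsizes: dict[str, int], bin_size: int) -> BinTable:
    """Build a :class:`BinTable` with ``ceil(length / bin_size)`` bins per chromosome."""
    return BinTable(dict(chromsizes), int(bin_size))


def read_chromsizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV into an ordered mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chromsizes(chromsizes: dict[str, int], path) -> None:
    pd.DataFrame(list(chromsizes.items())).to_csv(path, sep="\t", header=False, index=False)
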