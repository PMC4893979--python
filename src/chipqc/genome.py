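"""Genome layout and mapped-read containers.

All coordinates are 0-based, half-open (BED convention) throughout the
package; there is no 1-based interface anywhere.  A :class:`GenomeLayout`
fixes the binning grid once: each chromosome is tiled with half-open
windows ``[k*w, (k+1)*w)`` of width ``w`` (500 nt by default), the last
window truncated at the chromosome end.  Every per-bin quantity in the
package (read counts, dispersion, IDR windows) lives on this grid and is
addressed by a single *global bin index* that concatenates the
chromosomes in layout order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GenomeLayout", "MappedReadSet", "STRAND_CODES", "STRAND_CHARS"]

# strand encoding used in the read arrays
STRAND_CHARS = np.array(["+", "-", "."], dtype="U1")
STRAND_CODES = {"+": 0, "-": 1, ".": 2}


class LayoutError(ValueError):
    """Invalid genome layout definition."""


class ReadSetError(ValueError):
    """Invalid mapped-read records for a given layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths and the fixed binning grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in bp.
    bin_width
        Width of the counting windows in bp (default 500).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_width: int = 500

    # derived, filled in __post_init__
    _names: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _lengths: np.ndarray = field(init=False, repr=False, compare=False)
    _n_bins: np.ndarray = field(init=False, repr=False, compare=False)
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not chroms:
            raise LayoutError("layout must declare at least one chromosome")
        names = tuple(n for n, _ in chroms)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LayoutError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        lengths = np.array([l for _, l in chroms], dtype=np.int64)
        if (lengths <= 0).any():
            bad = names[int(np.argmax(lengths <= 0))]
            raise LayoutError(f"non-positive length for chromosome {bad!r}")
        if self.bin_width <= 0:
            raise LayoutError(f"bin_width must be > 0, got {self.bin_width}")
        n_bins = -(-lengths // self.bin_width)  # ceil division
        offsets = np.concatenate([[0], np.cumsum(n_bins)])
        object.__setattr__(self, "_names", names)
        object.__setattr__(self, "_lengths", lengths)
        object.__setattr__(self, "_n_bins", n_bins)
        object.__setattr__(self, "_offsets", offsets)

    # ------------------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def lengths(self) -> np.ndarray:
        """Chromosome lengths (bp), layout order."""
        return self._lengths

    @property
    def total_length(self) -> int:
        return int(self._lengths.sum())

    @property
    def n_chromosomes(self) -> int:
        return len(self._names)

    @property
    def total_bins(self) -> int:
        return int(self._offsets[-1])

    def n_bins(self, chrom: str) -> int:
        return int(self._n_bins[self.chrom_index(chrom)])

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._names.index(chrom)
        except ValueError:
            raise LayoutError(f"chromosome {chrom!r} not in layout") from None

    def bin_offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        return self._offsets[:-1]

    def global_bin(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Global bin index of position ``pos`` on chromosome ``chrom_idx``."""
        return self._offsets[chrom_idx] + pos // self.bin_width

    def bin_intervals(self, bins: np.ndarray) -> "pd.DataFrame":  # noqa: F821
        """(chrom, start, end) table for global bin indices ``bins``."""
        import pandas as pd

        bins = np.asarray(bins, dtype=np.int64)
        if bins.size and (bins.min() < 0 or bins.max() >= self.total_bins):
            raise LayoutError("bin index outside layout")
        chrom_idx = np.searchsorted(self._offsets, bins, side="right") - 1
        local = bins - self._offsets[chrom_idx]
        start = local * self.bin_width
        end = np.minimum(start + self.bin_width, self._lengths[chrom_idx])
        return pd.DataFrame(
            {
                "chrom": np.asarray(self._names, dtype=object)[chrom_idx],
                "start": start,
                "end": end,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return (
            self.chromosomes == other.chromosomes
            and self.bin_width == other.bin_width
        )

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.bin_width))


class MappedReadSet:
    """A collection of genome-aligned reads on a :class:`GenomeLayout`.

    Reads are held as parallel numpy arrays (chromosome index, start, end,
    strand code) so that subsampling and binning stay vectorised even at
    tens of millions of reads.  ``len(reads)`` (the *TMR count*, total
    mapped reads) is the sequencing-depth measure used throughout.
    """

    __slots__ = ("layout", "chrom_idx", "start", "end", "strand", "n_skipped")

    def __init__(
        self,
        layout: GenomeLayout,
        chrom_idx: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,
        *,
        n_skipped: int = 0,
        validate: bool = True,
    ) -> None:
        self.layout = layout
        self.chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = np.asarray(strand, dtype=np.int8)
        self.n_skipped = int(n_skipped)
        n = len(self.chrom_idx)
        if not (len(self.start) == len(self.end) == len(self.strand) == n):
            raise ReadSetError("read arrays have unequal lengths")
        if validate and n:
            self._validate()

    def _validate(self) -> None:
        if self.chrom_idx.size == 0:
            return
        if self.chrom_idx.min() < 0 or self.chrom_idx.max() >= self.layout.n_chromosomes:
            raise ReadSetError("chromosome index outside layout")
        if (self.start < 0).any():
            raise ReadSetError("negative start coordinate")
        if (self.start >= self.end).any():
            i = int(np.argmax(self.start >= self.end))
            raise ReadSetError(
                f"record {i}: start >= end ({self.start[i]} >= {self.end[i]})"
            )
        lengths = self.layout.lengths[self.chrom_idx]
        if (self.end > lengths).any():
            i = int(np.argmax(self.end > lengths))
            raise ReadSetError(
                f"record {i}: end {self.end[i]} exceeds chromosome length "
                f"{int(lengths[i])} of {self.layout.names[self.chrom_idx[i]]!r}; "
                "reads spanning a chromosome end indicate a layout/reads mismatch"
            )

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        layout: GenomeLayout,
        *,
        n_skipped: int = 0,
    ) -> "MappedReadSet":
        """Build from an iterable of ``(chrom, start, end[, strand])`` tuples."""
        recs = list(records)
        n = len(recs)
        chrom_idx = np.empty(n, dtype=np.int32)
        start = np.empty(n, dtype=np.int64)
        end = np.empty(n, dtype=np.int64)
        strand = np.full(n, STRAND_CODES["."], dtype=np.int8)
        for i, rec in enumerate(recs):
            chrom_idx[i] = layout.chrom_index(rec[0])
            start[i] = rec[1]
            end[i] = rec[2]
            if len(rec) > 3:
                strand[i] = STRAND_CODES.get(str(rec[3]), STRAND_CODES["."])
        return cls(layout, chrom_idx, start, end, strand, n_skipped=n_skipped)

    @property
    def tmr(self) -> int:
        """Total mapped reads."""
        return len(self.chrom_idx)

    def __len__(self) -> int:
        return self.tmr

    def subset(self, indices: np.ndarray) -> "MappedReadSet":
        """A new read set containing the records at ``indices`` (input order preserved)."""
        idx = np.sort(np.asarray(indices))
        return MappedReadSet(
            self.layout,
            self.chrom_idx[idx],
            self.start[idx],
            self.end[idx],
            self.strand[idx],
            validate=False,
        )

    def midpoints(self) -> np.ndarray:
        """Integer midpoint floor((start+end)/2) of every read."""
        return (self.start + self.end) // 2

    def sorted(self) -> "MappedReadSet":
        """Records ordered by (chromosome, start, end)."""
        order = np.lexsort((self.end, self.start, self.chrom_idx))
        return MappedReadSet(
            self.layout,
            self.chrom_idx[order],
            self.start[order],
            self.end[order],
            self.strand[order],
            validate=False,
        )

    def deduplicated(self) -> "MappedReadSet":
        """Drop exact duplicate records (same chrom, start, end, strand).

        Exposed as an optional pass-through; duplicate handling prior to QC
        is left to the caller and is off by default everywhere.
        """
        key = np.stack(
            [self.chrom_idx.astype(np.int64), self.start, self.end, self.strand.astype(np.int64)]
        )
        _, first = np.unique(key, axis=1, return_index=True)
        return self.subset(first)

    def to_frame(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": np.asarray(self.layout.names, dtype=object)[self.chrom_idx],
                "start": self.start,
                "end": self.end,
                "strand": STRAND_CHARS[self.strand],
            }
        )

    def checksum(self) -> str:
        """Order-insensitive content hash used for certificate provenance."""
        import hashlib

        s = self.sorted()
        h = hashlib.sha256()
        for arr in (s.chrom_idx, s.start, s.end, s.strand):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]
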