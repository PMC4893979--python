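"""Readers and writers for the tabular genomic formats the pipeline touches.

BED3+/BED6 reads, two-column ``chrom.sizes`` tables and bedGraph tracks,
plus a thin pysam adapter for SAM/BAM alignments.  Parsing and validation
only — no computation lives here.  Everything is 0-based half-open.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .genome import GenomeLayout, MappedReadSet, STRAND_CHARS, STRAND_CODES

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_alignments",
    "write_bedgraph",
    "read_bedgraph",
    "BedParseError",
]

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """Malformed line in a BED-like file; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def read_chrom_sizes(path: PathLike, bin_width: int = 500) -> GenomeLayout:
    """Read a two-column name/length table into a :class:`GenomeLayout`.

    Duplicate chromosome names and non-positive lengths are errors.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1],
        names=["chrom", "length"],
        dtype={"chrom": str},
        comment="#",
    )
    if table.empty:
        raise ValueError(f"{path}: empty chromosome-sizes table")
    lengths = pd.to_numeric(table["length"], errors="coerce")
    if lengths.isna().any():
        lineno = int(lengths.isna().idxmax()) + 1
        raise BedParseError(path, lineno, f"non-integer length {table['length'][lineno - 1]!r}")
    chroms = tuple(zip(table["chrom"], lengths.astype(np.int64)))
    return GenomeLayout(chroms, bin_width=bin_width)


def read_bed(
    path: PathLike,
    layout: GenomeLayout,
    *,
    strict: bool = False,
    deduplicate: bool = False,
) -> MappedReadSet:
    """Read a BED3+/BED6 file of mapped reads against ``layout``.

    Records on chromosomes not declared in the layout are an error when
    ``strict`` is true; otherwise they are excluded and their count is
    reported via a warning and ``MappedReadSet.n_skipped``.  Coordinates
    must satisfy ``0 <= start < end <= chromosome length``; violations
    raise :class:`BedParseError` naming the offending line.
    """
    try:
        # fixed 12-column frame: tolerates track/browser/comment lines and
        # the varying column counts of BED3..BED12
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=range(12),
            comment=None,
            dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty BED file", stacklevel=2)
        return _empty_read_set(layout)

    raw_first = table[0]
    first = raw_first.fillna("").astype(str)
    keep = ~(first.str.startswith(_SKIP_PREFIXES) | (first.str.strip() == ""))
    lineno = np.flatnonzero(keep.to_numpy()) + 1  # 1-based source line of each record
    table = table[keep]
    if table.empty:
        warnings.warn(f"{path}: no records in BED file", stacklevel=2)
        return _empty_read_set(layout)

    start = pd.to_numeric(table[1], errors="coerce")
    end = pd.to_numeric(table[2], errors="coerce")
    for col, vals in (("start", start), ("end", end)):
        bad = vals.isna().to_numpy()
        if bad.any():
            i = int(np.argmax(bad))
            raise BedParseError(path, int(lineno[i]), f"non-integer {col} coordinate {table.iloc[i][1 if col == 'start' else 2]!r}")
    start = start.to_numpy(np.int64)
    end = end.to_numpy(np.int64)

    bad = start >= end
    if bad.any():
        i = int(np.argmax(bad))
        raise BedParseError(path, int(lineno[i]), f"start >= end ({start[i]} >= {end[i]})")
    bad = start < 0
    if bad.any():
        i = int(np.argmax(bad))
        raise BedParseError(path, int(lineno[i]), f"negative start {start[i]}")

    chroms = table[0].to_numpy(dtype=object)
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    chrom_idx = np.array([name_to_idx.get(c, -1) for c in chroms], dtype=np.int32)
    unknown = chrom_idx < 0
    n_skipped = int(unknown.sum())
    if n_skipped:
        if strict:
            i = int(np.argmax(unknown))
            raise BedParseError(path, int(lineno[i]), f"chromosome {chroms[i]!r} not in layout")
        warnings.warn(
            f"{path}: skipped {n_skipped} record(s) on chromosomes not in the layout",
            stacklevel=2,
        )
        keep_mask = ~unknown
        chrom_idx = chrom_idx[keep_mask]
        start = start[keep_mask]
        end = end[keep_mask]
        table = table[keep_mask]
        lineno = lineno[keep_mask]

    # reads running past a chromosome end indicate a layout/reads mismatch
    over = end > layout.lengths[chrom_idx]
    if over.any():
        i = int(np.argmax(over))
        raise BedParseError(
            path,
            int(lineno[i]),
            f"end {end[i]} exceeds length of {layout.names[chrom_idx[i]]!r} "
            f"({int(layout.lengths[chrom_idx[i]])}); reads must not span chromosome ends",
        )

    strand = np.array(
        [STRAND_CODES.get(s, STRAND_CODES["."]) for s in table[5].fillna(".").astype(str)],
        dtype=np.int8,
    )

    reads = MappedReadSet(
        layout, chrom_idx, start, end, strand, n_skipped=n_skipped, validate=False
    )
    if deduplicate:
        reads = reads.deduplicated()
        reads.n_skipped = n_skipped
    return reads


def _empty_read_set(layout: GenomeLayout) -> MappedReadSet:
    z = np.empty(0)
    return MappedReadSet(layout, z, np.empty(0), np.empty(0), np.empty(0), validate=False)


def write_bed(reads: MappedReadSet, path: PathLike, *, name: str = ".", score: int = 0) -> None:
    """Write a read set as BED6 (chrom, start, end, name, score, strand)."""
    frame = reads.to_frame()
    frame.insert(3, "name", name)
    frame.insert(4, "score", score)
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_alignments(
    path: PathLike,
    layout: GenomeLayout,
    *,
    strict: bool = False,
    mode: Optional[str] = None,
) -> MappedReadSet:
    """Adapter: load mapped records from a SAM/BAM file via pysam.

    Only reference name, 0-based start, end and strand are taken from each
    mapped, primary, non-supplementary alignment; the core pipeline never
    sees alignment-specific fields.
    """
    import pysam

    chrom_idx_l: list[int] = []
    start_l: list[int] = []
    end_l: list[int] = []
    strand_l: list[int] = []
    n_skipped = 0
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            ci = name_to_idx.get(aln.reference_name, -1)
            if ci < 0:
                if strict:
                    raise ValueError(
                        f"{path}: alignment on chromosome {aln.reference_name!r} not in layout"
                    )
                n_skipped += 1
                continue
            chrom_idx_l.append(ci)
            start_l.append(aln.reference_start)
            end_l.append(aln.reference_end)
            strand_l.append(STRAND_CODES["-"] if aln.is_reverse else STRAND_CODES["+"])
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} alignment(s) on chromosomes not in the layout",
            stacklevel=2,
        )
    return MappedReadSet(
        layout,
        np.array(chrom_idx_l, dtype=np.int32),
        np.array(start_l, dtype=np.int64),
        np.array(end_l, dtype=np.int64),
        np.array(strand_l, dtype=np.int8),
        n_skipped=n_skipped,
    )


def write_bedgraph(
    values: np.ndarray,
    layout: GenomeLayout,
    path: PathLike,
    *,
    bins: Optional[np.ndarray] = None,
    track_name: str = "chipqc",
    merge: bool = False,
) -> None:
    """Write a per-bin numeric track as bedGraph (0-based, half-open).

    ``values`` is either one value per bin of the layout, or a sparse
    vector aligned with the global bin indices in ``bins``.  Adjacent
    equal-valued bins are merged when ``merge`` is true.
    """
    values = np.asarray(values)
    if bins is None:
        if len(values) != layout.total_bins:
            raise ValueError(
                f"dense track has {len(values)} values for {layout.total_bins} bins"
            )
        bins = np.arange(layout.total_bins, dtype=np.int64)
    else:
        bins = np.asarray(bins, dtype=np.int64)
        if len(bins) != len(values):
            raise ValueError("bins and values have unequal lengths")
        if bins.size and (bins.min() < 0 or bins.max() >= layout.total_bins):
            raise ValueError("bin index outside layout")

    header = f'track type=bedGraph name="{track_name}"\n'
    if values.size == 0:
        Path(path).write_text(header)
        return

    order = np.argsort(bins, kind="stable")
    bins = bins[order]
    values = values[order]
    ivals = layout.bin_intervals(bins)
    chrom = ivals["chrom"].to_numpy(dtype=object)
    start = ivals["start"].to_numpy(np.int64)
    end = ivals["end"].to_numpy(np.int64)

    if merge and len(bins) > 1:
        # merge runs of consecutive bins on one chromosome sharing a value
        same = (
            (bins[1:] == bins[:-1] + 1)
            & (chrom[1:] == chrom[:-1])
            & (values[1:] == values[:-1])
        )
        run_start = np.concatenate([[0], np.flatnonzero(~same) + 1])
        run_end = np.concatenate([run_start[1:], [len(bins)]]) - 1
        chrom = chrom[run_start]
        start = start[run_start]
        end = end[run_end]
        values = values[run_start]

    with open(path, "w") as fh:
        fh.write(header)
        frame = pd.DataFrame({"chrom": chrom, "start": start, "end": end, "value": values})
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_bedgraph(path: PathLike, layout: GenomeLayout) -> tuple[np.ndarray, np.ndarray]:
    """Read a bedGraph written by :func:`write_bedgraph` back to (bins, values).

    Merged runs are expanded to per-bin entries, so a write/read round trip
    reproduces the original dense or sparse track exactly.
    """
    try:
        table = pd.read_csv(path, sep="\t", header=None, comment=None, dtype=str, skiprows=_count_header_lines(path))
    except pd.errors.EmptyDataError:
        return np.empty(0, dtype=np.int64), np.empty(0)
    chrom = table[0].to_numpy(dtype=object)
    start = table[1].to_numpy(np.int64)
    end = table[2].to_numpy(np.int64)
    value = table[3].to_numpy(np.float64)
    w = layout.bin_width
    offsets = layout.bin_offsets()
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    bins_l: list[np.ndarray] = []
    vals_l: list[np.ndarray] = []
    for c, s, e, v in zip(chrom, start, end, value):
        ci = name_to_idx.get(c)
        if ci is None:
            raise ValueError(f"{path}: chromosome {c!r} not in layout")
        b0 = offsets[ci] + s // w
        b1 = offsets[ci] + (e - 1) // w + 1
        bins_l.append(np.arange(b0, b1, dtype=np.int64))
        vals_l.append(np.full(b1 - b0, v))
    return np.concatenate(bins_l), np.concatenate(vals_l)


def _count_header_lines(path: PathLike) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(_SKIP_PREFIXES):
                n += 1
            else:
                break
    return n
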