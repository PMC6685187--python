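"""Readers and writers for the plain-text formats the pipeline exchanges.

Strict coordinate conventions: BED and all in-memory structures are 0-based
half-open; fixedStep wiggle is written 1-based as its format requires, and
converted back on read. The adapter flag of a read, absent from standard BED,
travels as an ``adapter=0|1`` token inside the BED name field.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np

from .core import AlignedRead, ChromatinStateAnnotation, GenomicInterval, OccupancyTrack

TRACK_DIALECTS = ("fixedStep-wiggle", "bedGraph")


class BedParseError(ValueError):
    pass


def _parse_bed_line(line: str, lineno: int, path: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"{path}, line {lineno}: expected >= 3 BED fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}, line {lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, name=name)
    except ValueError as exc:
        raise BedParseError(f"{path}, line {lineno}: {exc}") from exc


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, 0-based half-open preserved."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno, path))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str,
              scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_reads_bed(path: str, default_adapter: bool = True) -> list[AlignedRead]:
    """Read MNase reads from BED.

    The adapter flag is recovered from an ``adapter=0|1`` token in the name
    field when present; otherwise ``default_adapter`` applies (public BED
    exports usually lack the bit).
    """
    reads = []
    for iv in read_bed(path):
        flag = default_adapter
        if iv.name:
            for token in iv.name.split(";"):
                if token.startswith("adapter="):
                    flag = token.split("=", 1)[1] not in ("0", "false", "False")
        reads.append(AlignedRead(interval=iv, reached_adapter=flag))
    return reads


def write_reads_bed(reads: Sequence[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            base = iv.name if iv.name is not None else f"read{i}"
            name = f"{base};adapter={int(r.reached_adapter)}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_sam_reads(path: str, default_adapter: bool = True) -> list[AlignedRead]:
    """Minimal SAM reader: mapped reads converted to intervals immediately.

    Only position, CIGAR reference span and the strand bit are used; all
    other flags are ignored because the downstream analysis needs intervals
    only. 1-based SAM positions are converted to 0-based half-open.
    """
    import re

    cig_re = re.compile(r"(\d+)([MIDNSHP=X])")
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4:  # unmapped
                continue
            chrom, pos, cigar = f[2], int(f[3]) - 1, f[5]
            span = sum(int(n) for n, op in cig_re.findall(cigar) if op in "MDN=X")
            if span == 0:
                continue
            strand = "-" if flag & 0x10 else "+"
            iv = GenomicInterval(chrom=chrom, start=pos, end=pos + span,
                                 strand=strand, name=f[0])
            reads.append(AlignedRead(interval=iv, reached_adapter=default_adapter))
    return reads


def read_states_bed(path: str) -> list[ChromatinStateAnnotation]:
    """Chromatin-state BED: the name column carries the CS1..CS9 label."""
    out = []
    for iv in read_bed(path):
        if iv.name is None:
            raise BedParseError(f"{path}: state BED requires a name column")
        out.append(ChromatinStateAnnotation(interval=iv, state=iv.name))
    return out


# ---------------------------------------------------------------------------
# Occupancy track I/O


def write_track(track: OccupancyTrack, path: str, dialect: str = "fixedStep-wiggle") -> None:
    """Write a binned track as fixedStep wiggle (1-based) or bedGraph (0-based)."""
    if dialect not in TRACK_DIALECTS:
        raise ValueError(f"unknown track dialect {dialect!r}; choose from {TRACK_DIALECTS}")
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chroms():
            vals = track.data[chrom]
            if dialect == "fixedStep-wiggle":
                fh.write(f"fixedStep chrom={chrom} start=1 step={bw} span={bw}\n")
                for v in vals:
                    fh.write(f"{v:.6f}\n")
            else:
                for i, v in enumerate(vals):
                    fh.write(f"{chrom}\t{i * bw}\t{(i + 1) * bw}\t{v:.6f}\n")


def read_track(path: str) -> OccupancyTrack:
    """Read a track written by :func:`write_track` (dialect auto-detected)."""
    data: dict[str, list[float]] = {}
    bin_width = 10
    with open(path) as fh:
        first = True
        fixed_chrom = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                fixed_chrom = kv["chrom"]
                bin_width = int(kv["step"])
                data.setdefault(fixed_chrom, [])
                first = False
                continue
            if fixed_chrom is not None:
                data[fixed_chrom].append(float(line))
            else:
                f = line.split("\t")
                chrom, start, end, v = f[0], int(f[1]), int(f[2]), float(f[3])
                if first:
                    bin_width = end - start
                    first = False
                data.setdefault(chrom, []).append(v)
    return OccupancyTrack(
        data={c: np.asarray(v, dtype=float) for c, v in data.items()},
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# Images


def read_image(path: str, pixel_size_nm: float = 2.0, channel: Optional[int] = None):
    """Read a grayscale TIFF/PNG into a float array with attached pixel size.

    Multi-channel images require an explicit ``channel``; the default pixel
    size of 2 nm matches transmission-EM acquisition at 24,500x magnification.
    Returns ``(array, pixel_size_nm)``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel image; pass channel= to select one"
            )
        axis = int(np.argmin(arr.shape))  # channel axis is the short one
        arr = np.take(arr, channel, axis=axis)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return arr.astype(float), float(pixel_size_nm)
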