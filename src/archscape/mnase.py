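"""Nucleosome positioning from single-end MNase-seq reads.

The pipeline mirrors how full-fragment single-end MNase libraries are
analysed when fragments are sequenced end to end: reads that ran through the
terminal adapter and fall in the mononucleosomal size range (147-220 bp,
inclusive) are kept; their centers approximate nucleosome dyads; the highest
center-coverage positions are selected greedily, each peak claiming the
footprint of the longest read observed at its center; consecutive peak-to-peak
distances then yield the nucleosome repeat length (NRL) distribution, which
is summarised in 10-bp histogram bins and in three biologically meaningful
spacing groups (short < 160 bp, mid 160-200 bp, long > 200 bp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import AlignedRead, GenomicInterval

DEFAULT_MIN_LEN = 147
DEFAULT_MAX_LEN = 220
NRL_SHORT_BOUND = 160  # distances < 160 bp are "short"
NRL_LONG_BOUND = 200   # distances > 200 bp are "long"; 160 and 200 are "mid"


def filter_full_length(
    reads: Iterable[AlignedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    require_adapter: bool = True,
) -> list[AlignedRead]:
    """Keep fully sequenced reads in the mononucleosomal length range.

    Both bounds are inclusive. Reads whose sequencing did not reach the
    terminal adapter have an unknown true fragment length and are dropped
    unless ``require_adapter`` is disabled.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [
        r
        for r in reads
        if min_len <= r.length <= max_len and (r.reached_adapter or not require_adapter)
    ]


def exclude_regions(
    reads: Sequence[AlignedRead], blacklist: Sequence[GenomicInterval]
) -> list[AlignedRead]:
    """Drop every read overlapping any blacklist interval (half-open semantics).

    Used to remove reads falling in residual introgressed segments of a
    foreign accession background, whose coordinates arrive as a BED file.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        # running maximum of ends lets a single searchsorted answer
        # "does any interval starting before x reach past y"
        ends_cummax = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[chrom] = (starts, ends_cummax)

    kept = []
    for r in reads:
        iv = r.interval
        hit = False
        if iv.chrom in index:
            starts, ends_cummax = index[iv.chrom]
            k = np.searchsorted(starts, iv.end, side="left")
            if k > 0 and ends_cummax[k - 1] > iv.start:
                hit = True
        if not hit:
            kept.append(r)
    return kept


def read_center(read: AlignedRead) -> int:
    """Center of ``[s, e)`` as ``floor((s + e) / 2)``."""
    return (read.interval.start + read.interval.end) // 2


@dataclass
class CenterPileup:
    """Per-chromosome pileup of read centers.

    ``counts[chrom][pos]`` is the number of read centers at ``pos``;
    ``longest[chrom][pos]`` is the interval of the longest read whose center
    is ``pos`` (ties broken toward the leftmost start).
    """

    counts: dict[str, dict[int, int]] = field(default_factory=dict)
    longest: dict[str, dict[int, GenomicInterval]] = field(default_factory=dict)
    n_reads: int = 0


def pileup_centers(reads: Iterable[AlignedRead]) -> CenterPileup:
    pileup = CenterPileup()
    for r in reads:
        chrom = r.interval.chrom
        c = read_center(r)
        counts = pileup.counts.setdefault(chrom, {})
        longest = pileup.longest.setdefault(chrom, {})
        counts[c] = counts.get(c, 0) + 1
        cur = longest.get(c)
        if cur is None or (r.length, -r.interval.start) > (cur.length, -cur.start):
            longest[c] = r.interval
        pileup.n_reads += 1
    return pileup


@dataclass(frozen=True)
class NucleosomePeak:
    """A called nucleosome position.

    ``boundary`` is the interval of the longest read contributing to the
    center, and ``coverage`` the number of read centers at that position.
    """

    chrom: str
    center: int
    boundary: GenomicInterval
    coverage: int

    def __post_init__(self) -> None:
        if not (self.boundary.start <= self.center < self.boundary.end):
            raise ValueError("peak center outside its boundary")
        if self.coverage < 1:
            raise ValueError("peak coverage must be >= 1")


def call_peaks_greedy(pileup: CenterPileup, min_count: int = 1) -> list[NucleosomePeak]:
    """Greedy nucleosome peak calling on a center pileup.

    Candidate positions are visited in order of decreasing center count
    (ties: leftmost first). A candidate is accepted iff its boundary -- the
    longest contributing read's interval -- does not overlap the boundary of
    any peak already accepted (half-open intersection; touching is allowed).
    The result is returned sorted by coordinate and its boundaries are
    guaranteed mutually non-overlapping.
    """
    peaks: list[NucleosomePeak] = []
    for chrom in sorted(pileup.counts):
        counts = pileup.counts[chrom]
        longest = pileup.longest[chrom]
        positions = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        cnts = np.fromiter((counts[p] for p in positions), dtype=np.int64,
                           count=len(positions))
        keep = cnts >= min_count
        positions, cnts = positions[keep], cnts[keep]
        if positions.size == 0:
            continue
        order = np.lexsort((positions, -cnts))
        max_end = max(longest[p].end for p in positions)
        occupied = np.zeros(max_end, dtype=bool)
        for idx in order:
            pos = int(positions[idx])
            b = longest[pos]
            if occupied[b.start : b.end].any():
                continue
            occupied[b.start : b.end] = True
            peaks.append(
                NucleosomePeak(chrom=chrom, center=pos, boundary=b,
                               coverage=int(cnts[idx]))
            )
    peaks.sort(key=lambda p: (p.chrom, p.center))
    _assert_non_overlapping(peaks)
    return peaks


def _assert_non_overlapping(peaks: Sequence[NucleosomePeak]) -> None:
    for a, b in zip(peaks, peaks[1:]):
        if a.chrom == b.chrom and a.boundary.end > b.boundary.start:
            raise AssertionError(
                f"overlapping peak boundaries at {a.chrom}:{a.boundary.end}"
            )


@dataclass
class NrlDistribution:
    """Peak-to-peak distance statistics housing the nucleosome repeat length.

    ``histogram`` maps the left edge of each ``bin_width`` bin (e.g. 170 for
    [170, 180)) to a distance count; ``group_freq`` gives percentages of all
    distances in the short / mid / long spacing groups.
    """

    distances: np.ndarray
    bin_width: int = 10
    per_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def histogram(self) -> dict[int, int]:
        if self.distances.size == 0:
            return {}
        left = (self.distances // self.bin_width) * self.bin_width
        edges, counts = np.unique(left, return_counts=True)
        return {int(e): int(c) for e, c in zip(edges, counts)}

    @property
    def group_counts(self) -> dict[str, int]:
        d = self.distances
        return {
            "short": int((d < NRL_SHORT_BOUND).sum()),
            "mid": int(((d >= NRL_SHORT_BOUND) & (d <= NRL_LONG_BOUND)).sum()),
            "long": int((d > NRL_LONG_BOUND).sum()),
        }

    @property
    def group_freq(self) -> dict[str, float]:
        n = self.distances.size
        if n == 0:
            return {"short": math.nan, "mid": math.nan, "long": math.nan}
        return {k: 100.0 * v / n for k, v in self.group_counts.items()}

    def modal_bin(self) -> Optional[int]:
        """Left edge of the most populated histogram bin (ties: smallest edge)."""
        hist = self.histogram
        if not hist:
            return None
        best = max(hist.values())
        return min(e for e, c in hist.items() if c == best)


def compute_nrl(peaks: Sequence[NucleosomePeak], bin_width: int = 10) -> NrlDistribution:
    """Distances between consecutive peak centers, per chromosome, pooled.

    No distance is recorded across a chromosome boundary. Distances are
    additionally kept per chromosome for diagnostics.
    """
    per_chrom: dict[str, list[int]] = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.center)):
        per_chrom.setdefault(p.chrom, []).append(p.center)
    dists: dict[str, np.ndarray] = {}
    for chrom, centers in per_chrom.items():
        arr = np.diff(np.asarray(centers, dtype=np.int64))
        if arr.size:
            dists[chrom] = arr
    if not dists:
        warnings.warn("fewer than 2 peaks on every chromosome: empty NRL distribution")
        return NrlDistribution(distances=np.array([], dtype=np.int64),
                               bin_width=bin_width)
    pooled = np.concatenate(list(dists.values()))
    return NrlDistribution(distances=pooled, bin_width=bin_width, per_chrom=dists)


def _freeman_halton_2x3(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2x3 table (Freeman-Halton extension)."""
    from scipy.special import gammaln

    table = np.asarray(table, dtype=np.int64)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()

    def log_p(a0: int, a1: int, a2: int) -> float:
        cells = np.array([a0, a1, a2, col[0] - a0, col[1] - a1, col[2] - a2])
        return float(
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(n + 1)
            - gammaln(cells + 1).sum()
        )

    obs = log_p(*table[0])
    total = 0.0
    for a0 in range(min(row[0], col[0]) + 1):
        for a1 in range(min(row[0] - a0, col[1]) + 1):
            a2 = row[0] - a0 - a1
            if a2 > col[2]:
                continue
            lp = log_p(a0, a1, a2)
            if lp <= obs + 1e-9:
                total += math.exp(lp)
    return min(total, 1.0)


def compare_nrl(dist_a: NrlDistribution, dist_b: NrlDistribution):
    """Chi-square test on the 2x3 table of short/mid/long spacing counts.

    Falls back to an exact conditional test when any expected cell count
    drops below 5. Returns ``(statistic, p_value, method)``.
    """
    if dist_a.distances.size == 0 or dist_b.distances.size == 0:
        raise ValueError("cannot compare an empty NRL distribution")
    table = np.array(
        [
            [dist_a.group_counts[g] for g in ("short", "mid", "long")],
            [dist_b.group_counts[g] for g in ("short", "mid", "long")],
        ],
        dtype=np.int64,
    )
    keep = table.sum(axis=0) > 0
    table_nz = table[:, keep]
    if np.array_equal(table_nz[0] * table_nz[1].sum(),
                      table_nz[1] * table_nz[0].sum()):
        return 0.0, 1.0, "chi2"
    stat, p, _, expected = stats.chi2_contingency(table_nz, correction=False)
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; using exact conditional test")
        if table_nz.shape[1] == 2:
            _, p = stats.fisher_exact(table_nz)
            return float(stat), float(p), "fisher"
        p = _freeman_halton_2x3(table_nz)
        return float(stat), float(p), "freeman-halton"
    return float(stat), float(p), "chi2"


FAKE_PAIR_LEN = 75


def make_fake_pairs(reads: Sequence[AlignedRead]):
    """Split each fully sequenced fragment into two 75-nt opposite-strand mates.

    For a read ``[s, e)`` the mates are ``[s, s+75)+`` and ``[e-75, e)-``,
    sharing a pair identifier. This emulates a paired-end library from
    single-end full-fragment reads so downstream tools need not shift read
    positions. Reads shorter than 75 bp are skipped; the count is returned.

    Returns ``(mates, n_skipped)`` where ``mates`` is a flat list of
    intervals, consecutive pairs belonging together.
    """
    mates: list[GenomicInterval] = []
    n_skipped = 0
    for i, r in enumerate(reads):
        iv = r.interval
        if iv.length < FAKE_PAIR_LEN:
            n_skipped += 1
            continue
        pid = iv.name if iv.name is not None else f"pair{i}"
        mates.append(GenomicInterval(iv.chrom, iv.start, iv.start + FAKE_PAIR_LEN,
                                     strand="+", name=f"{pid}/1"))
        mates.append(GenomicInterval(iv.chrom, iv.end - FAKE_PAIR_LEN, iv.end,
                                     strand="-", name=f"{pid}/2"))
    return mates, n_skipped
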