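"""Core in-memory data containers used throughout the pipeline.

All genomic coordinates are 0-based, half-open (``[start, end)``), BED-style.
Conversion to 1-based conventions (wiggle) happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

CHROMATIN_STATES = tuple(f"CS{i}" for i in range(1, 10))


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap under half-open semantics; touching ends do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """A mapped MNase read interval.

    ``reached_adapter`` records whether sequencing ran through the terminal
    adapter, i.e. whether the full nuclease-protected fragment was read.
    Only such reads carry a trustworthy fragment length.
    """

    interval: GenomicInterval
    reached_adapter: bool = True

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class ChromatinStateAnnotation:
    """A genome segment labelled with one of the nine chromatin states CS1-CS9."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in CHROMATIN_STATES:
            raise ValueError(f"unknown chromatin state {self.state!r}")


def check_states_disjoint(states: Iterable[ChromatinStateAnnotation]) -> None:
    """Reject overlapping state intervals on the same chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in states:
        by_chrom.setdefault(s.interval.chrom, []).append(
            (s.interval.start, s.interval.end)
        )
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping chromatin-state intervals on {chrom} near {s1}"
                )


@dataclass
class OccupancyTrack:
    """Genome-wide nucleosome-occupancy signal on contiguous fixed-width bins.

    ``data`` maps chromosome name to a dense array of bin values; bin ``i``
    covers base pairs ``[i * bin_width, (i + 1) * bin_width)``.
    """

    data: dict[str, np.ndarray]
    bin_width: int = 10
    smoothed: bool = False
    normalized: bool = False
    clipped_mass: float = 0.0

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def same_grid(self, other: "OccupancyTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chroms() == other.chroms()
            and all(self.data[c].shape == other.data[c].shape for c in self.data)
        )

    def copy(self) -> "OccupancyTrack":
        return OccupancyTrack(
            data={c: v.copy() for c, v in self.data.items()},
            bin_width=self.bin_width,
            smoothed=self.smoothed,
            normalized=self.normalized,
            clipped_mass=self.clipped_mass,
        )

    def concatenated(self) -> np.ndarray:
        """All bin values in chromosome-sorted order, as one vector."""
        return np.concatenate([self.data[c] for c in self.chroms()])
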