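"""Ceiling-and-remainder partition of chromosomes into near-equal windows.

Each chromosome is split into ``ceil(length / requested)`` windows.  The base
window length is ``floor(length / count)`` and the remaining base pairs are
distributed one per window starting from the first window, so window lengths
differ by at most one.  For example a 305-unit chromosome with a requested
size of 100 yields four windows of sizes 77, 76, 76, 76 (the length multiset
{76, 76, 76, 77}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Dict, Iterator, List

import numpy as np

from .errors import ParameterError
from .interval_io import GenomeBuild

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 100_000


@dataclass(frozen=True)
class Window:
    """One half-open genomic window [start, end); index is per-chromosome."""

    chrom: str
    start: int
    end: int
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


def partition_chromosome(length: int, requested: int) -> List[int]:
    """Window lengths for one chromosome, in genomic order.

    ``count = ceil(length / requested)``; the remainder over
    ``floor(length / count)`` goes one bp at a time to the lowest-index
    windows.  Always: lengths sum to ``length`` and spread <= 1.
    """
    if length < 1 or requested < 1:
        raise ParameterError("length and requested window size must be >= 1")
    count = ceil(length / requested)
    base = length // count
    rem = length - base * count
    return [base + 1] * rem + [base] * (count - rem)


@dataclass
class WindowPlan:
    """All windows of a genome partition, grouped by chromosome.

    ``edges[chrom]`` holds the ``count + 1`` window boundaries, enabling
    O(log) window lookup by coordinate; ``offsets`` maps each chromosome to
    its first window's position in the flattened genome-wide ordering.
    """

    requested_size: int
    build: GenomeBuild
    edges: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets: Dict[str, int] = {}
        off = 0
        for name in self.build.names:
            self.offsets[name] = off
            off += len(self.edges[name]) - 1

    @property
    def n_windows(self) -> int:
        return sum(len(e) - 1 for e in self.edges.values())

    def counts(self, chrom: str) -> int:
        return len(self.edges[chrom]) - 1

    def window_lengths(self, chrom: str) -> np.ndarray:
        return np.diff(self.edges[chrom])

    def iter_windows(self) -> Iterator[Window]:
        for name in self.build.names:
            e = self.edges[name]
            for i in range(len(e) - 1):
                yield Window(name, int(e[i]), int(e[i + 1]), i)

    def locate(self, chrom: str, pos: int) -> int:
        """Per-chromosome index of the window containing ``pos``."""
        e = self.edges[chrom]
        return int(np.searchsorted(e, pos, side="right") - 1)

    def to_bed(self, path) -> Path:
        """Export the plan as BED3 for inspection."""
        path = Path(path)
        with path.open("w") as fh:
            for w in self.iter_windows():
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
        return path


def partition_genome(build: GenomeBuild,
                     requested: int = DEFAULT_WINDOW_SIZE) -> WindowPlan:
    """Partition every chromosome of a build independently."""
    if len(build) == 0:
        raise ParameterError("genome build is empty")
    if requested < 1000:
        log.warning("window size %d bp is below 1 kb; per-window coverage "
                    "fractions will be statistically coarse", requested)
    edges = {}
    for name, length in build:
        lens = partition_chromosome(length, requested)
        edges[name] = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
    return WindowPlan(requested, build, edges)
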