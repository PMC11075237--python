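"""Per-window loci counts, OCR coverage fractions, and overlap counting.

These quantities parameterize the local binomial null: for each window *w*
containing at least one locus, ``n_w`` is the number of loci whose start
falls in the window and ``p_w`` is the fraction of the window covered by the
cell type's (indel-extended) open chromatin.  The observed statistic is the
genome-wide count of loci intersecting >= 1 bp of open chromatin.

Indel-aware extension: when a window contains loci longer than 1 bp, each
peak ``[s, e)`` is extended leftward to ``[s - (L - 1), e)`` with ``L`` the
maximum locus length in that window, so that every in-window start position
from which such a locus would touch the peak counts as a success.  The
extension affects only the coverage fraction, never the stored profile or
the observed overlap count.

Two pre-filters operate on whole profiles: a mask (keep only peaks touching
user-supplied regions, at full length) and the peak-uniqueness filter (drop
peaks whose uniqueness value -- the number of cell types, including its own,
with an overlapping peak -- exceeds ``k``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import intervals as iv
from .errors import ParameterError
from .genome_windows import Window, WindowPlan
from .interval_io import CellTypeProfile, Interval, LociSet, Locus

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowStat:
    """Null-model component for one occupied window."""

    window: Window
    n_w: int
    p_w: float


@dataclass(frozen=True)
class OverlapCount:
    """Genome-wide number of loci intersecting the profile's peaks."""

    total: int


def _window_counts(loci_set: LociSet, plan: WindowPlan
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Flattened per-window loci counts and max locus lengths.

    A locus belongs to the window containing its start coordinate, so the
    counts always sum to the number of on-build loci.  Loci on chromosomes
    missing from the plan are excluded with a logged count.
    """
    counts = np.zeros(plan.n_windows, dtype=np.int64)
    maxlen = np.ones(plan.n_windows, dtype=np.int64)
    n_unknown = 0
    for chrom, a in loci_set.loci.items():
        if chrom not in plan.edges:
            n_unknown += len(a)
            continue
        e = plan.edges[chrom]
        idx = np.searchsorted(e, a[:, 0], side="right") - 1
        ok = (idx >= 0) & (idx < len(e) - 1)
        n_unknown += int((~ok).sum())
        idx = idx[ok]
        lens = (a[:, 1] - a[:, 0])[ok]
        off = plan.offsets[chrom]
        counts[off:off + len(e) - 1] += np.bincount(idx, minlength=len(e) - 1)
        np.maximum.at(maxlen, off + idx, lens)
    if n_unknown:
        log.warning("loci set %s: %d loci outside the window plan excluded",
                    loci_set.name, n_unknown)
    return counts, maxlen


def assign_loci(loci_set: LociSet, plan: WindowPlan) -> Dict[Window, int]:
    """Map each occupied window to its loci count ``n_w``."""
    counts, _ = _window_counts(loci_set, plan)
    out: Dict[Window, int] = {}
    flat = 0
    for w in plan.iter_windows():
        if counts[flat]:
            out[w] = int(counts[flat])
        flat += 1
    return out


def effective_coverage(profile: CellTypeProfile, window: Window,
                       loci_in_window: Sequence[Locus] = ()) -> float:
    """Fraction of the window covered by (indel-extended) peaks, capped at 1."""
    lmax = max((l.end - l.start for l in loci_in_window), default=1)
    peaks = profile.peaks.get(window.chrom, iv.EMPTY)
    if len(peaks) == 0:
        return 0.0
    if lmax > 1:
        ext = peaks.copy()
        ext[:, 0] = np.maximum(ext[:, 0] - (lmax - 1), 0)
        peaks = iv.merge(ext)
    covered = int(iv.coverage_at(peaks, [window.end])[0]
                  - iv.coverage_at(peaks, [window.start])[0])
    return min(covered / window.length, 1.0)


def base_window_coverage(profile: CellTypeProfile, plan: WindowPlan) -> np.ndarray:
    """Flattened per-window coverage fraction without indel extension."""
    out = np.zeros(plan.n_windows, dtype=float)
    for chrom in plan.build.names:
        peaks = profile.peaks.get(chrom)
        e = plan.edges[chrom]
        off = plan.offsets[chrom]
        if peaks is None or len(peaks) == 0:
            continue
        out[off:off + len(e) - 1] = iv.windowed_coverage(peaks, e) / np.diff(e)
    return np.minimum(out, 1.0)


def window_statistics(profile: CellTypeProfile, loci_set: LociSet,
                      plan: WindowPlan,
                      base_cov: Optional[np.ndarray] = None) -> List[WindowStat]:
    """Null-model components (n_w, p_w) for every occupied window.

    ``base_cov`` may carry a precomputed :func:`base_window_coverage` array to
    avoid recomputation across loci sets; windows containing indels are
    recomputed individually with the leftward peak extension.
    """
    counts, maxlen = _window_counts(loci_set, plan)
    if base_cov is None:
        base_cov = base_window_coverage(profile, plan)
    stats: List[WindowStat] = []
    flat = 0
    for w in plan.iter_windows():
        n_w = int(counts[flat])
        if n_w >= 1:
            if maxlen[flat] > 1:
                lmax = int(maxlen[flat])
                dummy = [Locus(w.chrom, w.start, w.start + lmax)]
                p_w = effective_coverage(profile, w, dummy)
            else:
                p_w = float(base_cov[flat])
            stats.append(WindowStat(w, n_w, p_w))
        flat += 1
    return stats


def count_overlaps(loci_set: LociSet, profile: CellTypeProfile) -> OverlapCount:
    """Count loci intersecting >= 1 bp of the profile's merged peaks."""
    total = 0
    for chrom, a in loci_set.loci.items():
        peaks = profile.peaks.get(chrom)
        if peaks is None or len(peaks) == 0:
            continue
        total += int(iv.overlaps_any(peaks, a[:, 0], a[:, 1]).sum())
    return OverlapCount(total)


MaskLike = Union[Mapping[str, np.ndarray], Iterable[Interval]]


def _mask_arrays(mask: MaskLike) -> Dict[str, np.ndarray]:
    if isinstance(mask, Mapping):
        return {c: iv.merge(a) for c, a in mask.items()}
    per: Dict[str, list] = {}
    for it in mask:
        per.setdefault(it.chrom, []).append((it.start, it.end))
    return {c: iv.merge(iv.as_array(v)) for c, v in per.items()}


def apply_mask(profiles: Sequence[CellTypeProfile],
               mask: MaskLike) -> List[CellTypeProfile]:
    """Keep only peaks intersecting >= 1 bp of the mask, at full length."""
    marr = _mask_arrays(mask)
    if not any(len(a) for a in marr.values()):
        raise ParameterError("mask contains no intervals")
    out = []
    for prof in profiles:
        kept: Dict[str, np.ndarray] = {}
        for chrom, peaks in prof.peaks.items():
            m = marr.get(chrom)
            if m is None or len(m) == 0:
                continue
            keep = iv.overlaps_any(m, peaks[:, 0], peaks[:, 1])
            if keep.any():
                kept[chrom] = peaks[keep]
        out.append(CellTypeProfile(prof.name, kept))
    return out


def peak_uniqueness_values(profiles: Sequence[CellTypeProfile]
                           ) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-peak uniqueness values: cell types (including own) overlapping it."""
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for prof in profiles:
        per: Dict[str, np.ndarray] = {}
        for chrom, peaks in prof.peaks.items():
            uniq = np.ones(len(peaks), dtype=np.int64)  # own cell type
            for other in profiles:
                if other is prof:
                    continue
                op = other.peaks.get(chrom)
                if op is None or len(op) == 0:
                    continue
                uniq += iv.overlaps_any(op, peaks[:, 0], peaks[:, 1])
            per[chrom] = uniq
        out[prof.name] = per
    return out


def peak_uniqueness_filter(profiles: Sequence[CellTypeProfile],
                           k: int) -> List[CellTypeProfile]:
    """Remove, from every profile, peaks shared by more than ``k`` cell types."""
    if k < 1:
        raise ParameterError("uniqueness value k must be >= 1")
    if len(profiles) < 2:
        raise ParameterError("uniqueness filtering needs >= 2 profiles")
    values = peak_uniqueness_values(profiles)
    out = []
    for prof in profiles:
        kept: Dict[str, np.ndarray] = {}
        for chrom, peaks in prof.peaks.items():
            keep = values[prof.name][chrom] <= k
            if keep.any():
                kept[chrom] = peaks[keep]
        out.append(CellTypeProfile(prof.name, kept))
    return out
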