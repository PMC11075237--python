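"""Vectorized primitives on sorted, merged genomic interval arrays.

Throughout the package an interval set on one chromosome is a ``(k, 2)``
``int64`` array of half-open ``[start, end)`` rows, sorted by start with no
two rows overlapping or abutting (the *merged* normal form produced by
:func:`merge`).  All higher-level containers store one such array per
chromosome.  The functions here are the single authority for interval
arithmetic: coverage queries use a prefix-sum of merged lengths so that
per-window coverage over thousands of windows costs one ``searchsorted``.
"""

from __future__ import annotations

import numpy as np

EMPTY: np.ndarray = np.empty((0, 2), dtype=np.int64)


def as_array(pairs) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to a (k, 2) int64 array."""
    a = np.asarray(pairs, dtype=np.int64)
    if a.size == 0:
        return EMPTY.copy()
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("interval array must have shape (k, 2)")
    return a


def merge(a: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping *or abutting* intervals.

    ``[10, 20)`` and ``[20, 30)`` merge into ``[10, 30)`` so that the merged
    form is unique for a given covered set of base pairs.
    """
    a = as_array(a)
    if len(a) == 0:
        return EMPTY.copy()
    order = np.argsort(a[:, 0], kind="stable")
    s = a[order, 0]
    e = a[order, 1]
    cummax = np.maximum.accumulate(e)
    # a new block starts where the start lies strictly beyond everything seen
    new = np.concatenate([[True], s[1:] > cummax[:-1]])
    idx = np.flatnonzero(new)
    starts = s[idx]
    ends = np.concatenate([cummax[idx[1:] - 1], cummax[-1:]])
    return np.column_stack([starts, ends])


def total_bp(a: np.ndarray) -> int:
    """Total covered base pairs of a merged array."""
    if len(a) == 0:
        return 0
    return int((a[:, 1] - a[:, 0]).sum())


def clip(a: np.ndarray, length: int) -> np.ndarray:
    """Clip intervals to [0, length), dropping those that become empty."""
    if len(a) == 0:
        return EMPTY.copy()
    s = np.clip(a[:, 0], 0, length)
    e = np.clip(a[:, 1], 0, length)
    keep = s < e
    return np.column_stack([s[keep], e[keep]])


def coverage_at(a: np.ndarray, xs) -> np.ndarray:
    """Cumulative covered bp F(x) = |union(a) ∩ [0, x)| for each x (merged a)."""
    xs = np.asarray(xs, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(xs.shape, dtype=np.int64)
    starts = a[:, 0]
    ends = a[:, 1]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    i = np.searchsorted(starts, xs, side="right")
    f = cum[i]
    j = np.clip(i - 1, 0, None)
    partial = (i > 0) & (xs < ends[j])
    f = f - np.where(partial, ends[j] - xs, 0)
    return f


def windowed_coverage(a: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Covered bp inside each window [edges[i], edges[i+1]) of a merged array."""
    return np.diff(coverage_at(a, edges))


def overlaps_any(a: np.ndarray, qstart, qend) -> np.ndarray:
    """Boolean per query [qstart, qend): does it intersect >= 1 bp of merged a?"""
    qstart = np.asarray(qstart, dtype=np.int64)
    qend = np.asarray(qend, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(qstart.shape, dtype=bool)
    k = np.searchsorted(a[:, 1], qstart, side="right")
    valid = k < len(a)
    hit = np.zeros(qstart.shape, dtype=bool)
    kc = np.clip(k, 0, len(a) - 1)
    hit = valid & (a[kc, 0] < qend)
    return hit


def intersection_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total bp shared between two merged arrays."""
    if len(a) == 0 or len(b) == 0:
        return 0
    return int((coverage_at(b, a[:, 1]) - coverage_at(b, a[:, 0])).sum())


def complement(a: np.ndarray, length: int) -> np.ndarray:
    """Gaps of a merged array within [0, length)."""
    if len(a) == 0:
        return np.array([[0, length]], dtype=np.int64)
    bounds = np.concatenate([[0], a.ravel(), [length]])
    gaps = bounds.reshape(-1, 2)
    keep = gaps[:, 0] < gaps[:, 1]
    return gaps[keep]
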