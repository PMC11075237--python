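"""Pairwise chromatin-relatedness weights and cell-type clustering.

Two cell types sharing much of their open chromatin receive a weight near 0;
unrelated ones a weight near 1:

    Weight_ij = 1 - (overlap_ij / total_i) * (overlap_ij / total_j)

where ``overlap_ij`` is the base pairs shared by the two merged peak sets
and ``total_i`` the total merged peak bp of cell type *i*.  Base-pair
measures make the weight invariant to how peak calls fragment a covered
region.  The weight matrix rows are then treated as feature vectors and
clustered hierarchically (Euclidean distance, average linkage by default)
to produce the dendrogram that orders heatmap rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from . import intervals as iv
from .errors import ParameterError
from .interval_io import CellTypeProfile

log = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "complete", "ward")


@dataclass
class WeightMatrix:
    """Symmetric relatedness weights in [0, 1] with zero diagonal."""

    names: List[str]
    W: np.ndarray


@dataclass
class DendrogramOrder:
    """Deterministic leaf order plus the merge tree behind it."""

    leaf_order: List[str]
    merges: List[Tuple[int, int, float]]
    Z: np.ndarray = field(default=None, repr=False)

    def to_newick(self) -> str:
        """Nested-parenthesis export of the merge tree."""
        if self.Z is None or len(self.leaf_order) < 2:
            return "(" + ",".join(self.leaf_order) + ");"
        tree = to_tree(self.Z)
        names = self._names_by_id

        def rec(node) -> str:
            if node.is_leaf():
                return names[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
            dr = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
            return f"({left}:{dl:g},{right}:{dr:g})"

        return rec(tree) + ";"

    @property
    def _names_by_id(self):
        # leaf ids in Z refer to input order, not leaf order
        return {i: n for i, n in enumerate(self._input_names)}


def pairwise_weight(a: CellTypeProfile, b: CellTypeProfile) -> float:
    """Relatedness weight of two merged profiles, clamped to [0, 1]."""
    ta, tb = a.total_bp(), b.total_bp()
    if ta == 0 or tb == 0:
        log.warning("profile %s or %s has zero peak bp; weight defined as 1",
                    a.name, b.name)
        return 1.0
    ov = sum(iv.intersection_bp(pa, b.peaks[c])
             for c, pa in a.peaks.items() if c in b.peaks)
    w = 1.0 - (ov / ta) * (ov / tb)
    return min(max(w, 0.0), 1.0)


def weight_matrix(profiles: Sequence[CellTypeProfile]) -> WeightMatrix:
    """Full symmetric weight matrix over >= 2 profiles (zero diagonal)."""
    if len(profiles) < 2:
        raise ParameterError("weight matrix needs >= 2 profiles")
    n = len(profiles)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            W[i, j] = W[j, i] = pairwise_weight(profiles[i], profiles[j])
    return WeightMatrix([p.name for p in profiles], W)


def cluster_profiles(wm: WeightMatrix,
                     method: str = "average") -> DendrogramOrder:
    """Hierarchically cluster weight-matrix rows; deterministic leaf order.

    Rows of W are the feature vectors, so the Euclidean distance operates on
    whole relatedness profiles.  With fewer than two profiles (or all-equal
    rows) the input order is returned unchanged.
    """
    if method not in LINKAGE_METHODS:
        raise ParameterError(f"linkage method must be one of {LINKAGE_METHODS}")
    names = list(wm.names)
    if len(names) < 2:
        order = DendrogramOrder(names, [], None)
        order._input_names = names
        return order
    if np.allclose(wm.W, wm.W[0]):
        # indistinguishable profiles: tie broken by input order, with a
        # zero-height chain as the merge tree
        n = len(names)
        Z = np.zeros((n - 1, 4))
        Z[0, :2] = (0, 1)
        Z[0, 3] = 2
        for i in range(1, n - 1):
            Z[i, :2] = (n + i - 1, i + 1)
            Z[i, 3] = i + 2
        merges = [(int(r[0]), int(r[1]), float(r[2])) for r in Z]
        order = DendrogramOrder(names, merges, Z)
        order._input_names = names
        return order
    with warnings.catch_warnings():
        # rows of W are deliberately used as feature vectors, not distances
        warnings.simplefilter("ignore")
        Z = linkage(wm.W, method=method, metric="euclidean")
    leaves = [int(i) for i in leaves_list(Z)]
    merges = [(int(r[0]), int(r[1]), float(r[2])) for r in Z]
    order = DendrogramOrder([names[i] for i in leaves], merges, Z)
    order._input_names = names
    return order
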