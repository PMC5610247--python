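"""Module detection: average-linkage clustering of 1 - |w| with a hybrid cut.

Whatever produced the edge weights (soft-thresholded correlations or StARS
edge stabilities), nodes are clustered on the dissimilarity ``1 - |w_ij|``
with unweighted average linkage.  Modules are read off the dendrogram with a
two-step hybrid cut: a static cut yields candidate branches, branches below
the minimum size are dissolved, and the dissolved nodes are re-assigned to
the nearest module when close enough.  Nodes in no module carry the label 0
(reported as "grey", matching co-expression-network convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .corrnet import IntensityMatrix

__all__ = [
    "Dendrogram",
    "ModuleAssignment",
    "dissimilarity",
    "average_linkage",
    "cut_modules",
    "MODULE_COLORS",
]

# deterministic label -> color map for report parity; label 0 is "grey"
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
]


@dataclass
class Dendrogram:
    """Average-linkage merge history in scipy linkage form (P-1 merges)."""

    node_ids: list[str]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ModuleAssignment:
    """Module label per node; 0 means unassigned ("grey")."""

    node_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.node_ids),):
            raise ValueError("labels must align with node ids")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels[self.labels > 0]))

    def members(self, module: int) -> list[str]:
        return [n for n, l in zip(self.node_ids, self.labels) if l == module]

    def color(self, module: int) -> str:
        if module == 0:
            return "grey"
        return MODULE_COLORS[(module - 1) % len(MODULE_COLORS)]


def dissimilarity(W: IntensityMatrix | np.ndarray) -> np.ndarray:
    """``D_ij = 1 - |w_ij|`` with a zero diagonal.

    Applies identically to correlation-power and stability weights (for the
    latter this is one minus the edge's subsampling stability).
    """
    weights = W.weights if isinstance(W, IntensityMatrix) else np.asarray(W, float)
    D = 1.0 - np.abs(weights)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


def average_linkage(
    D: np.ndarray, node_ids: list[str] | None = None
) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration of a dissimilarity."""
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity diagonal must be zero")
    if D.min() < 0:
        raise ValueError("dissimilarity must be nonnegative")
    if node_ids is None:
        node_ids = [f"v{i}" for i in range(D.shape[0])]
    Z = hierarchy.linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
    return Dendrogram(list(node_ids), Z)


def cut_modules(
    dend: Dendrogram,
    D: np.ndarray,
    min_module_size: int = 3,
    cut_height_quantile: float = 0.99,
) -> ModuleAssignment:
    """Two-step hybrid cut of an average-linkage dendrogram.

    Step 1: a static cut at the ``cut_height_quantile`` quantile of the merge
    heights produces candidate branches; branches smaller than
    ``min_module_size`` are dissolved to unassigned.  Step 2: every
    unassigned node joins the module with the smallest average dissimilarity
    to it, provided that average lies below the cut height; otherwise it
    stays unassigned.  Modules are relabelled 1, 2, ... by decreasing size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0 < cut_height_quantile <= 1:
        raise ValueError("cut_height_quantile must be in (0, 1]")
    D = np.asarray(D, dtype=float)
    p = len(dend.node_ids)
    # quantile over the distinct merge levels: robust to ties, so several
    # equal-height top merges (e.g. equidistant blocks) still end up above
    # the cut, while a completely flat tree collapses into one module
    height = float(np.quantile(np.unique(dend.heights), cut_height_quantile))
    branches = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    labels = np.zeros(p, dtype=int)
    next_label = 1
    for b in np.unique(branches):
        members = np.flatnonzero(branches == b)
        if members.size >= min_module_size:
            labels[members] = next_label
            next_label += 1
    module_ids = [m for m in range(1, next_label)]
    if module_ids:
        for i in np.flatnonzero(labels == 0):
            avg = {
                m: D[i, labels == m].mean() for m in module_ids
            }
            best = min(avg, key=lambda m: (avg[m], m))
            if avg[best] < height:
                labels[i] = best
    if not (labels > 0).any():
        warnings.warn(
            "no module satisfies the minimum size; all nodes unassigned",
            stacklevel=2,
        )
        return ModuleAssignment(list(dend.node_ids), labels)
    # relabel by decreasing module size (ties: keep first-seen order)
    sizes = {m: int((labels == m).sum()) for m in np.unique(labels) if m > 0}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap.get(l, 0) for l in labels], dtype=int)
    return ModuleAssignment(list(dend.node_ids), labels)
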