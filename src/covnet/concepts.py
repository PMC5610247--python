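"""Network concepts: strength, degree, density, centralization, heterogeneity.

For an edge-weight matrix ``M`` (symmetric, zero diagonal, weights in [0,1])
with node strengths ``s_i = sum_{j != i} w_ij``:

    density        = mean edge weight             = s_bar / (P - 1)
    centralization = P/((P-1)(P-2)) * (max s - s_bar)
    heterogeneity  = coefficient of variation of s = sqrt(var(s)) / s_bar

Density near one indicates high interconnectedness; centralization is one
for a unit-weight star and zero for any regular network; heterogeneity is
zero for regular networks and grows with hub dominance.  The same formulas
apply to any weight matrix, whether soft-thresholded correlations or StARS
edge stabilities, and to whole networks or module submatrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ModuleAssignment
from .corrnet import AdjacencyMatrix, IntensityMatrix

__all__ = [
    "strength",
    "degree",
    "density",
    "centralization",
    "heterogeneity",
    "ConceptSummary",
    "summarize",
    "top_connected",
]


def _weights(M: IntensityMatrix | np.ndarray) -> np.ndarray:
    W = M.weights if isinstance(M, IntensityMatrix) else np.asarray(M, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    return W


def strength(M: IntensityMatrix | np.ndarray) -> np.ndarray:
    """Weighted degree ``s_i = sum_{j != i} w_ij`` (row sums, zero diagonal)."""
    W = _weights(M).copy()
    np.fill_diagonal(W, 0.0)
    return W.sum(axis=1)


def degree(A: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Number of neighbors of each node."""
    E = A.entries if isinstance(A, AdjacencyMatrix) else np.asarray(A)
    return E.sum(axis=1).astype(int)


def density(M: IntensityMatrix | np.ndarray) -> float:
    """Mean of the off-diagonal weights, ``s_bar / (P - 1)``."""
    W = _weights(M)
    p = W.shape[0]
    if p < 2:
        raise ValueError("density needs at least 2 nodes")
    s = strength(W)
    return float(s.sum() / (p * (p - 1)))


def centralization(M: IntensityMatrix | np.ndarray) -> float:
    """Excess strength of the hub: ``P/((P-1)(P-2)) * (max s - mean s)``."""
    W = _weights(M)
    p = W.shape[0]
    if p < 3:
        raise ValueError("centralization needs at least 3 nodes")
    s = strength(W)
    return float(p / ((p - 1) * (p - 2)) * (s.max() - s.mean()))


def heterogeneity(M: IntensityMatrix | np.ndarray, population: bool = True) -> float:
    """Coefficient of variation of the strength distribution.

    Uses the population (divide-by-P) variance by default; set
    ``population=False`` for the sample variance.  Undefined (raises) for an
    empty network.
    """
    s = strength(_weights(M))
    mean = s.mean()
    if mean == 0:
        raise ValueError("heterogeneity undefined for an empty network")
    var = s.var(ddof=0 if population else 1)
    return float(np.sqrt(var) / mean)


@dataclass
class ConceptSummary:
    """Density/centralization/heterogeneity of one node set."""

    scope: str
    n_nodes: int
    density: float
    centralization: float  # NaN when n_nodes < 3
    heterogeneity: float
    mean_strength: float
    max_strength: float
    color: str = ""


def summarize(
    M: IntensityMatrix, modules: ModuleAssignment | None = None
) -> pd.DataFrame:
    """Concept table: one row per module (decreasing density) plus the whole network.

    Module statistics are computed on the restricted submatrix of ``M``;
    unassigned nodes (module 0) get no row of their own.  Modules with fewer
    than 3 nodes report centralization as NaN.
    """
    if modules is not None and list(modules.node_ids) != list(M.node_ids):
        raise ValueError("module assignment does not match the weight matrix")
    rows: list[ConceptSummary] = []
    if modules is not None:
        for mod in modules.module_ids:
            idx = np.flatnonzero(modules.labels == mod)
            sub = M.weights[np.ix_(idx, idx)]
            s = strength(sub)
            rows.append(
                ConceptSummary(
                    scope=f"module {mod}",
                    n_nodes=int(idx.size),
                    density=density(sub),
                    centralization=(
                        centralization(sub) if idx.size >= 3 else float("nan")
                    ),
                    heterogeneity=heterogeneity(sub) if s.mean() > 0 else float("nan"),
                    mean_strength=float(s.mean()),
                    max_strength=float(s.max()),
                    color=modules.color(mod),
                )
            )
        rows.sort(key=lambda r: -r.density)
    s = strength(M)
    rows.append(
        ConceptSummary(
            scope="complete",
            n_nodes=M.n_nodes,
            density=density(M),
            centralization=centralization(M) if M.n_nodes >= 3 else float("nan"),
            heterogeneity=heterogeneity(M) if s.mean() > 0 else float("nan"),
            mean_strength=float(s.mean()),
            max_strength=float(s.max()),
            color="",
        )
    )
    return pd.DataFrame([r.__dict__ for r in rows])


def top_connected(A: AdjacencyMatrix, k: int = 15) -> pd.DataFrame:
    """Top-k nodes by degree (ties broken by node id, ascending)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    deg = degree(A)
    order = sorted(range(A.n_nodes), key=lambda i: (-deg[i], A.node_ids[i]))
    rows = [
        {"node": A.node_ids[i], "degree": int(deg[i])} for i in order[:k]
    ]
    return pd.DataFrame(rows)
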