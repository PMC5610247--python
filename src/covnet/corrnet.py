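"""Weighted correlation networks with soft thresholding.

The edge weight between metabolites i and j is ``|cor(y_i, y_j)|**gamma``.
When the network is not scale-free, the power ``gamma`` is chosen from the
sample size alone: the magnitude of a noise correlation between two Gaussian
variables on N samples is about ``1/sqrt(N)``, so the smallest integer gamma
with

    P*(P-1) / (2 * sqrt(N)**gamma) < 1

keeps the summed noise contribution over all P*(P-1)/2 node pairs below one.
A log-log regression of the strength (weighted degree) distribution provides
the scale-free diagnostic, and sparse views are produced by keeping the top
fraction of edges by weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import SampleTable

__all__ = [
    "IntensityMatrix",
    "AdjacencyMatrix",
    "ScaleFreeFit",
    "select_gamma",
    "intensity_matrix",
    "scale_free_fit",
    "top_fraction_edges",
]


@dataclass
class IntensityMatrix:
    """Symmetric nonnegative edge-weight matrix with a zero diagonal.

    ``kind`` records the provenance of the weights: ``correlation-power``
    for soft-thresholded absolute correlations (with the power in ``power``)
    or ``stability`` for StARS edge-selection frequencies.  All downstream
    code (modules, network concepts) is agnostic to the kind.
    """

    node_ids: list[str]
    weights: np.ndarray
    kind: str = "correlation-power"
    power: int | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if W.shape[0] != len(self.node_ids):
            raise ValueError("node ids do not match the weight matrix")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero (no self-edges)")
        if W.min() < -1e-12 or W.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip((W + W.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


@dataclass
class AdjacencyMatrix:
    """Unweighted symmetric 0/1 adjacency with a zero diagonal."""

    node_ids: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.entries)
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not (A == A.T).all():
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.entries = A.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ScaleFreeFit:
    """Log-log regression of the strength distribution."""

    r_squared: float
    slope: float
    n_bins: int


def select_gamma(n_samples: int, n_nodes: int, gamma_max: int = 12) -> int:
    """Smallest integer power suppressing the summed noise correlation.

    Returns the smallest integer ``gamma >= 1`` with
    ``P*(P-1)/(2*sqrt(N)**gamma) < 1``.  Raises when no power up to
    ``gamma_max`` suffices, reporting the power that would be required.
    """
    if n_samples < 2 or n_nodes < 2:
        raise ValueError("need N >= 2 samples and P >= 2 nodes")
    if gamma_max < 1:
        raise ValueError("gamma_max must be >= 1")
    total = n_nodes * (n_nodes - 1) / 2.0
    # closed form: gamma > 2*log(total)/log(N)
    gamma = 1
    while total / np.sqrt(n_samples) ** gamma >= 1:
        gamma += 1
        if gamma > gamma_max:
            needed = int(np.ceil(2 * np.log(total) / np.log(n_samples)))
            while total / np.sqrt(n_samples) ** needed >= 1:
                needed += 1
            raise ValueError(
                f"no power <= {gamma_max} suppresses the noise; gamma={needed} required"
            )
    return gamma


def intensity_matrix(
    data: SampleTable | np.ndarray, gamma: int, node_ids: list[str] | None = None
) -> IntensityMatrix:
    """Soft-thresholded absolute-correlation weights |cor|**gamma."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if isinstance(data, SampleTable):
        values = data.values
        node_ids = list(data.metabolite_ids)
    else:
        values = np.asarray(data, dtype=float)
        if node_ids is None:
            node_ids = [f"v{i}" for i in range(values.shape[1])]
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = node_ids[int(np.argmin(sd))]
        raise ValueError(f"zero-variance column {bad!r}: correlation undefined")
    C = np.corrcoef(values, rowvar=False)
    W = np.abs(np.clip(C, -1.0, 1.0)) ** gamma
    np.fill_diagonal(W, 0.0)
    return IntensityMatrix(node_ids, W, kind="correlation-power", power=int(gamma))


def scale_free_fit(
    W: IntensityMatrix | np.ndarray, n_bins: int = 10
) -> ScaleFreeFit:
    """Check approximate scale-free topology of the weighted network.

    Node strengths (row sums of the weight matrix, or a strength vector
    passed directly) are binned equal-width, zero-count bins are dropped,
    and ``log10`` frequency is regressed on ``log10`` bin center.  An
    R-squared near one indicates a power-law strength distribution.  Fewer
    than three non-empty bins (a degenerate, e.g. regular, network) raises.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if isinstance(W, IntensityMatrix):
        s = W.weights.sum(axis=1)
    else:
        s = np.asarray(W, dtype=float)
        if s.ndim == 2:
            s = s.sum(axis=1)
    if np.ptp(s) == 0:
        raise ValueError(
            "degenerate strength distribution (all strengths equal); "
            "scale-free diagnostic undefined"
        )
    counts, edges = np.histogram(s, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mask = (counts > 0) & (centers > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} non-empty bins; degenerate strength distribution"
        )
    res = stats.linregress(np.log10(centers[mask]), np.log10(counts[mask]))
    return ScaleFreeFit(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        n_bins=int(mask.sum()),
    )


def top_fraction_edges(
    W: IntensityMatrix, fraction: float
) -> tuple[float, AdjacencyMatrix]:
    """Keep the strongest ``fraction`` of all possible edges.

    The threshold is the nearest-rank upper quantile of the upper-triangle
    weights; every edge with weight >= threshold is kept, so a tie group at
    the threshold is kept whole.  ``fraction=0`` yields the empty edge set and
    ``fraction=1`` keeps every positive-weight edge.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    p = W.n_nodes
    weights = W.upper_triangle()
    n_edges = weights.size
    k = int(np.floor(fraction * n_edges))
    if k == 0:
        threshold = np.inf
    else:
        threshold = float(np.sort(weights)[::-1][k - 1])
    A = np.zeros((p, p), dtype=int)
    iu = np.triu_indices(p, k=1)
    keep = (weights >= threshold) & (weights > 0)
    A[iu[0][keep], iu[1][keep]] = 1
    A = A + A.T
    return threshold, AdjacencyMatrix(list(W.node_ids), A)
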