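"""Sparse Gaussian graphical models via the graphical lasso, with StARS.

Assuming centered data ``Y ~ N_P(0, Sigma)``, the precision matrix
``Theta = Sigma^{-1}`` encodes conditional independence: a zero off-diagonal
entry means no direct edge.  ``Theta`` is estimated by maximizing the
L1-penalized Gaussian log-likelihood

    log det Theta - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|,

where ``S`` is the sample covariance.  The penalty is selected by StARS
(stability approach to regularization selection): the graphical lasso is
refitted on random subsamples, the per-edge selection frequencies give a
total edge instability for every lambda, and the least regularization whose
(monotonized) instability stays below a disagreement allowance is chosen.
The per-edge selection frequencies at the chosen lambda double as edge
weights for module detection and network concepts.

The convex solver is the coordinate-descent graphical lasso from
scikit-learn; this module owns the covariance conventions, the optional
diagonal penalty, the StARS loop and the partial-correlation transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso as _sklearn_glasso

from .corrnet import IntensityMatrix
from .tables import SampleTable

__all__ = [
    "CovarianceMatrix",
    "PrecisionMatrix",
    "StarsResult",
    "sample_covariance",
    "graphical_lasso",
    "stars_select",
    "partial_correlations",
]

#: off-diagonal entries smaller than this (relative to the diagonal scale)
#: are treated as exact zeros when reading off the edge set
EDGE_TOL = 1e-10


@dataclass
class CovarianceMatrix:
    """Sample covariance ``S = Y'Y / N`` of column-centered data."""

    node_ids: list[str]
    S: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.S = (S + S.T) / 2.0

    def to_correlation(self) -> "CovarianceMatrix":
        d = np.sqrt(np.diag(self.S))
        if np.any(d == 0):
            bad = self.node_ids[int(np.argmin(d))]
            raise ValueError(f"zero-variance column {bad!r}")
        R = self.S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return CovarianceMatrix(list(self.node_ids), R, self.n_samples)


@dataclass
class PrecisionMatrix:
    """Estimated precision (inverse covariance) and the penalty that produced it."""

    node_ids: list[str]
    Theta: np.ndarray
    lambda_: float

    def __post_init__(self) -> None:
        T = np.asarray(self.Theta, dtype=float)
        if not np.all(np.isfinite(T)):
            raise ValueError("precision matrix has non-finite entries")
        if not np.allclose(T, T.T, atol=1e-8):
            raise ValueError("precision matrix must be symmetric")
        self.Theta = (T + T.T) / 2.0
        np.linalg.cholesky(self.Theta)  # raises unless positive definite

    def edge_matrix(self) -> np.ndarray:
        """Boolean adjacency of the estimated conditional-dependence graph."""
        d = np.sqrt(np.diag(self.Theta))
        scaled = np.abs(self.Theta) / np.outer(d, d)
        E = scaled > EDGE_TOL
        np.fill_diagonal(E, False)
        return E


def sample_covariance(data: SampleTable | np.ndarray,
                      node_ids: list[str] | None = None) -> CovarianceMatrix:
    """Column-center the data and return ``S = Y'Y / N`` (divide by N)."""
    if isinstance(data, SampleTable):
        values = data.values
        node_ids = list(data.metabolite_ids)
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if node_ids is None:
            node_ids = [f"v{i}" for i in range(values.shape[1])]
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    Yc = values - values.mean(axis=0)
    return CovarianceMatrix(node_ids, Yc.T @ Yc / n, n)


def graphical_lasso(
    cov: CovarianceMatrix,
    lambda_: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    penalize_diagonal: bool = False,
) -> PrecisionMatrix:
    """L1-penalized precision estimation.

    By default only off-diagonal entries are penalized (the edge set is the
    quantity of interest; penalizing the diagonal merely shrinks variances).
    ``penalize_diagonal=True`` solves the fully penalized problem, which is
    equivalent to the off-diagonal problem on ``S + lambda*I``.  With
    ``lambda_=0`` the unpenalized MLE ``S^{-1}`` is returned and ``S`` must
    be nonsingular.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    S = cov.S.copy()
    if lambda_ == 0:
        if np.linalg.matrix_rank(S) < S.shape[0]:
            raise np.linalg.LinAlgError(
                "singular covariance: the unpenalized MLE does not exist"
            )
        Theta = np.linalg.inv(S)
        return PrecisionMatrix(list(cov.node_ids), Theta, 0.0)
    if penalize_diagonal:
        S = S + lambda_ * np.eye(S.shape[0])
    # coordinate descent first; its dual gap can stall oscillating on some
    # subsample correlation matrices, in which case the exact LARS path is used
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            _, Theta = _sklearn_glasso(S, alpha=lambda_, tol=tol, max_iter=max_iter)
        except UserWarning:
            try:
                _, Theta = _sklearn_glasso(
                    S, alpha=lambda_, mode="lars", tol=tol, max_iter=max_iter
                )
            except UserWarning as exc:
                raise RuntimeError(
                    f"graphical lasso did not converge within {max_iter} "
                    f"iterations: {exc}"
                ) from None
    return PrecisionMatrix(list(cov.node_ids), Theta, float(lambda_))


def default_lambda_grid(cov: CovarianceMatrix, n_values: int = 30,
                        min_ratio: float = 0.05) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max = max off-diagonal |S| downward."""
    offdiag = np.abs(cov.S - np.diag(np.diag(cov.S)))
    lam_max = float(offdiag.max())
    if lam_max <= 0:
        raise ValueError("all off-diagonal covariances are zero")
    return np.geomspace(lam_max, min_ratio * lam_max, n_values)


@dataclass
class StarsResult:
    """StARS selection output.

    ``instability`` is the raw edge instability D(lambda); ``monotone`` its
    running supremum from the largest penalty downward.  ``stability`` is the
    edge-selection-frequency matrix at the selected penalty, reusable as an
    :class:`IntensityMatrix` everywhere a weighted network is accepted.
    """

    lambda_grid: np.ndarray
    instability: np.ndarray
    monotone: np.ndarray
    lambda_star: float
    stability: IntensityMatrix
    precision: PrecisionMatrix
    settings: dict = field(default_factory=dict)
    subsample_indices: list[np.ndarray] = field(default_factory=list)
    fallback: bool = False


def stars_select(
    data: SampleTable | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_subsamples: int = 100,
    subsample_size: int | None = None,
    allowance: float = 0.05,
    seed: int = 0,
    use_correlation: bool = True,
    node_ids: list[str] | None = None,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.05,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> StarsResult:
    """Select the graphical-lasso penalty by subsampling stability.

    For each penalty on a decreasing grid, the model is refitted on
    ``n_subsamples`` subsamples drawn without replacement; the per-edge
    selection frequency ``theta_ij`` gives the total instability
    ``D = mean(2 * theta_ij * (1 - theta_ij))`` over node pairs.  After
    monotonizing D from the largest penalty downward, the smallest penalty
    with instability at or below the allowance is selected.  If no grid point
    satisfies the allowance the largest penalty is returned with
    ``fallback=True`` and a warning.
    """
    if isinstance(data, SampleTable):
        values = data.values
        node_ids = list(data.metabolite_ids)
    else:
        values = np.asarray(data, dtype=float)
        if node_ids is None:
            node_ids = [f"v{i}" for i in range(values.shape[1])]
    n, p = values.shape
    if subsample_size is None:
        # the customary b(n) = floor(10*sqrt(n)), capped below n
        subsample_size = min(n - 1, int(np.floor(10 * np.sqrt(n))))
    if not 2 <= subsample_size < n:
        raise ValueError("subsample size must be in [2, N)")
    if n_subsamples < 2:
        raise ValueError("need at least 2 subsamples")
    if not 0 < allowance < 1:
        raise ValueError("allowance must be in (0, 1)")

    full_cov = sample_covariance(values, node_ids=node_ids)
    if use_correlation:
        full_cov = full_cov.to_correlation()
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(full_cov, n_lambda, lambda_min_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be sorted in decreasing order")

    rng = np.random.default_rng(seed)
    indices = [
        np.sort(rng.choice(n, size=subsample_size, replace=False))
        for _ in range(n_subsamples)
    ]
    iu = np.triu_indices(p, k=1)
    freq = np.zeros((lambda_grid.size, iu[0].size))
    for idx in indices:
        sub_cov = sample_covariance(values[idx], node_ids=node_ids)
        if use_correlation:
            sub_cov = sub_cov.to_correlation()
        for li, lam in enumerate(lambda_grid):
            prec = graphical_lasso(sub_cov, lam, tol=tol, max_iter=max_iter)
            freq[li] += prec.edge_matrix()[iu]
    freq /= n_subsamples
    instability = (2 * freq * (1 - freq)).mean(axis=1)
    monotone = np.maximum.accumulate(instability)

    ok = monotone <= allowance
    fallback = not ok.any()
    if fallback:
        warnings.warn(
            "no penalty on the grid satisfies the disagreement allowance; "
            "falling back to the largest penalty",
            stacklevel=2,
        )
        sel = 0
    else:
        sel = int(np.flatnonzero(ok)[-1])  # smallest lambda still within allowance
    lambda_star = float(lambda_grid[sel])

    stab = np.zeros((p, p))
    stab[iu] = freq[sel]
    stab = stab + stab.T
    stability = IntensityMatrix(list(node_ids), stab, kind="stability")
    precision = graphical_lasso(full_cov, lambda_star, tol=tol, max_iter=max_iter)
    return StarsResult(
        lambda_grid=lambda_grid,
        instability=instability,
        monotone=monotone,
        lambda_star=lambda_star,
        stability=stability,
        precision=precision,
        settings={
            "n_subsamples": n_subsamples,
            "subsample_size": subsample_size,
            "allowance": allowance,
            "seed": seed,
            "use_correlation": use_correlation,
        },
        subsample_indices=indices,
        fallback=fallback,
    )


def partial_correlations(prec: PrecisionMatrix | np.ndarray) -> np.ndarray:
    """Partial correlations ``-Theta_ij / sqrt(Theta_ii * Theta_jj)``.

    The diagonal is set to zero; an off-diagonal partial correlation is zero
    exactly where the precision entry is zero.  Requires a positive-definite
    precision matrix.
    """
    Theta = prec.Theta if isinstance(prec, PrecisionMatrix) else np.asarray(prec, float)
    try:
        np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "precision matrix is not positive definite"
        ) from None
    d = np.sqrt(np.diag(Theta))
    rho = -Theta / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho
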