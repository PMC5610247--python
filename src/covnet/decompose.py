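"""Decomposition of metabolite variation with respect to a covariable of interest.

Each metabolite ``y`` is modelled by a saturated interaction regression on the
covariables,

    y = b0 + b1*Xm + sum_d g_d * prod_j Xj^d_j + sum_d e_d * Xm o prod_j Xj^d_j + eps,

where ``Xm`` is the (categorical) covariable of interest, the ``g_d`` terms
carry all main effects and interactions among the remaining covariables, and
the ``e_d`` terms carry every interaction involving ``Xm`` (``o`` is the
elementwise product; ``d`` ranges over all non-zero 0/1 vectors indexing
subsets of the non-target covariables).  The covariable-relevant part of the
metabolite is the fitted contribution of the ``Xm`` main effect plus all its
interactions:

    y_tilde = b1_hat*Xm + sum_d e_d_hat * Xm o prod_j Xj^d_j,

i.e. the intercept and all non-target terms are excluded.  Networks built from
``y_tilde`` describe how metabolites co-respond to the covariable of interest
rather than how their raw concentrations co-vary.

Term selection is hierarchical: the interactions with the target are tested
backwards from the highest order with partial F-tests, stopping at the first
significant order (all lower-order terms are then retained).  Whether a
metabolite is kept at all is decided by a single joint F-test of every
target-involving term, so that under a null target effect the expected
fraction of metabolites kept equals the significance level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .tables import DesignTable, SampleTable

__all__ = [
    "expand_terms",
    "TermSpec",
    "ModelSpec",
    "DesignMatrix",
    "build_design_matrix",
    "FitResult",
    "fit_model",
    "hierarchical_select",
    "extract_covariable_part",
    "decompose",
    "DecompositionResult",
    "adjust_nuisance",
    "categorize_continuous",
]


def expand_terms(m_minus_1: int) -> list[tuple[int, ...]]:
    """All 0/1 vectors of length ``m_minus_1`` except the all-zero vector.

    Each vector indexes one product of non-target covariables; there are
    ``2**(m-1) - 1`` of them, returned in lexicographic order.  With no
    non-target covariables the set is empty.
    """
    if m_minus_1 < 0:
        raise ValueError("m_minus_1 must be non-negative")
    return [
        d for d in itertools.product((0, 1), repeat=m_minus_1) if any(d)
    ]


@dataclass(frozen=True)
class TermSpec:
    """One term group of the interaction model.

    ``role`` is ``intercept``, ``target`` (the b1 main-effect block),
    ``gamma`` (non-target product indexed by ``delta``) or ``eta``
    (target-by-product interaction indexed by ``delta``).
    """

    role: str
    delta: tuple[int, ...] = ()

    @property
    def order(self) -> int:
        """Number of covariables entering the term (interaction order)."""
        if self.role == "intercept":
            return 0
        if self.role == "target":
            return 1
        if self.role == "gamma":
            return sum(self.delta)
        return sum(self.delta) + 1

    def label(self, target: str, others: list[str]) -> str:
        if self.role == "intercept":
            return "1"
        if self.role == "target":
            return target
        factors = [n for n, d in zip(others, self.delta) if d]
        if self.role == "gamma":
            return ":".join(factors)
        return ":".join([target] + factors)

    @property
    def involves_target(self) -> bool:
        return self.role in ("target", "eta")


def full_model_terms(design: DesignTable) -> list[TermSpec]:
    """Every term of the saturated model for a given design."""
    deltas = expand_terms(len(design.non_target_names))
    terms = [TermSpec("intercept"), TermSpec("target")]
    terms += [TermSpec("gamma", d) for d in deltas]
    terms += [TermSpec("eta", d) for d in deltas]
    return terms


@dataclass
class ModelSpec:
    """A subset of the saturated model's term groups, plus the keep decision."""

    terms: list[TermSpec]
    kept: bool = True
    trace: list[dict] = field(default_factory=list)

    def has(self, role: str, delta: tuple[int, ...] = ()) -> bool:
        return any(t.role == role and t.delta == delta for t in self.terms)

    @property
    def target_terms(self) -> list[TermSpec]:
        return [t for t in self.terms if t.involves_target]


@dataclass
class DesignMatrix:
    """Expanded numeric design matrix with a column->term-group mapping."""

    X: pd.DataFrame
    groups: dict[str, list[str]]  # term label -> column names
    terms: list[TermSpec]
    target: str
    others: list[str]

    def columns_for(self, terms: list[TermSpec]) -> list[str]:
        cols: list[str] = []
        for t in terms:
            cols.extend(self.groups[t.label(self.target, self.others)])
        return cols


def _product_block(blocks: list[pd.DataFrame]) -> pd.DataFrame:
    """Elementwise products of one column from each block (all combinations)."""
    out = blocks[0]
    for nxt in blocks[1:]:
        cols = {}
        for a in out.columns:
            for b in nxt.columns:
                cols[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
        out = pd.DataFrame(cols)
    return out


def build_design_matrix(design: DesignTable, spec: ModelSpec) -> DesignMatrix:
    """Expand a term specification into a numeric design matrix.

    Categorical covariables are indicator-coded against their reference level;
    interaction columns are elementwise products of the constituent columns.
    Raises if the expansion is rank deficient (e.g. an empty design cell),
    naming the offending columns.
    """
    others = design.non_target_names
    n = design.n_samples
    pieces: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    for term in spec.terms:
        label = term.label(design.target, others)
        if term.role == "intercept":
            block = pd.DataFrame({"(intercept)": np.ones(n)})
        elif term.role == "target":
            block = design.indicator_columns(design.target)
        else:
            factors = [n_ for n_, d in zip(others, term.delta) if d]
            sub = [design.indicator_columns(f) for f in factors]
            if term.role == "eta":
                sub = [design.indicator_columns(design.target)] + sub
            block = _product_block(sub)
        pieces.append(block)
        groups[label] = list(block.columns)
    X = pd.concat(pieces, axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate columns in design expansion")
    _check_rank(X)
    return DesignMatrix(X, groups, list(spec.terms), design.target, others)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # QR with column pivoting flags the columns beyond the numerical rank
        _, _, piv = linalg.qr(arr, pivoting=True, mode="economic")
        bad = sorted(X.columns[piv[rank:]])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear/unestimable columns: {bad}"
        )


@dataclass
class FitResult:
    """Ordinary least-squares fit with per-term-group partial F-tests."""

    coef: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    df_resid: int
    sigma2: float
    group_pvalues: dict[str, float]


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_model(y: np.ndarray, dm: DesignMatrix) -> FitResult:
    """Fit the expanded model by OLS and test each term group.

    Each group p-value comes from the partial F-test comparing the full model
    with the model in which the whole group's columns are removed.
    """
    y = np.asarray(y, dtype=float)
    X = dm.X.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than columns ({k})")
    _check_rank(dm.X)
    beta, rss = _ols(y, X)
    df_resid = n - k
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    pvals: dict[str, float] = {}
    for label, cols in dm.groups.items():
        if label == "1":
            continue
        keep = [c for c in dm.X.columns if c not in cols]
        _, rss0 = _ols(y, dm.X[keep].to_numpy(dtype=float))
        pvals[label] = _partial_f_pvalue(rss0, rss, len(cols), df_resid)
    return FitResult(
        coef=pd.Series(beta, index=dm.X.columns),
        fitted=X @ beta,
        residuals=y - X @ beta,
        rss=rss,
        df_resid=df_resid,
        sigma2=sigma2,
        group_pvalues=pvals,
    )


def _partial_f_pvalue(rss0: float, rss1: float, df1: int, df2: int) -> float:
    if df2 <= 0:
        return np.nan
    num = max(rss0 - rss1, 0.0) / df1
    den = rss1 / df2
    if den <= 0:
        # saturated (zero-residual) fit: any reduction is infinitely significant
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / den, df1, df2))


def _largest_estimable(design: DesignTable, terms: list[TermSpec]) -> tuple[list[TermSpec], list[TermSpec]]:
    """Drop unestimable terms, highest order first, until full rank."""
    terms = list(terms)
    dropped: list[TermSpec] = []
    while True:
        try:
            build_design_matrix(design, ModelSpec(terms))
            return terms, dropped
        except np.linalg.LinAlgError:
            candidates = [t for t in terms if t.role in ("eta", "gamma")]
            if not candidates:
                raise
            worst = max(
                candidates,
                key=lambda t: (t.order, t.role == "eta", t.delta),
            )
            terms.remove(worst)
            dropped.append(worst)


def hierarchical_select(
    y: np.ndarray,
    design: DesignTable,
    alpha: float = 0.05,
) -> tuple[ModelSpec, FitResult]:
    """Select model terms hierarchically and decide whether to keep the metabolite.

    The keep/discard decision is a single joint partial F-test, at level
    ``alpha``, of all terms involving the target covariable (main effect plus
    every interaction with it); a metabolite with no detectable target
    association is discarded.  For kept metabolites the interaction structure
    is chosen backwards: the highest-order target interactions are tested as a
    group and removed when non-significant, iterating downward; at the first
    significant order all remaining terms are retained.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    trace: list[dict] = []
    terms, dropped = _largest_estimable(design, full_model_terms(design))
    for t in dropped:
        trace.append(
            {
                "step": "unestimable",
                "term": t.label(design.target, design.non_target_names),
                "p_value": np.nan,
                "action": "dropped (not estimable)",
            }
        )

    def fit(term_list: list[TermSpec]) -> tuple[DesignMatrix, FitResult]:
        dm = build_design_matrix(design, ModelSpec(term_list))
        return dm, fit_model(y, dm)

    dm_full, fit_full = fit(terms)
    target_terms = [t for t in terms if t.involves_target]
    base_terms = [t for t in terms if not t.involves_target]
    _, fit_base = fit(base_terms)
    p_gate = _partial_f_pvalue(
        fit_base.rss,
        fit_full.rss,
        len(dm_full.columns_for(target_terms)),
        fit_full.df_resid,
    )
    trace.append(
        {
            "step": "target-gate",
            "term": "all target terms",
            "p_value": p_gate,
            "action": "kept" if p_gate < alpha else "discarded",
        }
    )
    if not (p_gate < alpha):
        return ModelSpec(base_terms, kept=False, trace=trace), fit_full

    # backward hierarchy over the orders of the target interactions
    current = list(terms)
    current_fit = fit_full
    while True:
        etas = [t for t in current if t.role == "eta"]
        if not etas:
            break
        top = max(t.order for t in etas)
        group = [t for t in etas if t.order == top]
        label = "+".join(
            t.label(design.target, design.non_target_names) for t in group
        )
        dm_cur = build_design_matrix(design, ModelSpec(current))
        reduced = [t for t in current if t not in group]
        _, fit_red = fit(reduced)
        _, fit_cur = fit(current)
        p = _partial_f_pvalue(
            fit_red.rss,
            fit_cur.rss,
            len(dm_cur.columns_for(group)),
            fit_cur.df_resid,
        )
        if p < alpha:
            trace.append(
                {"step": f"eta-order-{top}", "term": label, "p_value": p,
                 "action": "significant; all remaining terms included"}
            )
            current_fit = fit_cur
            break
        trace.append(
            {"step": f"eta-order-{top}", "term": label, "p_value": p,
             "action": "removed"}
        )
        current = reduced
        current_fit = fit_red

    if not any(t.role == "eta" for t in current):
        # only the main target effect is left to examine
        reduced = [t for t in current if t.role != "target"]
        _, fit_red = fit(reduced)
        _, fit_cur = fit(current)
        dm_cur = build_design_matrix(design, ModelSpec(current))
        p = _partial_f_pvalue(
            fit_red.rss,
            fit_cur.rss,
            len(dm_cur.columns_for([TermSpec("target")])),
            fit_cur.df_resid,
        )
        action = (
            "significant" if p < alpha
            else "retained (metabolite kept by the joint target test)"
        )
        trace.append(
            {"step": "target-main", "term": design.target, "p_value": p,
             "action": action}
        )
        current_fit = fit_cur

    return ModelSpec(current, kept=True, trace=trace), current_fit


def extract_covariable_part(
    fit: FitResult, dm: DesignMatrix, spec: ModelSpec
) -> np.ndarray:
    """Fitted contribution of the target covariable and its interactions.

    The intercept and all non-target (gamma) terms are excluded, so the
    result is identically zero when every target-involving coefficient is
    zero.  Refuses to run for discarded metabolites.
    """
    if not spec.kept:
        raise ValueError(
            "covariable part is undefined for a discarded metabolite (kept=False)"
        )
    cols = dm.columns_for(spec.target_terms)
    if not cols:
        raise ValueError("selected model contains no target-involving term")
    return dm.X[cols].to_numpy(dtype=float) @ fit.coef[cols].to_numpy()


@dataclass
class DecompositionResult:
    """Per-metabolite selected models and the covariable-relevant data matrix."""

    metabolite_ids: list[str]
    kept: dict[str, bool]
    specs: dict[str, ModelSpec]
    fits: dict[str, FitResult]
    covariable_parts: SampleTable | None  # kept metabolites only
    alpha: float

    @property
    def kept_ids(self) -> list[str]:
        return [m for m in self.metabolite_ids if self.kept[m]]

    def report(self) -> pd.DataFrame:
        """Selection report: one row per metabolite with terms and p-values."""
        rows = []
        for m in self.metabolite_ids:
            spec = self.specs[m]
            gate = next(
                (s for s in spec.trace if s["step"] == "target-gate"), None
            )
            rows.append(
                {
                    "metabolite": m,
                    "kept": self.kept[m],
                    "target_p_value": gate["p_value"] if gate else np.nan,
                    "included_terms": " ".join(
                        t.role if not t.delta else f"{t.role}{''.join(map(str, t.delta))}"
                        for t in spec.terms
                    ),
                    "n_terms": len(spec.terms),
                    "sigma2": self.fits[m].sigma2,
                }
            )
        return pd.DataFrame(rows)


def decompose(
    samples: SampleTable,
    design: DesignTable,
    alpha: float = 0.05,
    selection: bool = True,
) -> DecompositionResult:
    """Run the decomposition for every metabolite of a sample table.

    With ``selection=False`` the saturated model is fitted as-is for every
    metabolite (no term selection, nothing discarded); otherwise the
    hierarchical procedure decides both the retained terms and the keep flag.
    """
    design = design.align_to(samples)
    kept: dict[str, bool] = {}
    specs: dict[str, ModelSpec] = {}
    fits: dict[str, FitResult] = {}
    parts: dict[str, np.ndarray] = {}
    full = ModelSpec(full_model_terms(design))
    for m in samples.metabolite_ids:
        y = samples.column(m)
        if selection:
            spec, fit = hierarchical_select(y, design, alpha=alpha)
        else:
            dm = build_design_matrix(design, full)
            fit = fit_model(y, dm)
            spec = ModelSpec(list(full.terms), kept=True,
                             trace=[{"step": "fixed-full-model", "term": "all",
                                     "p_value": np.nan, "action": "no selection"}])
        kept[m] = spec.kept
        specs[m] = spec
        fits[m] = fit
        if spec.kept:
            dm_sel = build_design_matrix(design, spec)
            parts[m] = extract_covariable_part(fit, dm_sel, spec)
    cov_parts = None
    kept_ids = [m for m in samples.metabolite_ids if kept[m]]
    if len(kept_ids) >= 2:
        cov_parts = SampleTable(
            samples.sample_ids,
            kept_ids,
            np.column_stack([parts[m] for m in kept_ids]),
        )
    return DecompositionResult(
        metabolite_ids=list(samples.metabolite_ids),
        kept=kept,
        specs=specs,
        fits=fits,
        covariable_parts=cov_parts,
        alpha=alpha,
    )


def adjust_nuisance(samples: SampleTable, nuisance: pd.DataFrame) -> SampleTable:
    """Replace each metabolite by its OLS residual on the nuisance columns.

    Constant nuisance columns are absorbed by the intercept (pure
    mean-centering); collinear adjusters raise.  Residuals have zero sample
    correlation with every adjuster.
    """
    Z = nuisance.to_numpy(dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != samples.n_samples:
        raise ValueError("nuisance table does not match the sample table")
    keep = [j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
    X = np.column_stack([np.ones(samples.n_samples)] + [Z[:, j] for j in keep])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear nuisance adjusters")
    beta, _, _, _ = np.linalg.lstsq(X, samples.values, rcond=None)
    resid = samples.values - X @ beta
    return SampleTable(samples.sample_ids, samples.metabolite_ids, resid)


def categorize_continuous(
    x: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a continuous covariable into ``n_classes`` equally sized classes.

    Boundaries sit at the empirical quantiles ``i/n_classes`` (linear
    interpolation); classes are ordered and coded ``1..n_classes``, the lowest
    class being the natural reference.  Returns ``(codes, boundaries)``.
    Ties that empty a class raise with a suggestion to use fewer classes.
    """
    x = np.asarray(x, dtype=float)
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if x.size < n_classes:
        raise ValueError("more classes than samples")
    qs = np.arange(1, n_classes) / n_classes
    boundaries = np.quantile(x, qs)
    codes = np.searchsorted(boundaries, x, side="left") + 1
    counts = np.bincount(codes, minlength=n_classes + 1)[1:]
    if np.any(counts == 0):
        empty = int(np.argmin(counts)) + 1
        raise ValueError(
            f"ties leave class {empty} empty; try fewer than {n_classes} classes"
        )
    return codes, boundaries
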