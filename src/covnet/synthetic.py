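"""Synthetic metabolite studies with known covariable-effect structure.

Two study designs are emulated.  The *factorial* design mirrors a 2x2x2
seed-physiology experiment: two genotypes crossed with two binary treatments
(osmotic stress by PEG, abscisic acid), with unbalanced cell counts
(wild type: 6 control + 3 per treated cell; mutant: 3 per cell; N = 27).
The *observational* design mirrors a population cohort: sex ~ Bernoulli(0.5),
age ~ Uniform(25, 74), and a continuous adiposity score categorized into
thirtiles that serves as the categorical covariable of interest (N = 419).

Metabolites are generated from the same interaction model the decomposition
fits: each module of metabolites shares one template of target-covariable
coefficients (main effect plus interactions), every metabolite additionally
receives its own random non-target (nuisance) coefficients, and residuals
are multivariate Gaussian with exchangeable correlation ``rho`` within a
module and independence between modules.  The planted coefficients and
module labels are returned for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import (
    ModelSpec,
    build_design_matrix,
    categorize_continuous,
    full_model_terms,
)
from .tables import Covariable, DesignTable, SampleTable

__all__ = [
    "ModuleTemplate",
    "ScenarioSpec",
    "GroundTruth",
    "simulate_design",
    "simulate_metabolites",
    "simulate_scenario",
    "FACTORIAL_CELL_COUNTS",
]

#: (genotype, PEG, ABA) -> sample count; the unbalanced 2x2x2 default design
FACTORIAL_CELL_COUNTS: dict[tuple[str, int, int], int] = {
    ("wildtype", 0, 0): 6,
    ("wildtype", 1, 0): 3,
    ("wildtype", 0, 1): 3,
    ("wildtype", 1, 1): 3,
    ("mutant", 0, 0): 3,
    ("mutant", 1, 0): 3,
    ("mutant", 0, 1): 3,
    ("mutant", 1, 1): 3,
}


@dataclass
class ModuleTemplate:
    """Target-covariable coefficient pattern shared by one module.

    ``beta1`` is the target main effect; ``eta`` maps each non-target subset
    (0/1 vector) to the coefficient of the corresponding interaction with
    the target.  Values are expressed in units of the residual sd.
    """

    beta1: float = 0.0
    eta: dict[tuple[int, ...], float] = field(default_factory=dict)


@dataclass
class ScenarioSpec:
    """Full description of one synthetic study."""

    kind: str = "factorial"  # or "observational"
    cell_counts: dict | None = None  # factorial only
    n_samples: int = 419  # observational only
    module_sizes: tuple[int, ...] = (12, 12)
    n_background: int = 0  # metabolites with no target effect
    templates: tuple[ModuleTemplate, ...] | None = None
    rho: float = 0.3  # within-module residual correlation
    sigma: float = 1.0  # residual sd
    nuisance_sd: float = 0.0  # sd of per-metabolite non-target coefficients
    baseline: float = 10.0  # intercept (arbitrary concentration scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("factorial", "observational"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.templates is None:
            # two modules responding to the target through opposite-sign vs
            # same-sign treatment interactions: strong (5 sd) and mutually
            # near-orthogonal target-effect patterns
            self.templates = (
                ModuleTemplate(beta1=0.0, eta={(1, 0): 5.0, (0, 1): -5.0}),
                ModuleTemplate(beta1=0.0, eta={(1, 0): 5.0, (0, 1): 5.0}),
            )
        if len(self.templates) != len(self.module_sizes):
            raise ValueError("need one template per module")

    @property
    def n_metabolites(self) -> int:
        return sum(self.module_sizes) + self.n_background


@dataclass
class GroundTruth:
    """Planted structure: module labels and the coefficient matrix used."""

    module_labels: np.ndarray  # per metabolite; 0 = background
    coefficients: pd.DataFrame  # design columns x metabolites

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.T.copy()
        out.insert(0, "module", self.module_labels)
        return out


def simulate_design(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> DesignTable:
    """Draw the covariable table for a scenario."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.kind == "factorial":
        counts = spec.cell_counts or FACTORIAL_CELL_COUNTS
        if any(c < 1 for c in counts.values()):
            raise ValueError("every design cell needs at least one sample")
        rows = []
        for (geno, peg, aba), count in counts.items():
            rows += [{"genotype": geno, "PEG": peg, "ABA": aba}] * count
        data = pd.DataFrame(rows)
        ids = [f"s{i + 1:03d}" for i in range(len(data))]
        return DesignTable(
            ids,
            data,
            [
                Covariable("genotype", "categorical", reference="wildtype"),
                Covariable("PEG", "categorical", reference=0),
                Covariable("ABA", "categorical", reference=0),
            ],
            target="genotype",
        )
    n = spec.n_samples
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.uniform(25, 74, size=n)
    adiposity = rng.normal(26.5, 4.2, size=n)
    codes, _ = categorize_continuous(adiposity, 3)
    data = pd.DataFrame(
        {"age": age, "sex": sex, "bmi_class": codes, "adiposity": adiposity}
    )
    ids = [f"s{i + 1:04d}" for i in range(n)]
    return DesignTable(
        ids,
        data,
        [
            Covariable("age", "continuous"),
            Covariable("sex", "categorical", reference="F"),
            Covariable("bmi_class", "categorical", reference=1),
        ],
        target="bmi_class",
    )


def _column_scale(design: DesignTable, column: str) -> float:
    """Scale factor keeping planted effects comparable across covariable types.

    Interaction columns involving a continuous covariable (e.g. age) have a
    much larger numeric range than indicators; the planted coefficient is
    divided by the product of the sample sd of each continuous constituent,
    so template values stay interpretable in residual-sd units.
    """
    scale = 1.0
    for cov in design.covariables:
        if cov.kind == "continuous" and cov.name in column.split(":"):
            scale *= float(np.std(pd.to_numeric(design.data[cov.name])))
    return scale


def simulate_metabolites(
    design: DesignTable,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> tuple[SampleTable, GroundTruth]:
    """Generate the metabolite matrix for a design, returning the ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    dm = build_design_matrix(design, ModelSpec(full_model_terms(design)))
    cols = list(dm.X.columns)
    n = design.n_samples
    p = spec.n_metabolites
    labels = np.concatenate(
        [np.full(size, i + 1) for i, size in enumerate(spec.module_sizes)]
        + [np.zeros(spec.n_background, dtype=int)]
    ).astype(int)

    B = pd.DataFrame(0.0, index=cols, columns=range(p))
    for j in range(p):
        B.loc["(intercept)", j] = spec.baseline
        # per-metabolite random nuisance (non-target) coefficients
        if spec.nuisance_sd > 0:
            for term in dm.terms:
                if term.role != "gamma":
                    continue
                for c in dm.groups[term.label(dm.target, dm.others)]:
                    B.loc[c, j] = (
                        rng.normal(0, spec.nuisance_sd)
                        * spec.sigma / _column_scale(design, c)
                    )
        if labels[j] == 0:
            continue
        tpl = spec.templates[labels[j] - 1]
        for term in dm.terms:
            if not term.involves_target:
                continue
            coef = tpl.beta1 if term.role == "target" else tpl.eta.get(term.delta, 0.0)
            if coef == 0.0:
                continue
            for c in dm.groups[term.label(dm.target, dm.others)]:
                B.loc[c, j] = coef * spec.sigma / _column_scale(design, c)

    mean = dm.X.to_numpy(dtype=float) @ B.to_numpy()
    resid = np.empty((n, p))
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        z = rng.standard_normal((n, idx.size))
        if mod > 0 and spec.rho > 0:
            common = rng.standard_normal((n, 1))
            block = np.sqrt(spec.rho) * common + np.sqrt(1 - spec.rho) * z
        else:
            block = z
        resid[:, idx] = spec.sigma * block

    met_ids = [f"m{j + 1:03d}" for j in range(p)]
    samples = SampleTable(design.sample_ids, met_ids, mean + resid)
    B.columns = met_ids
    return samples, GroundTruth(module_labels=labels, coefficients=B)


def simulate_scenario(
    spec: ScenarioSpec,
) -> tuple[SampleTable, DesignTable, GroundTruth]:
    """Draw design and metabolites from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    design = simulate_design(spec, rng)
    samples, truth = simulate_metabolites(design, spec, rng)
    return samples, design, truth
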