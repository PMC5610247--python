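"""Core data containers: sample-by-metabolite matrices and covariable designs.

The two tables mirror the inputs of a designed (or observational) metabolomics
study: a numeric concentration matrix ``Y`` with one row per sample and one
column per metabolite, and a per-sample covariable table in which exactly one
categorical column is designated as the covariable of interest (genotype, BMI
class, ...).  Both are thin, validated wrappers around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleTable", "Covariable", "DesignTable"]


@dataclass
class SampleTable:
    """N x P matrix of metabolite concentrations with row/column identifiers.

    Parameters
    ----------
    sample_ids : ordered, unique sample identifiers (length N).
    metabolite_ids : ordered, unique metabolite identifiers (length P).
    values : real N x P array; every entry must be finite.
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.metabolite_ids):
            raise ValueError(
                f"values has {p} columns but {len(self.metabolite_ids)} metabolite ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len(set(self.metabolite_ids)) != p:
            raise ValueError("metabolite ids are not unique")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 metabolites, got {p}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite concentration for sample "
                f"{self.sample_ids[i]!r}, metabolite {self.metabolite_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def column(self, metabolite: str) -> np.ndarray:
        return self.values[:, self.metabolite_ids.index(metabolite)]

    def subset(self, metabolites: list[str]) -> "SampleTable":
        idx = [self.metabolite_ids.index(m) for m in metabolites]
        return SampleTable(self.sample_ids, list(metabolites), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class Covariable:
    """Declaration of one covariable column.

    ``kind`` is ``"categorical"`` (finite levels, indicator-coded against
    ``reference``) or ``"continuous"``.  For categorical columns with no
    declared reference the first level in sorted order is used.
    """

    name: str
    kind: str = "categorical"
    reference: object | None = None
    levels: list | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariable kind {self.kind!r}")


@dataclass
class DesignTable:
    """Per-sample covariables with one designated covariable of interest.

    The target covariable must be categorical with at least two levels; its
    part of each metabolite's variation is what the covariable-specific
    network is built from.
    """

    sample_ids: list[str]
    data: pd.DataFrame
    covariables: list[Covariable]
    target: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if len(self.data) != len(self.sample_ids):
            raise ValueError("covariable table does not match sample ids")
        names = [c.name for c in self.covariables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariable names")
        missing = set(names) - set(self.data.columns)
        if missing:
            raise ValueError(f"covariables not in table: {sorted(missing)}")
        if self.target not in names:
            raise ValueError(f"target covariable {self.target!r} not declared")
        tgt = self.covariable(self.target)
        if tgt.kind != "categorical":
            raise ValueError("target covariable must be categorical")
        # resolve levels and references once, in sorted order when undeclared
        for cov in self.covariables:
            if cov.kind != "categorical":
                continue
            observed = sorted(pd.unique(self.data[cov.name]).tolist())
            if cov.levels is None:
                cov.levels = observed
            if cov.reference is None:
                cov.reference = cov.levels[0]
            if cov.reference not in cov.levels:
                raise ValueError(
                    f"reference {cov.reference!r} is not a level of {cov.name!r}"
                )
        if len(tgt.levels) < 2:
            raise ValueError("target covariable needs at least 2 levels")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariable(self, name: str) -> Covariable:
        for cov in self.covariables:
            if cov.name == name:
                return cov
        raise KeyError(name)

    @property
    def non_target_names(self) -> list[str]:
        return [c.name for c in self.covariables if c.name != self.target]

    def indicator_columns(self, name: str) -> pd.DataFrame:
        """Indicator (reference-coded) columns for a covariable.

        Continuous covariables come back as a single numeric column; a
        categorical covariable with L levels yields L-1 indicator columns
        named ``name[level]``.
        """
        cov = self.covariable(name)
        if cov.kind == "continuous":
            return pd.DataFrame(
                {name: pd.to_numeric(self.data[name]).to_numpy(dtype=float)}
            )
        cols = {}
        for level in cov.levels:
            if level == cov.reference:
                continue
            cols[f"{name}[{level}]"] = (
                (self.data[name] == level).to_numpy(dtype=float)
            )
        return pd.DataFrame(cols)

    def align_to(self, samples: SampleTable) -> "DesignTable":
        """Reorder rows to match a SampleTable's sample order."""
        if set(self.sample_ids) != set(samples.sample_ids):
            missing = sorted(set(samples.sample_ids) - set(self.sample_ids))
            extra = sorted(set(self.sample_ids) - set(samples.sample_ids))
            raise ValueError(
                f"sample id mismatch: missing from design {missing}, "
                f"not in samples {extra}"
            )
        order = [self.sample_ids.index(s) for s in samples.sample_ids]
        return DesignTable(
            list(samples.sample_ids),
            self.data.iloc[order].reset_index(drop=True),
            self.covariables,
            self.target,
        )
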