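import numpy as np
import pandas as pd
import pytest

from covnet.tables import Covariable, DesignTable, SampleTable


@pytest.fixture
def factorial_design() -> DesignTable:
    """Unbalanced 2x2x2 genotype-by-treatment design (N=27)."""
    from covnet.synthetic import ScenarioSpec, simulate_design

    return simulate_design(ScenarioSpec(kind="factorial", seed=0))


@pytest.fixture
def binary_design() -> DesignTable:
    """Small binary-target design with two binary covariables (N=16)."""
    rows = []
    for g in (0, 1):
        for a in (0, 1):
            for b in (0, 1):
                rows += [{"group": g, "A": a, "B": b}] * 2
    data = pd.DataFrame(rows)
    return DesignTable(
        [f"s{i}" for i in range(len(data))],
        data,
        [
            Covariable("group", "categorical", reference=0),
            Covariable("A", "categorical", reference=0),
            Covariable("B", "categorical", reference=0),
        ],
        target="group",
    )


def make_samples(values: np.ndarray, sample_ids=None) -> SampleTable:
    n, p = values.shape
    return SampleTable(
        sample_ids or [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(p)],
        values,
    )
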