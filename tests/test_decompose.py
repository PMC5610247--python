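"""Interaction-model decomposition: design expansion, fitting, selection, extraction."""

import numpy as np
import pandas as pd
import pytest

from covnet.decompose import (
    ModelSpec,
    TermSpec,
    adjust_nuisance,
    build_design_matrix,
    categorize_continuous,
    decompose,
    expand_terms,
    extract_covariable_part,
    fit_model,
    full_model_terms,
    hierarchical_select,
)
from covnet.tables import Covariable, DesignTable, SampleTable

from conftest import make_samples


class TestExpandTerms:
    @pytest.mark.parametrize(
        "m_minus_1, expected",
        [
            (0, []),
            (1, [(1,)]),
            (2, [(0, 1), (1, 0), (1, 1)]),
        ],
    )
    def test_small_cases(self, m_minus_1, expected):
        assert expand_terms(m_minus_1) == expected

    def test_counts_match_brute_force(self):
        # brute force: all binary vectors of length 3 except the zero vector
        brute = {
            (a, b, c)
            for a in (0, 1) for b in (0, 1) for c in (0, 1)
            if a or b or c
        }
        got = expand_terms(3)
        assert set(got) == brute
        assert len(got) == 2**3 - 1
        assert got == sorted(got)  # lexicographic


class TestBuildDesignMatrix:
    def test_full_binary_expansion_has_eight_columns(self, binary_design):
        dm = build_design_matrix(binary_design, ModelSpec(full_model_terms(binary_design)))
        # intercept + target + 3 gamma products + 3 target interactions
        assert dm.X.shape[1] == 8
        assert len(dm.groups) == 8

    def test_intercept_only(self, binary_design):
        dm = build_design_matrix(binary_design, ModelSpec([TermSpec("intercept")]))
        assert dm.X.shape[1] == 1
        assert (dm.X.to_numpy() == 1).all()

    def test_multilevel_target_indicator_counts(self):
        data = pd.DataFrame(
            {"grp": ["a", "b", "c"] * 4, "trt": [0, 0, 1, 1] * 3}
        )
        design = DesignTable(
            [f"s{i}" for i in range(12)],
            data,
            [
                Covariable("grp", "categorical", reference="a"),
                Covariable("trt", "categorical", reference=0),
            ],
            target="grp",
        )
        dm = build_design_matrix(design, ModelSpec(full_model_terms(design)))
        # intercept + 2 target indicators + 1 gamma + 2 interaction columns
        assert dm.X.shape[1] == 6

    def test_empty_cell_reports_unestimable_term(self, binary_design):
        # remove every treated-mutant sample so the 3-way interaction is empty
        mask = ~(
            (binary_design.data["group"] == 1)
            & (binary_design.data["A"] == 1)
            & (binary_design.data["B"] == 1)
        )
        design = DesignTable(
            [s for s, m in zip(binary_design.sample_ids, mask) if m],
            binary_design.data[mask].reset_index(drop=True),
            binary_design.covariables,
            "group",
        )
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            build_design_matrix(design, ModelSpec(full_model_terms(design)))


class TestFitModel:
    def test_exact_linear_fit_has_zero_residuals(self, binary_design):
        dm = build_design_matrix(
            binary_design, ModelSpec([TermSpec("intercept"), TermSpec("target")])
        )
        y = 1.0 + 2.0 * dm.X["group[1]"].to_numpy()
        fit = fit_model(y, dm)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_response_gives_zero_slopes(self, binary_design):
        dm = build_design_matrix(
            binary_design, ModelSpec([TermSpec("intercept"), TermSpec("target")])
        )
        fit = fit_model(np.full(binary_design.n_samples, 3.0), dm)
        assert fit.coef["(intercept)"] == pytest.approx(3.0)
        assert fit.coef["group[1]"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, binary_design):
        rng = np.random.default_rng(42)
        dm = build_design_matrix(
            binary_design,
            ModelSpec([TermSpec("intercept"), TermSpec("target"), TermSpec("gamma", (1, 0))]),
        )
        y = rng.normal(size=binary_design.n_samples)
        fit = fit_model(y, dm)
        X = dm.X.to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta_oracle, atol=1e-8)


class TestHierarchicalSelect:
    def test_strong_three_way_interaction_keeps_full_model(self, factorial_design):
        rng = np.random.default_rng(1)
        from covnet.decompose import build_design_matrix as bdm

        dm = bdm(factorial_design, ModelSpec(full_model_terms(factorial_design)))
        # plant a 5-sd three-way interaction
        y = 5.0 * dm.X["genotype[mutant]:PEG[1]:ABA[1]"].to_numpy() + rng.normal(
            size=factorial_design.n_samples
        )
        spec, _ = hierarchical_select(y, factorial_design, alpha=0.05)
        assert spec.kept
        assert spec.has("eta", (1, 1))

    def test_main_effect_only_drops_interactions(self, factorial_design):
        rng = np.random.default_rng(2)
        geno = (factorial_design.data["genotype"] == "mutant").to_numpy(float)
        y = 5.0 * geno + rng.normal(size=factorial_design.n_samples)
        spec, _ = hierarchical_select(y, factorial_design, alpha=0.05)
        assert spec.kept
        assert spec.has("target")
        assert not any(t.role == "eta" for t in spec.terms)

    def test_null_target_discards(self, factorial_design):
        rng = np.random.default_rng(3)
        kept = 0
        for _ in range(100):
            y = rng.normal(size=factorial_design.n_samples)
            spec, _ = hierarchical_select(y, factorial_design, alpha=0.05)
            kept += spec.kept
        # 100 null metabolites: expect about 5 kept, allow a wide band
        assert kept <= 15

    def test_hierarchy_never_keeps_eta_above_removed_order(self, factorial_design):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.normal(size=factorial_design.n_samples) + rng.choice(
                [0, 5]
            ) * (factorial_design.data["genotype"] == "mutant").to_numpy(float)
            spec, _ = hierarchical_select(y, factorial_design)
            removed = [
                int(s["step"].split("-")[-1])
                for s in spec.trace
                if s["step"].startswith("eta-order") and s["action"] == "removed"
            ]
            if removed:
                max_removed = max(removed)
                assert all(
                    t.order < max_removed for t in spec.terms if t.role == "eta"
                )


class TestExtractCovariablePart:
    def test_binary_main_effect_direct_substitution(self, binary_design):
        dm = build_design_matrix(
            binary_design, ModelSpec([TermSpec("intercept"), TermSpec("target")])
        )
        y = 1.0 + 2.0 * dm.X["group[1]"].to_numpy()
        fit = fit_model(y, dm)
        spec = ModelSpec([TermSpec("intercept"), TermSpec("target")])
        part = extract_covariable_part(fit, dm, spec)
        np.testing.assert_allclose(part, 2.0 * dm.X["group[1]"].to_numpy(), atol=1e-10)

    def test_refuses_discarded_metabolite(self, binary_design):
        dm = build_design_matrix(binary_design, ModelSpec([TermSpec("intercept")]))
        fit = fit_model(np.ones(binary_design.n_samples), dm)
        spec = ModelSpec([TermSpec("intercept")], kept=False)
        with pytest.raises(ValueError, match="discarded"):
            extract_covariable_part(fit, dm, spec)

    def test_factorial_cell_means_oracle(self, factorial_design):
        # plant known coefficients and verify the extracted part per design cell
        beta1, e10, e01, e11 = 1.0, 0.5, -0.5, 2.0
        dm = build_design_matrix(
            factorial_design, ModelSpec(full_model_terms(factorial_design))
        )
        g = dm.X["genotype[mutant]"].to_numpy()
        peg = dm.X["PEG[1]"].to_numpy()
        aba = dm.X["ABA[1]"].to_numpy()
        y = beta1 * g + e10 * g * peg + e01 * g * aba + e11 * g * peg * aba
        fit = fit_model(y, dm)
        spec = ModelSpec(full_model_terms(factorial_design))
        part = extract_covariable_part(fit, dm, spec)
        # enumerate the 8 cells: wild type contributes 0; mutant cells add up
        for gi, pi, ai in [(0, 0, 0), (0, 1, 1), (1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1)]:
            expected = gi * (beta1 + e10 * pi + e01 * ai + e11 * pi * ai)
            cell = (g == gi) & (peg == pi) & (aba == ai)
            np.testing.assert_allclose(part[cell], expected, atol=1e-8)

    def test_null_coefficients_give_zero_part(self, factorial_design):
        dm = build_design_matrix(
            factorial_design, ModelSpec(full_model_terms(factorial_design))
        )
        y = np.ones(factorial_design.n_samples)  # no target signal at all
        fit = fit_model(y, dm)
        part = extract_covariable_part(fit, dm, ModelSpec(full_model_terms(factorial_design)))
        np.testing.assert_allclose(part, 0.0, atol=1e-10)


class TestReconstruction:
    def test_full_model_reconstructs_response(self, factorial_design):
        rng = np.random.default_rng(7)
        y = rng.normal(size=factorial_design.n_samples)
        spec = ModelSpec(full_model_terms(factorial_design))
        dm = build_design_matrix(factorial_design, spec)
        fit = fit_model(y, dm)
        part = extract_covariable_part(fit, dm, spec)
        non_target = [t for t in spec.terms if not t.involves_target]
        cols = dm.columns_for(non_target)
        rest = dm.X[cols].to_numpy() @ fit.coef[cols].to_numpy()
        np.testing.assert_allclose(part + rest + fit.residuals, y, atol=1e-8)


class TestDecomposeTable:
    def test_discarded_metabolites_absent_from_parts(self, factorial_design):
        rng = np.random.default_rng(11)
        n = factorial_design.n_samples
        geno = (factorial_design.data["genotype"] == "mutant").to_numpy(float)
        signal = 6.0 * geno[:, None] + rng.normal(size=(n, 2))
        null = rng.normal(size=(n, 3))
        samples = make_samples(
            np.column_stack([signal, null]), sample_ids=factorial_design.sample_ids
        )
        deco = decompose(samples, factorial_design)
        assert deco.kept["m0"] and deco.kept["m1"]
        parts_ids = deco.covariable_parts.metabolite_ids
        assert {"m0", "m1"} <= set(parts_ids)
        assert set(parts_ids) == set(deco.kept_ids)
        report = deco.report()
        assert set(report["metabolite"]) == {f"m{i}" for i in range(5)}

    def test_no_selection_keeps_everything(self, factorial_design):
        rng = np.random.default_rng(12)
        samples = make_samples(
            rng.normal(size=(factorial_design.n_samples, 4)),
            sample_ids=factorial_design.sample_ids,
        )
        deco = decompose(samples, factorial_design, selection=False)
        assert all(deco.kept.values())
        assert deco.covariable_parts.n_metabolites == 4


class TestAdjustNuisance:
    def test_exact_dependence_leaves_zero_residuals(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=20)
        samples = make_samples(np.column_stack([2.0 * z, -z]))
        out = adjust_nuisance(samples, pd.DataFrame({"z": z}))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_constant_adjuster_mean_centers(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(15, 3)) + 7.0
        samples = make_samples(vals)
        out = adjust_nuisance(samples, pd.DataFrame({"c": np.ones(15)}))
        np.testing.assert_allclose(out.values, vals - vals.mean(axis=0), atol=1e-10)

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(25, 2))
        vals = rng.normal(size=(25, 4))
        samples = make_samples(vals)
        out = adjust_nuisance(samples, pd.DataFrame(Z, columns=["a", "b"]))
        X = np.column_stack([np.ones(25), Z])
        P = np.eye(25) - X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(out.values, P @ vals, atol=1e-8)
        # residuals uncorrelated with each adjuster
        for j in range(2):
            corr = np.corrcoef(out.values[:, 0], Z[:, j])[0, 1]
            assert abs(corr) < 1e-8

    def test_collinear_adjusters_raise(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=10)
        samples = make_samples(rng.normal(size=(10, 2)))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            adjust_nuisance(samples, pd.DataFrame({"a": z, "b": 2 * z}))


class TestCategorizeContinuous:
    def test_nine_values_three_classes(self):
        codes, bounds = categorize_continuous(np.arange(1.0, 10.0), 3)
        np.testing.assert_allclose(bounds, [11 / 3, 19 / 3])
        assert np.bincount(codes)[1:].tolist() == [3, 3, 3]

    def test_each_sample_its_own_class(self):
        codes, _ = categorize_continuous(np.array([3.0, 1.0, 2.0]), 3)
        assert sorted(codes.tolist()) == [1, 2, 3]

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="fewer"):
            categorize_continuous(np.ones(9), 3)
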