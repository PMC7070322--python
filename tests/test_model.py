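"""OLS fitting, term elimination, and fit statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqbd import (DesignPoint, DesignTable, Factor, TermSpec,
                  backward_eliminate, build_model_matrix,
                  coefficient_intervals, fit_ols, fit_statistics,
                  full_quadratic, generate_ccf, model_from_json,
                  model_to_json)
from aqbd.datasets import RESPONSE_NAMES


def random_table(rng, n_runs, k, response=None):
    factors = [Factor(f"f{i}", 0.0, 1.0) for i in range(k)]
    points = []
    for i in range(n_runs):
        levels = {f.name: float(rng.uniform(0, 1)) for f in factors}
        coded = {f.name: f.code(levels[f.name]) for f in factors}
        points.append(DesignPoint(f"N{i+1}", levels, coded, "factorial"))
    responses = {"y": list(response)} if response is not None else {}
    return DesignTable(factors=factors, points=points, responses=responses)


class TestModelMatrix:
    def test_full_quadratic_term_count(self, ccf_design):
        terms = full_quadratic(ccf_design.factor_names)
        M = build_model_matrix(ccf_design, terms)
        assert M.shape == (17, 10)

    def test_center_row_is_intercept_only(self, ccf_design):
        terms = full_quadratic(ccf_design.factor_names)
        M = build_model_matrix(ccf_design, terms)
        center_rows = M[ccf_design.center_mask()]
        expected = np.zeros(10)
        expected[0] = 1.0
        for row in center_rows:
            np.testing.assert_array_equal(row, expected)

    def test_corner_row_selected_terms(self, factors):
        table = generate_ccf(factors, n_center=0)
        terms = [TermSpec("intercept"),
                 TermSpec("linear", ("acetonitrile",)),
                 TermSpec("interaction", ("acetonitrile", "temperature"))]
        M = build_model_matrix(table, terms)
        # corner (+1, +1, -1) is the binary-order row (1,1,0) -> index 6
        coded = table.coded_matrix()
        idx = int(np.flatnonzero(
            (coded == np.array([1.0, 1.0, -1.0])).all(axis=1))[0])
        np.testing.assert_array_equal(M[idx], [1.0, 1.0, -1.0])

    def test_unknown_factor_rejected(self, ccf_design):
        with pytest.raises(KeyError, match="nope"):
            build_model_matrix(ccf_design, [TermSpec("linear", ("nope",))])


class TestFitOLS:
    def test_noise_free_recovery(self, factors):
        table = generate_ccf(factors, n_center=3)
        terms = full_quadratic(table.factor_names)
        rng = np.random.default_rng(7)
        truth = rng.normal(size=len(terms))
        y = build_model_matrix(table, terms) @ truth
        model = fit_ols(table.with_responses({"y": list(y)}), "y", terms)
        np.testing.assert_allclose(model.coefficients, truth, atol=1e-10)
        np.testing.assert_allclose(model.residuals, 0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, 8, 2, response=rng.normal(size=8))
        terms = [TermSpec("intercept"), TermSpec("linear", ("f0",)),
                 TermSpec("linear", ("f1",))]
        model = fit_ols(table, "y", terms)
        M = build_model_matrix(table, terms)
        y = table.response("y")
        oracle = np.linalg.solve(M.T @ M, M.T @ y)
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-10)

    def test_matches_statsmodels(self, ccf_design):
        sm = pytest.importorskip("statsmodels.api")
        terms = full_quadratic(ccf_design.factor_names)
        M = build_model_matrix(ccf_design, terms)
        for rname in RESPONSE_NAMES:
            model = fit_ols(ccf_design, rname, terms)
            ref = sm.OLS(ccf_design.response(rname), M).fit()
            np.testing.assert_allclose(model.coefficients, ref.params,
                                       atol=1e-9)
            np.testing.assert_allclose(
                np.sqrt(np.diag(model.coefficient_covariance)), ref.bse,
                atol=1e-9)
            np.testing.assert_allclose(model.term_p_values, ref.pvalues,
                                       atol=1e-9)

    def test_rank_deficiency_names_terms(self, ccf_design):
        terms = [TermSpec("intercept"), TermSpec("linear", ("acetonitrile",)),
                 TermSpec("linear", ("acetonitrile",))]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(ccf_design, "R1", terms)

    def test_run_order_invariance(self, ccf_design):
        terms = full_quadratic(ccf_design.factor_names)
        base = fit_ols(ccf_design, "R1", terms)
        rng = np.random.default_rng(3)
        perm = rng.permutation(ccf_design.n_runs)
        shuffled = DesignTable(
            factors=ccf_design.factors,
            points=[ccf_design.points[i] for i in perm],
            responses={r: [v[i] for i in perm]
                       for r, v in ccf_design.responses.items()})
        other = fit_ols(shuffled, "R1", terms)
        np.testing.assert_allclose(other.coefficients, base.coefficients,
                                   atol=1e-12)


class TestBackwardElimination:
    def test_noise_free_full_quadratic_keeps_all_terms(self, factors):
        table = generate_ccf(factors, n_center=3)
        terms = full_quadratic(table.factor_names)
        rng = np.random.default_rng(11)
        truth = rng.uniform(0.5, 2.0, size=len(terms))
        y = build_model_matrix(table, terms) @ truth
        model = backward_eliminate(table.with_responses({"y": list(y)}), "y")
        assert set(model.terms) == set(terms)

    def test_linear_truth_drops_higher_order_terms(self, factors):
        # with only linear effects, square/interaction terms are removed;
        # allow the nominal-alpha false-retention rate across seeds
        table = generate_ccf(factors, n_center=3)
        lin_terms = [TermSpec("intercept")] + \
            [TermSpec("linear", (n,)) for n in table.factor_names]
        M = build_model_matrix(table, lin_terms)
        truth = np.array([10.0, 3.0, -2.0, 1.5])
        clean = M @ truth
        n_extra = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 0.05, size=len(clean))
            model = backward_eliminate(table.with_responses({"y": list(y)}),
                                       "y")
            assert all(TermSpec("linear", (n,)) in model.terms
                       for n in table.factor_names)
            n_extra += sum(1 for t in model.terms
                           if t.kind in ("square", "interaction"))
        # 6 candidate spurious terms per seed at alpha=0.05
        assert n_extra <= 0.05 * 6 * n_seeds + 3 * np.sqrt(0.05 * 6 * n_seeds)

    def test_rt_model_keeps_square_and_interaction(self, fitted_models):
        terms = set(fitted_models["RT"].terms)
        assert TermSpec("square", ("acetonitrile",)) in terms
        assert TermSpec("interaction", ("acetonitrile", "flow_rate")) in terms

    def test_hierarchy_protects_linear_terms(self, fitted_models):
        for model in fitted_models.values():
            names = {t.factors[0] for t in model.terms if t.kind == "linear"}
            for t in model.terms:
                if t.kind in ("square", "interaction"):
                    assert set(t.factors) <= names


class TestFitStatistics:
    def test_press_matches_explicit_leave_one_out(self, ccf_design):
        terms = full_quadratic(ccf_design.factor_names)
        y = ccf_design.response("R1")
        M = build_model_matrix(ccf_design, terms)
        model = fit_ols(ccf_design, "R1", terms)
        stats = fit_statistics(model, ccf_design)
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            b = np.linalg.lstsq(M[keep], y[keep], rcond=None)[0]
            press += (y[i] - M[i] @ b) ** 2
        assert stats.press == pytest.approx(press, abs=1e-9)

    def test_reproducibility_from_center_replicates(self, fitted_models,
                                                    ccf_design):
        st1 = fit_statistics(fitted_models["R1"], ccf_design)
        assert round(st1.reproducibility, 4) == 0.9986
        # R2 centre replicates are identical -> zero pure error
        st2 = fit_statistics(fitted_models["R2"], ccf_design)
        assert st2.ms_pure_error == pytest.approx(0.0, abs=1e-18)
        assert round(st2.reproducibility, 4) == 1.0

    def test_no_residual_dof_rejected(self):
        rng = np.random.default_rng(0)
        terms = [TermSpec("intercept"), TermSpec("linear", ("f0",)),
                 TermSpec("square", ("f0",))]
        with pytest.raises(ValueError, match="runs cannot identify"):
            fit_ols(random_table(rng, 3, 1, response=rng.normal(size=3)),
                    "y", terms)

    def test_unit_leverage_makes_press_undefined(self):
        # two replicated levels plus one isolated level: the isolated run
        # determines its own fitted value exactly (h_ii = 1)
        f = Factor("f0", 0.0, 1.0)
        points = [DesignPoint(f"N{i+1}", {"f0": x}, {"f0": f.code(x)},
                              "factorial")
                  for i, x in enumerate([0.0, 0.0, 0.0, 1.0])]
        table = DesignTable(factors=[f], points=points,
                            responses={"y": [1.0, 1.2, 0.9, 5.0]})
        terms = [TermSpec("intercept"), TermSpec("linear", ("f0",))]
        model = fit_ols(table, "y", terms)
        with pytest.raises(ValueError, match="saturated"):
            fit_statistics(model, table)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60)
    def test_q2_never_exceeds_r2(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 16))
        table = random_table(rng, n, 2, response=rng.normal(size=n))
        terms = [TermSpec("intercept"), TermSpec("linear", ("f0",)),
                 TermSpec("linear", ("f1",)),
                 TermSpec("interaction", ("f0", "f1"))]
        model = fit_ols(table, "y", terms)
        stats = fit_statistics(model, table)
        assert stats.q2 <= stats.r2 + 1e-12
        assert stats.r2_adjusted <= stats.r2 + 1e-12

    def test_adding_terms_never_decreases_r2(self, ccf_design):
        base = [TermSpec("intercept"),
                TermSpec("linear", ("acetonitrile",))]
        prev = -np.inf
        for extra in [TermSpec("linear", ("flow_rate",)),
                      TermSpec("linear", ("temperature",)),
                      TermSpec("square", ("acetonitrile",))]:
            base = base + [extra]
            model = fit_ols(ccf_design, "RT", base)
            r2 = fit_statistics(model, ccf_design).r2
            assert r2 >= prev - 1e-12
            prev = r2


class TestIntervalsAndPrediction:
    def test_interval_midpoint_is_estimate(self, fitted_models):
        ci = coefficient_intervals(fitted_models["R1"])
        np.testing.assert_allclose((ci["lower"] + ci["upper"]) / 2,
                                   ci["estimate"], atol=1e-12)

    def test_zero_noise_zero_width(self, factors):
        table = generate_ccf(factors, n_center=3)
        terms = full_quadratic(table.factor_names)
        y = build_model_matrix(table, terms) @ np.ones(len(terms))
        model = fit_ols(table.with_responses({"y": list(y)}), "y", terms)
        ci = coefficient_intervals(model)
        np.testing.assert_allclose(ci["upper"] - ci["lower"], 0, atol=1e-8)

    def test_matches_statsmodels_interval_oracle(self, ccf_design):
        sm = pytest.importorskip("statsmodels.api")
        terms = full_quadratic(ccf_design.factor_names)
        model = fit_ols(ccf_design, "RT", terms)
        ci = coefficient_intervals(model, level=0.95)
        ref = sm.OLS(ccf_design.response("RT"),
                     build_model_matrix(ccf_design, terms)).fit()
        ref_ci = ref.conf_int(alpha=0.05)
        np.testing.assert_allclose(ci["lower"], ref_ci[:, 0], atol=1e-9)
        np.testing.assert_allclose(ci["upper"], ref_ci[:, 1], atol=1e-9)

    def test_center_prediction_is_intercept(self, fitted_models, factors):
        center = {f.name: f.center for f in factors}
        for model in fitted_models.values():
            assert model.predict(center) == pytest.approx(
                model.coefficients[0], abs=1e-12)

    def test_prediction_at_study_optimum(self, fitted_models, optimum_point):
        assert fitted_models["R1"].predict(optimum_point) == \
            pytest.approx(2.593, abs=0.02)

    def test_missing_factor_rejected(self, fitted_models):
        with pytest.raises(KeyError, match="temperature"):
            fitted_models["R1"].predict({"acetonitrile": 45,
                                         "flow_rate": 0.8})


class TestJSONRoundTrip:
    def test_bit_stable(self, fitted_models):
        for model in fitted_models.values():
            back = model_from_json(model_to_json(model))
            np.testing.assert_array_equal(back.coefficients,
                                          model.coefficients)
            np.testing.assert_array_equal(back.coefficient_covariance,
                                          model.coefficient_covariance)
            assert back.terms == model.terms
            assert back.residual_variance == model.residual_variance
            assert back.factors == model.factors
            assert model_to_json(back) == model_to_json(model)
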