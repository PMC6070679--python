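"""Structural equations, local CI tests, Fisher's C, and interventions."""

import numpy as np
import pandas as pd
import pytest

from riversem.causal_graph import DSepStatement, build_diagram
from riversem.ordination import AliasedPredictorsError
from riversem.sem_pipeline import (
    COMMUNITY,
    FisherCResult,
    derive_structural_equations,
    evaluate_model,
    fishers_c,
    fit_equation,
    kfold_predictive_r2,
    local_ci_test,
    partial_regression_data,
    predict_intervention,
)


class TestDeriveEquations:
    def test_fork(self):
        g = build_diagram(["X", "Y", "Z"], [("X", "Y"), ("X", "Z")])
        eqs = derive_structural_equations(g)
        assert {e.child: e.parents for e in eqs} == {"Y": ("X",), "Z": ("X",)}

    def test_empty_diagram(self):
        assert derive_structural_equations(build_diagram(["A", "B"])) == []

    def test_community_equation_flagged_multivariate(self):
        g = build_diagram(
            ["nutrient", "distance", "time", COMMUNITY],
            [("nutrient", COMMUNITY), ("distance", COMMUNITY), ("time", "nutrient")],
        )
        eqs = {e.child: e for e in derive_structural_equations(g)}
        assert eqs[COMMUNITY].multivariate
        assert not eqs["nutrient"].multivariate

    def test_formula_override(self):
        g = build_diagram(["X", "Y"], [("X", "Y")])
        (eq,) = derive_structural_equations(g, formulas={"Y": ["X", "X:X"]})
        assert eq.terms == ("X", "X:X")


class TestFitEquation:
    def test_parameter_recovery(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1.0, n)
        table = pd.DataFrame({"X": x, "Y": y})
        g = build_diagram(["X", "Y"], [("X", "Y")])
        (eq,) = derive_structural_equations(g)
        fitted = fit_equation(eq, table)
        se = fitted.results.bse
        assert abs(fitted.coefficients["const"] - 1.0) < 3 * se["const"]
        assert abs(fitted.coefficients["X"] - 2.0) < 3 * se["X"]
        assert fitted.anova.loc["X", "p"] < 1e-6

    def test_collinear_parents_named(self, rng):
        n = 50
        x = rng.normal(size=n)
        table = pd.DataFrame({"A": x, "B": 2 * x, "Y": rng.normal(size=n)})
        g = build_diagram(["A", "B", "Y"], [("A", "Y"), ("B", "Y")])
        (eq,) = derive_structural_equations(g)
        with pytest.raises(AliasedPredictorsError) as exc:
            fit_equation(eq, table)
        assert set(exc.value.aliased) <= {"A", "B"}

    def test_partial_regression_slope_matches_coefficient(self, rng):
        n = 120
        a = rng.normal(size=n)
        b = 0.5 * a + rng.normal(size=n)
        y = 1.0 + 1.5 * a - 0.7 * b + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"A": a, "B": b, "Y": y})
        g = build_diagram(["A", "B", "Y"], [("A", "Y"), ("B", "Y")])
        (eq,) = derive_structural_equations(g)
        fitted = fit_equation(eq, table)
        clouds = partial_regression_data(fitted, table)
        for term in ("A", "B"):
            cloud = clouds[term]
            slope = np.polyfit(cloud["x_resid"], cloud["y_resid"], 1)[0]
            assert slope == pytest.approx(fitted.coefficients[term], abs=1e-8)

    def test_kfold_r2_positive_for_real_signal(self, rng):
        n = 150
        x = rng.normal(size=n)
        table = pd.DataFrame({"X": x, "Y": 2 * x + rng.normal(0, 0.5, n)})
        g = build_diagram(["X", "Y"], [("X", "Y")])
        (eq,) = derive_structural_equations(g)
        assert kfold_predictive_r2(eq, table, k=5, seed=0) > 0.8


class TestFishersC:
    def test_all_ones(self):
        res = fishers_c([1.0, 1.0, 1.0])
        assert res.C == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_k1_identity(self):
        res = fishers_c([0.05])
        assert res.C == pytest.approx(5.9915, abs=1e-4)
        assert res.p_value == pytest.approx(0.05, abs=1e-9)

    def test_df4_closed_form(self):
        # C = -2(ln .5 + ln .5) = 2.7726; survival = exp(-C/2)(1 + C/2)
        res = fishers_c([0.5, 0.5])
        assert res.C == pytest.approx(2.7726, abs=1e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(np.exp(-res.C / 2) * (1 + res.C / 2), abs=1e-12)
        assert res.p_value == pytest.approx(0.5966, abs=1e-4)

    def test_permutation_invariant_and_monotone(self, rng):
        ps = list(rng.uniform(0.01, 1.0, 6))
        a = fishers_c(ps)
        b = fishers_c(ps[::-1])
        assert a.C == pytest.approx(b.C)
        smaller = sorted(ps)
        smaller[0] /= 2
        c = fishers_c(smaller)
        assert c.C > a.C and c.p_value <= a.p_value

    def test_zero_p_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = fishers_c([0.0, 0.5])
        assert np.isfinite(res.C)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fishers_c([])
        with pytest.raises(ValueError):
            fishers_c([1.5])


class TestLocalCITest:
    def test_power_against_direct_dependence(self, rng):
        g = build_diagram(["X", "Y"], [])  # hypothesised: no arrow
        hits = 0
        for rep in range(30):
            x = rng.normal(size=200)
            y = x + rng.normal(0, 1.0, 200)
            table = pd.DataFrame({"X": x, "Y": y})
            res = local_ci_test(DSepStatement("X", "Y"), g, table)
            hits += res.p_value < 0.05
        assert hits >= 29  # slope 1, noise SD 1, n=200: near-certain detection

    def test_null_rejection_rate_nominal(self, rng):
        # X <- Z -> Y: X ⊥ Y | Z holds exactly
        g = build_diagram(["Z", "X", "Y"], [("Z", "X"), ("Z", "Y")])
        st = DSepStatement("X", "Y", {"Z"})
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            z = rng.normal(size=100)
            table = pd.DataFrame(
                {
                    "Z": z,
                    "X": z + rng.normal(size=100),
                    "Y": -0.5 * z + rng.normal(size=100),
                }
            )
            rejections += local_ci_test(st, g, table).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_response_is_later_in_topological_order(self, rng):
        g = build_diagram(["A", "B", "C"], [("A", "B"), ("B", "C")])
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=["A", "B", "C"])
        res = local_ci_test(DSepStatement("A", "C", {"B"}), g, table)
        assert res.response == "C"
        assert res.test_kind == "nested_F"

    def test_community_statement_uses_dbrda(self, rng):
        n = 30
        g = build_diagram(
            ["W", "N", COMMUNITY], [("N", COMMUNITY)]
        )
        table = pd.DataFrame(
            {"W": rng.normal(size=n), "N": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        com = pd.DataFrame(
            rng.poisson(np.exp(2.0 + np.outer(table["N"], rng.normal(0, 0.5, 8)))),
            index=table.index,
        )
        res = local_ci_test(
            DSepStatement("W", COMMUNITY, {"N"}), g, table, community=com,
            n_permutations=99, seed=0,
        )
        assert res.test_kind == "conditioned_dbrda"
        assert 1 / 100 <= res.p_value <= 1.0


class TestEvaluateModel:
    def test_complete_dag_vacuously_consistent(self, rng):
        g = build_diagram(["A", "B"], [("A", "B")])
        table = pd.DataFrame(rng.normal(size=(30, 2)), columns=["A", "B"])
        ev = evaluate_model(g, table)
        assert ev.status == "vacuously_consistent"
        assert ev.consistent is True
        assert ev.fisher is None

    def test_explicit_latent_makes_statements_untestable(self, rng):
        # a declared latent with no data column pollutes every conditioning
        # set here, so nothing is testable — and that is reported, not hidden
        g = build_diagram(
            ["plant", "load1", "load2", "flow"],
            [("plant", "load1"), ("plant", "load2")],
        )
        table = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=["load1", "load2", "flow"]
        )  # no data column for the latent 'plant'
        ev = evaluate_model(g, table)
        assert ev.status == "nothing_testable"
        assert ev.fisher is None and ev.consistent is None
        assert len(ev.untestable) == 4
        assert any("plant" in str(s) for s in ev.untestable)

    def test_bidirected_latent_keeps_statements_testable(self, rng):
        # same latent expressed as a bidirected arrow: the exempted pair
        # drops out and the remaining statements are testable
        g = build_diagram(
            ["load1", "load2", "flow"], [], [("load1", "load2")]
        )
        table = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=["load1", "load2", "flow"]
        )
        ev = evaluate_model(g, table, seed=1)
        assert ev.status == "tested"
        assert ev.fisher.k == len(ev.results) == 2  # (load1,flow), (load2,flow)
        assert not ev.untestable

    def test_k_counts_testable_only(self, rng):
        g = build_diagram(["A", "B", "C"], [("A", "B")])
        table = pd.DataFrame(rng.normal(size=(40, 3)), columns=["A", "B", "C"])
        ev = evaluate_model(g, table, seed=3)
        assert ev.fisher.k == len(ev.results) == 2
        assert ev.fisher.df == 4

    def test_report_serialises(self, rng):
        import json

        g = build_diagram(["A", "B", "C"], [("A", "B")])
        table = pd.DataFrame(rng.normal(size=(40, 3)), columns=["A", "B", "C"])
        ev = evaluate_model(g, table, seed=3)
        payload = json.loads(ev.to_json())
        assert payload["fisher_c"]["df"] == 4
        assert len(payload["local_tests"]) == 2
        assert "Fisher's C" in ev.to_text()


class TestPredictIntervention:
    def _fit_chain(self, rng, n=400, noise=0.0):
        # X -> M -> Y with beta_MX = 1.5, beta_YM = 2.0
        x = rng.normal(size=n)
        m = 1.5 * x + noise * rng.normal(size=n)
        y = 2.0 * m + noise * rng.normal(size=n)
        table = pd.DataFrame({"X": x, "M": m, "Y": y})
        g = build_diagram(["X", "M", "Y"], [("X", "M"), ("M", "Y")])
        eqs = [fit_equation(e, table) for e in derive_structural_equations(g)]
        return g, eqs, table

    def test_noiseless_direct_effect(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"X": x, "Y": 2.0 * x})
        g = build_diagram(["X", "Y"], [("X", "Y")])
        eqs = [fit_equation(e, table) for e in derive_structural_equations(g)]
        pred = predict_intervention(eqs, g, {"X": 3.0}, table)
        assert np.allclose(pred["Y"], 6.0, atol=1e-8)

    def test_chain_propagation(self, rng):
        g, eqs, table = self._fit_chain(rng, noise=0.3)
        pred = predict_intervention(eqs, g, {"X": 2.0}, table)
        # E[Y | do(X=2)] = 2.0 * 1.5 * 2 = 6, within simulation error
        assert np.mean(pred["Y"]) == pytest.approx(6.0, abs=0.2)

    def test_sink_intervention_changes_nothing_else(self, rng):
        g, eqs, table = self._fit_chain(rng, noise=0.3)
        base = predict_intervention(eqs, g, {}, table)
        pred = predict_intervention(eqs, g, {"Y": 0.0}, table)
        assert np.allclose(pred["M"], base["M"])

    def test_empty_intervention_returns_fitted_means(self, rng):
        g, eqs, table = self._fit_chain(rng, noise=0.3)
        pred = predict_intervention(eqs, g, {}, table)
        fitted_m = eqs[0].results.fittedvalues
        assert np.mean(pred["M"]) == pytest.approx(np.mean(fitted_m), abs=1e-9)

    def test_undefined_variable_rejected(self, rng):
        g, eqs, table = self._fit_chain(rng)
        with pytest.raises(KeyError):
            predict_intervention(eqs, g, {"Q": 1.0}, table)

    def test_unaccepted_model_warns(self, rng):
        g, eqs, table = self._fit_chain(rng)
        with pytest.warns(UserWarning, match="caution"):
            predict_intervention(eqs, g, {"X": 1.0}, table, model_accepted=False)
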