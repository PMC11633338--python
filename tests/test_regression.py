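"""ilr regression, rotation invariance, isotemporal substitution curves."""

import numpy as np
import pandas as pd
import pytest

from timeuse24.coda import (close_composition, compositional_mean,
                            ilr_transform, pivot_basis, rotation_order)
from timeuse24.regression import (ILR_NAMES, all_reallocation_curves,
                                  fit_all_rotations, fit_ilr_model,
                                  leading_effects_table, model_diagnostics,
                                  one_for_remaining, reallocation_curve)


def _random_compositions(rng, n=60):
    parts = np.column_stack([
        rng.normal(480.0, 50.0, n), rng.normal(740.0, 60.0, n),
        rng.normal(180.0, 35.0, n), rng.lognormal(np.log(15.0), 0.6, n)])
    return close_composition(np.clip(parts, 2.0, None))


@pytest.fixture(scope="module")
def planted_fit():
    """Compositions + outcome from a known linear ilr model, all rotations."""
    rng = np.random.default_rng(42)
    comps = _random_compositions(rng, n=120)
    beta0 = np.array([6.0, -5.0, -1.5])
    y = 35.0 + ilr_transform(comps, rotation=0) @ beta0 \
        + rng.normal(0.0, 1.0, size=len(comps))
    results = fit_all_rotations(comps, y, outcome_name="pcs12")
    return comps, beta0, y, results


class TestFit:
    def test_constant_outcome_zero_slopes(self, rng):
        comps = _random_compositions(rng)
        res = fit_ilr_model(comps, np.full(len(comps), 42.0))
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)
        for name in ILR_NAMES:
            assert res.params[name] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_observations_rejected(self, rng):
        comps = _random_compositions(rng, n=4)
        with pytest.raises(ValueError, match="too small"):
            fit_ilr_model(comps, np.arange(4.0))

    def test_singular_design_named(self, rng):
        comps = _random_compositions(rng, n=30)
        cov = pd.DataFrame({"dup": np.ones(30)})  # collinear with intercept
        with pytest.raises(ValueError, match="dup"):
            fit_ilr_model(comps, rng.normal(size=30), covariates=cov)

    def test_planted_betas_recovered(self, planted_fit):
        _, beta0, _, results = planted_fit
        res = results[0]
        for i, name in enumerate(ILR_NAMES):
            assert abs(res.params[name] - beta0[i]) <= 3 * res.bse[name]

    def test_covariates_enter_model(self, rng):
        comps = _random_compositions(rng, n=80)
        age = rng.normal(68.0, 9.0, 80)
        y = 10.0 + 0.5 * age + rng.normal(0.0, 1.0, 80)
        res = fit_ilr_model(comps, y, covariates=pd.DataFrame({"age": age}))
        assert res.params["age"] == pytest.approx(0.5, abs=0.1)


class TestRotations:
    def test_fitted_values_and_r2_invariant(self, planted_fit):
        _, _, _, results = planted_fit
        base = results[0]
        for other in results[1:]:
            assert np.max(np.abs(base.fittedvalues - other.fittedvalues)) < 1e-8
            assert abs(base.r_squared - other.r_squared) < 1e-8

    def test_leading_betas_match_basis_change_oracle(self, planted_fit):
        # rotation-r coefficients are V_r' V_0 beta_0 (orthonormal basis change)
        _, _, _, results = planted_fit
        V = pivot_basis(4)
        beta_fit0 = results[0].params[list(ILR_NAMES)].to_numpy()
        for res in results[1:]:
            P0 = np.eye(4)[:, list(rotation_order(0))]
            Pr = np.eye(4)[:, list(rotation_order(res.rotation))]
            R = (Pr @ V).T @ (P0 @ V)
            expected = R @ beta_fit0
            np.testing.assert_allclose(
                res.params[list(ILR_NAMES)].to_numpy(), expected, atol=1e-8)

    def test_leading_effects_table_layout(self, planted_fit):
        _, _, _, results = planted_fit
        table = leading_effects_table(results)
        assert list(table["domain"]) == ["sleep", "sedentary", "lpa", "mvpa"]
        assert {"beta", "se", "p_value"} <= set(table.columns)

    def test_sign_pattern_recovery(self, rng):
        # positive sleep/MVPA and negative sedentary/LPA leading effects
        comps = _random_compositions(rng, n=400)
        V = pivot_basis(4)
        # build a clr-space effect with the desired one-vs-rest signs
        clr_beta = np.array([6.0, -6.0, -2.0, 2.0])
        clr_beta -= clr_beta.mean()
        beta0 = (np.eye(4)[:, list(rotation_order(0))] @ V).T @ clr_beta
        y = ilr_transform(comps) @ beta0 + rng.normal(0.0, 0.5, 400)
        table = leading_effects_table(fit_all_rotations(comps, y))
        signs = dict(zip(table["domain"], np.sign(table["beta"])))
        assert signs["sleep"] > 0 and signs["mvpa"] > 0
        assert signs["sedentary"] < 0 and signs["lpa"] < 0


class TestReallocation:
    def test_zero_delta_zero_difference(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        curve = reallocation_curve(results[0], ref, "sleep",
                                   deltas=np.array([0.0]))
        row = curve.table.iloc[0]
        assert row["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert row["upper"] - row["lower"] == pytest.approx(0.0, abs=1e-12)

    def test_one_for_remaining_conservation(self, planted_fit):
        comps, _, _, _ = planted_fit
        ref = compositional_mean(comps)
        new = one_for_remaining(ref, "mvpa", 15.0)
        assert new.sum() == pytest.approx(1440.0, abs=1e-9)
        assert new[3] == pytest.approx(ref[3] + 15.0)
        # the remaining parts shrink proportionally to their shares
        shrink = (new[:3] - ref[:3]) / ref[:3]
        np.testing.assert_allclose(shrink, shrink[0], atol=1e-12)

    def test_infeasible_delta_flagged_not_extrapolated(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        curve = reallocation_curve(results[0], ref, "mvpa",
                                   deltas=np.array([-ref[3] - 5.0, 0.0, 10.0]))
        assert not curve.table.iloc[0]["feasible"]
        assert curve.table.iloc[1:]["feasible"].all()

    def test_bounds_bracket_estimate(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        for domain in ("sleep", "sedentary", "lpa", "mvpa"):
            tab = reallocation_curve(results[0], ref, domain).table
            feas = tab[tab["feasible"]]
            assert (feas["lower"] <= feas["estimate"] + 1e-12).all()
            assert (feas["upper"] >= feas["estimate"] - 1e-12).all()

    def test_small_delta_slope_sign_matches_leading_beta(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        for res in results:
            domain = res.leading_domain
            curve = reallocation_curve(results[0], ref, domain,
                                       deltas=np.array([-1.0, 0.0, 1.0]))
            slope = np.gradient(curve.table["estimate"].to_numpy(),
                                curve.table["delta_min"].to_numpy())[1]
            assert np.sign(slope) == np.sign(res.leading_beta)

    def test_prediction_matches_brute_force_oracle(self, planted_fit):
        # independent route: predicted difference from the fitted model's
        # design-row predictions at the new and reference compositions
        comps, _, _, results = planted_fit
        res = results[0]
        ref = compositional_mean(comps)
        curve = reallocation_curve(res, ref, "mvpa",
                                   deltas=np.array([15.0]))
        est = curve.table.iloc[0]["estimate"]
        new = one_for_remaining(ref, "mvpa", 15.0)
        beta = res.params
        design = lambda c: np.concatenate(([1.0], ilr_transform(c)))
        brute = design(new) @ beta.to_numpy() - design(ref) @ beta.to_numpy()
        assert est == pytest.approx(brute, abs=1e-10)

    def test_curves_rotation_invariant(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        base = None
        for res in results:
            tab = reallocation_curve(res, ref, "sleep").table
            if base is None:
                base = tab
            else:
                np.testing.assert_allclose(tab["estimate"], base["estimate"],
                                           atol=1e-8)
                np.testing.assert_allclose(tab["lower"], base["lower"],
                                           atol=1e-8)

    def test_all_curves_cover_four_domains(self, planted_fit):
        comps, _, _, results = planted_fit
        ref = compositional_mean(comps)
        curves = all_reallocation_curves(results[0], ref)
        assert set(curves) == {"sleep", "sedentary", "lpa", "mvpa"}


class TestDiagnostics:
    def test_report_keys_and_plot(self, planted_fit, tmp_path):
        _, _, _, results = planted_fit
        report = model_diagnostics(results[0], tmp_path, prefix="pcs12")
        for key in ("breusch_pagan_stat", "breusch_pagan_p",
                    "shapiro_stat", "shapiro_p"):
            assert key in report
        assert (tmp_path / "pcs12_diagnostics.png").exists()

    def test_shapiro_null_calibration(self, rng):
        # Gaussian errors: Shapiro-Wilk p-values uniform across replicates
        import scipy.stats
        comps = _random_compositions(rng, n=50)
        pvals = []
        for _ in range(200):
            y = rng.normal(0.0, 1.0, 50)
            res = fit_ilr_model(comps, y)
            pvals.append(model_diagnostics(res)["shapiro_p"])
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_breusch_pagan_detects_heteroscedasticity(self, rng):
        # variance growing with the mean: BP should reject in > 50% of runs
        comps = _random_compositions(rng, n=200)
        z1 = ilr_transform(comps)[:, 0]
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            mean = 3.0 * z1
            y = mean + rng.normal(0.0, 0.3 + np.abs(mean), 200)
            res = fit_ilr_model(comps, y)
            rejections += model_diagnostics(res)["breusch_pagan_p"] < 0.05
        assert rejections / n_rep > 0.5
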