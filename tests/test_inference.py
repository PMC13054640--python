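"""Mixed-model machinery: standardization, fits, selection, VIF, contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from ecostab.lmm import (
    DEFAULT_LADDER,
    fit_lmm,
    fit_lrr_models,
    fit_stability_models,
    pairwise_tukey,
    select_model_loglik,
    sensitivity_leave_one_out,
    standardize_predictors,
    unstandardize,
    vif,
)


def _grouped_frame(rng, n_groups=10, per_group=20, group_sd=0.5, slope=0.15, resid=0.3):
    g = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(size=len(g))
    eff = rng.normal(0, group_sd, n_groups)
    y = 1.0 + slope * x + eff[g] + rng.normal(0, resid, len(g))
    return pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 100)})
        out, scaling = standardize_predictors(df, ["a"])
        assert abs(out["a"].mean()) < 1e-12
        assert out["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_errors_with_name(self):
        df = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError, match="'a'"):
            standardize_predictors(df, ["a"])

    def test_scaling_round_trips(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 50)})
        out, scaling = standardize_predictors(df, ["a"])
        back = unstandardize(out["a"], "a", scaling)
        assert np.allclose(back, df["a"], atol=1e-12)


class TestFitLmm:
    def test_matches_ols_when_groups_have_no_variance(self, rng):
        df = _grouped_frame(rng, group_sd=0.0)
        # remove sampling noise in the group means so the between-group
        # variance is exactly zero and the GLS fit collapses to OLS
        resid = df["y"] - (1.0 + 0.15 * df["x"])
        df["y"] = 1.0 + 0.15 * df["x"] + resid - resid.groupby(df["g"]).transform("mean")
        fit = fit_lmm("y ~ x", df, vc_factors=["g"], reml=True)
        ols = smf.ols("y ~ x", df).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-6)

    def test_single_level_factor_flagged_not_fatal(self, rng):
        df = _grouped_frame(rng, n_groups=1)
        fit = fit_lmm("y ~ x", df, vc_factors=["g"])
        assert any("< 2 levels" in f for f in fit.flags)

    def test_aliased_factors_deduplicated(self, rng):
        df = _grouped_frame(rng)
        df["g2"] = "c" + df["g"]
        fit = fit_lmm("y ~ x", df, vc_factors=["g", "g2"])
        assert any("aliases" in f for f in fit.flags)
        assert list(fit.vcomp) == ["g"]

    def test_slope_recovery_coverage(self):
        # the +-2 SE band should cover the generating slope in nearly all
        # replicates of a correctly specified model
        hits = 0
        for seed in range(50):
            df = _grouped_frame(np.random.default_rng(seed))
            fit = fit_lmm("y ~ x", df, vc_factors=["g"])
            hits += abs(fit.params["x"] - 0.15) <= 2 * fit.bse["x"]
        assert hits >= 45

    def test_aicc_identity(self, rng):
        df = _grouped_frame(rng)
        fit = fit_lmm("y ~ x", df, vc_factors=["g"], reml=False)
        k, n = fit.k_params, fit.n
        assert fit.aicc == pytest.approx(
            -2 * fit.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_marginal_r2_limits(self, rng):
        df = _grouped_frame(rng)
        intercept_only = fit_lmm("y ~ 1", df, vc_factors=["g"])
        assert intercept_only.marginal_r2 == pytest.approx(0.0, abs=1e-10)
        noiseless = pd.DataFrame({"x": rng.normal(size=200)})
        noiseless["y"] = 2.0 + 0.5 * noiseless["x"]
        noiseless["g"] = "a"
        fit = fit_lmm("y ~ x", noiseless, vc_factors=[])
        assert fit.marginal_r2 >= 0.999

    def test_marginal_r2_matches_variance_ratio(self, rng):
        df = _grouped_frame(rng)
        fit = fit_lmm("y ~ x", df, vc_factors=["g"])
        var_f = np.var(fit.params["Intercept"] + fit.params["x"] * df["x"], ddof=0)
        expected = var_f / (var_f + sum(fit.vcomp.values()) + fit.scale)
        assert fit.marginal_r2 == pytest.approx(expected, abs=1e-6)


class TestVif:
    def test_orthogonal_predictors_are_unity(self, rng):
        n = 400
        Q = np.linalg.qr(rng.normal(size=(n, 3)))[0]
        Q -= Q.mean(axis=0)  # orthogonal to the intercept as well
        Q = np.linalg.qr(Q)[0]
        X = pd.DataFrame(Q, columns=list("abc"))
        assert np.allclose(vif(X), 1.0, atol=1e-8)

    def test_duplicated_predictor_unbounded(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x})
        assert np.isinf(vif(X)).all()

    def test_closed_form_at_known_correlation(self, rng):
        n = 200_000
        x = rng.normal(size=n)
        y = 0.38 * x + np.sqrt(1 - 0.38**2) * rng.normal(size=n)
        got = vif(pd.DataFrame({"a": x, "b": y}))
        assert got["a"] == pytest.approx(1.0 / (1 - 0.38**2), rel=0.02)


class TestModelSelection:
    def _interaction_frame(self, rng, beta_int):
        n = 400
        g = rng.integers(0, 10, n).astype(str)
        x = rng.normal(size=n)
        t = rng.integers(0, 2, n)
        y = 0.3 * x + 0.2 * t + beta_int * x * t + rng.normal(0, 0.5, n)
        return pd.DataFrame({"y": y, "x": x, "t": t, "g": g})

    def test_null_interaction_dropped(self):
        drops = 0
        for seed in range(20):
            df = self._interaction_frame(np.random.default_rng(seed), 0.0)
            final, ladder = select_model_loglik("y ~ x + t + x:t", ["x:t"], df, ["g"])
            drops += "x:t" not in final
        assert drops >= 18

    def test_strong_interaction_retained(self):
        keeps = 0
        for seed in range(20):
            df = self._interaction_frame(np.random.default_rng(seed), 0.5)
            final, ladder = select_model_loglik("y ~ x + t + x:t", ["x:t"], df, ["g"])
            keeps += "x:t" in final
        assert keeps >= 18

    def test_no_droppable_terms_returns_full(self, rng):
        df = self._interaction_frame(rng, 0.0)
        final, ladder = select_model_loglik("y ~ x + t", [], df, ["g"])
        assert final == "y ~ x + t"
        assert ladder.empty

    def test_ladder_reports_lr_and_p(self, rng):
        df = self._interaction_frame(rng, 0.0)
        _, ladder = select_model_loglik("y ~ x + t + x:t", ["x:t"], df, ["g"])
        assert {"term", "lr", "df", "p", "action"} <= set(ladder.columns)
        assert (ladder["lr"] >= 0).all()


class TestStabilityModels:
    def test_per_event_type_fits_recover_generator_effects(self, stability_table, bundle):
        res = fit_stability_models(stability_table, select=False)
        fit = res["fits"][("resistance", "dry")]
        truth = bundle.truth["resistance_effects"]["dry"]["richness"]
        assert abs(fit.params["richness"] - truth) <= 2 * fit.bse["richness"]

    def test_wet_only_input_flags_dry_models_absent(self, stability_table):
        wet = stability_table[stability_table["event_type"] == "extreme_wet"]
        res = fit_stability_models(wet, select=False)
        assert ("resistance", "dry") not in res["fits"]
        assert any("resistance/dry" in f for f in res["flags"])


class TestLrrModels:
    def test_four_cells_give_six_tukey_contrasts(self, lrr_table):
        res = fit_lrr_models(lrr_table)
        assert len(res["contrasts"]["biomass"]) == 6
        assert set(res["cells"]["biomass"]["cell"]) == {
            "dry:control", "dry:nutrient", "wet:control", "wet:nutrient",
        }

    def test_identical_cells_adjusted_p_near_one(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "lrr": rng.normal(0, 0.2, n),
                "event_type": np.where(rng.random(n) < 0.5, "extreme_dry", "extreme_wet"),
                "treatment": np.where(rng.random(n) < 0.5, "control", "nutrient"),
                "metric": "biomass",
                "site": "s1",
                "plot_uid": rng.integers(0, 10, n).astype(str),
                "experiment_uid": "e1",
                "year": rng.integers(0, 5, n),
            }
        )
        res = fit_lrr_models(df, vc_factors=["plot_uid"])
        assert (res["contrasts"]["biomass"]["p_tukey"] > 0.3).all()

    def test_dry_nutrient_biomass_lrr_negative(self, lrr_table):
        res = fit_lrr_models(lrr_table)
        cells = res["cells"]["biomass"].set_index("cell")
        assert cells.loc["dry:nutrient", "estimate"] < cells.loc["dry:control", "estimate"] < 0


class TestSensitivity:
    def test_refit_per_omitted_level_plus_base(self, rng):
        df = _grouped_frame(rng)
        df["site"] = np.repeat(["a", "b", "c", "d"], 50)
        out = sensitivity_leave_one_out("y ~ x", df, "site", vc_factors=["g"])
        assert out["omitted"].nunique() == 5  # 4 sites + base run
        base = out[out["omitted"] == "<none>"].set_index("term")["beta"]
        full = fit_lmm("y ~ x", df, vc_factors=["g"])
        assert np.allclose(base.loc[full.params.index], full.params, atol=1e-10)

    def test_aberrant_site_shifts_coefficient_most(self, rng):
        df = _grouped_frame(rng, n_groups=8)
        df["site"] = np.repeat(["a", "b", "c", "d"], 40)
        df.loc[df["site"] == "d", "y"] += 5.0 * df.loc[df["site"] == "d", "x"]
        out = sensitivity_leave_one_out("y ~ x", df, "site", vc_factors=["g"])
        x_rows = out[out["term"] == "x"].set_index("omitted")["beta"]
        base = x_rows["<none>"]
        shifts = (x_rows.drop("<none>") - base).abs()
        assert shifts.idxmax() == "d"

    def test_needs_three_levels(self, rng):
        df = _grouped_frame(rng)
        df["site"] = np.repeat(["a", "b"], 100)
        with pytest.raises(ValueError, match=">= 3"):
            sensitivity_leave_one_out("y ~ x", df, "site", vc_factors=["g"])


def test_tukey_contrast_count_and_symmetry(rng):
    n = 300
    df = pd.DataFrame({"cell": rng.integers(0, 4, n).astype(str)})
    df["y"] = rng.normal(size=n)
    df["g"] = rng.integers(0, 5, n).astype(str)
    fit = fit_lmm("y ~ 0 + C(cell)", df, vc_factors=["g"])
    terms = [f"C(cell)[{c}]" for c in sorted(df["cell"].unique())]
    contrasts = pairwise_tukey(fit, terms)
    assert len(contrasts) == 6
    assert ((contrasts["p_tukey"] >= 0) & (contrasts["p_tukey"] <= 1)).all()
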