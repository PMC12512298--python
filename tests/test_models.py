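import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from anolechroma import models
from anolechroma.errors import (
    ConvergenceError,
    InvalidComparisonError,
    InvalidInputError,
)
from conftest import make_records_with_temp


class TestAssignSeason:
    @pytest.mark.parametrize(
        "date,expected",
        [
            ("2022-04-01", "breeding"),
            ("2022-09-30", "breeding"),
            ("2022-10-01", "nonbreeding"),
            ("2022-03-31", "nonbreeding"),
            ("2022-12-25", "nonbreeding"),
            ("2022-07-15", "breeding"),
        ],
    )
    def test_window(self, date, expected):
        assert models.assign_season(date) == expected


class TestWeekOfYear:
    def test_range_and_formula(self):
        dates = pd.date_range("2022-01-01", "2022-12-31")
        weeks = models.week_of_year(dates)
        assert (weeks >= 0).all() and (weeks < 52).all()
        assert weeks[0] == 0.0
        assert weeks[7] == 1.0

    def test_day_365_wraps_to_zero(self):
        assert models.week_of_year(["2022-12-31"])[0] == 0.0


def make_2x2_records():
    # green|warm=40, brown|warm=10, green|cold=20, brown|cold=30
    rows = (
        [("green", 1.0)] * 40 + [("brown", 1.0)] * 10
        + [("green", 0.0)] * 20 + [("brown", 0.0)] * 30
    )
    return pd.DataFrame(
        {"label": [r[0] for r in rows], "hourly_temp": [r[1] for r in rows]}
    )


def grid_search_loglik(x, y, lo=-6.0, hi=6.0, passes=4, width=201):
    """Independent oracle: brute-force likelihood grid for logit(p)=b0+b1*x."""
    b0_lo, b0_hi, b1_lo, b1_hi = lo, hi, lo, hi
    best = (0.0, 0.0)
    for _ in range(passes):
        b0s = np.linspace(b0_lo, b0_hi, width)
        b1s = np.linspace(b1_lo, b1_hi, width)
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (b0s[i], b1s[j])
        span0 = (b0_hi - b0_lo) / 10
        span1 = (b1_hi - b1_lo) / 10
        b0_lo, b0_hi = best[0] - span0, best[0] + span0
        b1_lo, b1_hi = best[1] - span1, best[1] + span1
    return best


class TestFitLogistic:
    def test_2x2_closed_form(self):
        fit = models.fit_logistic(make_2x2_records(), "temp_only")
        assert fit.coefficients["hourly_temp"] == pytest.approx(math.log(6.0), abs=1e-6)

    def test_agrees_with_likelihood_grid(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(-2, 2, size=40)
        y = (rng.random(40) < expit(0.3 + 0.8 * x)).astype(float)
        df = pd.DataFrame(
            {"label": np.where(y == 1, "green", "brown"), "hourly_temp": x}
        )
        fit = models.fit_logistic(df, "temp_only")
        b0, b1 = grid_search_loglik(x, y)
        assert fit.coefficients["intercept"] == pytest.approx(b0, abs=1e-3)
        assert fit.coefficients["hourly_temp"] == pytest.approx(b1, abs=1e-3)

    def test_null_z_statistics_bounded(self):
        rng = np.random.default_rng(2)
        n = 2000
        df = pd.DataFrame(
            {
                "label": np.where(rng.random(n) < 0.5, "green", "brown"),
                "hourly_temp": rng.uniform(0, 30, n),
                "season": np.where(rng.random(n) < 0.5, "breeding", "nonbreeding"),
            }
        )
        fit = models.fit_logistic(df, "temp_by_season_interaction")
        for name in ("hourly_temp", "breeding", "hourly_temp:breeding"):
            z = fit.coefficients[name] / fit.standard_errors[name]
            assert abs(z) < 4

    def test_planted_interaction_recovery(self):
        cfg, records, _ = make_records_with_temp(
            n=5000, seed=31, season_amp0=0.0, season_amp_per_lat=0.0
        )
        fit = models.fit_logistic(records, "temp_by_season_interaction")
        slopes = fit.extras["season_slopes"]
        nb, b = slopes["nonbreeding"], slopes["breeding"]
        assert abs(nb["slope"] - cfg.beta_temp_nonbreeding) <= 3 * nb["se"]
        assert abs(b["slope"] - 0.0) <= 3 * b["se"]

    def test_aic_identity(self):
        fit = models.fit_logistic(make_2x2_records(), "temp_only")
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.effective_df)

    def test_deviance_explained_label_swap_invariant(self):
        df = make_2x2_records()
        fit = models.fit_logistic(df, "temp_only")
        swapped = df.assign(label=df["label"].map({"green": "brown", "brown": "green"}))
        fit2 = models.fit_logistic(swapped, "temp_only")
        assert fit2.deviance_explained == pytest.approx(fit.deviance_explained)
        assert fit2.coefficients["hourly_temp"] == pytest.approx(
            -fit.coefficients["hourly_temp"]
        )

    def test_complete_separation_raises(self):
        df = pd.DataFrame(
            {
                "label": ["green"] * 20 + ["brown"] * 20,
                "hourly_temp": np.r_[np.linspace(20, 30, 20), np.linspace(0, 10, 20)],
            }
        )
        with pytest.raises(ConvergenceError):
            models.fit_logistic(df, "temp_only")

    def test_single_label_rejected(self):
        df = pd.DataFrame({"label": ["green"] * 30, "hourly_temp": np.arange(30.0)})
        with pytest.raises(InvalidInputError):
            models.fit_logistic(df, "temp_only")

    def test_small_season_level_rejected(self):
        df = make_2x2_records().assign(season="breeding")
        with pytest.raises(InvalidInputError):
            models.fit_logistic(df, "temp_plus_season")


class TestFitCyclicGam:
    def test_week_0_equals_week_52(self, small_table):
        _, records, _ = small_table
        fit = models.fit_cyclic_gam(records, "week_only")
        lp, _ = fit.predict(pd.DataFrame({"week": [0.0, 52.0]}))
        assert abs(lp[0] - lp[1]) < 1e-8

    def test_periodicity_plus_52(self, small_table):
        _, records, _ = small_table
        fit = models.fit_cyclic_gam(records, "week_by_lat_interaction")
        nd1 = pd.DataFrame({"week": [3.0, 17.5, 40.0], "latitude": [27.0, 30.0, 35.0]})
        nd2 = nd1.assign(week=nd1["week"] + 52.0)
        lp1, se1 = fit.predict(nd1)
        lp2, se2 = fit.predict(nd2)
        assert np.allclose(lp1, lp2) and np.allclose(se1, se2)

    def test_null_week_effect_shrinks(self):
        _, records, _ = make_records_with_temp(
            n=5000, seed=11, beta0=0.3, beta_temp_nonbreeding=0.0, beta_breeding=0.0,
            season_amp0=0.0, season_amp_per_lat=0.0,
        )
        fit = models.fit_cyclic_gam(records, "week_only")
        lp, _ = fit.predict(pd.DataFrame({"week": np.linspace(0, 52, 209)}))
        assert (lp.max() - lp.min()) / 2 < 0.2

    def test_deviance_not_above_null(self, small_table):
        _, records, _ = small_table
        for variant in models.GAM_VARIANTS:
            fit = models.fit_cyclic_gam(records, variant)
            assert fit.deviance <= fit.null_deviance + 1e-8
            assert fit.aic == pytest.approx(fit.deviance + 2 * fit.effective_df)

    def test_partial_cycle_warns(self):
        _, records, _ = make_records_with_temp(n=800, seed=3)
        winter = records[records["week"] < 20]
        with pytest.warns(UserWarning, match="cycle"):
            models.fit_cyclic_gam(winter, "week_only")


def fake_fit(name, deviance, edf, fingerprint="fp", null=200.0):
    return models.ModelFitResult(
        model_name=name,
        coefficients={},
        standard_errors={},
        pvalues={},
        deviance=deviance,
        null_deviance=null,
        effective_df=edf,
        aic=deviance + 2 * edf,
        deviance_explained=(null - deviance) / null,
        predict=lambda nd: (np.zeros(len(nd)), np.zeros(len(nd))),
        n_obs=100,
        data_fingerprint=fingerprint,
    )


class TestAICCompare:
    def test_arithmetic(self):
        cmp = models.aic_compare([fake_fit("a", 100.0, 2.0), fake_fit("b", 90.0, 4.0)])
        assert cmp.best == "b"
        assert cmp.delta_aic == pytest.approx(98.0 - 104.0)

    def test_tie_prefers_fewer_df(self):
        cmp = models.aic_compare([fake_fit("a", 100.0, 3.0), fake_fit("b", 102.0, 2.0)])
        assert cmp.best == "b"
        assert cmp.delta_aic == 0.0

    def test_differing_records_rejected(self):
        with pytest.raises(InvalidComparisonError):
            models.aic_compare(
                [fake_fit("a", 100.0, 2.0, "fp1"), fake_fit("b", 90.0, 2.0, "fp2")]
            )


class TestPredictWithCI:
    def test_zero_se_collapses(self):
        fit = fake_fit("zero", 100.0, 1.0)
        out = models.predict_with_ci(fit, pd.DataFrame({"week": [1.0, 2.0]}))
        assert (out["probability"] == 0.5).all()
        assert (out["lower"] == 0.5).all() and (out["upper"] == 0.5).all()

    def test_ordering_and_bounds(self, small_table):
        _, records, _ = small_table
        fit = models.fit_logistic(records, "temp_by_season_interaction")
        nd = pd.DataFrame(
            {"hourly_temp": np.linspace(0, 40, 20),
             "season": ["nonbreeding"] * 10 + ["breeding"] * 10}
        )
        out = models.predict_with_ci(fit, nd)
        assert (out["lower"] <= out["probability"] + 1e-12).all()
        assert (out["probability"] <= out["upper"] + 1e-12).all()
        assert (out["lower"] > 0).all() and (out["upper"] < 1).all()

    def test_missing_covariate_rejected(self, small_table):
        _, records, _ = small_table
        fit = models.fit_logistic(records, "temp_only")
        with pytest.raises(InvalidInputError):
            fit.predict(pd.DataFrame({"wrong_name": [1.0]}))


class TestBackgroundLM:
    def test_identity_line(self):
        df = pd.DataFrame({"bg_greenness": [0.2, 0.4, 0.6, 0.8],
                           "greenness": [0.2, 0.4, 0.6, 0.8]})
        res = models.fit_background_lm(df)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        # oracle: hand-computed normal equations (Sxy = Sxx = 0.02)
        df = pd.DataFrame({"bg_greenness": [0.30, 0.40, 0.50],
                           "greenness": [0.32, 0.41, 0.52]})
        res = models.fit_background_lm(df)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.41666666666666663 - 0.4, abs=1e-10)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"bg_greenness": [0.4, 0.4, 0.4],
                           "greenness": [0.1, 0.2, 0.3]})
        with pytest.raises(InvalidInputError):
            models.fit_background_lm(df)

    def test_too_few_rejected(self):
        df = pd.DataFrame({"bg_greenness": [0.4, 0.5], "greenness": [0.1, 0.2]})
        with pytest.raises(InvalidInputError):
            models.fit_background_lm(df)

    def test_confounder_check_reported(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "bg_greenness": rng.uniform(0.2, 0.5, 200),
                "greenness": rng.uniform(0.2, 0.5, 200),
                "hourly_temp": rng.uniform(5, 35, 200),
            }
        )
        res = models.fit_background_lm(df)
        assert res.temp_correlation is not None
        assert -1 <= res.temp_correlation <= 1
        assert 0 <= res.temp_regression_p <= 1
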