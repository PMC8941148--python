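"""Random-intercept ML fit, likelihood-ratio ANOVA, percent effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aapflux.mixedlm import (
    EffectSummary,
    RandomInterceptLM,
    RandomInterceptLMResults,
    f_test_anova,
    fit_light_effect,
    interaction_fit,
    lrt_anova,
    percent_difference,
)


def _simulate(
    n_dates=8,
    reps=3,
    mu=0.30,
    effect=-0.15,
    date_sd=0.08,
    resid_sd=0.02,
    seed=0,
    multiplicative=True,
):
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0, date_sd, n_dates)
    for j in range(n_dates):
        for treatment in ("dark", "IR"):
            shift = (
                (mu + b[j]) * (1 + effect)
                if (multiplicative and treatment == "IR")
                else (mu + b[j]) + (0 if treatment == "dark" else effect)
            )
            if multiplicative and treatment == "dark":
                shift = mu + b[j]
            for r in range(reps):
                rows.append(
                    {
                        "date": j,
                        "treatment": treatment,
                        "replicate": r,
                        "value": shift + rng.normal(0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestFit:
    def test_reduces_to_ols_without_group_variance(self):
        df = _simulate(date_sd=0.0, seed=1)
        fit = RandomInterceptLM.from_dataframe(df).fit()
        X = np.column_stack(
            [np.ones(len(df)), (df.treatment == "IR").to_numpy(float)]
        )
        beta_ols = np.linalg.lstsq(X, df.value.to_numpy(), rcond=None)[0]
        assert fit.params.to_numpy() == pytest.approx(beta_ols, abs=1e-6)

    def test_matches_brute_force_likelihood_grid(self):
        """Exhaustive (sigma_d^2, sigma^2) grid with an independent full
        covariance-matrix likelihood: the profiled optimum dominates."""
        df = pd.DataFrame(
            {
                "date": [0, 0, 0, 0, 1, 1, 1, 1],
                "treatment": ["dark", "dark", "IR", "IR"] * 2,
                "value": [0.31, 0.29, 0.26, 0.27, 0.35, 0.36, 0.30, 0.31],
            }
        )
        model = RandomInterceptLM.from_dataframe(df)
        fit = model.fit()

        y = df.value.to_numpy()
        X = np.column_stack(
            [np.ones(8), (df.treatment == "IR").to_numpy(float)]
        )
        Z = np.zeros((8, 2))
        Z[np.arange(8), df.date.to_numpy()] = 1.0

        def dense_loglike(sd2, s2):
            V = s2 * np.eye(8) + sd2 * Z @ Z.T
            Vinv = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            r = y - X @ beta
            sign, logdet = np.linalg.slogdet(V)
            return -0.5 * (8 * np.log(2 * np.pi) + logdet + r @ Vinv @ r)

        grid_ll = max(
            dense_loglike(sd2, s2)
            for sd2 in np.linspace(1e-6, 0.01, 60)
            for s2 in np.linspace(1e-6, 0.005, 60)
        )
        assert fit.llf >= grid_ll - 1e-4
        assert abs(fit.llf - grid_ll) < 0.05  # grid resolution slack

    def test_matches_statsmodels_ml(self):
        import statsmodels.formula.api as smf

        df = _simulate(seed=5)
        fit = RandomInterceptLM.from_dataframe(df).fit()
        sm = smf.mixedlm("value ~ treatment", df, groups=df["date"]).fit(
            reml=False
        )
        assert fit.llf == pytest.approx(sm.llf, abs=1e-5)
        assert abs(fit.params.iloc[1]) == pytest.approx(
            abs(sm.params.iloc[1]), abs=1e-6
        )

    def test_monte_carlo_recovery_and_coverage(self):
        """Additive effect beta1: mean bias < 2% and Wald CI coverage in
        [92, 98]% over 500 replicates."""
        beta1 = -0.05
        est, hits = [], []
        for s in range(500):
            df = _simulate(
                n_dates=16, effect=beta1, multiplicative=False, seed=s
            )
            fit = RandomInterceptLM.from_dataframe(df).fit()
            bhat = fit.params["treatment[IR]"]
            ci = fit.conf_int().loc["treatment[IR]"]
            est.append(bhat)
            hits.append(ci["lower"] <= beta1 <= ci["upper"])
        assert abs(np.mean(est) - beta1) < 0.02 * abs(beta1)
        assert 0.92 <= np.mean(hits) <= 0.98

    def test_affine_equivariance(self):
        df = _simulate(seed=9)
        fit1 = RandomInterceptLM.from_dataframe(df).fit()
        df2 = df.assign(value=df.value * 3.0)
        fit2 = RandomInterceptLM.from_dataframe(df2).fit()
        assert fit2.params.to_numpy() == pytest.approx(
            3.0 * fit1.params.to_numpy(), rel=1e-5
        )
        assert np.sqrt(fit2.sigma2) == pytest.approx(
            3.0 * np.sqrt(fit1.sigma2), rel=1e-4
        )

    def test_single_observation_per_group_rejected(self):
        df = pd.DataFrame(
            {
                "date": range(6),
                "treatment": ["dark", "IR"] * 3,
                "value": np.linspace(0.2, 0.4, 6),
            }
        )
        with pytest.raises(ValueError, match="confounded|identifiable"):
            RandomInterceptLM.from_dataframe(df)

    def test_summary_renders(self):
        fit = RandomInterceptLM.from_dataframe(_simulate(seed=2)).fit()
        text = fit.summary()
        assert "sigma_d^2" in text and "treatment[IR]" in text


class TestLrt:
    def test_identical_models_give_p_one(self):
        df = _simulate(seed=3)
        fit = RandomInterceptLM.from_dataframe(df).fit()
        stat, dof, p = lrt_anova(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_rejected(self):
        full = RandomInterceptLM.from_dataframe(_simulate(seed=3)).fit()
        other = RandomInterceptLM.from_dataframe(
            _simulate(n_dates=6, seed=3)
        ).fit()
        with pytest.raises(ValueError, match="nested"):
            lrt_anova(full, other)  # different data

    def test_type_one_error_calibrated(self):
        """Null simulations: LRT rejection rate at alpha = 0.05 must sit
        in [3.5, 6.5]% over 1000 replicates."""
        rejections = 0
        n_reps = 1000
        for s in range(n_reps):
            df = _simulate(n_dates=8, reps=3, effect=0.0, seed=10_000 + s)
            full = RandomInterceptLM.from_dataframe(df).fit()
            reduced = RandomInterceptLM.from_dataframe(
                df, treatment_col=None
            ).fit()
            _, _, p = lrt_anova(full, reduced)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065

    def test_f_variant_is_more_conservative(self):
        df = _simulate(seed=4)
        full = RandomInterceptLM.from_dataframe(df).fit()
        reduced = RandomInterceptLM.from_dataframe(df, treatment_col=None).fit()
        _, _, p_chi = lrt_anova(full, reduced)
        _, _, _, p_f = f_test_anova(full, reduced)
        assert p_f >= p_chi


class TestPercentDifference:
    def _synthetic_fit(self, beta_t, mu_ref=0.30, se=0.01):
        df = _simulate(n_dates=2, reps=2, seed=0)
        model = RandomInterceptLM.from_dataframe(df)
        params = pd.Series([mu_ref, beta_t], index=model.exog_names)
        cov = pd.DataFrame(
            np.diag([1e-6, se**2]),
            index=model.exog_names,
            columns=model.exog_names,
        )
        return RandomInterceptLMResults(
            model=model, params=params, cov_params=cov,
            sigma_d2=0.0, sigma2=1e-4, llf=0.0,
        )

    def test_headline_arithmetic(self):
        summ = percent_difference(self._synthetic_fit(-0.0456), analyte="respiration")
        assert summ.percent == pytest.approx(15.2, rel=1e-9)
        assert summ.direction == "higher in dark"

    def test_zero_effect_symmetric(self):
        summ = percent_difference(self._synthetic_fit(0.0))
        assert summ.percent == 0.0
        assert summ.ci_low == pytest.approx(-summ.ci_high, rel=1e-9)

    def test_recovery_of_multiplicative_truth(self):
        """Mean estimated percent within +-1.5 points of the 15% truth
        over replicate simulated studies."""
        vals = []
        for s in range(200):
            df = _simulate(n_dates=16, effect=-0.15, seed=s)
            _, summ = fit_light_effect(df)
            vals.append(summ.percent)
        assert abs(np.mean(vals) - 15.0) < 1.5

    def test_negative_reference_mean_rejected(self):
        with pytest.raises(ValueError, match="reference mean"):
            percent_difference(self._synthetic_fit(-0.05, mu_ref=-0.2))


class TestInteraction:
    def _sim_interaction(self, delta, n_dates=16, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 5.0, n_dates)  # positive covariate
        b = rng.normal(0, 0.02, n_dates)
        rows = []
        for j in range(n_dates):
            for treatment, slope in (("dark", 0.1), ("IR", 0.1 + delta)):
                for _ in range(reps):
                    y = 0.3 + b[j] + slope * np.log10(x[j]) + rng.normal(0, 0.02)
                    rows.append(
                        {
                            "date": j,
                            "treatment": treatment,
                            "value": y,
                            "covariate": x[j],
                        }
                    )
        return pd.DataFrame(rows)

    def test_reports_per_level_slopes(self):
        out = interaction_fit(self._sim_interaction(0.3, seed=1), "covariate")
        tab = out.per_level.set_index(["treatment", "term"])
        dark_slope = tab.loc[("dark", "slope"), "estimate"]
        ir_slope = tab.loc[("IR", "slope"), "estimate"]
        assert dark_slope == pytest.approx(0.1, abs=0.08)
        assert ir_slope == pytest.approx(0.4, abs=0.08)

    def test_null_flag_rate_near_alpha(self):
        flags = sum(
            interaction_fit(
                self._sim_interaction(0.0, seed=100 + s), "covariate"
            ).significant
            for s in range(100)
        )
        assert flags <= 12  # binomial slack around 5%

    def test_power_at_three_se_slope_difference(self):
        """A slope difference of 3 standard errors (the sampling SD of
        the null interaction estimate) is flagged >= 80% of the time at
        16 dates."""
        null_est = []
        for s in range(100):
            pilot = interaction_fit(
                self._sim_interaction(0.0, seed=200 + s), "covariate"
            )
            iname = [
                n for n in pilot.results.params.index
                if n.startswith("treatment:")
            ][0]
            null_est.append(pilot.results.params[iname])
        delta = 3.0 * np.std(null_est)
        hits = sum(
            interaction_fit(
                self._sim_interaction(delta, seed=500 + s), "covariate"
            ).significant
            for s in range(100)
        )
        assert hits >= 80

    def test_constant_covariate_rejected(self):
        df = self._sim_interaction(0.1, seed=2).assign(covariate=2.0)
        with pytest.raises(ValueError, match="singular|constant"):
            interaction_fit(df, "covariate")

    def test_nonpositive_covariate_rejected(self):
        df = self._sim_interaction(0.1, seed=3)
        df.loc[0, "covariate"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            interaction_fit(df, "covariate")


def test_effect_summary_str():
    s = EffectSummary("respiration", 15.2, 6.6, 23.8, "higher in dark", 0.0008)
    assert "15.2%" in str(s) and "higher in dark" in str(s)
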