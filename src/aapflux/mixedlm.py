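"""Random-intercept linear mixed models for the dark-vs-IR light effect.

The design has triplicate bottles per treatment nested in sampling
dates; dates contribute a shared random intercept:

    y_ij = x_ij' beta + b_j + e_ij,   b_j ~ N(0, sigma_d^2),
                                      e_ij ~ N(0, sigma^2)

Estimation is maximum likelihood via the profiled likelihood over the
variance ratio lambda = sigma_d^2 / sigma^2: at each lambda the GLS
coefficients and the residual variance have closed forms, leaving a
one-dimensional optimisation.  Fixed effects get Wald standard errors;
treatment significance is tested by a likelihood-ratio chi-square
against the model without the treatment term (the "ANOVA" of the nlme
workflow), with an F variant for sensitivity.

The headline quantity is the percent difference between treatments:
100 * |beta_treatment| / mu_ref with mu_ref the model-implied mean under
the reference (dark) treatment, CI by scaling the Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RandomInterceptLM",
    "RandomInterceptLMResults",
    "EffectSummary",
    "fit_light_effect",
    "lrt_anova",
    "percent_difference",
    "interaction_fit",
]


def build_design(
    df: pd.DataFrame,
    treatment_col: str | None = "treatment",
    reference: str = "dark",
    covariates: list[str] | None = None,
    log10_covariates: bool = True,
    interaction: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, a two-level treatment dummy coded
    against ``reference``, optional log10 covariates and treatment x
    covariate interactions."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    tdummy = None
    if treatment_col is not None:
        levels = sorted(df[treatment_col].unique())
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from data")
        others = [lv for lv in levels if lv != reference]
        if len(others) != 1:
            raise ValueError("treatment must have exactly two levels")
        tdummy = (df[treatment_col] == others[0]).to_numpy(float)
        cols.append(tdummy)
        names.append(f"treatment[{others[0]}]")
    for cov in covariates or []:
        x = df[cov].to_numpy(float)
        if log10_covariates:
            if np.any(x <= 0):
                raise ValueError(
                    f"covariate {cov!r} has non-positive values; cannot log10 "
                    "(pass log10_covariates=False if pre-transformed)"
                )
            x = np.log10(x)
            cname = f"log10({cov})"
        else:
            cname = cov
        cols.append(x)
        names.append(cname)
        if interaction:
            if tdummy is None:
                raise ValueError("interaction requires a treatment column")
            cols.append(tdummy * x)
            names.append(f"treatment:{cname}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (constant covariate?)")
    return X, names


class RandomInterceptLM:
    """Linear mixed model with one random intercept per group.

    Parameters
    ----------
    endog : (n,) response vector.
    exog : (n, p) fixed-effect design matrix (include the intercept).
    groups : (n,) group labels (the sampling date).
    exog_names : optional column names for summaries.
    """

    def __init__(self, endog, exog, groups, exog_names: list[str] | None = None):
        self.endog = np.asarray(endog, float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.groups = np.asarray(groups)
        codes, uniques = pd.factorize(self.groups, sort=True)
        self._codes = codes
        self.group_labels = uniques
        self.n, self.k_fixed = self.exog.shape
        self.n_groups = len(uniques)
        if np.linalg.matrix_rank(self.exog) < self.k_fixed:
            raise ValueError("singular design matrix")
        self.exog_names = exog_names or [f"x{i}" for i in range(self.k_fixed)]
        sizes = np.bincount(codes)
        if np.all(sizes == 1):
            raise ValueError(
                "one observation per group: the between-group and residual "
                "variances are confounded (not identifiable)"
            )
        self._sizes = sizes

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "value",
        group: str = "date",
        treatment_col: str | None = "treatment",
        reference: str = "dark",
        covariates: list[str] | None = None,
        log10_covariates: bool = True,
        interaction: bool = False,
    ) -> "RandomInterceptLM":
        X, names = build_design(
            df, treatment_col, reference, covariates, log10_covariates, interaction
        )
        return cls(df[response].to_numpy(float), X, df[group].to_numpy(), names)

    # -- profiled likelihood machinery ------------------------------------

    def _profile(self, lam: float):
        """GLS quantities at a fixed variance ratio lambda.

        Returns (loglike, beta, sigma2, xtvx_inv) where covariances are on
        the V0 = I + lam Z Z' scale (multiply by sigma2 for beta's cov).
        """
        y, X, codes, sizes = self.endog, self.exog, self._codes, self._sizes
        shrink = lam / (1.0 + lam * sizes)  # per-group V0^-1 correction weight
        # V0^-1 a = a - shrink_j * sum_j(a) within group
        def vinv(a: np.ndarray) -> np.ndarray:
            gs = np.zeros((self.n_groups,) + a.shape[1:])
            np.add.at(gs, codes, a)
            return a - (shrink[codes].reshape(-1, *([1] * (a.ndim - 1)))) * gs[codes]

        Xv = vinv(X)
        xtvx = X.T @ Xv
        beta = np.linalg.solve(xtvx, Xv.T @ y)
        r = y - X @ beta
        quad = float(r @ vinv(r))
        # floor against exact (noise-free) fits where the ML residual
        # variance degenerates to zero
        yscale = max(float(np.var(y)), float(np.mean(y * y)), 1e-300)
        sigma2 = max(quad / self.n, 1e-24 * yscale)
        logdet = float(np.sum(np.log1p(lam * sizes)))
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return ll, beta, sigma2, np.linalg.inv(xtvx)

    def loglike(self, sigma_d2: float, sigma2: float, profile_beta: bool = True):
        """Full ML log-likelihood at given variance components (beta
        profiled out).  Exposed for brute-force verification."""
        if sigma2 <= 0 or sigma_d2 < 0:
            return -np.inf
        lam = sigma_d2 / sigma2
        y, X, codes, sizes = self.endog, self.exog, self._codes, self._sizes
        shrink = lam / (1.0 + lam * sizes)

        def vinv(a):
            gs = np.zeros((self.n_groups,) + a.shape[1:])
            np.add.at(gs, codes, a)
            return a - (shrink[codes].reshape(-1, *([1] * (a.ndim - 1)))) * gs[codes]

        Xv = vinv(X)
        beta = np.linalg.solve(X.T @ Xv, Xv.T @ y)
        r = y - X @ beta
        quad = float(r @ vinv(r)) / sigma2
        logdet = self.n * np.log(sigma2) + float(np.sum(np.log1p(lam * sizes)))
        return -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)

    def fit(self, conf_level: float = 0.95) -> "RandomInterceptLMResults":
        """Maximum-likelihood fit via the profiled variance ratio."""
        # optimise on log(lambda); also check the lambda = 0 boundary
        res = optimize.minimize_scalar(
            lambda t: -self._profile(np.exp(t))[0],
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"profiled-likelihood optimisation failed: {res}")
        lam = float(np.exp(res.x))
        ll = -res.fun
        ll0 = self._profile(0.0)[0]
        if ll0 >= ll:
            lam, ll = 0.0, ll0
        _, beta, sigma2, xtvx_inv = self._profile(lam)
        cov = sigma2 * xtvx_inv
        return RandomInterceptLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov, index=self.exog_names, columns=self.exog_names
            ),
            sigma_d2=lam * sigma2,
            sigma2=sigma2,
            llf=float(ll),
            conf_level=conf_level,
        )


@dataclass
class RandomInterceptLMResults:
    """ML estimates with Wald uncertainties for a RandomInterceptLM."""

    model: RandomInterceptLM
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_d2: float
    sigma2: float
    llf: float
    conf_level: float = 0.95

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float | None = None) -> pd.DataFrame:
        if alpha is None:
            alpha = 1 - self.conf_level
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params.to_numpy()

    def predict_mean(self, exog: np.ndarray) -> float:
        """Mean of the fixed-effect prediction over rows of ``exog``."""
        return float(np.mean(np.atleast_2d(exog) @ self.params.to_numpy()))

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  n obs: {self.model.n}   groups: {self.model.n_groups}   "
            f"log-likelihood: {self.llf:.4f}",
            f"  sigma_d^2 (between-group): {self.sigma_d2:.6g}   "
            f"sigma^2 (residual): {self.sigma2:.6g}",
            f"  {'term':<24}{'coef':>12}{'se':>10}{'z':>8}{'p':>10}"
            f"{'ci_low':>12}{'ci_high':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<24}{self.params[name]:>12.5g}{self.bse[name]:>10.3g}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>10.2g}"
                f"{ci.loc[name, 'lower']:>12.5g}{ci.loc[name, 'upper']:>12.5g}"
            )
        return "\n".join(lines)


@dataclass
class EffectSummary:
    """Treatment effect expressed as a percent of the reference mean."""

    analyte: str
    percent: float
    ci_low: float
    ci_high: float
    direction: str
    p_value: float

    def __str__(self) -> str:
        return (
            f"{self.analyte}: {self.percent:.1f}% (95% CI {self.ci_low:.1f}-"
            f"{self.ci_high:.1f}%, p = {self.p_value:.4g}) {self.direction}"
        )


def lrt_anova(
    full: RandomInterceptLMResults, reduced: RandomInterceptLMResults
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p).

    The chi-square reference is standard for fixed-effect comparisons of
    ML fits; ``f_test_anova`` offers the F variant.
    """
    df = full.model.k_fixed - reduced.model.k_fixed
    if df < 0 or full.model.n != reduced.model.n:
        raise ValueError("models are not nested on the same data")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    if df == 0:
        if abs(full.llf - reduced.llf) > 1e-8:
            raise ValueError("models are not nested (equal size, different fit)")
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def f_test_anova(
    full: RandomInterceptLMResults, reduced: RandomInterceptLMResults
) -> tuple[float, int, int, float]:
    """F-flavoured LRT with containment denominator df: (F, df1, df2, p)."""
    stat, df1, _ = lrt_anova(full, reduced)
    df2 = full.model.n - full.model.n_groups - full.model.k_fixed + 1
    fval = stat / df1
    return fval, df1, df2, float(stats.f.sf(fval, df1, df2))


def percent_difference(
    fit: RandomInterceptLMResults,
    reference: str = "dark",
    analyte: str = "",
    p_value: float = np.nan,
    conf_level: float = 0.95,
) -> EffectSummary:
    """Treatment effect as a percent of the model-implied reference mean.

    percent = 100 * |beta_t| / mu_ref, where mu_ref averages the fixed
    effect prediction with the treatment dummy set to the reference
    level; CI endpoints scale beta's Wald interval the same way.
    """
    tnames = [n for n in fit.params.index if n.startswith("treatment[")]
    if len(tnames) != 1:
        raise ValueError("fit does not contain a single treatment effect")
    tname = tnames[0]
    other = tname[len("treatment[") : -1]
    beta = fit.params[tname]
    se = fit.bse[tname]
    X0 = fit.model.exog.copy()
    X0[:, list(fit.params.index).index(tname)] = 0.0
    mu_ref = fit.predict_mean(X0)
    if mu_ref <= 0:
        raise ValueError("non-positive reference mean; percent undefined")
    z = stats.norm.ppf(0.5 + conf_level / 2)
    sign = -1.0 if beta < 0 else 1.0
    lo, hi = sorted(
        (100.0 * sign * (beta - z * se) / mu_ref, 100.0 * sign * (beta + z * se) / mu_ref)
    )
    direction = f"higher in {reference}" if beta < 0 else f"higher in {other}"
    if beta == 0:
        direction = "no difference"
    return EffectSummary(
        analyte=analyte,
        percent=100.0 * abs(beta) / mu_ref,
        ci_low=lo,
        ci_high=hi,
        direction=direction,
        p_value=p_value,
    )


def fit_light_effect(
    table: pd.DataFrame,
    analyte: str | None = None,
    response: str = "value",
    reference: str = "dark",
) -> tuple[RandomInterceptLMResults, EffectSummary]:
    """Fit ``value ~ treatment + (1 | date)`` and summarise the percent
    light effect; significance from the likelihood-ratio ANOVA against
    the intercept-only mixed model."""
    df = table if analyte is None else table[table.analyte == analyte]
    if df["date"].nunique() < 2:
        raise ValueError("need at least two dates")
    full = RandomInterceptLM.from_dataframe(
        df, response=response, reference=reference
    ).fit()
    reduced = RandomInterceptLM.from_dataframe(
        df, response=response, treatment_col=None
    ).fit()
    _, _, p = lrt_anova(full, reduced)
    summ = percent_difference(
        full, reference=reference, analyte=analyte or "", p_value=p
    )
    return full, summ


@dataclass
class InteractionFit:
    results: RandomInterceptLMResults
    per_level: pd.DataFrame  # intercept/slope with CIs per light level
    p_interaction: float
    significant: bool


def interaction_fit(
    df: pd.DataFrame,
    covariate: str,
    response: str = "value",
    reference: str = "dark",
    log10_covariate: bool = True,
    alpha: float = 0.05,
) -> InteractionFit:
    """Fit rate ~ treatment * log10(covariate) with a date random
    intercept, report per-treatment intercepts/slopes, and flag a
    significant treatment x covariate interaction by LRT."""
    full = RandomInterceptLM.from_dataframe(
        df,
        response=response,
        reference=reference,
        covariates=[covariate],
        log10_covariates=log10_covariate,
        interaction=True,
    ).fit()
    reduced = RandomInterceptLM.from_dataframe(
        df,
        response=response,
        reference=reference,
        covariates=[covariate],
        log10_covariates=log10_covariate,
        interaction=False,
    ).fit()
    _, _, p_int = lrt_anova(full, reduced)

    names = list(full.params.index)
    tname = [n for n in names if n.startswith("treatment[") and ":" not in n][0]
    other = tname[len("treatment[") : -1]
    cname = [n for n in names if n.startswith("log10(") or n == covariate][0]
    iname = [n for n in names if n.startswith("treatment:")][0]
    cov = full.cov_params.to_numpy()
    beta = full.params.to_numpy()
    z = stats.norm.ppf(0.975)
    rows = []
    for level, combos in (
        (reference, {"intercept": ["Intercept"], "slope": [cname]}),
        (other, {"intercept": ["Intercept", tname], "slope": [cname, iname]}),
    ):
        for what, terms in combos.items():
            c = np.array([1.0 if n in terms else 0.0 for n in names])
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            rows.append(
                {
                    "treatment": level,
                    "term": what,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                }
            )
    return InteractionFit(
        results=full,
        per_level=pd.DataFrame(rows),
        p_interaction=p_int,
        significant=p_int < alpha,
    )
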