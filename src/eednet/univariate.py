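"""Exposure-by-exposure screening models with a site random intercept.

Binary deficiency outcomes are screened with a mixed-effects logistic model
(outcome ~ exposure + ln AGP + (1 | site)), reporting the odds ratio per 1 SD
of the standardized exposure with a Wald 95% CI.  Continuous biomarkers use a
linear mixed model (biomarker ~ exposure + (1 | site)) without the AGP
covariate, reporting the mean effect per 1 SD.  Biomarker co-variation is
summarized by within-site Spearman correlations averaged over sites, with a
bootstrap-over-children percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._rng import substream
from .glmm import fit_logistic_glmm

__all__ = ["UnivariateResult", "fit_univariate_binary", "fit_univariate_continuous",
           "correlation_summary", "screen_all"]


@dataclass
class UnivariateResult:
    """One screening fit: effect per 1 SD of the exposure with its 95% CI.

    For logistic fits ``estimate`` is the odds ratio and ``beta`` the
    log-odds coefficient; for linear fits the two coincide.
    """

    exposure: str
    outcome: str
    family: str
    estimate: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    n: int
    converged: bool

    @property
    def significant(self) -> bool:
        null = 1.0 if self.family == "logistic" else 0.0
        return bool(self.ci_low > null or self.ci_high < null)


def fit_univariate_binary(df: pd.DataFrame, exposure: str, outcome: str,
                          adjust_ln_agp: bool = True) -> UnivariateResult:
    """Mixed logistic screen: outcome ~ exposure (+ ln AGP) + (1 | site)."""
    cols = [exposure, outcome, "site"] + (["agp"] if adjust_ln_agp else [])
    d = df.dropna(subset=cols)
    names = ["intercept", exposure] + (["agp"] if adjust_ln_agp else [])
    X = np.column_stack([np.ones(len(d)), d[exposure].to_numpy(float)]
                        + ([d["agp"].to_numpy(float)] if adjust_ln_agp else []))
    y = d[outcome].to_numpy(float)
    fit = fit_logistic_glmm(X, y, d["site"].to_numpy(), names=names)
    if not fit.converged or not np.isfinite(fit.se[1]):
        return UnivariateResult(exposure, outcome, "logistic", np.nan, np.nan, np.nan,
                                np.nan, np.nan, len(d), False)
    lo, hi = fit.wald_ci(1)
    return UnivariateResult(exposure, outcome, "logistic",
                            float(np.exp(fit.beta[1])), float(np.exp(lo)),
                            float(np.exp(hi)), float(fit.beta[1]), float(fit.se[1]),
                            len(d), True)


def fit_univariate_continuous(df: pd.DataFrame, exposure: str, biomarker: str
                              ) -> UnivariateResult:
    """Linear mixed screen: biomarker ~ exposure + (1 | site), REML."""
    import statsmodels.api as sm

    d = df.dropna(subset=[exposure, biomarker, "site"])
    exog = sm.add_constant(d[exposure].to_numpy(float))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(d[biomarker].to_numpy(float), exog,
                             groups=d["site"].to_numpy()).fit(reml=True)
        except Exception:
            converged = False
    if not converged:
        return UnivariateResult(exposure, biomarker, "linear", np.nan, np.nan,
                                np.nan, np.nan, np.nan, len(d), False)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return UnivariateResult(exposure, biomarker, "linear", beta,
                            beta - 1.959963984540054 * se, beta + 1.959963984540054 * se,
                            beta, se, len(d), bool(fit.converged))


def correlation_summary(df: pd.DataFrame, columns: list[str],
                        n_boot: int = 1000, seed: int = 0,
                        min_per_site: int = 10) -> pd.DataFrame:
    """Pairwise within-site Spearman correlations averaged across sites.

    The 95% CI is a percentile bootstrap resampling children within site
    (``n_boot`` resamples).  Sites with fewer than ``min_per_site`` children
    are excluded from the average.
    """
    groups = [g for _, g in df.groupby("site") if len(g) >= min_per_site]
    if not groups:
        raise ValueError(f"no site has >= {min_per_site} children")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            rho = float(np.mean([spearmanr(g[a], g[b]).statistic for g in groups]))
            rng = substream(seed, "spearman", a, b)
            boots = np.empty(n_boot)
            for k in range(n_boot):
                vals = []
                for g in groups:
                    idx = rng.integers(0, len(g), len(g))
                    vals.append(spearmanr(g[a].to_numpy()[idx], g[b].to_numpy()[idx]).statistic)
                boots[k] = np.mean(vals)
            lo, hi = np.quantile(boots, [0.025, 0.975])
            rows.append({"var_a": a, "var_b": b, "mean_rho": rho,
                         "ci_low": float(lo), "ci_high": float(hi),
                         "n_sites": len(groups)})
    return pd.DataFrame(rows)


def screen_all(analytic: pd.DataFrame, exposures: list[str],
               binary_outcomes: list[str], continuous_outcomes: list[str],
               adjust_ln_agp: bool = True) -> pd.DataFrame:
    """Run the full screening grid and return a tidy table with significance
    stars (CI excluding the null)."""
    rows = []
    for ex in exposures:
        for out in binary_outcomes:
            r = fit_univariate_binary(analytic, ex, out, adjust_ln_agp=adjust_ln_agp)
            rows.append(_row(r))
        for out in continuous_outcomes:
            r = fit_univariate_continuous(analytic, ex, out)
            rows.append(_row(r))
    return pd.DataFrame(rows)


def _row(r: UnivariateResult) -> dict:
    return {"exposure": r.exposure, "outcome": r.outcome, "family": r.family,
            "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "beta": r.beta, "se": r.se, "n": r.n, "converged": r.converged,
            "star": "*" if r.converged and r.significant else ""}
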