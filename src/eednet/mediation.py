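"""Total-vs-direct effect comparison and path-product mediation.

The headline inference contrasts each diet exposure's *total* association with
a deficiency outcome (the univariate mixed-model screen, adjusted for site and
ln AGP) with its *direct* association in the network (conditioning on the
gut-function mediators).  The qualitative verdict follows the
significance-pattern rule:

* ``full``    — total CI excludes the null, direct CrI includes it;
* ``partial`` — both exclude the null and |direct| < |total|;
* ``none``    — otherwise.

A quantitative product-of-coefficients estimator is reported alongside: for
each exposure -> mediator -> outcome path the per-draw product of the two leg
coefficients (legs are posterior-independent across nodes, so paired draws are
draws from the joint posterior), with the total indirect effect the per-draw
sum over mediators.  On the log-odds scale for a logistic outcome the identity
total = direct + indirect holds only approximately (odds ratios are
non-collapsible); for all-linear chains it is exact up to Monte-Carlo error.
The numeric mediation estimand is this package's formalization of an otherwise
qualitative comparison, and output headers label it as such.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .config import EED_NODES
from .network import MCMCConfig, NetworkSpec, PosteriorSummary, fit_network

logger = logging.getLogger(__name__)

__all__ = ["total_vs_direct", "indirect_effects", "sensitivity_fever", "verdict"]

FEVER_COLUMNS = ["fever_prop", "fever_pre_draw", "fever_post_draw"]


def verdict(total_sig: bool, direct_sig: bool, attenuated: bool) -> str:
    if total_sig and not direct_sig:
        return "full"
    if total_sig and direct_sig and attenuated:
        return "partial"
    return "none"


def indirect_effects(summary: PosteriorSummary,
                     mediators: list[str] | None = None) -> pd.DataFrame:
    """Per-path products exposure -> mediator -> outcome with 95% CrIs.

    One row per path plus, per (exposure, outcome), a ``total_indirect`` row
    summing the mediator paths draw-by-draw.
    """
    mediators = mediators if mediators is not None else list(EED_NODES)
    spec = summary.spec
    rows = []
    outcomes = [c for c in spec.parents
                if any(m in spec.parents[c] for m in mediators)]
    for child in outcomes:
        exposures = [p for p in spec.parents[child] if p.startswith("diet_")]
        meds = [m for m in mediators if m in spec.parents[child] and m in spec.parents]
        for ex in exposures:
            total = None
            for m in meds:
                if ex not in spec.parents[m]:
                    continue
                leg1 = summary.arc_draws(ex, m)
                leg2 = summary.arc_draws(m, child)
                prod = leg1 * leg2
                total = prod if total is None else total + prod
                rows.append(_summary_row(ex, child, m, prod))
            if total is not None:
                rows.append(_summary_row(ex, child, "total_indirect", total))
    return pd.DataFrame(rows, columns=["exposure", "outcome", "mediator", "estimand",
                                       "mean", "q2.5", "q97.5", "significant"])


def _summary_row(exposure: str, outcome: str, mediator: str, draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"exposure": exposure, "outcome": outcome, "mediator": mediator,
            "estimand": "product_of_coefficients",
            "mean": float(draws.mean()), "q2.5": float(lo), "q97.5": float(hi),
            "significant": bool(lo > 0 or hi < 0)}


def total_vs_direct(univariate: pd.DataFrame, summary: PosteriorSummary,
                    mediators: list[str] | None = None) -> pd.DataFrame:
    """Compare the univariate (total) and network (direct) effect per arc.

    ``univariate`` is the tidy screen table (one row per exposure/outcome with
    log-scale ``beta`` and CI bounds); effects are compared on the log-odds
    (or linear) scale.  Exposures or outcomes absent from either layer are
    skipped with a log message.
    """
    ind = indirect_effects(summary, mediators)
    rows = []
    for r in univariate.itertuples():
        if not r.exposure.startswith("diet_"):
            continue
        try:
            direct = summary.arc_row(r.exposure, r.outcome)
        except KeyError:
            logger.info("no network arc for %s -> %s; skipped", r.exposure, r.outcome)
            continue
        if not r.converged:
            logger.info("univariate fit for %s -> %s not converged; skipped",
                        r.exposure, r.outcome)
            continue
        null = 1.0 if r.family == "logistic" else 0.0
        total_sig = bool(r.ci_low > null or r.ci_high < null)
        direct_sig = bool(direct["significant"])
        total_beta = float(r.beta)
        direct_beta = float(direct["mean"])
        attenuated = abs(direct_beta) < abs(total_beta)
        same_sign = total_beta * direct_beta >= 0
        prop_att = (1.0 - direct_beta / total_beta
                    if total_sig and same_sign and total_beta != 0 else np.nan)
        sub = ind[(ind["exposure"] == r.exposure) & (ind["outcome"] == r.outcome)
                  & (ind["mediator"] == "total_indirect")]
        rows.append({
            "exposure": r.exposure, "outcome": r.outcome, "family": r.family,
            "total_beta": total_beta, "total_ci_low_beta": _log_or(r.ci_low, r.family),
            "total_ci_high_beta": _log_or(r.ci_high, r.family),
            "direct_beta": direct_beta,
            "direct_q2.5": float(direct["q2.5"]), "direct_q97.5": float(direct["q97.5"]),
            "indirect_total": float(sub["mean"].iloc[0]) if len(sub) else np.nan,
            "indirect_q2.5": float(sub["q2.5"].iloc[0]) if len(sub) else np.nan,
            "indirect_q97.5": float(sub["q97.5"].iloc[0]) if len(sub) else np.nan,
            "total_significant": total_sig, "direct_significant": direct_sig,
            "proportion_attenuated": prop_att,
            "verdict": verdict(total_sig, direct_sig, attenuated),
        })
    return pd.DataFrame(rows)


def _log_or(bound: float, family: str) -> float:
    return float(np.log(bound)) if family == "logistic" else float(bound)


def sensitivity_fever(analytic: pd.DataFrame, summary: PosteriorSummary,
                      mcmc: MCMCConfig | None = None,
                      fever_columns: list[str] | None = None
                      ) -> tuple[pd.DataFrame, PosteriorSummary]:
    """Refit the outcome nodes with the fever covariates added.

    Returns a side-by-side arc table (base vs refit coefficient, shift) and
    the refitted summary.  Degenerate (constant) fever columns are dropped
    with a warning; missing columns raise.
    """
    fever_columns = fever_columns if fever_columns is not None else list(FEVER_COLUMNS)
    missing = [c for c in fever_columns if c not in analytic.columns]
    if missing:
        raise KeyError(f"fever columns absent from the analytic data: {missing}")
    usable = []
    for c in fever_columns:
        if analytic[c].nunique() < 2:
            warnings.warn(f"fever column {c!r} is constant; dropped")
        else:
            usable.append(c)
    spec = summary.spec
    extra = dict(spec.extra_covariates)
    for child, fam in spec.families.items():
        if fam == "logistic" and child in spec.parents:
            extra[child] = extra.get(child, []) + usable
    refit_spec = NetworkSpec(parents=spec.parents, families=spec.families,
                             sites=spec.sites, reference_site=spec.reference_site,
                             extra_covariates=extra)
    refit = fit_network(analytic, refit_spec, mcmc or summary.mcmc)

    base_arcs = summary.table[summary.table["is_arc"]]
    refit_arcs = refit.table[refit.table["is_arc"]]
    merged = base_arcs.merge(
        refit_arcs[["child", "parameter", "mean", "q2.5", "q97.5", "significant"]],
        on=["child", "parameter"], suffixes=("_base", "_fever"))
    merged["shift"] = merged["mean_fever"] - merged["mean_base"]
    merged.attrs["max_abs_shift"] = float(merged["shift"].abs().max())
    cols = ["child", "parameter", "family", "mean_base", "mean_fever", "shift",
            "q2.5_base", "q97.5_base", "q2.5_fever", "q97.5_fever",
            "significant_base", "significant_fever"]
    return merged[cols], refit
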