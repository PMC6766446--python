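"""From raw longitudinal streams to the standardized analytic dataset.

The pipeline follows a fixed transform-then-average order:

* nutrient densities: sqrt(intake per 1000 kcal) per recall, then the mean
  over the 9-15 mo recalls;
* fecal biomarkers (MPO, NEO, AAT): natural log per non-diarrheal sample,
  then the mean;
* urinary sugar tests: per-test z-scores of ln % recovery (lactulose,
  mannitol) and of ln(L:M ratio) against an age/sex reference fitted on the
  designated reference stratum, then the mean over the 9- and 15-mo tests;
* blood panel at 15 mo: altitude-adjusted hemoglobin, strict-threshold
  deficiency flags, ln AGP;
* complete-case selection, then pooled standardization (mean 0, SD 1,
  denominator n-1) of every continuous model variable.

Inflammation adjustment of biomarker distributions (regression correction on
ln AGP) is applied only when reporting deficiency prevalences; the network
consumes unadjusted values with AGP as an explicit node.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import NUTRIENTS

logger = logging.getLogger(__name__)

__all__ = [
    "DietSummary", "LMReference", "AnalyticResult",
    "summarize_diet", "summarize_fecal", "fit_lm_reference", "lm_zscores",
    "adjust_hemoglobin_altitude", "classify_deficiency",
    "adjust_inflammation_brinda", "standardize", "complete_cases",
    "build_analytic",
]

NUTRIENT_UNITS = {
    "iron": "mg", "zinc": "mg", "calcium": "mg", "vitamin_a": "ug",
    "vitamin_b6": "ug", "folate": "ug", "vitamin_b12": "ug", "vitamin_c": "mg",
    "protein": "g",
}

#: strict deficiency thresholds (classification uses < for "low", > for "high")
THRESHOLDS = {
    "anemia": ("hemoglobin_adj_g_dl", 11.0, "<"),
    "low_retinol": ("retinol_umol_l", 0.70, "<"),
    "low_ferritin": ("ferritin_ug_l", 12.0, "<"),
    "low_zinc": ("zinc_umol_l", 9.9, "<"),
    "high_tfr": ("tfr_mg_l", 8.3, ">"),
    "elevated_agp": ("agp_g_l", 1.0, ">"),
}

CONTINUOUS_ANALYTIC = [f"diet_{v}" for v in NUTRIENTS] + ["mpo", "neo", "aat", "lmz", "agp"]
FLAG_COLUMNS = ["anemia", "low_ferritin", "high_tfr", "low_retinol", "low_zinc", "elevated_agp"]


@dataclass
class DietSummary:
    """Per-child diet summary: mean sqrt nutrient densities, % energy from
    macronutrients, number of usable recalls."""

    densities: dict[str, float]
    pct_energy: dict[str, float]
    n_recalls: int


def summarize_diet(recalls: pd.DataFrame) -> DietSummary:
    """Summarize one child's 24-h recalls.

    Density is computed per recall as sqrt(1000 * amount / energy) and then
    averaged (sqrt before mean); recalls with non-positive energy are dropped
    with a warning.
    """
    usable = recalls[recalls["energy_kcal"] > 0]
    n_bad = len(recalls) - len(usable)
    if n_bad:
        logger.warning("dropped %d recall(s) with non-positive energy", n_bad)
    if usable.empty:
        raise ValueError("no usable recalls (all have non-positive energy)")
    energy = usable["energy_kcal"].to_numpy(float)
    densities = {}
    for v, unit in NUTRIENT_UNITS.items():
        col = f"{v}_{unit}"
        if col not in usable.columns:
            densities[v] = float("nan")
            continue
        amount = usable[col].to_numpy(float)
        densities[v] = float(np.mean(np.sqrt(1000.0 * amount / energy)))
    kcal = {"carb": 4.0 * usable.get("carb_g", np.nan),
            "protein": 4.0 * usable.get("protein_g", np.nan),
            "fat": 9.0 * usable.get("fat_g", np.nan)}
    pct = {k: float(np.mean(np.asarray(v, float) / energy * 100.0)) for k, v in kcal.items()}
    return DietSummary(densities=densities, pct_energy=pct, n_recalls=len(usable))


def summarize_fecal(stool: pd.DataFrame) -> dict[str, float]:
    """Mean natural-log fecal biomarker concentrations for one child.

    Non-positive concentrations are rejected per analyte with a warning.
    """
    out: dict[str, float] = {}
    n_total = 0
    for node, col in (("mpo", "mpo_ng_ml"), ("neo", "neo_nmol_l"), ("aat", "aat_ug_g")):
        vals = stool[col].to_numpy(float) if col in stool.columns else np.array([])
        ok = vals > 0
        if (~ok & np.isfinite(vals)).any():
            logger.warning("rejected %d non-positive %s record(s)", int((~ok).sum()), node)
        vals = vals[ok & np.isfinite(vals)]
        out[node] = float(np.mean(np.log(vals))) if vals.size else float("nan")
        n_total = max(n_total, vals.size)
    out["n_stool"] = n_total
    return out


@dataclass
class LMReference:
    """Age/sex reference for the urinary sugar recoveries, fitted on the
    reference stratum: ln % recovery (and ln L:M ratio) regressed on age and
    sex, with residual SDs for z-scoring."""

    coef: dict[str, dict[str, float]]  # sugar -> {intercept, age_slope, sex_effect}
    resid_sd: dict[str, float]

    def predict(self, sugar: str, age_mo: np.ndarray, female: np.ndarray) -> np.ndarray:
        c = self.coef[sugar]
        return (c["intercept"] + c["age_slope"] * np.asarray(age_mo, float)
                + c["sex_effect"] * np.asarray(female, float))


def fit_lm_reference(tests: pd.DataFrame) -> LMReference:
    """Fit the internal lactulose/mannitol reference on the reference stratum.

    ``tests`` needs columns age_mo, female (0/1), lactulose_pct, mannitol_pct.
    Requires >= 30 tests spanning both ages and both sexes.
    """
    ok = tests.dropna(subset=["lactulose_pct", "mannitol_pct"])
    ok = ok[(ok["lactulose_pct"] > 0) & (ok["mannitol_pct"] > 0)]
    if len(ok) < 30:
        raise ValueError(f"need >= 30 reference tests, got {len(ok)}")
    if ok["age_mo"].nunique() < 2 or ok["female"].nunique() < 2:
        raise ValueError("degenerate reference design: need both ages and both sexes")
    X = sm.add_constant(ok[["age_mo", "female"]].to_numpy(float))
    coef, resid_sd = {}, {}
    responses = {
        "lactulose": np.log(ok["lactulose_pct"].to_numpy(float)),
        "mannitol": np.log(ok["mannitol_pct"].to_numpy(float)),
        "ratio": np.log(ok["lactulose_pct"].to_numpy(float))
        - np.log(ok["mannitol_pct"].to_numpy(float)),
    }
    for sugar, y in responses.items():
        fit = sm.OLS(y, X).fit()
        coef[sugar] = {"intercept": fit.params[0], "age_slope": fit.params[1],
                       "sex_effect": fit.params[2]}
        sd = float(np.sqrt(fit.scale))  # residual SD, denominator n - p
        if sd <= 0:
            raise ValueError(f"non-positive residual SD for {sugar}")
        resid_sd[sugar] = sd
    return LMReference(coef=coef, resid_sd=resid_sd)


def lm_zscores(tests: pd.DataFrame, ref: LMReference) -> dict[str, float]:
    """Per-child mean lactulose / mannitol / L:M-ratio z-scores.

    Each available test contributes z = (ln observed - reference prediction) /
    reference residual SD for each defined sugar; LMZ is computed the same way
    on ln(L:M).  Tests missing one sugar contribute only the defined scores.
    """
    age = tests["age_mo"].to_numpy(float)
    female = tests["female"].to_numpy(float)
    lac = tests["lactulose_pct"].to_numpy(float) if "lactulose_pct" in tests else np.full(len(tests), np.nan)
    man = tests["mannitol_pct"].to_numpy(float) if "mannitol_pct" in tests else np.full(len(tests), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_lac = (np.log(lac) - ref.predict("lactulose", age, female)) / ref.resid_sd["lactulose"]
        z_man = (np.log(man) - ref.predict("mannitol", age, female)) / ref.resid_sd["mannitol"]
        z_ratio = (np.log(lac) - np.log(man) - ref.predict("ratio", age, female)) / ref.resid_sd["ratio"]

    def _mean(a: np.ndarray) -> float:
        a = a[np.isfinite(a)]
        return float(a.mean()) if a.size else float("nan")

    return {"lacz": _mean(z_lac), "manz": _mean(z_man), "lmz": _mean(z_ratio),
            "n_lm_tests": int(np.isfinite(z_ratio).sum())}


def adjust_hemoglobin_altitude(hb_g_dl: float | np.ndarray,
                               altitude_m: float | np.ndarray) -> np.ndarray:
    """Altitude-corrected hemoglobin: subtract the polynomial correction
    -0.032 a + 0.022 a^2 (a = altitude in thousands of feet) when a > 3,
    clipped at zero; unchanged below the threshold."""
    hb = np.asarray(hb_g_dl, float)
    alt = np.asarray(altitude_m, float)
    if np.any(hb[np.isfinite(hb)] < 0):
        raise ValueError("negative hemoglobin")
    if np.any(alt < 0):
        raise ValueError("negative altitude")
    a = alt * 3.280839895 / 1000.0
    corr = np.where(a > 3.0, np.maximum(0.0, -0.032 * a + 0.022 * a * a), 0.0)
    return hb - corr


def classify_deficiency(panel: pd.DataFrame) -> pd.DataFrame:
    """Binary deficiency flags from the 15-mo panel, strict thresholds.

    Expects hemoglobin already altitude-adjusted in ``hemoglobin_adj_g_dl``.
    A missing analyte yields a missing (NaN) flag, not False.
    """
    flags = pd.DataFrame(index=panel.index)
    for flag, (col, thr, op) in THRESHOLDS.items():
        if col not in panel.columns:
            flags[flag] = np.nan
            continue
        x = panel[col].astype(float)
        res = (x < thr) if op == "<" else (x > thr)
        flags[flag] = res.astype(float).where(x.notna())
    return flags


def adjust_inflammation_brinda(concentration: np.ndarray, ln_agp: np.ndarray,
                               reference_ln_agp: float | None = None,
                               min_n: int = 50) -> np.ndarray:
    """Inflammation regression-correction of a biomarker distribution.

    Regresses ln concentration on ln AGP over the sample and removes the
    fitted inflammation component relative to a low-inflammation reference
    (default: the lowest-decile ln AGP), only for observations above the
    reference: adjusted = exp(ln c - bhat * (ln AGP - ref)).  Used for
    prevalence reporting only.  With fewer than ``min_n`` complete pairs the
    adjustment is skipped with a warning.
    """
    c = np.asarray(concentration, float)
    a = np.asarray(ln_agp, float)
    ok = np.isfinite(c) & np.isfinite(a) & (c > 0)
    if ok.sum() < min_n:
        warnings.warn(f"only {int(ok.sum())} observations; skipping inflammation adjustment")
        return c.copy()
    if reference_ln_agp is None:
        reference_ln_agp = float(np.quantile(a[ok], 0.10))
    if float(np.var(a[ok])) < 1e-12:  # no inflammation gradient to regress on
        return c.copy()
    X = sm.add_constant(a[ok])
    beta = float(sm.OLS(np.log(c[ok]), X).fit().params[1])
    adj = c.copy()
    apply = ok & (a > reference_ln_agp)
    adj[apply] = np.exp(np.log(c[apply]) - beta * (a[apply] - reference_ln_agp))
    return adj


def standardize(df: pd.DataFrame, columns: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise (x - mean)/SD over the pooled sample, SD with n-1.

    Returns the standardized frame and the scaling parameters (for mapping
    effects back to natural units).  A constant column raises, naming it.
    """
    out = df.copy()
    cols = columns if columns is not None else list(df.columns)
    params = []
    for col in cols:
        x = df[col].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - mu) / sd
        params.append({"column": col, "mean": mu, "sd": sd})
    return out, pd.DataFrame(params)


def complete_cases(df: pd.DataFrame, required: list[str]
                   ) -> tuple[pd.DataFrame, dict]:
    """Keep rows with no missing required entry; log exclusions by site and by
    missing variable."""
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"required variables absent from the table: {missing}")
    mask = df[required].notna().all(axis=1)
    dropped = df[~mask]
    log = {
        "n_input": int(len(df)),
        "n_kept": int(mask.sum()),
        "by_site": dropped.groupby("site").size().to_dict() if "site" in df.columns else {},
        "by_variable": {c: int(df[c].isna().sum()) for c in required if df[c].isna().any()},
    }
    kept = df[mask].reset_index(drop=True)
    if kept.empty:
        raise ValueError("complete-case selection removed every child")
    return kept, log


@dataclass
class AnalyticResult:
    """The model-ready dataset plus provenance side products."""

    analytic: pd.DataFrame            # standardized continuous vars + flags
    scaling: pd.DataFrame             # standardization parameters
    exclusions: dict
    prevalence: pd.DataFrame          # site-stratified, adjusted + unadjusted
    child_summaries: pd.DataFrame     # pre-standardization per-child values
    lm_reference: LMReference
    diagnostics: dict = field(default_factory=dict)


def build_analytic(cohort, reference_site: str | None = None,
                   required: list[str] | None = None,
                   min_recalls: int = 1, min_stool: int = 1, min_lm: int = 1,
                   brinda_min_n: int = 50) -> AnalyticResult:
    """Run the full preprocessing chain on a :class:`~eednet.simulate.RawCohort`
    (or any object exposing the same tables)."""
    children = cohort.children
    ref_site = reference_site or children["site"].iloc[0]

    # per-child diet and stool summaries
    rows = []
    for cid, grp in cohort.recalls.groupby("child_id"):
        try:
            ds = summarize_diet(grp)
        except ValueError:
            continue
        if ds.n_recalls < min_recalls:
            continue
        row = {"child_id": cid, "n_recalls": ds.n_recalls,
               **{f"diet_{v}": d for v, d in ds.densities.items()},
               **{f"pct_energy_{k}": p for k, p in ds.pct_energy.items()}}
        rows.append(row)
    diet = pd.DataFrame(rows)

    fec = []
    for cid, grp in cohort.stool.groupby("child_id"):
        s = summarize_fecal(grp)
        if s["n_stool"] >= min_stool:
            fec.append({"child_id": cid, **s})
    fecal = pd.DataFrame(fec)

    # urinary sugar z-scores against the reference stratum
    sex = children.set_index("child_id")["sex"]
    lm = cohort.lm.copy()
    lm["female"] = (sex.reindex(lm["child_id"]).to_numpy() == "F").astype(float)
    ref_children = set(children.loc[children["site"] == ref_site, "child_id"])
    ref = fit_lm_reference(lm[lm["child_id"].isin(ref_children)])
    lmz_rows = []
    for cid, grp in lm.groupby("child_id"):
        z = lm_zscores(grp, ref)
        if z["n_lm_tests"] >= min_lm:
            lmz_rows.append({"child_id": cid, **z})
    lmz = pd.DataFrame(lmz_rows)

    # blood panel: altitude-adjusted hemoglobin, flags, ln AGP
    blood = cohort.blood.merge(children[["child_id", "site", "altitude_m"]], on="child_id")
    blood["hemoglobin_adj_g_dl"] = adjust_hemoglobin_altitude(
        blood["hemoglobin_g_dl"], blood["altitude_m"])
    flags = classify_deficiency(blood)
    blood = pd.concat([blood, flags], axis=1)
    blood["ln_agp"] = np.log(blood["agp_g_l"].astype(float))

    wide = (children[["child_id", "site", "sex", "breastfed_prop"]]
            .merge(diet, on="child_id", how="left")
            .merge(fecal, on="child_id", how="left")
            .merge(lmz, on="child_id", how="left")
            .merge(blood.drop(columns=["site", "altitude_m"]), on="child_id", how="left"))
    if getattr(cohort, "fever", None) is not None and len(cohort.fever):
        wide = wide.merge(cohort.fever, on="child_id", how="left")

    required = required or (CONTINUOUS_ANALYTIC
                            + ["anemia", "low_ferritin", "high_tfr", "low_retinol", "low_zinc"])
    wide = wide.rename(columns={"ln_agp": "agp"})
    kept, excl = complete_cases(wide, required)

    std_cols = [c for c in CONTINUOUS_ANALYTIC if c in kept.columns]
    analytic, scaling = standardize(kept, std_cols)
    for c in FLAG_COLUMNS:
        if c in analytic.columns:
            analytic[c] = analytic[c].astype(int)

    prevalence = _prevalence_table(kept, brinda_min_n)
    return AnalyticResult(analytic=analytic, scaling=scaling, exclusions=excl,
                          prevalence=prevalence, child_summaries=kept, lm_reference=ref)


def _prevalence_table(panel: pd.DataFrame, brinda_min_n: int) -> pd.DataFrame:
    """Deficiency prevalences by site, unadjusted and inflammation-adjusted.

    Only the plasma analytes are regression-corrected; anemia (hemoglobin) is
    reported unadjusted apart from the altitude correction already applied.
    """
    adjusted = panel.copy()
    ln_agp = panel["agp"].to_numpy(float) if "agp" in panel else np.log(
        panel["agp_g_l"].to_numpy(float))
    for col in ("ferritin_ug_l", "retinol_umol_l", "zinc_umol_l", "tfr_mg_l"):
        if col in panel.columns:
            adjusted[col] = adjust_inflammation_brinda(
                panel[col].to_numpy(float), ln_agp, min_n=brinda_min_n)
    adj_flags = classify_deficiency(adjusted)
    rows = []
    flag_cols = [c for c in FLAG_COLUMNS if c in panel.columns]
    for site, grp in panel.groupby("site"):
        row = {"site": site, "n": len(grp), "provenance": "unadjusted"}
        row.update({c: float(grp[c].mean()) for c in flag_cols})
        rows.append(row)
        arow = {"site": site, "n": len(grp), "provenance": "inflammation_adjusted"}
        sub = adj_flags.loc[grp.index]
        arow.update({c: float(sub[c].mean()) for c in flag_cols})
        arow["anemia"] = float(grp["anemia"].mean()) if "anemia" in grp else math.nan
        rows.append(arow)
    return pd.DataFrame(rows)
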