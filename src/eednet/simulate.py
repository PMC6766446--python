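"""Synthetic multi-site cohort generator.

Generation is latent-first: each child receives latent values on exactly the
scale the network estimator consumes (transformed, pooled-standardized, per-1-SD
units), drawn from a user-specified ground-truth DAG; observables are then
produced by inverting the preprocessing transforms (square the diet densities,
exponentiate the log biomarkers, undo the z-scoring against the urinary-sugar
reference) with site-level location shifts and independent month-to-month noise.
Running the ``preprocess`` module on the output approximately recovers the
latent standardized values, so the simulator's coefficients are the exact
recovery target for the downstream estimators.

Two entry points:

* :func:`generate_cohort` — the full raw-data path (recalls, stool assays,
  urinary sugar tests, blood panel, fever surveillance) with calibrated
  site heterogeneity.
* :func:`generate_analytic` — a fast path that emits the latent analytic
  matrix directly (used by the simulation studies, where the estimand must be
  expressed without the extra layer of measurement noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from .config import NUTRIENTS, SimConfig
from .truth import TruthDAG, layer_of, truth_table

__all__ = ["RawCohort", "generate_cohort", "generate_analytic", "write_cohort", "read_cohort"]

CONTINUOUS_NODES = ["mpo", "neo", "aat", "lmz", "agp"]
_OBS_KEY = {"mpo": "ln_mpo", "neo": "ln_neo", "aat": "ln_aat", "lmz": "lmz", "agp": "agp"}


@dataclass
class RawCohort:
    """Tidy per-stream tables plus the generating truth and latent values.

    ``latents`` carries each child's latent standardized variables and true
    outcome flags (columns ``true_*``); it is synthetic ground truth used by
    recovery tests, never an input to the analysis pipeline.
    """

    children: pd.DataFrame
    recalls: pd.DataFrame
    stool: pd.DataFrame
    lm: pd.DataFrame
    blood: pd.DataFrame
    fever: pd.DataFrame
    latents: pd.DataFrame
    truth: TruthDAG


def _exchangeable_chol(k: int, rho: float) -> np.ndarray:
    corr = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    return np.linalg.cholesky(corr)


class _Scale:
    """Location/scale map between a latent (pooled mean 0, SD ~1) variable and
    its observable transformed scale, given per-site targets and a within-site
    SD: observable = pooled_mean + pooled_sd * latent, with the site shift
    delta_s = (target_s - pooled_mean) / pooled_sd folded into the latent."""

    def __init__(self, targets: dict[str, float], within_sd: float, sites: list[str]):
        t = np.array([targets[s] for s in sites], float)
        self.m = float(t.mean())
        self.g = float(math.sqrt(np.var(t) + within_sd**2))
        self.delta = {s: (targets[s] - self.m) / self.g for s in sites}
        self.w = within_sd / self.g  # within-site latent SD

    def to_obs(self, latent: np.ndarray) -> np.ndarray:
        return self.m + self.g * latent


def _build_scales(config: SimConfig) -> dict[str, _Scale]:
    cal, sites = config.calibration, config.sites
    scales: dict[str, _Scale] = {}
    cv = float(cal["sqrt_density_cv"])
    for v in NUTRIENTS:
        t = {s: math.sqrt(cal["density_median"][v][s]) for s in sites}
        within = cv * float(np.mean(list(t.values())))
        scales[f"diet_{v}"] = _Scale(t, within, sites)
    for node in ("mpo", "neo", "aat"):
        key = _OBS_KEY[node]
        scales[node] = _Scale(cal[f"{key}_mean"], cal["within_sd"][key], sites)
    scales["lmz"] = _Scale(cal["lmz_mean"], cal["within_sd"]["lmz"], sites)
    scales["manz"] = _Scale(cal["manz_mean"], cal["within_sd"]["manz"], sites)
    ln_agp = {s: math.log(cal["agp_mean"][s]) - cal["ln_sd"]["agp"] ** 2 / 2 for s in sites}
    scales["agp"] = _Scale(ln_agp, cal["ln_sd"]["agp"], sites)
    return scales


def _site_center(node: str, site: str, truth: TruthDAG, scales: dict[str, _Scale]) -> float:
    """Expected site mean of a node's latent/flag (used to center parents)."""
    if layer_of(node) == "outcome":
        return float(expit(truth.intercept(node, site)))
    delta = scales[node].delta[site] if node in scales else 0.0
    if layer_of(node) == "diet":
        return delta
    base = delta + truth.intercept(node, site)
    return base + sum(b * _site_center(p, site, truth, scales) for p, b in truth.parents(node))


def generate_cohort(config: SimConfig, truth: TruthDAG,
                    inflammation_distortion: dict[str, float] | None = None) -> RawCohort:
    """Draw a full synthetic cohort from the truth DAG under ``config``.

    ``inflammation_distortion`` maps analyte ("ferritin", "retinol", "zinc",
    "tfr") to a coefficient gamma: the stored concentration is shifted by
    ``exp(gamma * latent ln-AGP z-score)`` while the *latent* deficiency flag is
    left at its undistorted value — emulating inflammation-biased biomarker
    distributions that an inflammation regression-correction should undo.
    """
    cal, sites = config.calibration, config.sites
    scales = _build_scales(config)
    distort = inflammation_distortion or {}
    noise = cal["month_noise"]
    chol = _exchangeable_chol(len(NUTRIENTS), float(cal["diet_correlation"]))
    diet_nodes = [f"diet_{v}" for v in NUTRIENTS]
    thresholds = {"low_ferritin": ("ferritin", math.log(12.0), "below"),
                  "high_tfr": ("tfr", math.log(8.3), "above"),
                  "low_retinol": ("retinol", math.log(0.70), "below"),
                  "low_zinc": ("zinc", math.log(9.9), "below")}

    children, recalls, stool, lm, blood, fever, latents = [], [], [], [], [], [], []
    for site in sites:
        alt = float(cal["altitude_m"][site])
        for c in range(config.n_children(site)):
            rng = substream(config.seed, site, c)
            cid = f"{site}-{c:04d}"
            sex = "F" if rng.random() < 0.5 else "M"
            female = 1.0 if sex == "F" else 0.0
            bf = float(rng.beta(cal["breastfed_prop_alpha"], 1.0))

            lat: dict[str, float] = {}
            z = chol @ rng.standard_normal(len(NUTRIENTS))
            for j, v in enumerate(NUTRIENTS):
                node = f"diet_{v}"
                lat[node] = scales[node].delta[site] + scales[node].w * z[j]
            # middle layer then outcomes, in truth order
            for node in truth.topological_children():
                parents = truth.parents(node)
                struct = sum(b * (lat[p] - _site_center(p, site, truth, scales))
                             for p, b in parents)
                if truth.family(node) == "linear":
                    fam_sigma = truth.node_families[node][1]
                    sd = fam_sigma if fam_sigma is not None else (
                        scales[node].w * truth.residual_sd(node) if node in scales
                        else truth.residual_sd(node))
                    delta = scales[node].delta[site] if node in scales else 0.0
                    lat[node] = (delta + truth.intercept(node, site) + struct
                                 + sd * rng.standard_normal())
                else:
                    eta = truth.intercept(node, site) + struct
                    lat[node] = float(rng.random() < expit(eta))
            for node in CONTINUOUS_NODES:  # nodes absent from the truth: pure noise
                if node not in lat:
                    lat[node] = scales[node].delta[site] \
                        + scales[node].w * rng.standard_normal()

            children.append({"child_id": cid, "site": site, "sex": sex,
                             "altitude_m": alt, "breastfed_prop": bf})
            row = {"child_id": cid, "site": site, **{k: lat[k] for k in diet_nodes},
                   **{k: lat[k] for k in CONTINUOUS_NODES if k in lat}}
            row.update({f"true_{o}": int(lat[o]) for o in thresholds if o in lat})
            if "anemia" in lat:
                row["true_anemia"] = int(lat["anemia"])
            latents.append(row)

            # --- dietary recalls -------------------------------------------
            e_mu, e_sd = cal["energy_kcal_mean"][site], cal["energy_kcal_sd"][site]
            e_child = max(80.0, float(rng.normal(e_mu, e_sd)))
            carb_pct_c = float(cal["carb_pct_energy"][site] + rng.normal(0.0, 2.0))
            for month in config.months:
                if rng.random() < config.missing_rate("recalls"):
                    continue
                energy = max(50.0, e_child * (1.0 + noise["energy_frac"] * rng.standard_normal()))
                rec = {"child_id": cid, "age_mo": month, "energy_kcal": energy}
                dens: dict[str, float] = {}
                for v in NUTRIENTS:
                    node = f"diet_{v}"
                    tau = noise["sqrt_density_frac"] * scales[node].w
                    sq = scales[node].to_obs(lat[node] + tau * rng.standard_normal())
                    sq = max(sq, 0.05 * scales[node].m)
                    dens[v] = sq * sq
                for v in NUTRIENTS:
                    if v == "protein":
                        continue
                    unit = {"iron": "mg", "zinc": "mg", "calcium": "mg", "vitamin_a": "ug",
                            "vitamin_b6": "ug", "folate": "ug", "vitamin_b12": "ug",
                            "vitamin_c": "mg"}[v]
                    rec[f"{v}_{unit}"] = dens[v] * energy / 1000.0
                protein_g = dens["protein"] * energy / 1000.0
                protein_pct = 4.0 * protein_g / energy * 100.0
                carb_pct = float(np.clip(carb_pct_c + rng.normal(0.0, 1.0),
                                         10.0, max(10.0, 98.0 - protein_pct)))
                fat_pct = 100.0 - carb_pct - protein_pct
                rec["protein_g"] = protein_g
                rec["carb_g"] = carb_pct / 100.0 * energy / 4.0
                rec["fat_g"] = fat_pct / 100.0 * energy / 9.0
                recalls.append(rec)

            # --- stool assays ----------------------------------------------
            k = min(config.stool_samples_per_child, len(config.months))
            stool_months = np.sort(rng.choice(config.months, size=k, replace=False))
            for month in stool_months:
                if rng.random() < config.missing_rate("stool"):
                    continue
                vals = {}
                for node, col in (("mpo", "mpo_ng_ml"), ("neo", "neo_nmol_l"),
                                  ("aat", "aat_ug_g")):
                    tau = noise[_OBS_KEY[node]] / scales[node].g
                    ln_v = scales[node].to_obs(lat[node] + tau * rng.standard_normal())
                    vals[col] = math.exp(ln_v)
                stool.append({"child_id": cid, "age_mo": int(month), **vals})

            # --- lactulose:mannitol tests ----------------------------------
            ref = cal["lm_reference"]
            for age in config.lm_test_ages:
                if rng.random() < config.missing_rate("lm"):
                    continue
                man_z = scales["manz"].to_obs(
                    scales["manz"].delta[site] + scales["manz"].w * rng.standard_normal()
                    + noise["lm_test"] * rng.standard_normal())
                lmz_z = scales["lmz"].to_obs(lat["lmz"]
                                             + noise["lm_test"] * rng.standard_normal())
                rm = ref["ln_mannitol"]
                ln_man = (rm["intercept"] + rm["age_slope"] * (age - 12)
                          + rm["sex_effect"] * female + rm["resid_sd"] * man_z)
                rr = ref["ln_ratio"]
                ln_ratio = (rr["intercept"] + rr["age_slope"] * (age - 12)
                            + rr["sex_effect"] * female + rr["resid_sd"] * lmz_z)
                lm.append({"child_id": cid, "age_mo": age,
                           "lactulose_pct": math.exp(ln_ratio + ln_man),
                           "mannitol_pct": math.exp(ln_man)})

            # --- blood panel at 15 mo --------------------------------------
            if rng.random() >= config.missing_rate("blood"):
                panel = {"child_id": cid, "age_mo": 15}
                hb_mu, hb_sd = cal["hb_mean"][site], cal["hb_sd"][site]
                anemic = bool(lat.get("anemia", 0))
                hb_adj = _truncated_normal(rng, hb_mu, hb_sd, 11.0, below=anemic)
                panel["hemoglobin_g_dl"] = hb_adj + _altitude_correction(alt)
                for flag, (analyte, ln_thr, side) in thresholds.items():
                    med = cal[f"{analyte}_median"][site]
                    sd = cal["ln_sd"][analyte]
                    deficient = bool(lat.get(flag, 0))
                    below = deficient if side == "below" else not deficient
                    ln_c = _truncated_normal(rng, math.log(med), sd, ln_thr, below=below)
                    # inflammation distortion anchored at the low-inflammation
                    # reference (~10th percentile of the AGP z-score), so the
                    # latent flag describes the child's low-inflammation state
                    ln_c += distort.get(analyte, 0.0) * (lat["agp"] + 1.2816)
                    unit = {"ferritin": "ug_l", "tfr": "mg_l",
                            "retinol": "umol_l", "zinc": "umol_l"}[analyte]
                    panel[f"{analyte}_{unit}"] = math.exp(ln_c)
                ln_agp = scales["agp"].to_obs(lat["agp"]) \
                    + cal["agp_assay_noise"] * rng.standard_normal()
                panel["agp_g_l"] = math.exp(ln_agp)
                blood.append(panel)

            # --- fever surveillance ----------------------------------------
            p_fev = cal["fever_prop"][site]
            logit_p = math.log(max(p_fev, 1e-4) / (1 - max(p_fev, 1e-4)))
            fever.append({
                "child_id": cid,
                "fever_prop": float(expit(logit_p + 0.8 * rng.standard_normal())),
                "fever_pre_draw": int(rng.random() < cal["fever_near_draw_rate"]),
                "fever_post_draw": int(rng.random() < cal["fever_near_draw_rate"]),
            })

    return RawCohort(
        children=pd.DataFrame(children),
        recalls=pd.DataFrame(recalls),
        stool=pd.DataFrame(stool),
        lm=pd.DataFrame(lm),
        blood=pd.DataFrame(blood),
        fever=pd.DataFrame(fever),
        latents=pd.DataFrame(latents),
        truth=truth,
    )


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      threshold: float, below: bool) -> float:
    """One N(mu, sd) draw conditioned to fall strictly below/above threshold."""
    from scipy.stats import truncnorm

    if below:
        a, b = -np.inf, (threshold - mu) / sd
    else:
        a, b = (threshold - mu) / sd, np.inf
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def _altitude_correction(altitude_m: float) -> float:
    """Hemoglobin altitude correction (g/dL) on the polynomial-in-kilofeet
    scale; zero below the 3000-ft threshold."""
    a = altitude_m * 3.280839895 / 1000.0
    if a <= 3.0:
        return 0.0
    return max(0.0, -0.032 * a + 0.022 * a * a)


def generate_analytic(truth: TruthDAG, n_per_site: int = 200, sites: list[str] | None = None,
                      seed: int = 0, diet_correlation: float = 0.3) -> pd.DataFrame:
    """Draw the latent analytic matrix directly (no measurement layer).

    Continuous nodes are generated with pooled mean 0 / SD ~1 and no site
    shifts (truth intercepts, if any, are honored); binary outcomes use the
    truth's per-site intercepts.  Returned columns are exactly the analytic
    columns the network consumes, so fitted coefficients estimate the truth's
    standardized coefficients without attenuation.
    """
    sites = sites or [f"S{i}" for i in range(7)]
    diet_nodes = sorted(n for n in truth.nodes if layer_of(n) == "diet")
    frames = []
    for site in sites:
        rng = substream(seed, "analytic", site)
        n = n_per_site
        cols: dict[str, np.ndarray] = {}
        if diet_nodes:
            chol = _exchangeable_chol(len(diet_nodes), diet_correlation)
            z = rng.standard_normal((len(diet_nodes), n))
            d = chol @ z
            for j, node in enumerate(diet_nodes):
                cols[node] = d[j]
        for node in truth.topological_children():
            eta = np.full(n, truth.intercept(node, site))
            for p, b in truth.parents(node):
                parent = cols[p]
                if layer_of(p) == "outcome":
                    parent = parent - expit(truth.intercept(p, site))
                eta = eta + b * parent
            if truth.family(node) == "linear":
                cols[node] = eta + truth.residual_sd(node) * rng.standard_normal(n)
            else:
                cols[node] = (rng.random(n) < expit(eta)).astype(float)
        df = pd.DataFrame(cols)
        df.insert(0, "site", site)
        df.insert(0, "child_id", [f"{site}-{i:04d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: RawCohort, out_dir: str | Path) -> None:
    """Write the cohort as tidy CSVs plus truth.json (latents.csv is labelled
    synthetic ground truth and is not an analysis input)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("children", "recalls", "stool", "lm", "blood", "fever", "latents"):
        getattr(cohort, name).to_csv(out / f"{name}.csv", index=False)
    truth = cohort.truth
    payload = {
        "arcs": [{"parent": p, "child": c, "beta_true": b} for p, c, b in truth.arcs],
        "node_families": {k: list(v) for k, v in truth.node_families.items()},
        "intercepts": truth.intercepts,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
    truth_table(truth).to_csv(out / "truth_table.csv", index=False)


def read_cohort(in_dir: str | Path) -> RawCohort:
    import json

    d = Path(in_dir)
    raw = json.loads((d / "truth.json").read_text())
    truth = TruthDAG(
        arcs=[(a["parent"], a["child"], a["beta_true"]) for a in raw["arcs"]],
        node_families={k: (v[0], v[1]) for k, v in raw["node_families"].items()},
        intercepts=raw["intercepts"],
    )
    tables = {name: pd.read_csv(d / f"{name}.csv")
              for name in ("children", "recalls", "stool", "lm", "blood", "fever", "latents")}
    return RawCohort(truth=truth, **tables)
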