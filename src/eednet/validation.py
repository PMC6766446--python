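"""End-to-end validation studies with known ground truth.

These are the package's own checks of its estimators, run on synthetic data
where the estimand is known exactly:

* sampler-vs-oracle agreement (conjugate closed form; maximum likelihood);
* frequentist calibration of the 95% credibility intervals (coverage and
  null significant-arc rate) on a layered, study-shaped truth;
* mediation-verdict operating characteristics under full-mediation and null
  truths;
* the path-tracing identity (total = direct + sum of indirect) on an
  all-linear chain;
* the preprocessing round trip (latent recovery) and simulator determinism.

Every study takes an integer seed and scales with an explicit replicate
count, so the same functions back both the test suite and the acceptance
script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._rng import substream
from .config import SimConfig
from .network import MCMCConfig, NetworkSpec, build_network, fit_network
from .preprocess import build_analytic
from .samplers import conjugate_nig_posterior, sample_linear_node, sample_logistic_node
from .simulate import generate_analytic, generate_cohort
from .truth import TruthDAG, default_truth
from .univariate import fit_univariate_binary, fit_univariate_continuous

__all__ = [
    "conjugate_oracle_check", "logistic_oracle_check", "coverage_study",
    "mediation_study", "path_identity_check", "roundtrip_check",
    "threshold_check", "determinism_check", "coverage_truth",
]

LN125 = math.log(1.25)


# ---------------------------------------------------------------------------
# sampler oracles
# ---------------------------------------------------------------------------

def conjugate_oracle_check(seed: int, n: int = 20) -> dict[str, float]:
    """Gibbs vs exact normal-inverse-gamma posterior on a tiny linear node.

    Returns the largest coefficient discrepancy (posterior mean and SD) in
    units of the Monte-Carlo standard error of the sampler.
    """
    rng = substream(seed, "conj")
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([0.2, 0.5]) + 0.8 * rng.standard_normal(n)
    cfg = MCMCConfig(n_chains=4, n_iterations=6000, n_burnin=1000, seed=seed,
                     coef_prior_sd=10.0, sigma_prior=("nig", 2.0, 1.0))
    draws, _ = sample_linear_node(X, y, cfg, node_key="oracle")
    oracle = conjugate_nig_posterior(X, y, 10.0, 2.0, 1.0)
    flat = draws.reshape(-1, X.shape[1])
    n_draws = flat.shape[0]
    import arviz as az

    max_z_mean = 0.0
    max_z_sd = 0.0
    for j in range(X.shape[1]):
        ess = float(az.ess(draws[:, :, j]))
        s = flat[:, j].std(ddof=1)
        mc_se_mean = s / math.sqrt(ess)
        # delta-method MC error of the SD estimate via the fourth moment
        # (the marginal posterior is a t, so heavier-tailed than normal)
        m4 = float(np.mean((flat[:, j] - flat[:, j].mean()) ** 4))
        mc_se_sd = math.sqrt(max(m4 - s**4, 0.0) / ess) / (2.0 * s)
        max_z_mean = max(max_z_mean, abs(flat[:, j].mean() - oracle["mean"][j]) / mc_se_mean)
        max_z_sd = max(max_z_sd, abs(flat[:, j].std(ddof=1) - oracle["sd"][j]) / mc_se_sd)
    return {"max_z_mean": max_z_mean, "max_z_sd": max_z_sd, "n": n,
            "n_draws": n_draws}


def logistic_oracle_check(seed: int, n: int = 5000, beta_true: float = 0.5
                          ) -> dict[str, float]:
    """Polya-Gamma Gibbs posterior mean vs the ML estimate at large n."""
    import statsmodels.api as sm
    from scipy.special import expit

    rng = substream(seed, "logit-oracle")
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = (rng.random(n) < expit(X @ np.array([-0.2, beta_true]))).astype(float)
    mle = sm.Logit(y, X).fit(disp=0).params
    cfg = MCMCConfig(n_chains=2, n_iterations=2500, n_burnin=500, seed=seed)
    draws = sample_logistic_node(X, y, cfg, node_key="oracle")
    post_mean = draws.reshape(-1, 2).mean(axis=0)
    return {"abs_diff": float(abs(post_mean[1] - mle[1])),
            "posterior_mean": float(post_mean[1]), "mle": float(mle[1]), "n": n}


# ---------------------------------------------------------------------------
# coverage of the credibility intervals
# ---------------------------------------------------------------------------

def coverage_truth(sites: list[str]) -> TruthDAG:
    """A reduced, layered truth with arc coefficients drawn from the effect
    classes {0, 0.1, 0.2, ln 1.25} in both arc families."""
    arcs = [
        ("diet_iron", "mpo", 0.0), ("diet_zinc", "mpo", 0.1), ("diet_vitamin_a", "mpo", 0.2),
        ("diet_iron", "lmz", 0.1), ("diet_zinc", "lmz", 0.2), ("diet_vitamin_a", "lmz", 0.0),
        ("diet_iron", "agp", 0.0), ("diet_zinc", "agp", 0.1), ("diet_vitamin_a", "agp", 0.2),
        ("diet_iron", "anemia", 0.0), ("diet_zinc", "anemia", 0.1),
        ("diet_vitamin_a", "anemia", 0.2),
        ("mpo", "anemia", LN125), ("lmz", "anemia", 0.0), ("agp", "anemia", 0.1),
        ("low_ferritin", "anemia", LN125),
        ("diet_iron", "low_ferritin", 0.1), ("diet_zinc", "low_ferritin", 0.0),
        ("diet_vitamin_a", "low_ferritin", 0.0),
        ("mpo", "low_ferritin", 0.2), ("lmz", "low_ferritin", LN125),
        ("agp", "low_ferritin", 0.0),
    ]
    families = {"mpo": ("linear", None), "lmz": ("linear", None), "agp": ("linear", None),
                "anemia": ("logistic", None), "low_ferritin": ("logistic", None)}
    # mild site heterogeneity in outcome risk, absorbed by the site dummies
    base = {"anemia": -0.6, "low_ferritin": -0.4}
    intercepts = {out: {s: base[out] + 0.3 * ((i % 3) - 1) for i, s in enumerate(sites)}
                  for out in base}
    return TruthDAG(arcs=arcs, node_families=families, intercepts=intercepts)


def _coverage_spec(sites: list[str]) -> NetworkSpec:
    return build_network(diet_vars=["iron", "zinc", "vitamin_a"],
                         eed_nodes=["mpo", "lmz"],
                         outcome_nodes=["anemia", "low_ferritin"],
                         sites=sites, reference_site=sites[0])


def coverage_study(seed: int, n_reps: int = 50, n_per_site: int = 200,
                   n_sites: int = 7, mcmc_iters: int = 1200,
                   mcmc_burnin: int = 600) -> dict[str, float]:
    """Frequentist calibration of the network's 95% CrIs.

    Repeatedly simulates from the reduced layered truth, fits the network and
    records, per arc, whether the CrI covered the true coefficient and
    whether a null arc was flagged significant.  Coverage is pooled over arcs
    within (family, |beta|) class and over replicates.
    """
    sites = [f"S{i}" for i in range(n_sites)]
    truth = coverage_truth(sites)
    spec = _coverage_spec(sites)
    true_beta = {(p, c): b for p, c, b in truth.arcs}
    counts: dict[str, list[int]] = {}
    null_sig = 0
    null_total = 0
    for rep in range(n_reps):
        df = generate_analytic(truth, n_per_site=n_per_site, sites=sites,
                               seed=seed * 100003 + rep)
        mcmc = MCMCConfig(n_chains=2, n_iterations=mcmc_iters, n_burnin=mcmc_burnin,
                          seed=seed * 100003 + rep)
        summary = fit_network(df, spec, mcmc)
        arcs = summary.table[summary.table["is_arc"]]
        for _, row in arcs.iterrows():
            b = true_beta.get((row["parameter"], row["child"]), 0.0)
            cls = f"{row['family']}_{abs(b):.3f}"
            counts.setdefault(cls, []).append(int(row["q2.5"] <= b <= row["q97.5"]))
            if b == 0.0:
                null_total += 1
                null_sig += int(row["significant"])
    out: dict[str, float] = {"n_reps": float(n_reps), "n": float(n_per_site * n_sites)}
    all_cov: list[int] = []
    for cls, hits in sorted(counts.items()):
        out[f"coverage_pct_{cls}"] = 100.0 * float(np.mean(hits))
        all_cov.extend(hits)
    lin = [h for cls, v in counts.items() if cls.startswith("linear") for h in v]
    log = [h for cls, v in counts.items() if cls.startswith("logistic") for h in v]
    out["coverage_pct_linear"] = 100.0 * float(np.mean(lin))
    out["coverage_pct_logistic"] = 100.0 * float(np.mean(log))
    out["coverage_pct_overall"] = 100.0 * float(np.mean(all_cov))
    out["null_significant_rate_pct"] = 100.0 * null_sig / null_total
    return out


# ---------------------------------------------------------------------------
# mediation operating characteristics
# ---------------------------------------------------------------------------

def _mediation_truth(sites: list[str], full: bool) -> TruthDAG:
    """diet_zinc -> LMZ -> low_retinol with no direct arc (full mediation),
    or the all-null version of the same graph."""
    arcs = [("diet_zinc", "lmz", -0.5), ("lmz", "low_retinol", 0.6)] if full else []
    families = {"lmz": ("linear", None), "low_retinol": ("logistic", None)}
    intercepts = {"low_retinol": {s: -0.8 + 0.2 * ((i % 3) - 1)
                                  for i, s in enumerate(sites)}}
    return TruthDAG(arcs=arcs, node_families=families, intercepts=intercepts)


def mediation_study(seed: int, n_reps: int = 50, n_per_site: int = 200,
                    n_sites: int = 7, full: bool = True,
                    mcmc_iters: int = 1200, mcmc_burnin: int = 600) -> dict[str, float]:
    """Rate of the "full mediation" verdict under a full-mediation truth
    (power) or an all-null truth (false-verdict rate)."""
    from .mediation import verdict as verdict_rule

    sites = [f"S{i}" for i in range(n_sites)]
    truth = _mediation_truth(sites, full=full)
    spec = build_network(diet_vars=["zinc"], eed_nodes=["lmz"],
                         outcome_nodes=["low_retinol"], include_agp=False,
                         sites=sites, reference_site=sites[0])
    n_full = 0
    n_done = 0
    for rep in range(n_reps):
        rep_seed = seed * 99991 + rep
        df = generate_analytic(truth, n_per_site=n_per_site, sites=sites, seed=rep_seed)
        if "diet_zinc" not in df.columns:  # null truth has no diet node in its arcs
            rng = substream(rep_seed, "nulldiet")
            df["diet_zinc"] = rng.standard_normal(len(df))
        uni = fit_univariate_binary(df, "diet_zinc", "low_retinol", adjust_ln_agp=False)
        if not uni.converged:
            continue
        mcmc = MCMCConfig(n_chains=2, n_iterations=mcmc_iters, n_burnin=mcmc_burnin,
                          seed=rep_seed)
        summary = fit_network(df, spec, mcmc)
        direct = summary.arc_row("diet_zinc", "low_retinol")
        v = verdict_rule(uni.significant, bool(direct["significant"]),
                         abs(float(direct["mean"])) < abs(uni.beta))
        n_full += int(v == "full")
        n_done += 1
    return {"full_verdict_pct": 100.0 * n_full / max(n_done, 1),
            "n_reps_done": float(n_done), "n": float(n_per_site * n_sites)}


# ---------------------------------------------------------------------------
# path-tracing identity on an all-linear chain
# ---------------------------------------------------------------------------

def path_identity_check(seed: int, n_per_site: int = 400, n_sites: int = 4,
                        n_reps: int = 3) -> dict[str, float]:
    """On a linear chain, total effect = direct + sum of path products.

    The "outcome" node is declared linear, so the decomposition is exact in
    expectation; the reported gap is |total_hat - (direct + indirect)| in
    posterior-mean units, maximized over replicates, together with the
    Monte-Carlo scale it should stay within.
    """
    sites = [f"S{i}" for i in range(n_sites)]
    truth = TruthDAG(
        arcs=[("diet_zinc", "lmz", 0.4), ("diet_zinc", "low_zinc", 0.15),
              ("lmz", "low_zinc", 0.5)],
        node_families={"lmz": ("linear", None), "low_zinc": ("linear", None)},
    )
    spec = NetworkSpec(parents={"lmz": ["diet_zinc"], "low_zinc": ["diet_zinc", "lmz"]},
                       families={"lmz": "linear", "low_zinc": "linear"},
                       sites=sites, reference_site=sites[0])
    max_gap = 0.0
    max_se = 0.0
    for rep in range(n_reps):
        rep_seed = seed * 77003 + rep
        df = generate_analytic(truth, n_per_site=n_per_site, sites=sites, seed=rep_seed)
        total = fit_univariate_continuous(df, "diet_zinc", "low_zinc")
        mcmc = MCMCConfig(n_chains=2, n_iterations=2000, n_burnin=500, seed=rep_seed)
        summary = fit_network(df, spec, mcmc)
        direct = summary.arc_draws("diet_zinc", "low_zinc")
        indirect = (summary.arc_draws("diet_zinc", "lmz")
                    * summary.arc_draws("lmz", "low_zinc"))
        decomposed = direct.mean() + indirect.mean()
        gap = abs(total.beta - decomposed)
        # Monte-Carlo scale: total's SE plus the posterior SD of the sum
        se = math.hypot(total.se, float((direct + indirect).std(ddof=1)))
        if gap > max_gap:
            max_gap, max_se = gap, se
    return {"max_abs_gap": max_gap, "mc_scale": max_se,
            "n": float(n_per_site * n_sites)}


# ---------------------------------------------------------------------------
# preprocessing round trip, thresholds, determinism
# ---------------------------------------------------------------------------

def roundtrip_check(seed: int, children_per_site: int = 80) -> dict[str, float]:
    """Generate a calibrated cohort, preprocess it, and correlate the
    standardized analytic variables with the generating latents."""
    cfg = SimConfig(children_per_site=children_per_site, seed=seed)
    truth = default_truth(cfg.calibration, cfg.sites)
    cohort = generate_cohort(cfg, truth)
    prep = build_analytic(cohort, reference_site="BRF")
    merged = prep.analytic.merge(cohort.latents, on="child_id", suffixes=("", "_latent"))
    checked = [f"diet_{v}" for v in ("iron", "zinc", "calcium", "vitamin_a", "protein")] \
        + ["mpo", "neo", "aat", "lmz", "agp"]
    cors = {c: float(np.corrcoef(merged[c], merged[f"{c}_latent"])[0, 1]) for c in checked}
    std_cols = [c for c in prep.scaling["column"]]
    max_abs_mean = max(abs(float(prep.analytic[c].mean())) for c in std_cols)
    max_sd_err = max(abs(float(prep.analytic[c].std(ddof=1)) - 1.0) for c in std_cols)
    flag_agreement = float(np.mean([
        (prep.analytic[o] == merged[f"true_{o}"]).mean()
        for o in ("anemia", "low_ferritin", "high_tfr", "low_retinol", "low_zinc")
        if f"true_{o}" in merged.columns
    ])) if len(merged) else float("nan")
    return {"min_correlation": min(cors.values()), "max_abs_mean": max_abs_mean,
            "max_sd_err": max_sd_err, "flag_agreement": flag_agreement,
            "n": float(len(prep.analytic)), **{f"cor_{k}": v for k, v in cors.items()}}


def threshold_check() -> dict[str, float]:
    """Boundary behavior of the deficiency classification (strict thresholds)."""
    from .preprocess import classify_deficiency

    panel = pd.DataFrame({
        "hemoglobin_adj_g_dl": [11.0, 10.99],
        "retinol_umol_l": [0.70, 0.69],
        "ferritin_ug_l": [12.0, 11.99],
        "zinc_umol_l": [9.9, 9.89],
        "tfr_mg_l": [8.3, 8.31],
        "agp_g_l": [1.0, 1.01],
    })
    flags = classify_deficiency(panel)
    expected_not = (flags.iloc[0] == 0).all()   # at the printed value: not flagged
    expected_yes = (flags.iloc[1] == 1).all()   # just past it: flagged
    return {"boundary_accuracy": float(expected_not and expected_yes)}


def determinism_check(seed: int) -> dict[str, float]:
    """Same config + seed twice: identical cohort tables and identical
    posterior draws."""
    cfg = SimConfig(n_sites=2, children_per_site=15, seed=seed)
    truth = default_truth(cfg.calibration, cfg.sites)
    a = generate_cohort(cfg, truth)
    b = generate_cohort(cfg, truth)
    same_cohort = all(
        getattr(a, t).equals(getattr(b, t))
        for t in ("children", "recalls", "stool", "lm", "blood", "fever", "latents"))
    sites = ["S0", "S1"]
    t2 = _mediation_truth(sites, full=True)
    df = generate_analytic(t2, n_per_site=100, sites=sites, seed=seed)
    spec = build_network(diet_vars=["zinc"], eed_nodes=["lmz"],
                         outcome_nodes=["low_retinol"], include_agp=False,
                         sites=sites, reference_site=sites[0])
    mcmc = MCMCConfig(n_chains=2, n_iterations=400, n_burnin=200, seed=seed)
    s1 = fit_network(df, spec, mcmc)
    s2 = fit_network(df, spec, mcmc)
    same_draws = all(np.array_equal(s1.draws[k], s2.draws[k]) for k in s1.draws)
    return {"identical": float(same_cohort and same_draws),
            "cohort_identical": float(same_cohort),
            "draws_identical": float(same_draws)}
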