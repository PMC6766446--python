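"""Mediation: verdict rules, path products, fever sensitivity."""

import numpy as np
import pandas as pd
import pytest

from eednet.mediation import indirect_effects, sensitivity_fever, total_vs_direct, verdict
from eednet.network import MCMCConfig, NetworkSpec, build_network, fit_network
from eednet.simulate import generate_analytic
from eednet.truth import TruthDAG
from eednet.univariate import fit_univariate_binary
from eednet.validation import path_identity_check

FAST = MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=700, seed=0)


def test_verdict_rules():
    assert verdict(total_sig=True, direct_sig=False, attenuated=True) == "full"
    assert verdict(total_sig=True, direct_sig=True, attenuated=True) == "partial"
    assert verdict(total_sig=True, direct_sig=True, attenuated=False) == "none"
    assert verdict(total_sig=False, direct_sig=False, attenuated=True) == "none"
    assert verdict(total_sig=False, direct_sig=True, attenuated=True) == "none"


def _fitted_layers(beta_direct, beta_leg1=-0.5, beta_leg2=0.6, seed=0, n_per_site=250):
    arcs = [("diet_zinc", "lmz", beta_leg1), ("lmz", "low_retinol", beta_leg2)]
    if beta_direct:
        arcs.append(("diet_zinc", "low_retinol", beta_direct))
    truth = TruthDAG(arcs=arcs,
                     node_families={"lmz": ("linear", None),
                                    "low_retinol": ("logistic", None)})
    sites = [f"S{i}" for i in range(4)]
    df = generate_analytic(truth, n_per_site=n_per_site, sites=sites, seed=seed)
    spec = build_network(diet_vars=["zinc"], eed_nodes=["lmz"],
                         outcome_nodes=["low_retinol"], include_agp=False,
                         sites=sites, reference_site=sites[0])
    summary = fit_network(df, spec, FAST)
    uni = fit_univariate_binary(df, "diet_zinc", "low_retinol", adjust_ln_agp=False)
    uni_table = pd.DataFrame([{
        "exposure": "diet_zinc", "outcome": "low_retinol", "family": "logistic",
        "beta": uni.beta, "ci_low": uni.estimate and np.exp(uni.beta - 1.96 * uni.se),
        "ci_high": np.exp(uni.beta + 1.96 * uni.se), "converged": uni.converged,
    }])
    return df, uni_table, summary


def test_full_mediation_pattern_is_detected():
    _, uni, summary = _fitted_layers(beta_direct=0.0, seed=3)
    table = total_vs_direct(uni, summary)
    row = table.iloc[0]
    assert row["total_significant"] and not row["direct_significant"]
    assert row["verdict"] == "full"
    # the indirect path carries the effect: leg product is negative and significant
    ind = indirect_effects(summary)
    path = ind[(ind["mediator"] == "lmz")].iloc[0]
    assert path["mean"] == pytest.approx(-0.5 * 0.6, abs=0.1)
    assert path["significant"]


def test_null_legs_give_null_indirect_effect():
    _, _, summary = _fitted_layers(beta_direct=0.3, beta_leg1=0.0, beta_leg2=0.0, seed=4)
    ind = indirect_effects(summary)
    path = ind[ind["mediator"] == "lmz"].iloc[0]
    assert path["q2.5"] < 0.0 < path["q97.5"]
    assert abs(path["mean"]) < 0.05


def test_mediation_verdict_is_invariant_to_mediator_sign():
    """Flipping the mediator's sign flips both legs; the product, the direct
    effect and the verdict are unchanged."""
    df, uni, summary = _fitted_layers(beta_direct=0.0, seed=5)
    flipped = df.assign(lmz=-df["lmz"])
    summary_f = fit_network(flipped, summary.spec, FAST)
    t1 = total_vs_direct(uni, summary)
    t2 = total_vs_direct(uni, summary_f)
    assert t1.iloc[0]["verdict"] == t2.iloc[0]["verdict"]
    i1 = indirect_effects(summary)
    i2 = indirect_effects(summary_f)
    p1 = i1[i1["mediator"] == "lmz"]["mean"].iloc[0]
    p2 = i2[i2["mediator"] == "lmz"]["mean"].iloc[0]
    assert p1 == pytest.approx(p2, abs=0.03)


def test_identical_total_and_direct_is_no_mediation():
    """total == direct exactly -> proportion attenuated 0, verdict 'none'."""
    uni = pd.DataFrame([{"exposure": "diet_zinc", "outcome": "low_retinol",
                         "family": "logistic", "beta": 0.4,
                         "ci_low": np.exp(0.2), "ci_high": np.exp(0.6),
                         "converged": True}])
    table = pd.DataFrame([{"child": "low_retinol", "parameter": "diet_zinc",
                           "family": "logistic", "mean": 0.4, "sd": 0.1,
                           "q2.5": 0.2, "q97.5": 0.6, "significant": True,
                           "converged": True, "separated": False, "is_arc": True}])
    spec = NetworkSpec(parents={"low_retinol": ["diet_zinc"]},
                       families={"low_retinol": "logistic"},
                       sites=["A", "B"], reference_site="A")
    from eednet.network import PosteriorSummary

    summary = PosteriorSummary(spec=spec, mcmc=FAST,
                               param_names={"low_retinol": ["diet_zinc"]},
                               draws={"low_retinol": np.full((2, 10, 1), 0.4)},
                               sigma_draws={}, table=table, n=100)
    out = total_vs_direct(uni, summary)
    assert out.iloc[0]["proportion_attenuated"] == pytest.approx(0.0)
    assert out.iloc[0]["verdict"] == "none"


def test_linear_chain_total_equals_direct_plus_indirect():
    res = path_identity_check(seed=0, n_per_site=300, n_sites=3, n_reps=2)
    assert res["max_abs_gap"] < 3 * res["mc_scale"]


# ---------------------------------------------------------------------------
# fever sensitivity
# ---------------------------------------------------------------------------

def _fever_data(fever_tracks_inflammation, seed=0):
    """Outcome driven by latent systemic inflammation; AGP and (optionally)
    fever are two noisy markers of it.  Conditioning on a second marker of the
    same latent splits the inflammation effect, so the AGP arc attenuates."""
    truth = TruthDAG(
        arcs=[("diet_zinc", "lmz", -0.3), ("lmz", "low_retinol", 0.4)],
        node_families={"lmz": ("linear", None), "low_retinol": ("logistic", None)})
    sites = [f"S{i}" for i in range(4)]
    df = generate_analytic(truth, n_per_site=300, sites=sites, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = len(df)
    inflam = rng.standard_normal(n)
    lam = 0.85  # marker reliability
    df["agp"] = lam * inflam + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    eta = 0.7 * inflam - 0.6
    df["low_retinol"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if fever_tracks_inflammation:
        df["fever_prop"] = lam * inflam + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        df["fever_pre_draw"] = (inflam + 0.5 * rng.standard_normal(n) > 1).astype(int)
    else:
        df["fever_prop"] = rng.standard_normal(n)
        df["fever_pre_draw"] = rng.integers(0, 2, n)
    df["fever_post_draw"] = rng.integers(0, 2, n)
    spec = build_network(diet_vars=["zinc"], eed_nodes=["lmz"],
                         outcome_nodes=["low_retinol"],
                         sites=sites, reference_site=sites[0])
    return df, fit_network(df, spec, FAST)


def test_independent_fever_leaves_arcs_unchanged():
    df, summary = _fever_data(fever_tracks_inflammation=False)
    comp, _ = sensitivity_fever(df, summary)
    assert comp.attrs["max_abs_shift"] < 0.12


def test_fever_driven_by_agp_attenuates_agp_arcs_only():
    df, summary = _fever_data(fever_tracks_inflammation=True, seed=2)
    comp, _ = sensitivity_fever(df, summary)
    agp_row = comp[(comp["parameter"] == "agp") & (comp["child"] == "low_retinol")].iloc[0]
    assert abs(agp_row["mean_fever"]) < abs(agp_row["mean_base"])
    others = comp[(comp["parameter"] != "agp")]
    assert others["shift"].abs().max() < 0.12


def test_fever_column_validation():
    df, summary = _fever_data(fever_tracks_inflammation=False, seed=3)
    with pytest.raises(KeyError, match="absent"):
        sensitivity_fever(df.drop(columns=["fever_prop"]), summary)
    degenerate = df.assign(fever_post_draw=0)
    with pytest.warns(UserWarning, match="constant"):
        comp, _ = sensitivity_fever(degenerate, summary)
    assert len(comp)
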