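"""Preprocessing: transform order, references, thresholds, standardization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eednet.preprocess import (
    adjust_hemoglobin_altitude, adjust_inflammation_brinda, classify_deficiency,
    complete_cases, fit_lm_reference, lm_zscores, standardize, summarize_diet,
    summarize_fecal,
)


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def test_density_is_sqrt_of_intake_per_1000_kcal():
    recalls = pd.DataFrame({"energy_kcal": [500.0], "iron_mg": [8.0]})
    ds = summarize_diet(recalls)
    assert ds.densities["iron"] == pytest.approx(4.0)  # sqrt(1000*8/500) = sqrt(16)


def test_sqrt_is_applied_before_averaging():
    # densities 9 and 25 -> mean of (3, 5) = 4, not sqrt(17) = 4.123
    recalls = pd.DataFrame({"energy_kcal": [1000.0, 1000.0], "iron_mg": [9.0, 25.0]})
    ds = summarize_diet(recalls)
    assert ds.densities["iron"] == pytest.approx(4.0)
    assert ds.densities["iron"] != pytest.approx(math.sqrt(17.0))


def test_zero_energy_recalls_are_excluded():
    recalls = pd.DataFrame({"energy_kcal": [0.0, 500.0], "iron_mg": [5.0, 8.0]})
    assert summarize_diet(recalls).n_recalls == 1
    with pytest.raises(ValueError, match="no usable recalls"):
        summarize_diet(pd.DataFrame({"energy_kcal": [0.0], "iron_mg": [1.0]}))


def test_macronutrient_energy_shares_sum_to_100(preprocessed):
    _, prep = preprocessed
    total = (prep.child_summaries[["pct_energy_carb", "pct_energy_protein",
                                   "pct_energy_fat"]].sum(axis=1))
    assert np.allclose(total, 100.0, atol=0.5)


# ---------------------------------------------------------------------------
# fecal biomarkers
# ---------------------------------------------------------------------------

def test_fecal_log_mean():
    e = math.e
    stool = pd.DataFrame({"mpo_ng_ml": [e, e], "neo_nmol_l": [e**2, 1.0],
                          "aat_ug_g": [5.0, np.nan]})
    out = summarize_fecal(stool)
    assert out["mpo"] == pytest.approx(1.0)
    assert out["neo"] == pytest.approx(1.0)          # mean of (2, 0)
    assert out["aat"] == pytest.approx(math.log(5.0))  # single defined sample


def test_nonpositive_concentrations_are_rejected():
    stool = pd.DataFrame({"mpo_ng_ml": [-1.0, math.e],
                          "neo_nmol_l": [1.0, 1.0], "aat_ug_g": [1.0, 1.0]})
    assert summarize_fecal(stool)["mpo"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# lactulose / mannitol reference
# ---------------------------------------------------------------------------

def _reference_tests(rng, n=200, age_slope=0.0, sex_effect=0.0):
    age = rng.choice([9.0, 15.0], n)
    female = rng.integers(0, 2, n).astype(float)
    ln_man = 1.5 + age_slope * (age - 12) + sex_effect * female + 0.5 * rng.standard_normal(n)
    ln_lac = -1.0 + 0.4 * rng.standard_normal(n) + ln_man
    return pd.DataFrame({"age_mo": age, "female": female,
                         "lactulose_pct": np.exp(ln_lac), "mannitol_pct": np.exp(ln_man)})


def test_reference_with_no_age_sex_effect_fits_null_slopes():
    rng = np.random.default_rng(0)
    ref = fit_lm_reference(_reference_tests(rng, n=600))
    assert ref.coef["mannitol"]["age_slope"] == pytest.approx(0.0, abs=0.05)
    assert ref.coef["mannitol"]["sex_effect"] == pytest.approx(0.0, abs=0.15)


def test_reference_recovers_known_slopes():
    rng = np.random.default_rng(1)
    tests = _reference_tests(rng, n=2000, age_slope=0.05, sex_effect=-0.2)
    ref = fit_lm_reference(tests)
    assert ref.coef["mannitol"]["age_slope"] == pytest.approx(0.05, abs=0.02)
    assert ref.coef["mannitol"]["sex_effect"] == pytest.approx(-0.2, abs=0.08)


def test_reference_stratum_self_normalizes():
    rng = np.random.default_rng(2)
    tests = _reference_tests(rng, n=800)
    ref = fit_lm_reference(tests)
    z = lm_zscores(tests, ref)  # all tests of the stratum at once
    # per-test z over the stratum has mean ~0; here all tests in one call
    zs = (np.log(tests["lactulose_pct"]) - ref.predict(
        "lactulose", tests["age_mo"], tests["female"])) / ref.resid_sd["lactulose"]
    assert abs(zs.mean()) < 1e-10
    assert zs.std(ddof=1) == pytest.approx(1.0, abs=0.01)
    assert abs(z["lacz"]) < 1e-10


def test_reference_requires_nondegenerate_design():
    rng = np.random.default_rng(3)
    tests = _reference_tests(rng, n=100)
    tests["age_mo"] = 9.0
    with pytest.raises(ValueError, match="degenerate"):
        fit_lm_reference(tests)
    with pytest.raises(ValueError, match=">= 30"):
        fit_lm_reference(_reference_tests(rng, n=10))


def test_lm_zscores_trivial_cases():
    rng = np.random.default_rng(4)
    ref = fit_lm_reference(_reference_tests(rng, n=400))
    # a test exactly at the reference prediction -> all z = 0
    age, female = 9.0, 1.0
    exact = pd.DataFrame({
        "age_mo": [age], "female": [female],
        "lactulose_pct": [math.exp(ref.predict("lactulose", age, female))],
        "mannitol_pct": [math.exp(ref.predict("mannitol", age, female))],
    })
    z = lm_zscores(exact, ref)
    assert z["lacz"] == pytest.approx(0.0, abs=1e-10)
    assert z["lmz"] == pytest.approx(0.0, abs=1e-10)
    # two tests with ratio z-scores 0.2 and 0.6 -> per-child LMZ 0.4
    two = pd.concat([exact, exact], ignore_index=True)
    two["age_mo"] = [9.0, 15.0]
    for i, target in enumerate((0.2, 0.6)):
        pred = ref.predict("ratio", two.loc[i, "age_mo"], female)
        ln_man = math.log(two.loc[i, "mannitol_pct"])
        two.loc[i, "lactulose_pct"] = math.exp(
            pred + target * ref.resid_sd["ratio"] + ln_man)
    assert lm_zscores(two, ref)["lmz"] == pytest.approx(0.4)
    # a test missing one sugar still contributes the defined scores
    two.loc[1, "mannitol_pct"] = np.nan
    z = lm_zscores(two, ref)
    assert z["manz"] == pytest.approx(0.0, abs=1e-10)  # only test 0 contributes


# ---------------------------------------------------------------------------
# hemoglobin altitude correction
# ---------------------------------------------------------------------------

def test_altitude_zero_leaves_hemoglobin_unchanged():
    assert adjust_hemoglobin_altitude(10.5, 0.0) == pytest.approx(10.5)
    assert adjust_hemoglobin_altitude(10.5, 800.0) == pytest.approx(10.5)


def test_altitude_correction_is_monotone_nonincreasing():
    alts = np.linspace(0, 4500, 200)
    adj = adjust_hemoglobin_altitude(np.full_like(alts, 12.0), alts)
    assert np.all(np.diff(adj) <= 1e-12)


def test_altitude_correction_matches_polynomial():
    # independent evaluation of the correction at 1700 m
    a = 1700 * 3.280839895 / 1000.0
    expected = -0.032 * a + 0.022 * a**2
    assert adjust_hemoglobin_altitude(12.0, 1700.0) == pytest.approx(12.0 - expected)
    with pytest.raises(ValueError, match="negative hemoglobin"):
        adjust_hemoglobin_altitude(-1.0, 0.0)


# ---------------------------------------------------------------------------
# deficiency classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("col,flag,at,past", [
    ("retinol_umol_l", "low_retinol", 0.70, 0.69),
    ("ferritin_ug_l", "low_ferritin", 12.0, 11.9),
    ("zinc_umol_l", "low_zinc", 9.9, 9.8),
    ("hemoglobin_adj_g_dl", "anemia", 11.0, 10.9),
    ("tfr_mg_l", "high_tfr", 8.3, 8.31),
    ("agp_g_l", "elevated_agp", 1.0, 1.01),
])
def test_thresholds_are_strict(col, flag, at, past):
    panel = pd.DataFrame({col: [at, past]})
    flags = classify_deficiency(panel)
    assert flags[flag].iloc[0] == 0  # boundary value: not deficient
    assert flags[flag].iloc[1] == 1


def test_missing_analyte_gives_undefined_flag():
    panel = pd.DataFrame({"retinol_umol_l": [np.nan, 0.5]})
    flags = classify_deficiency(panel)
    assert np.isnan(flags["low_retinol"].iloc[0])
    assert flags["low_retinol"].iloc[1] == 1
    assert np.isnan(flags["low_zinc"]).all()  # column absent entirely


def test_classification_is_monotone_in_each_analyte():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0.2, 1.5, 50))
    flags = classify_deficiency(pd.DataFrame({"retinol_umol_l": x}))["low_retinol"]
    assert np.all(np.diff(flags) <= 0)  # deficiency can only switch off as retinol rises


# ---------------------------------------------------------------------------
# inflammation adjustment (prevalence reporting only)
# ---------------------------------------------------------------------------

def test_brinda_noop_cases():
    rng = np.random.default_rng(0)
    c = np.exp(rng.normal(2.0, 0.5, 300))
    ln_agp = rng.normal(0.0, 0.3, 300)
    ref = float(np.quantile(ln_agp, 0.10))
    # at the reference, unchanged
    adj = adjust_inflammation_brinda(c, np.full(300, ref))
    assert np.allclose(adj, c)
    # independent concentration: slope ~0, adjustment ~none
    adj = adjust_inflammation_brinda(c, ln_agp)
    assert np.allclose(np.log(adj), np.log(c), atol=0.15)
    with pytest.warns(UserWarning, match="skipping"):
        out = adjust_inflammation_brinda(c[:20], ln_agp[:20])
    assert np.allclose(out, c[:20])


def test_brinda_recovers_latent_prevalence_under_distortion():
    """Ferritin simulated with an AGP-dependent distortion: the adjusted
    prevalence of low ferritin is closer to the latent prevalence than the
    unadjusted one."""
    from eednet.config import SimConfig
    from eednet.preprocess import build_analytic
    from eednet.simulate import generate_cohort
    from eednet.truth import default_truth

    cfg = SimConfig(children_per_site=90, seed=21)
    truth = default_truth(cfg.calibration, cfg.sites)
    cohort = generate_cohort(cfg, truth, inflammation_distortion={"ferritin": 0.6})
    prep = build_analytic(cohort, reference_site="BRF")
    latent = (cohort.latents.set_index("child_id")["true_low_ferritin"]
              .reindex(prep.child_summaries["child_id"]).mean())
    prev = prep.prevalence
    w = prev.groupby("provenance").apply(
        lambda g: np.average(g["low_ferritin"], weights=g["n"]), include_groups=False)
    err_unadj = abs(w["unadjusted"] - latent)
    err_adj = abs(w["inflammation_adjusted"] - latent)
    assert err_adj < err_unadj


# ---------------------------------------------------------------------------
# standardization and complete cases
# ---------------------------------------------------------------------------

def test_standardize_closed_form_and_idempotence():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    out, params = standardize(df, ["x"])
    assert np.allclose(out["x"], [-1.0, 0.0, 1.0])  # SD with n-1 is exactly 1
    assert params.loc[0, "sd"] == pytest.approx(1.0)
    twice, _ = standardize(out, ["x"])
    pd.testing.assert_frame_equal(twice, out)
    with pytest.raises(ValueError, match="'x'"):
        standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
def test_standardization_is_affine_invariant(scale, shift):
    x = np.array([0.3, -1.2, 2.4, 0.9, -0.5])
    a, _ = standardize(pd.DataFrame({"x": x}), ["x"])
    b, _ = standardize(pd.DataFrame({"x": scale * x + shift}), ["x"])
    assert np.allclose(a["x"], b["x"], atol=1e-8)


def test_complete_cases_drops_and_logs():
    df = pd.DataFrame({"site": ["A", "A", "B"], "x": [1.0, np.nan, 2.0],
                       "y": [1.0, 1.0, 1.0]})
    kept, log = complete_cases(df, ["x", "y"])
    assert len(kept) == 2
    assert log["by_variable"] == {"x": 1}
    assert log["by_site"] == {"A": 1}
    full, log2 = complete_cases(df[["site", "y"]], ["y"])
    assert len(full) == 3 and log2["by_variable"] == {}
    with pytest.raises(KeyError):
        complete_cases(df, ["absent"])
    with pytest.raises(ValueError, match="every child"):
        complete_cases(df.assign(x=np.nan), ["x"])
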