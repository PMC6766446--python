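# Methods

## Scientific setting

`eednet` models how the nutrient density of complementary foods relates to
micronutrient status at 15 months in multi-site birth cohorts of children
living with high enteropathogen exposure, with environmental enteric
dysfunction (EED) as the hypothesized mediating layer.  The observables are:

* **Diet** — monthly quantitative 24-h recalls from 9 to 15 mo: energy from
  non-breast-milk foods and intakes of iron, zinc, calcium, vitamin A, B6,
  folate, B12, vitamin C and protein.  Analyses use *densities* (intake per
  1000 kcal), square-root transformed and averaged over recalls.
* **Gut function** — fecal myeloperoxidase (MPO, ng/mL), neopterin (NEO,
  nmol/L) and α-1-antitrypsin (AAT, μg/g) from non-diarrheal stools
  (log-transformed, then averaged per child), and the dual-sugar
  lactulose:mannitol (LM) urine test at 9 and 15 mo, expressed as age- and
  sex-referenced z-scores (%Lac-Z, %Man-Z and the ratio z-score LMZ).
* **Systemic inflammation** — plasma α-1-acid glycoprotein (AGP, g/L) at
  15 mo, elevated when > 1 g/L; analyzed as standardized ln AGP.
* **Micronutrient status at 15 mo** — binary flags with strict thresholds:
  anemia (altitude-adjusted hemoglobin < 11.0 g/dL), low retinol
  (< 0.70 μmol/L), low ferritin (< 12 μg/L), elevated transferrin receptor
  (TfR > 8.3 mg/L), low plasma zinc (< 9.9 μmol/L).

## The joint model

The core estimator is a Bayesian network expressed as conditionally
independent generalized linear regressions over a fixed, layered DAG:

    diet densities  →  {MPO, NEO, AAT, LMZ, AGP}  →  deficiency outcomes,

plus direct diet → outcome arcs, AGP → outcome arcs, and arcs from the four
deficiency outcomes into anemia.  Gut-function and AGP nodes are Gaussian
regressions; outcome nodes are Bernoulli-logit regressions.  Every non-root
node carries an intercept and site dummy variables (reference site omitted),
so all associations are within-site.  Because every parent is observed, the
joint posterior factorizes and each node is sampled independently — the
package asserts this draw-for-draw (a node's posterior is identical whether
fitted alone or with the rest of the network).

Continuous variables are standardized (mean 0, SD 1, denominator n−1) over
the pooled complete-case sample, so linear-node coefficients are mean effects
per 1 SD and logistic-node coefficients exponentiate to odds ratios per 1 SD.
An arc is reported *significant* when its equal-tailed 95% credibility
interval excludes the null; no multiplicity adjustment is applied.

The default diet set in the network is iron, zinc, calcium, vitamin A, B6,
B12 and protein; folate and vitamin C are excluded (screened out upstream:
no univariate signal, and folate is collinear with B6/B12).

### Priors and samplers

* Coefficients (including site dummies and intercepts): Normal(0, 10²) on
  the standardized scale — weakly informative for effects measured in SD
  units.
* Linear-node residual SD: Half-Cauchy(1), implemented through its
  inverse-gamma scale-mixture representation so the Gibbs sampler stays fully
  conjugate.  An InverseGamma(a₀, b₀) option on the variance (with the
  coefficient prior scaled by σ², i.e. the normal-inverse-gamma family) is
  provided because that variant has an exact closed-form posterior, used as
  the sampler's oracle in tests.
* Logistic nodes: Gibbs with Pólya-Gamma data augmentation.  The exact
  PG(1, z) alternating-series rejection sampler (truncated inverse-Gaussian /
  truncated exponential proposal mixture) is implemented in numba; its means
  match E[PG(1, z)] = tanh(z/2)/(2z) and the full conditional for the
  coefficients is a conjugate Gaussian update.
* Defaults: 4 chains × 5000 iterations, 2500 burn-in, thin 1, overdispersed
  initial values (β⁰ ~ N(0, 2²)).  Convergence gate: split-R̂ ≤ 1.01 and
  bulk ESS ≥ 400 per parameter (computed with arviz); parameters failing the
  gate, and logistic nodes with |posterior mean| > 10 on the log-odds scale
  (quasi-separation), are flagged and excluded from the significant-arc set
  with a warning.  Simulation studies in the test-suite and acceptance script
  use 2 chains × 1200 iterations per fit to fit many replicates on desk
  hardware; the oracle checks show the shorter chains are amply converged for
  these node sizes.

Chains are seeded from (seed, node, chain) substreams of a single
`SeedSequence`, making every posterior reproducible draw-for-draw.

## Screening layer

Univariate screens use mixed models with a site random intercept:

* binary outcomes: `outcome ~ exposure + ln AGP + (1 | site)` by maximum
  likelihood with adaptive Gauss-Hermite quadrature (25 nodes, per-site mode
  and curvature), Wald 95% CIs from the numerical Hessian.  The fit matches
  `lme4::glmer(..., nAGQ=25)` to ≈10⁻³ and reduces exactly to ordinary
  logistic ML when there is a single site or the random-intercept variance
  collapses to zero.
* continuous biomarkers: `biomarker ~ exposure + (1 | site)` via REML
  (statsmodels MixedLM).  These screens do not adjust for AGP — AGP is
  itself one of the screened responses.
* biomarker correlations: Spearman ρ within site, averaged over sites, with
  a percentile bootstrap over children within site (1000 resamples) for the
  95% CI.

## Mediation

The total-vs-direct comparison takes the *total* effect from the AGP-adjusted
univariate screen and the *direct* effect from the network (conditioning on
MPO, NEO, AAT and LMZ).  The qualitative verdict is "full" when the total CI
excludes the null but the direct CrI does not, "partial" when both exclude
the null with |direct| < |total|, and "none" otherwise.  Because
"significance disappears" is not by itself an estimand, the package also
reports a labelled product-of-coefficients estimator: for each
diet → mediator → outcome path the per-draw product of the two legs (nodes
are posterior-independent, so index-paired draws are joint-posterior draws),
and the per-draw sum over mediators as the total indirect effect.  On the
log-odds scale the identity total = direct + indirect holds only
approximately (non-collapsibility of odds ratios); the identity is asserted
exactly (to Monte-Carlo error) on all-linear chains only.

The fever sensitivity refit adds three covariates (proportion of days with
fever 9–15 mo; fever within 7 d before/after the blood draw) to every
outcome node and reports arc-by-arc coefficient shifts.

## Preprocessing decisions

* **Transform order is fixed**: sqrt (diet) and ln (biomarkers) are applied
  per observation *before* averaging; the non-commutativity is pinned by a
  worked example (per-recall densities 9 and 25 average to 4, not √17).
* **LM reference**: rather than an external normative standard, the
  reference is fitted internally on a designated reference stratum (default:
  the Fortaleza-like site, whose sugar z-scores are centered near zero),
  regressing ln % recovery on age and sex for lactulose, mannitol and the
  ln ratio, and storing residual SDs.  Per-test z-scores use
  (ln observed − prediction)/residual SD; the per-child value is the mean
  over available tests.  LMZ is defined as the z of ln(L:M); the alternative
  (difference of the two sugar z-scores) is equivalent only when the two
  residual SDs are equal, and is not used.
* **Altitude**: hemoglobin is corrected by the polynomial
  −0.032·a + 0.022·a² g/dL (a = altitude in thousands of feet), applied when
  a > 3 and clipped at zero; site altitudes live in the calibration file.
* **Inflammation adjustment (prevalence reporting only)**: each plasma
  analyte's ln concentration is regressed on ln AGP over the analytic sample;
  observations above the low-inflammation reference (lowest-decile ln AGP)
  are corrected by subtracting β̂·(ln AGP − ref).  CRP is not part of this
  data model, so the correction uses the single measured covariate.  The
  network always consumes unadjusted values with AGP as an explicit node —
  the prevalence table carries a provenance column to keep the two uses
  separate.
* **Complete cases**: children missing any required model variable are
  dropped, with exclusions logged by site and by variable; no imputation.
  Minimum data per child: ≥1 recall, ≥1 stool sample, ≥1 LM test
  (configurable).

## The synthetic cohort generator

Generation is *latent-first*: each child's standardized analytic variables
are drawn directly from the ground-truth DAG (so true coefficients are in
exactly the units the estimators report), then observables are produced by
inverting the preprocessing transforms with site-level shifts and
month-to-month noise:

* Latent diet densities are exchangeably correlated (ρ = 0.3) standard
  normals; gut-function/AGP latents follow the truth's linear equations with
  residual SDs chosen so pooled variance ≈ 1; outcomes are
  Bernoulli(logit⁻¹(site intercept + Σβ·centered parents)).
* Observables: monthly sqrt-densities, ln-biomarker assay values and LM
  recoveries are the latent value mapped through per-variable location/scale
  calibration plus independent month noise; concentrations for the blood
  panel are drawn from site-calibrated lognormals truncated to agree with
  the latent deficiency flag, and hemoglobin is shifted up by the altitude
  correction at high-altitude sites so the preprocessing has to undo it.
* Site calibration constants (per-site ln-biomarker means, sugar-score
  means, density medians, energy, blood-analyte medians, AGP, deficiency
  prevalence targets, altitudes) are shipped in
  `eednet/data/site_calibration.yaml`, emulating the magnitudes of a
  seven-site study of this design; they are synthetic calibration values,
  not measurements.  Within-child month-to-month variance components are not
  observable from published site summaries; the defaults (e.g. ln-MPO month
  SD 0.60) are chosen so that per-child means retain r ≥ 0.9 with the latent
  and are labelled as such in the calibration file.
* Randomness is split into per-child substreams keyed by (seed, site, child
  counter), so cohorts are reproducible independent of iteration order.
* An optional inflammation distortion multiplies a blood analyte by
  exp(γ·(AGP z + 1.28)) — anchored at the low-inflammation decile — while
  leaving the latent flag untouched, to exercise the regression-correction.

The fast path `generate_analytic` emits the latent analytic matrix directly
(no measurement layer) and is what the simulation studies use, since there
the estimand must not be attenuated by measurement noise.

What the generator does **not** emulate: enteropathogen detections,
breast-milk intake and composition, anthropometry, diarrheal episodes,
informative (site-biased) missingness, assay batch effects, or within-child
trends over age (months are exchangeable around the child's latent mean).
Passing tests therefore demonstrate estimator correctness under the stated
generative model, not robustness to those real-data features.

## Validation studies (tests and the acceptance script)

* **Conjugate oracle** — a single linear node at n = 20 under the NIG prior:
  every coefficient's posterior mean and SD within 2 Monte-Carlo SEs of the
  closed form (SD errors use a fourth-moment delta method, since the marginal
  posterior is a t).
* **Logistic oracle** — one node at n = 5000, β = 0.5: posterior mean within
  0.05 of the ML estimate.
* **Coverage** — a reduced layered truth (3 diet nodes, MPO + LMZ + AGP, two
  outcomes with an outcome → anemia-style arc) with coefficients in
  {0, 0.1, 0.2, ln 1.25}, 7 sites × 200 children, 50 replicates: 95% CrIs
  cover the truth in 93–97% of arc × replicate trials per arc family, and
  null arcs are flagged significant in 5% ± 2%.
* **Mediation** — diet → LMZ → outcome with no direct arc at n = 1400:
  "full" verdict in ≥ 80% of 50 replicates; under an all-null truth ≤ 7%.
* **Path identity** — all-linear chain: |total − (direct + Σ indirect)|
  within 3× the Monte-Carlo scale, every replicate.
* **Round trip** — calibrated cohort (7 × 80 children): every analytic
  variable correlates ≥ 0.9 with its generating latent; standardized columns
  are mean-0/SD-1 to 10⁻⁸; deficiency flags are recovered exactly.
* **Thresholds, determinism** — strict-boundary classification and
  byte-identical rerun behavior.

Replicate counts and per-fit chain lengths are the package's desk-scale
choices; all studies accept larger values through their arguments.

## Known limitations

* The DAG is fixed a priori; no structure learning, no latent-variable or
  measurement-error modelling of the biomarkers.
* Associational semantics: adjustment is limited to site, AGP and the
  modelled parents; the mediation verdicts inherit the usual caveats of
  total-vs-direct comparisons for non-collapsible odds ratios.
* The internal LM reference makes z-scores relative to the chosen reference
  stratum, not to an external healthy-population standard; site contrasts are
  unaffected, absolute z levels shift with the stratum choice.
* The inflammation regression-correction uses AGP only (one acute-phase
  protein, one time point).
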