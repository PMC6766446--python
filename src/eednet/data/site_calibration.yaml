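# Default calibration for the synthetic multi-site cohort generator.
#
# Site-level location targets emulate the magnitudes observed across seven
# field sites of a multi-country birth-cohort study of complementary feeding,
# gut function and micronutrient status (Dhaka/BGD, Vellore/INV,
# Bhaktapur/NEB, Naushero Feroze/PKN, Fortaleza/BRF, Loreto/PEL, Haydom/TZH).
# All constants are synthetic-calibration values, not measurements.
#
# Scales:
#   fecal biomarkers      -> natural-log scale (ln ng/mL, ln nmol/L, ln ug/g)
#   urinary sugar scores  -> z-score scale against the reference stratum
#   nutrient densities    -> median intake per 1000 kcal (natural units)
#   blood analytes        -> medians in conventional units; hemoglobin g/dL
#   prevalences           -> proportions in [0, 1]

sites: [BGD, INV, NEB, PKN, BRF, PEL, TZH]
reference_site: BRF          # stratum used to fit the lactulose/mannitol reference
altitude_m: {BGD: 0, INV: 0, NEB: 1400, PKN: 0, BRF: 0, PEL: 0, TZH: 1700}

children_per_site: {BGD: 187, INV: 220, NEB: 209, PKN: 207, BRF: 133, PEL: 196, TZH: 129}

# --- gut-function biomarkers: site means on the transformed scale -----------
ln_mpo_mean:  {BGD: 8.5,  INV: 8.8,  NEB: 8.5,   PKN: 8.1,  BRF: 8.0,   PEL: 8.8,   TZH: 8.2}
ln_neo_mean:  {BGD: 6.8,  INV: 7.5,  NEB: 7.6,   PKN: 6.3,  BRF: 7.4,   PEL: 7.9,   TZH: 6.5}
ln_aat_mean:  {BGD: -1.0, INV: -1.1, NEB: -0.93, PKN: -2.0, BRF: -1.4,  PEL: -0.84, TZH: -1.4}
lacz_mean:    {BGD: 1.5,  INV: 2.3,  NEB: 0.81,  PKN: 1.1,  BRF: 0.047, PEL: 1.5,   TZH: 0.092}
manz_mean:    {BGD: 0.87, INV: 1.2,  NEB: 0.66,  PKN: 0.35, BRF: 0.016, PEL: 0.23,  TZH: -0.19}
lmz_mean:     {BGD: 0.29, INV: 0.84, NEB: 0.062, PKN: 0.68, BRF: 0.039, PEL: 1.0,   TZH: 0.39}

# within-site SD of the per-child mean, transformed scale
within_sd: {ln_mpo: 0.85, ln_neo: 0.70, ln_aat: 0.70, lacz: 0.90, manz: 0.85, lmz: 0.80}

# --- blood panel at 15 mo ----------------------------------------------------
hb_mean:         {BGD: 11.0, INV: 11.0, NEB: 11.0, PKN: 9.3,  BRF: 11.0, PEL: 11.0, TZH: 11.0}
hb_sd:           {BGD: 1.5,  INV: 1.3,  NEB: 1.2,  PKN: 1.4,  BRF: 2.2,  PEL: 1.2,  TZH: 1.2}
retinol_median:  {BGD: 0.95, INV: 1.10, NEB: 1.06, PKN: 0.75, BRF: 1.23, PEL: 0.87, TZH: 0.66}   # umol/L
ferritin_median: {BGD: 12.7, INV: 10.5, NEB: 10.2, PKN: 9.2,  BRF: 15.1, PEL: 17.1, TZH: 10.8}   # ug/L
tfr_median:      {BGD: 7.2,  INV: 4.9,  NEB: 9.5,  PKN: 7.0,  BRF: 9.9,  PEL: 7.4,  TZH: 5.1}    # mg/L
zinc_median:     {BGD: 11.5, INV: 9.2,  NEB: 12.3, PKN: 8.5,  BRF: 14.9, PEL: 17.0, TZH: 11.6}   # umol/L
agp_mean:        {BGD: 0.96, INV: 0.99, NEB: 1.20, PKN: 0.98, BRF: 1.10, PEL: 1.20, TZH: 1.20}   # g/L

# ln-scale SDs for the skewed plasma analytes; AGP ln-scale SD
ln_sd: {retinol: 0.30, ferritin: 0.80, tfr: 0.45, zinc: 0.25, agp: 0.33}

# target marginal deficiency prevalences (used to set per-site logit intercepts)
prevalence:
  anemia:       {BGD: 0.55, INV: 0.52, NEB: 0.50, PKN: 0.88, BRF: 0.40, PEL: 0.48, TZH: 0.55}
  low_ferritin: {BGD: 0.51, INV: 0.51, NEB: 0.51, PKN: 0.82, BRF: 0.51, PEL: 0.51, TZH: 0.51}
  high_tfr:     {BGD: 0.30, INV: 0.15, NEB: 0.55, PKN: 0.30, BRF: 0.72, PEL: 0.32, TZH: 0.11}
  low_retinol:  {BGD: 0.20, INV: 0.12, NEB: 0.14, PKN: 0.45, BRF: 0.06, PEL: 0.30, TZH: 0.61}
  low_zinc:     {BGD: 0.25, INV: 0.73, NEB: 0.20, PKN: 0.65, BRF: 0.02, PEL: 0.05, TZH: 0.22}

# --- complementary-food intake ----------------------------------------------
energy_kcal_mean: {BGD: 240, INV: 580, NEB: 300, PKN: 460, BRF: 880, PEL: 510, TZH: 850}
energy_kcal_sd:   {BGD: 120, INV: 250, NEB: 130, PKN: 230, BRF: 270, PEL: 180, TZH: 220}
carb_pct_energy:  {BGD: 64, INV: 61, NEB: 58, PKN: 53, BRF: 53, PEL: 70, TZH: 65}
protein_pct_energy: {BGD: 12, INV: 11, NEB: 11, PKN: 11, BRF: 17, PEL: 11, TZH: 12}

# median nutrient density per 1000 kcal, by site
density_median:
  iron:        {BGD: 4.1,  INV: 3.4,  NEB: 3.6,  PKN: 3.3,  BRF: 14.0,  PEL: 5.9,  TZH: 7.7}   # mg
  zinc:        {BGD: 3.5,  INV: 4.0,  NEB: 3.5,  PKN: 3.3,  BRF: 9.2,   PEL: 3.1,  TZH: 5.5}   # mg
  calcium:     {BGD: 320,  INV: 440,  NEB: 330,  PKN: 550,  BRF: 1100,  PEL: 360,  TZH: 490}   # mg
  vitamin_a:   {BGD: 190,  INV: 230,  NEB: 210,  PKN: 250,  BRF: 1100,  PEL: 430,  TZH: 170}   # ug
  vitamin_b6:  {BGD: 0.8,  INV: 0.4,  NEB: 0.6,  PKN: 0.7,  BRF: 1.2,   PEL: 0.5,  TZH: 0.1}   # ug
  folate:      {BGD: 110,  INV: 120,  NEB: 120,  PKN: 95,   BRF: 180,   PEL: 93,   TZH: 69}    # ug
  vitamin_b12: {BGD: 1.5,  INV: 0.7,  NEB: 1.3,  PKN: 1.5,  BRF: 5.1,   PEL: 1.7,  TZH: 1.7}   # ug
  vitamin_c:   {BGD: 36,   INV: 13,   NEB: 19,   PKN: 19,   BRF: 120,   PEL: 110,  TZH: 5.4}   # mg
  protein:     {BGD: 30,   INV: 27.5, NEB: 27.5, PKN: 27.5, BRF: 42.5,  PEL: 27.5, TZH: 30}    # g

# within-site SD of sqrt-density, as a fraction of the pooled mean sqrt-density
sqrt_density_cv: 0.18
diet_correlation: 0.3        # exchangeable correlation among latent nutrient densities

# fever: median proportion of surveillance days with fever, 9-15 mo
fever_prop: {BGD: 0.066, INV: 0.056, NEB: 0.047, PKN: 0.108, BRF: 0.005, PEL: 0.042, TZH: 0.019}
fever_near_draw_rate: 0.15   # probability of fever <7 d before / after the blood draw

# --- lactulose/mannitol reference model (reference stratum truth) -----------
# ln % urinary recovery = intercept + age_slope * (age_mo - 12) + sex_effect * female
lm_reference:
  ln_mannitol: {intercept: 1.60, age_slope: 0.03,  sex_effect: -0.05, resid_sd: 0.70}
  ln_ratio:    {intercept: -2.80, age_slope: -0.02, sex_effect: 0.00,  resid_sd: 0.60}

# --- repeated-measure (month-to-month) noise SDs, transformed scale ---------
# Not observed in field summaries; synthetic defaults chosen so that per-child
# means over the scheduled visits retain >= 0.9 correlation with the latent.
month_noise: {ln_mpo: 0.60, ln_neo: 0.50, ln_aat: 0.55, sqrt_density_frac: 0.50,
              lm_test: 0.50, energy_frac: 0.25}
agp_assay_noise: 0.10

breastfed_prop_alpha: 12     # Beta(alpha, 1) proportion of days breastfed
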