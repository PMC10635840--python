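# Methods

## Background and scope

Exhaled breath carries hundreds of volatile organic compounds (VOCs)
whose joint pattern reflects airway and systemic metabolism.  An
electronic nose (eNose) measures this pattern with a small array of
cross-reactive metal-oxide semiconductor sensors: no individual
compound is identified, but the joint sensor response ("breathprint")
can discriminate disease states.  This package implements, end to end,
the analysis used in prospective eNose studies of COPD and lung cancer:

1. a forward simulator of the breath maneuver and the paired
   exhaled/ambient 7-sensor arrays, producing cohorts with known ground
   truth;
2. signal processing from raw traces to a 13-dimensional breathprint;
3. the statistical core — correlation PCA with Kaiser retention,
   t-test + bootstrap component selection, a two-class Fisher linear
   discriminant with leave-one-out cross-validation (LOOCV), ROC/AUC
   with a DeLong 95% CI, and diagnostic likelihood ratios;
4. cohort-level drivers for the case-control contrast (COPD vs lung
   cancer), the prospective contrast (incident lung cancer within two
   years among baseline COPD), comorbidity/stage subset analyses, and a
   confounder regression.

No clinical recordings ship with the package; every analysis runs on
synthetic cohorts whose group sizes mirror the study population
(682 COPD, of whom 37 develop lung cancer within two years, and
211 lung cancer; duplicate measurements per subject).

## Breath maneuver and sensor model

The simulated maneuver is the clinical protocol: five tidal breaths,
an inspiratory capacity maneuver to total lung capacity, a 5-s breath
hold, then a slow expiration with flow < 0.4 L/s.  Defaults: 4-s tidal
period, 2.5-s inspiration, 10-s expiration at 0.35 L/s, sampled at
10 Hz (the protocol specifies no sample rate or signal units; both are
artifact choices and configurable).

Each subject's VOC mixture is reduced to three nonnegative latent
components — COPD-associated, cancer-associated, and shared/ambient —
with between-subject SD 0.25 and small within-subject replicate jitter
(SD 0.05).  Sensor `s` responds as

    exhaled_s(t) = b_s · (1 + (S v)_s · g(t)) + r·t + ε(t)
    ambient_s(t) = b_s + r·t + ε'(t)

where `b_s` is the baseline level, `S` the 7×3 sensitivity matrix,
`v` the latent vector, `r` a linear drift common to both arrays
(default 0.01 units/s), ε white noise (SD 0.05), and `g(t) ∈ [0,1]` a
smooth maneuver-locked response kernel: zero during tidal breathing,
rising through inspiration, flattening to a 0.55 plateau by the end of
the breath hold, peaking at 1 early in the slow expiration, then
relaxing.  The plateau and peak are the two landmarks the feature
extraction reads; both are analytically known, which the oracle tests
exploit.

### Class structure and calibration

Class separation enters only through the latent means, scaled by a
single knob `effect_size` (in units of the latent SD):

* cancer subjects: the cancer-associated component is shifted by
  `effect_size · 0.25 · stage_factor`, with stage factors
  I 0.5, II 0.75, III 1.25, IV 1.5 (a steep tumour-burden gradient, so
  the early-vs-advanced contrast remains detectable in a 37-subject
  group);
* double-diagnosis subjects (cancer + comorbid COPD, 55% of the cancer
  group) receive only 75% of the shift — intermediate breathprints, so
  excluding them sharpens the contrast;
* non-comorbid cancer subjects additionally lack part of the
  obstructive-airway signature (COPD component lowered, again scaled
  with `effect_size`);
* incident-cancer COPD subjects carry the same stage-scaled cancer
  shift at baseline.

Every between-class difference is proportional to `effect_size`, so
`effect_size = 0` yields a fully exchangeable null cohort — the basis
of the null-calibration tests.  The default `effect_size = 2.0` was
chosen once so that the default cohort reproduces separations of the
magnitude reported for real breathprint data (case-control AUC around
0.86–0.90, prospective AUC around 0.9); it is an emulation target, not
a fit to any particular dataset.

Covariates (age, sex, BMI, smoking status, pack-years, FEV1 %pred,
GOLD stage, histology, stage) are drawn from normal/categorical/
lognormal distributions parameterised to the reported baseline tables.
By default they do not influence the sensor signal
(`covariate_leakage = 0`), so the confounder regression is null by
construction; a leakage term exists for power studies.

## Signal processing

Per channel: (1) least-squares linear detrend with the mean level
re-added (a pure ramp collapses to its midpoint value); (2) 0.5-s
moving-average low-pass (wide enough to suppress sensor noise, an
order of magnitude narrower than the ~3.5-s response peak, so peak
location shifts by at most a couple of samples); (3) ambient
correction, by default common-mode subtraction
`exhaled − (ambient − median(ambient))`, with a guarded ratio mode as
an alternative; (4) landmark detection: the peak P is the maximum over
the expiration window and the breath-hold value B is the last sample
of the hold segment.  When phase labels are unavailable, P is the
global maximum and B the flattest point (minimum smoothed
derivative-magnitude) in the 5 s preceding the peak.

Quality control: a channel fails when its peak does not clear the
baseline median by 5 robust noise SDs, where noise is estimated from
successive differences in the tidal window (differencing removes the
local trend that whole-trace detrending leaves there).  A flat channel
therefore fails QC rather than raising.

Features per measurement: `P_s / P_2` for the six non-reference
sensors (sensor 2 is the designated stable reference; its own ratio is
identically 1 and dropped) plus `P_s / B_s` for all seven sensors — 13
values, invariant to rescaling the whole recording.  Duplicate
measurements are averaged element-wise; a relative difference > 20% on
any feature flags the pair as discordant (advisory), one failed
replicate falls back to the other (flagged), two failed replicates
exclude the subject.  An `include_raw_peaks`-style raw-peak channel is
deliberately not part of the feature vector; the 13 ratio features are
the documented surface.

## Statistics

* **PCA** is computed on the correlation matrix (features are ratio
  scales of different magnitudes; the Kaiser rule presumes
  unit-variance inputs), standardised with training-set means/SDs
  only, and applied frozen to held-out subjects.  Components with
  eigenvalue > 1 are retained, floored at one.  Loading signs are fixed
  by making the largest-magnitude element positive.
* **Selection**: Student's pooled-variance two-sample t-test per
  retained component, selected at p < .05 (no multiplicity correction,
  matching the stated procedure; a Bonferroni toggle exists).  A
  zero-variance group falls back to Welch.  Selection is validated by
  1,000 bootstrap resamples within groups; the reported support is the
  fraction of resamples with p < .05.  Note the support approximates
  the test level only when the observed t is 0; for null data in
  general it is inflated (~0.17 on average), because the bootstrap
  recentres at the observed statistic.
* **Discriminant**: two-class Fisher rule with equal priors,
  `w = S_pooled⁻¹(μ₁ − μ₀)`, boundary at the midpoint of the projected
  class means; a singular pooled covariance receives a small logged
  ridge.  LOOCV refits the discriminant per fold while keeping the PCA
  and the component selection fixed from the full set, mirroring the
  study sequence (PCA first, selection, then cross-validated
  discriminant); this is a documented optimism source, and a
  `selection_inside_folds` toggle repeats the selection within every
  fold instead.
* **ROC/AUC**: empirical ROC over the LOOCV held-out discriminant
  scores; AUC is the Mann–Whitney concordance probability (ties ½),
  with a DeLong 95% CI by default and a seeded 2,000-rep stratified
  bootstrap as an alternative.  Diagnostic sensitivity/specificity and
  LR+ = sens/(1−spec), LR− = (1−sens)/spec are reported both at the
  default midpoint boundary and at the Youden-optimal point of the
  LOOCV ROC; the procedure behind the published operating point is not
  specified, so neither is labelled canonical.  LRs are computed from
  unrounded sensitivity/specificity; public dicts round percentages to
  integers and LRs to two decimals.
* **Confounder regression**: per-component OLS (statsmodels) on age,
  sex, BMI, smoking status, pack-years and FEV1 %pred; complete-case,
  dummy-coded, with aliased columns dropped and reported.

## Pipeline design

The 2:1 train/validation split is stratified by diagnosis group
(guaranteeing both classes in both sets at small simulated sizes) and
deterministic under its seed; at the study sizes it realises exactly
596/297.  Validation subjects never influence standardisation,
loadings, selection or weights — asserted by a test that permutes
validation rows and checks the trained model bit-identical.  The
combined-set analysis refits a fresh PCA on all subjects.  The
prospective analysis is restricted to COPD subjects with the 2-year
incident flag as outcome, and additionally applies the frozen
case-control model to all COPD baseline measurements, counting
incident cases already classified as cancer (the baseline screen).
For calibration/null runs, `fallback_all_retained` fits the
discriminant on all Kaiser-retained components when no component
passes selection, so a validation AUC exists for every seed; the
no-discriminating-component status is still reported.

All randomness flows from explicit integer seeds; reports are
versioned JSON with SHA-256 digests of their inputs, and identical
inputs reproduce identical bytes.

## What the simulation does and does not show

The generator reproduces the *structure* of the measurement (maneuver
phases, paired arrays, duplicate measurements, drift, replicate noise,
class geometry including comorbidity and stage) but none of the
physics or chemistry of metal-oxide sensing: no temperature/humidity
kinetics, no compound-specific adsorption, no inter-device variation,
no real VOC chemistry.  Passing tests therefore demonstrate that the
*analysis chain* is correct, calibrated under the null, and able to
recover planted effects of realistic magnitude — not that any
particular clinical accuracy would be attained on real patients.
Cohort-specific published values are used only as emulation targets
for the generator's defaults.

Problem sizes used by the test suite and the acceptance script: the
study-sized cohort (893 subjects, 1,786 recordings) for single-run
analyses; 20 seeds at effect 0 and 10 seeds per point of the effect
grid {0, 0.5, 1, 1.5, 2} for calibration and recovery; smaller cohorts
(~120–160 subjects) for structural unit tests.

## Known limitations

* The proprietary detrending/filtering of the clinical device is not
  public; the linear-detrend + moving-average choice here is an
  artifact of this package.
* The breath-hold landmark without phase labels relies on a
  flattest-point heuristic and is validated only on simulated shapes.
* LOOCV after full-set selection is optimistic; the per-fold toggle
  quantifies but does not remove this (PCA itself is still fit once).
* The DeLong CI is asymptotic; for the 37-subject stage contrast the
  bootstrap CI option is more appropriate.
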