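# Methods

## Behaviour compositions and the ILR transform

A participant's waking day is summarised as average daily minutes of
sitting, standing and stepping; the three parts sum to waking wear time.
All compositional operations use the closure constant equal to that sum
(waking time), not 1440 min, because reallocations are defined within the
time the monitor observed the participant awake.

ILR coordinates are built from a sequential binary partition (SBP): a
balance separating a group of r parts from a group of s parts gets
log-contrast coefficients `+sqrt(s/(r(r+s)))` and `-sqrt(r/(s(r+s)))`.
The default SBP is the pivot partition in part order (sit, stand, step):
first sit vs {stand, step}, then stand vs step. Any valid SBP gives the
same reallocation predictions (coordinates differ only by rotation), so
the default is purely a reproducibility convention; `build_ilr_basis`
accepts any SBP and verifies orthonormality, which certifies the partition
is well formed.

Zero behaviour minutes make log-ratios undefined. The transform refuses
zeros with an explicit error; `multiplicative_zero_replacement` (default
δ = 1 min, total-preserving) is available when a dataset needs recoding.
It is not applied silently because a replacement policy is a modelling
decision the analyst should make knowingly.

`mean_composition` defaults to the geometric mean closed to the mean
waking total — the compositional convention — with the arithmetic mean
available because descriptive tables report arithmetic means and
reconstructions from published tables must use them.

## The two substitution models

Both models use OLS on a standardised outcome with covariates age, sex
(binary), ethnicity (reference-coded, White European reference), IMD
deprivation score (linear), blood-pressure medication and lipid-lowering
medication. Behaviours are expressed in hours so coefficients read as
per-hour effects. The outcome is z-scored within each analysis sample
(rows complete for that outcome, the behaviours and the covariates).

*ISM*: design columns {1, wear_h, stand_h, step_h, covariates}. Sitting is
the omitted behaviour, so the stand/step coefficients are substitution
effects per hour of sitting. A t-minute estimate is the coefficient scaled
by t/60; reverse-direction estimates are sign negations. Both identities
are algebraically exact, which the test suite asserts at 1e-12.

*CISM*: design columns {1, z1, z2, covariates}. A reallocation estimate at
base composition x0 is `gamma · (ilr(reallocate(x0)) - ilr(x0))`. The 95%
CI uses the delta method for a linear combination of coefficients,
`estimate ± 1.96 · sqrt(dz' Sigma_gamma dz)`, with the normal critical
value: at cohort sizes in the hundreds and above the t-correction is
negligible (coefficient covariance itself uses the n−p OLS estimator).
The published analyses this mirrors do not state their CI construction;
the delta method is the standard choice for this quantity and a
participant-resampling bootstrap (`cism_reallocation_bootstrap`) exists
for sensitivity analysis. No multiple-testing adjustment is applied; α is
reported per test.

The incremental grid derives all 5–60-minute estimates from a single fit
per method, since coefficients do not depend on the reallocated minutes
(ISM scales; CISM re-perturbs the base composition). A literal
one-model-per-increment mode (`refit_per_increment`) exists and reproduces
identical numbers, as a test asserts.

## Wear-day screening

A monitored day is valid when wear ≥ 600 min (10 h), step events ≥ 500
(an event is a two-step stride, so 500 events ≈ 1000 steps), and no single
behaviour exceeds 95% of wear time. Thresholds are closed bounds (exactly
600 min passes); the dominance denominator is wear time by default with
the behaviour-sum alternative available, since upstream summaries may
leave small gaps between behaviours and wear (a 1-min tolerance is
accepted). Participants need ≥ 4 valid days; their behaviour profile is
the arithmetic mean over valid days.

## Risk scores

CCRS is the mean of sample z-scores of HbA1c, triglycerides, mean cuff
blood pressure ((SBP+DBP)/2), inverted HDL and — in the adiposity
variant — waist circumference; higher is worse. Standardisation uses the
pooled included sample with the n−1 denominator. Missing components are
handled available-case (rowwise mean of observed z-scores), with a
complete-case switch; a row with no observed components gets a missing
score. The two variants satisfy `ccrs = (4·ccrs_no_adiposity + z_waist)/5`
on complete rows, which is tested.

## Synthetic cohort generator

The generator emulates the pooled cross-sectional structure of a
multi-study sample of UK adults at high risk of type 2 diabetes wearing a
thigh monitor, at its default calibration: n = 1524; behaviours
548 ± 112 / 286 ± 96 / 107 ± 40 min/day; age 59.8 ± 11.9 y; 51.7% male;
72.9% White European (remainder split 20.0% South Asian / 7.1% other — the
published table reports only the White European fraction); 40.2% on
blood-pressure and 27.9% on lipid-lowering medication; BMI 30.3 ± 5.7,
waist 100 ± 14 cm, HbA1c 5.8 ± 0.4%. Marginals with no published pooled
value were set once to figures typical of this population: total
cholesterol 5.2 ± 1.0, HDL 1.3 ± 0.35, LDL 3.0 ± 0.9, triglycerides
1.7 ± 0.9 mmol/L, SBP 132 ± 16, DBP 80 ± 10 mmHg, IMD score 20 ± 12
(truncated at 0).

*Behaviour model.* Compositions are logistic-normal: bivariate normal ILR
coordinates (pivot basis) times an independent normal waking-wear total,
which guarantees strictly positive parts. Minute-scale moments of this
family have no closed form, so the seven parameters (two ILR means, two
SDs, their correlation, wear mean and SD) are moment-matched numerically
to the six behaviour means/SDs by least squares over a fixed bank of 4096
standard-normal draws; the fixed draws make the calibration deterministic
and smooth. The ILR correlation is fitted rather than pinned at zero
because the six moment targets cannot all be reached with independent
coordinates (the fitted value at the default targets is ≈ −0.13); a fixed
correlation remains available as a parameter. Infeasible target sets
(residual > 2%) raise rather than silently approximate.

*Outcomes.* Each outcome is `mean + sd·u`, where `u` is the centred
behaviour signal — ILR-scale γ·(z − μz) in `gamma` mode or per-hour
β·(hours − mean hours) in `beta` mode — plus small centred covariate
effects, plus Gaussian noise sized so Var(u) = 1 (using the calibrated
behaviour covariance, so no data-dependent rescaling biases the truth).
Standardising the generated outcome and regressing it on the behaviour
terms therefore recovers the configured truth, which the recovery and
coverage tests verify (bias < 0.02, CI coverage in the 99% binomial band
around 0.95 over 200 replicates at n = 1524). Default truths: BMI
γ = (1.2, −0.34) — the scale implied by published standardised-BMI
reallocation effects at this mean composition — with analogous values for
waist, triglycerides, HDL and blood pressure, and null truths for HbA1c,
total and LDL cholesterol, mirroring the null findings reported for those
markers. Exactly one truth mode drives a run. A `confound_age_rho` knob
correlates age with the first ILR coordinate to exercise covariate
adjustment; covariates are otherwise independent of behaviour.

*Day-level records.* Valid days jitter the participant composition
multiplicatively (log-normal, σ = 0.10) and are repaired to satisfy every
screening criterion; invalid days break exactly one named criterion
(short wear, low step events, or > 95% single-behaviour dominance) and
carry their construction in a `truth_label` column so the screening code
can be audited against ground truth. Step events are ≈ 40 per stepping
minute (a typical adult cadence of ~80 steps/min, two steps per event).

*What the generator does not emulate*: study-specific recruitment windows
and eligibility, within-participant day-to-day autocorrelation,
device-processing artefacts, informative missingness, and real covariate–
behaviour confounding beyond the single age knob. Passing tests therefore
demonstrate correctness of the estimators under the assumed data-generating
model, not robustness to the messiness of field data.

## Numerical choices and problem sizes

OLS is delegated to statsmodels; rank deficiency is detected up front and
reported with the offending columns (pivoted QR). ILR inversion subtracts
the row maximum before exponentiating to guard overflow. Ties and bounds:
screening thresholds are closed; reallocations require the donor behaviour
to stay strictly positive, and an infeasible grid cell is flagged rather
than aborting the run. Test and validation problem sizes — 1524
participants for cohort-level checks, 100 000 for moment-match asymptotics,
200 replicates for coverage — were chosen as the smallest sizes at which
the corresponding statistical claims are sharp.

## Known limitations

Only 3-part compositions are wired through the high-level pipeline (the
ILR machinery itself is D-part general). The CCRS inherits whatever
measurement error its components carry; no measurement-error model is
included. CISM confidence intervals treat the base composition as fixed;
uncertainty in estimating the mean composition is ignored, as is
conventional. Cross-sectional associations only — nothing here supports
causal or longitudinal interpretation.
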