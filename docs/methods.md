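# Methods

This note documents the models, parameters and design choices behind
`actimet`: what is simulated, how the estimation pipeline works, and what
the shipped tests do and do not establish about real recordings.

## 1. Protocols and metabolic arithmetic

The **standardized protocol** is 15 bouts in fixed order: lying (12 min),
sitting, standing, then treadmill walking (4/5/6 km/h), treadmill running
(7/8/9 km/h women; 7/8.5/10 km/h men), ergometer cycling (70/85/100 rpm at
0.016 kp/kg body mass for women, 0.02 kp/kg for men) and stair walking
(50/70/90 steps/min, 0.173 m steps), 5 min per bout. Reference EE is
averaged over the last 2 min of each bout, except stairs, where
cadence-specific windows (115/110/128 s) balance ascending and descending
steps. The **semi-standardized protocol** is 10 min of the three stationary
activities followed by 20 min of the four physical activities, self-ordered,
every activity at least twice, every bout at least 30 s.

Intensity targets derive from the ACSM equations: running
VO₂ = 0.2·speed + 0.9·speed·grade + 3.5 mL/kg/min and leg cycling
VO₂ = 1.8·(kp·rpm·6 m)/mass + 7 mL/kg/min. Two details are deliberate:

* the published intensity anchors (33.5 and 36.8 mL/kg/min for the top
  running speeds) match the running equation at **grade 0**, although the
  treadmill bouts prescribe 1% inclination. The protocol records both: the
  bout carries `grade = 0.01`, the `vo2_target` extra is computed level.
* the flywheel travel of 6 m per pedal revolution (Monark convention) is
  required for the 28.6 mL/kg/min men's cycling anchor to come out and is
  exposed as a parameter.

MET is defined operationally as kcal per kg of (participant + 1.6 kg worn
device) per hour (`met_from_kcal`), and 1 MET = 3.5 mL O₂/kg/min where a
VO₂ bridge is needed.

## 2. Counts pipeline

Proprietary actigraphy counts are replaced by an open chain: per axis,
order-2 Butterworth band-pass 0.29–1.63 Hz (initialised at DC steady state,
so a constant offset yields exactly zero output), rectification, a 0.02 g
deadband, quantization in 0.01 g steps capped at 255 levels, and
integration over 10-s epochs (sum of quantized levels / sample rate).
Vector-magnitude counts (default) combine the three axis counts in
quadrature; a single-axis mode exists for sensitivity checks. CPM = counts
× 60/epoch length. The absolute scale differs from commercial counts; this
is immaterial because **all regressions are fit and applied on the same
pipeline**. Epochs are anchored at the recording start, half-open
[start, start+len), trailing partial epochs dropped.

Calibration CPM uses the bout minus its first and last 30 s (the stairs
bouts instead use their cadence-specific windows, which is how the stated
stair windows read most naturally for CPM). Step cadence is peak counting
on the band-passed longitudinal axis (peaks ≥ 0.1 g, ≥ fs/3.75 samples
apart).

## 3. Activity classification

Per-second features per site: total signal SD within the second
(square-root of summed per-axis variances), inclination of the 2-s
low-passed acceleration vector against the segment's longitudinal axis, and
the forward/backward pitch excursion (max−min of the low-passed atan2(z, x)
angle over a centred 5-s window). The decision tree:

1. thigh SD < 0.08 g → stationary; thigh inclination ≥ 45° → horizontal
   thigh, split lying vs sitting on hip inclination ≥ 45°; else standing;
2. otherwise dynamic: hip SD < 0.15 g **and** thigh inclination in
   [30°, 80°] → cycling; else forward/backward excursion ≥ 20° → stairs;
   else thigh SD ≥ 0.55 g → running, below → walking. Nothing else matches
   → "move".

All thresholds are named in `ClassifierThresholds` and in the run config.
They were tuned only against the synthetic generator; the fidelity target is
the ≥99% per-second, per-class round-trip on default synthetic cohorts —
not byte equality with any proprietary classifier, whose exact thresholds
are not described here. With only thigh and hip sensors, lying vs sitting
rests on a trunk-angle proxy (hip inclination), a stand-in for the original
instrumentation.

Epoch labels take the most frequent second-level label per 10-s epoch; exact
ties go to the later entry of the priority order lying < sitting < standing
< walking < stairs < running < cycling < move (prefers the rarer,
higher-energy class; the tie rule is this package's own choice).

## 4. Calibration and estimation

Per activity, ordinary least squares of reference MET on trimmed-bout CPM;
cycling adds the sex covariate (1 = female, 2 = male) because the sexes
pedalled against different resistances — the published equations use one
line with a gender term, so that is the default, with a separate-per-sex
switch (`cycling_sex_term=False`). If the training data contain one sex
only, the covariate is collinear with the intercept and is dropped. R² is
the Pearson coefficient of determination; SEE uses residual degrees of
freedom n − p (the source is silent on the denominator; n − p is the
standard choice). Fits are cross-checked against statsmodels OLS in tests
to 1e-9.

LOSO: subject i's `CalibrationModel` is fit on all subjects ≠ i; tests
verify that corrupting subject i's rows leaves their own model bit-identical.
Fixed stationary METs support two readings of the source description —
`own_subject` (each participant's own measured bout MET; the default, as the
literal reading) and `loso_group_mean` (mean over the other subjects); both
agree on homogeneous cohorts and neither is asserted as the original intent.

`estimate_acti4` maps each labelled 10-s epoch to MET (fixed values for
postures, regressions for movement, walking line for "move") and aggregates
periods as time-weighted MET means. With uniform epochs this equals summing
kcal per epoch and converting back — the equivalence is tested — which
resolves the unstated kcal↔MET intermediate in the original description.
The posture-monitor comparator uses lying/sitting 1.0 MET, standing
1.4 MET, stepping MET = 0.0186·(steps/min) + 1.4. External estimators
(heart-rate branched models, proprietary count algorithms) are out of scope
and enter only via `ingest_external_estimates`, which validates the epoch
grid and passes values through unchanged.

## 5. Agreement statistics

MSE = ((N−1)/N)·s² + z̄² over per-subject differences (algebraically the
mean squared difference — both forms are asserted). Percent bias is stored
at full precision and rounded only for display. Bland–Altman plots
difference against the reference with limits z̄ ± 1.96 s and an OLS
proportional-bias trend. ICC defaults to ICC(2,1) — two-way random effects,
absolute agreement, single measures, computed from the mean-squares
decomposition and cross-checked against pingouin; the original analysis
does not state its ICC form, so ICC(3,1) is available behind a flag.
Paired t tests are two-sided at α = 0.05; no multiple-testing correction is
applied (none was in the original analysis).

## 6. Synthetic-data generator

Per bout and site, acceleration = posture gravity vector + activity
sinusoid + white noise (default SD 0.03 g, 30 Hz; the devices being
emulated sample at 30–60 Hz and 30 Hz keeps simulations small). Postures:
x (down the segment) reads +1 g upright; lying puts both sites horizontal;
sitting only the thigh; cycling tilts the thigh ≈50° with a quiet hip.
Sinusoid frequency follows the prescribed target (0.3 Hz per km/h on the
treadmill; cadence/60 for cycling and stairs); stair walking adds a slow
±22°, 0.25 Hz forward/backward pitch wave emulating alternating
ascent/descent. Bout transitions cross-fade postures over 3–8 s and are
labelled `transition` (excluded from accuracy scoring, matching the
protocol's note that transition states go unclassified). A per-subject
amplitude factor (SD 6%) provides between-subject spread.

Thigh amplitudes per (activity, intensity) were anchored once so that the
realized CPM of this counts pipeline lands where the published thigh
regressions map the corresponding group-mean METs (e.g. walking ≈
730/990/1310 CPM); they are model defaults, not measurements.

Ground-truth EE is generated **from the realized CPM** of the generating
site (default thigh): per bout, MET = a·CPM + c·sex + b from the published
regression bank, plus one Gaussian residual per bout (default SD = each
regression's published SEE; stationary METs drawn per subject around
1.27/1.16/1.30 with the published SDs). Because EE is an exact function of
realized CPM when residuals are zero, a noiseless cohort is a parameter-
recovery oracle: LOSO calibration must return the generating lines to
machine precision, and the acceptance suite asserts ≤1e-6. Heart rate is
HR = 60 + 22·(MET−1) + N(0, 3) bpm clipped to [40, 200] — an invented
affine stand-in needed only for the sleeping-HR rule and external-estimate
paths.

**What the simulator does not emulate:** biomechanical gait waveforms and
harmonics, device filter chains and clock drift, inter-individual movement
styles, non-steady-state metabolism, or heart-rate kinetics. Passing tests
therefore certify the pipeline's internal correctness (feature logic,
calibration algebra, LOSO hygiene, statistics), not field accuracy on human
recordings; the published human-cohort R²/ICC values are not reproducible
without the original data and are not targeted.

## 7. Numerical and degenerate-input choices

* Counts filter initialised with `lfilter_zi`-scaled state: DC-exact zeros.
* Regression requires ≥2 points (≥3 with covariate) and non-constant CPM;
  rank-deficient designs raise.
* `bout_average_cpm` averages only epochs fully inside the window and
  raises when none fits; a 5-min trimmed bout holds exactly 24 ten-second
  epochs.
* Dominant-activity ties use the documented priority order; empty epochs
  raise.
* `sleeping_hr` needs one full 60-s epoch; zero-variance inputs to paired t,
  Pearson and ICC raise rather than returning NaN.
* All randomness flows from explicit integer seeds via numpy Generators;
  per-subject seeds derive from a `SeedSequence`, and CSVs are written with
  a fixed `%.6f` format (readers parse with round-trip precision), so a rerun
  with the same config and seed is byte-identical.

## 8. Problem sizes used in the shipped checks

The test suite simulates cohorts of 14 subjects for parameter recovery,
ten seeded sessions for classifier fidelity, 200 bout-level cohorts for the
slope-recovery property, 500 replicates for slope-SE coverage, and 10 000
replicates (n = 14) for the paired-t type-I rate; the end-to-end
determinism check runs a two-subject study twice. These sizes mirror the
study scale where it matters (14 subjects) and are otherwise chosen to make
the Monte-Carlo assertions stable.
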