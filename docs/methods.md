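# Methods

This note documents the models, conventions and numerical choices behind
`vcgtwist`, and what the synthetic-data experiments do and do not show.

## Signal model and pre-processing

Recordings are matrices of microvolt samples, one row per lead, at any rate
≥ 250 Hz; everything downstream runs at 1 kHz, reached by cubic-spline
resampling (records already at 1 kHz pass through untouched).  Filtering is
zero-phase throughout (forward-backward IIR), so fiducial points are never
shifted: a 3rd-order 0.5 Hz Butterworth high-pass for DC and drift (≈27 dB
attenuation of 0.3 Hz wander after the double pass), a 4th-order 150 Hz
low-pass, and an optional mains notch.  These defaults are standard
resting-ECG practice chosen not to distort QRS/T morphology; all are
configurable through `FilterSettings`.

Twelve-lead input is reduced to the 8 algebraically independent leads
(I, II, V1–V6).  When redundant limb leads are present they are first
checked against the Einthoven/Goldberger identities with a 5 µV tolerance —
a cheap detector of mislabelled files — and then dropped.  The chest-belt
set is the three bipolar differences V2−V1, V5−V2, V6−V5; the shared
Wilson-terminal reference cancels exactly, and the three leads telescope to
V6−V1 by construction.

## Beat processing

**QRS detection** runs on the root-sum-of-squares vector magnitude: an
80 ms integrated-energy envelope with a relative threshold and a 200 ms
refractory period proposes beats; each is refined to the apex of a 60 ms
moving-RMS of the magnitude, then template-aligned against the ensemble
average beat shape.  The wide apex window matters: a multilead magnitude
can be multi-humped within the QRS, and a narrow window leaves a flat
plateau whose argmax wanders under noise or filter ripple.

**Median beat.** Windows of −300/+600 ms around each R peak are screened by
correlation (≥ 0.9 against the ensemble average) and combined by per-lead,
per-sample median — robust to a single corrupted beat.  At high heart rates
the post-R extent shrinks to 85% of the mean RR so a neighbouring beat
never leaks into the representative beat; the −300/+600 ms figures are
configurable.

**Delineation** operates on the vector magnitude of the
*baseline-corrected* median beat: each lead's terminal-50 ms mean is
subtracted first, because zero-phase high-pass filtering centres each lead
over the whole record and leaves flat beat segments on a non-zero pedestal
that would bias threshold crossings.  QRS onset and offset are sustained
threshold crossings at 5% of the R amplitude above baseline, searched
backward/forward from the R apex on a 15 ms moving-RMS of the magnitude
(the sustain requirement skips brief within-QRS dips).  T offset uses the
tangent method: the steepest descending tangent of the T limb extrapolated
to the baseline level (mean of the terminal 50 ms).  Any fiducial can be
overridden manually; overrides are taken verbatim and flagged
`source="manual"`.

**Intervals.** Heart rate is 60000 / mean RR over all RR intervals of the
recording; QRS duration = offset − onset; QT = T offset − QRS onset;
QTc by Fridericia, QT/(RR in s)^(1/3); the T peak is the argmax of the
vector magnitude on (QRS offset, T offset], ties broken toward the earliest
sample (conservatively maximising TpTe), and TpTe = T offset − T peak.

## Loop decomposition and non-planarity

The QRS window spans QRS onset→offset; the T window spans QRS offset→T
offset, deliberately including the ST segment (its content is small but the
window definition stays simple and matches the delineation exactly).
Segments are referenced to the per-lead amplitude at QRS onset — the
isoelectric point — rather than mean-centred, because vectorcardiographic
loops are defined relative to the isoelectric level and mean-centring would
distort open loops.

The segment is decomposed by full SVD.  Invariants maintained and tested:
singular values descending; Σsᵢ² equals the squared Frobenius norm
(energy conservation, checked to 1e-9 relative); orthogonal rotations of
lead space leave singular values (hence non-planarity) unchanged.

Non-planarity conventions (always recorded in the result):

* `first3_energy` (default): `100·s₃²/(s₁²+s₂²+s₃²)`.  The loop is a 3-D
  object living in the space of its first three components; the "relative
  extent" of a component is conventionally energy-based.
* `total_energy`: `100·s₃²/Σᵢsᵢ²` — differs from the default only by
  higher-component noise energy.
* `amplitude`: `100·s₃/(s₁+s₂+s₃)`.

The belt-lead panel is computed from the belt combination of the median
beat's precordial rows, with the same delineation, so the four panel values
(QRS/T × 8-lead/belt) always refer to the same representative beat.

**Belt-lead recombination is *not* invariant.**  Alternative pairings of
the same four electrodes (e.g. V2−V1, V5−V1, V6−V1) are invertible linear
recombinations of the default three leads, but an invertible, non-orthogonal
recombination does not preserve singular-value ratios in general.  The
package therefore treats this as an empirical quantity to report, not an
identity to assume, and the validation run confirms measurable differences
(fractions of a percentage point up to a few points, depending on the lead
field) between combinations.

**Spatial QRS-T angle.**  The full QRS-onset→T-offset segment is decomposed
once; QRS and T windows are projected onto its first three components, each
is summed over time into an area vector, and the angle between the two area
vectors is reported in degrees within [0, 180].  This area-vector
convention is fixed and documented here because published variants differ;
parallel loops give 0°, polarity-reversed loops 180°.

## Synthetic ECG generator

The dipole is built from the Fourier sine basis `sin(kπj/N)`, `k=1,2,3`,
over each wave window: two in-plane courses (amplitudes `a ≥ b`) and one
out-of-plane course (`c ≤ b`).  On the integer sample grid this basis is
*exactly* orthogonal (discrete sine transform orthogonality), so the three
principal energies of a wave are exactly `a², b², c²` (times N/2) and the
true non-planarity has the closed form `100·c²/(a²+b²+c²)` — not an
approximation.  The constraint `c ≤ b` keeps the out-of-plane course on the
*third* singular value; with `a = b` the construction reaches twist
fractions up to 33%, well beyond the clinically observed range of a few
percent.  The dominant first harmonic has no interior zero, so each wave's
vector magnitude is single-humped, as in real beats.

Defaults emulate the recording conditions of short pre-implant ECGs:
10-second strips, 1 kHz, resting heart rate (60 bpm, configurable 20–300),
multiplicative RR jitter, QRS in-plane amplitudes of ~1 mV and T amplitudes
of ~0.3 mV, white noise of 0–20 µV and sinusoidal baseline wander
(0.25 Hz).  Beats are projected to 8 leads through a lead field with
orthonormal columns — drawn per seed, or the fixed shipped matrix — which
preserves singular values and per-sample vector magnitude exactly, so the
dipole-level ground truth transfers to the 8-lead record unchanged.  All
randomness flows from a single seed.

The ground-truth R time is defined as the apex of the 60 ms moving-RMS
magnitude — the same functional the detector uses — so that detector
accuracy is measured against a well-defined fiducial rather than a
plateau-sensitive raw argmax.

What the generator does **not** model: realistic torso volume-conduction
(the lead field is an abstract orthonormal projection; real lead fields are
non-orthogonal, which is also why the belt-lead values differ from the
8-lead values), pathology morphologies (bundle-branch block, infarction),
ectopy, muscle-noise colour, or electrode motion artefacts.  Passing tests
therefore demonstrate correctness of the *measurement machinery* under
controlled truth, not clinical performance on real ECGs.

## Cohort workflow

Follow-up is restricted to 5 years = 1826 days (leap-inclusive,
configurable); events beyond the horizon are recoded as censored at the
horizon.  For the shock endpoint, patients without an appropriate shock are
censored at their death time or follow-up end, whichever is earlier; rows
with unavailable shock data are excluded from shock analyses only.  The two
endpoint sets overlap by design: a shocked patient who later dies is an
event for both.

Non-planarity enters continuous models after a base-2 log transform, so a
hazard ratio reads as risk per doubling of the twist.  Dichotomisation uses
strict inequalities at guideline thresholds — age > 75 y, heart rate >
75 bpm, QRS > 120 ms, QTc > 450 ms, TpTe > 100 ms, QRS-T angle > 110°, and
LVEF < 25% (risk direction reversed) — while the non-planarity indices are
split at the *analysed cohort's* medians, never at fixed numbers.

Cox models are fitted by partial likelihood via lifelines with Efron tie
handling.  Backwards stepwise elimination removes, at each step, the
covariate with the largest Wald p ≥ α (default α = 0.05, matching the
conventional significance level; Wald rather than likelihood-ratio criteria
because the reported summaries are Wald-based) and refits until all
retained p < α; an emptied model is a valid, error-free outcome, and the
elimination order is recorded.  A configurable floor of 10 events per model
guards against unstable fits.  The two multivariable presets differ only in
which twist indices enter: model 1 the 8-lead values, model 2 the belt
values.  Kaplan-Meier curves and the log-rank test come from lifelines as
well; with no censoring the estimator reduces to the empirical survival
function (tested).

**Synthetic cohorts** draw covariates loosely emulating a primary-
prophylactic ICD population (≈21% female, ≈62% ischaemic aetiology, ≈41%
CRT-D, LVEF ≈ 26 ± 7%, QRS ≈ 135 ± 28 ms, log-normal twist indices with
medians of a few percent), attach true log hazard ratios through a
proportional-hazards exponential event-time model on centred covariates,
and censor with an independent exponential clock plus optional
administrative cut-off.  Baseline rates default to ≈15% five-year mortality
and ≈11% five-year shock incidence; ≈3% of rows have the shock endpoint
marked unavailable.  Everything is determined by the seed.

## Validation experiments and problem sizes

`vcgtwist.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) regenerates each experiment from a seed:

* twist recovery at true fractions {0, 1, 2, 5, 10, 20}% at 0 and 10 µV
  noise (tolerances 0.1 and 1 percentage point);
* energy conservation and rotation invariance on 1000 random segments
  (1e-9 relative);
* a 2% vs 11% QRS-twist pair through the complete pipeline under noise,
  jitter and wander — ordering preserved with a gap above 5 points;
* delineation across heart rates 50–110 bpm and noise up to 20 µV
  (30 records, 90 fiducials): ≥95% within ±10 ms of truth;
* Cox CI coverage for true HRs 1.0 and 1.5 (n = 2000, 200 replicates each,
  ~30% censoring) within 95 ± 2 points, and stepwise retention/rejection
  (100 replicates) at ≥90%;
* the censoring-rule fixtures and the belt-lead telescoping identity.

These sizes keep the full validation run under a minute of CPU while
leaving the stochastic checks adequately powered; coverage at 200
replicates has a binomial standard error of ≈1.5 points, so the ±2-point
band is a genuine, occasionally tight, probabilistic check.

## Known limitations

* Only the documented CSV dialect is read; clinical container formats
  (SCP-ECG, DICOM-ECG, HL7 aECG) and binary waveform databases are out of
  scope.
* Delineation accuracy is guaranteed (±10 ms) only on generator-style
  beats; real-world T morphologies (biphasic, low-amplitude) may need the
  manual override path.
* The QRS-T angle convention (area vectors in SVD 3-space) is one of
  several published variants; absolute values are comparable only within
  this convention.
* No competing-risks modelling, shock adjudication, or device-programming
  covariates in the cohort stage.
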