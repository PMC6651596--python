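# Methods

`limbbcg` implements an end-to-end analysis of limb ballistocardiography
(BCG) for unobtrusive cardiovascular (CV) parameter estimation: a synthetic
waveform generator with exported ground truth, signal pre-conditioning,
transformation of armband acceleration BCG into weighing-scale displacement
BCG, fiducial and feature extraction, and subject-level bootstrap regression
of six CV parameters (DP, PP, SP, SV, CO, TPR) on sixteen BCG/PPG
characteristic features. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## The synthetic cohort

No human recordings ship with the package; every analysis runs on synthetic
subjects whose statistical and morphological structure matches what the
pipeline assumes, with per-beat ground truth exported so that each stage can
be tested against a known answer.

**Protocol.** Nine ordered periods — R1, cold pressor (CP), R2, mental
arithmetic (MA), R3, slow breathing (SB), R4, breath hold (BH), R5 — with
default durations 90/120/90/180/90/180/90/60/90 s. The breath-hold duration
is not standardized anywhere and is exposed as configuration (default 60 s,
a comfortable post-exhalation hold). A `duration_scale` knob shrinks every
period proportionally; tests and the bundled analysis scripts use scales of
0.2–0.3 (periods of 12–54 s, cohorts of 1–6 subjects) so the full chain runs
in seconds per subject. These sizes are the package's own desk-scale choice;
the defaults remain the full protocol.

**CV trajectories.** Four primary parameters are simulated per beat — DP,
PP, SV, HR — and the remainder derived so the physiological identities hold
by construction: SP = DP + PP, CO = SV·HR/1000, TPR = MAP/CO with
MAP = DP + PP/3. Baseline: DP 80 mmHg, PP 40 mmHg, SV 70 mL, HR 60 bpm.
Interventions shift the primary parameters by signed fractions of baseline
(CP: DP +15%, PP +20%, SV −10%, HR +15%; MA: +12/+8/−8/+12%; SB:
−8/−12/−8/+4%; BH: +10/+18/−8/−2%), ramped linearly over a configurable
onset (default 10 s) from the previous period's level. The magnitudes are
typical young-adult responses chosen so that the sign of every *derived*
parameter's shift matches the published extremum-direction table (pressures
and TPR up under CP/MA/BH and down under SB; SV down under every
intervention; CO up under CP/MA, slightly down under SB/BH); the generator
validates this at construction and refuses a configuration that violates
it. DP and PP effect ratios differ across interventions so that
pulse-pressure-coupled amplitude features cannot masquerade as DP
predictors. Beat-to-beat variability is multiplicative Gaussian noise per
primary parameter (default SD 2% of the local mean).

One deliberate deviation: the narrative description of the study data says
CO rose modestly under slow breathing, while the published extremum table
assigns CO a *minimum* in SB. The extremum-window search consumes the
table, so the generator follows the table (a small CO decrease in SB).

**Beat templates.** Analytic shapes keep the fiducial ground truth
closed-form:

* ECG — a Gaussian R spike (σ 8 ms); nothing downstream uses ECG morphology
  beyond R timing.
* Scale BCG — three Gaussian bumps: I (negative, R+100 ms, σ 20 ms),
  J (positive, R+190 ms, σ 24 ms), K (negative, R+280 ms, σ 28 ms).
  The K amplitude coupling is balanced against the I/J areas so the complex
  has near-zero net area: like a real displacement BCG it is oscillatory
  with little sub-heart-rate energy, which keeps the post-integration
  high-pass (at 2.5× heart rate) from eating into the complex itself.
* Arterial BP — a raised-cosine systolic upstroke that attains SP exactly,
  with a tapered exponential decay back to DP (attained exactly at the
  beat's first sample), so the per-beat min/max reproduce DP/SP at sample
  precision.
* PPG — a logistic upstroke (τ = 20 ms, 10–90% rise ≈ 88 ms, a realistic
  finger-PPG rise) whose intersecting-tangent foot is closed-form (the
  tangent at the half-rise point meets the baseline 2τ earlier), followed
  by a tapered decay; the channel is emitted AC-coupled as optical
  front-ends do.
* Armband acceleration — the second central difference of the limb
  displacement, computed over the whole concatenated record. The limb
  displacement equals the scale BCG under the rigid-body assumption; an
  optional first-order low-pass "body compliance" distortion (default off)
  can be applied before differentiation to emulate a non-rigid arm path.

**Feature–CV coupling.** Features are tied to the CV state by a
configurable linear map mirroring the mechanistic account of the BCG:
PTT_I = 0.35 − 0.0011·DP s (transit time shortens as pressure rises, the
foot being placed at I-time + PTT_I), A_J = 0.02·PP (the J wave tracks
pulse pressure), A_I = −0.50 + 0.0025·DP (the I trough shallows with DP),
A_K = 0.214 − 0.0171·PP. Because the map is linear and known, regression
recovery has an exact expected answer.

**Timing jitter.** The J and K delays receive independent per-beat Gaussian
jitter (SD 8 ms, clipped at 2.5σ). Real BCG wave timings vary
independently; without this the three transit times PTT_I/PTT_J/PTT_K are
numerically collinear and the exhaustive model search cannot distinguish
them. The I wave and the PPG foot keep their configured coupling exactly.

**Noise and artifacts.** Additive Gaussian noise, low-passed at 100 Hz (a
typical anti-aliasing bandwidth for 1 kHz acquisition), scaled per channel
to a configured SNR (defaults: ECG 30, BP 40, both BCG 25, PPG 30 dB).
Artifact injection corrupts a configured fraction of beats (≤ 50%) with
amplitude spikes (×5), narrow Gaussian distortion bumps between I and K
(relative height 0.5, σ 8 ms, with the analytic second derivative added to
the acceleration channel so the two BCG channels stay physically
consistent), or sub-hertz baseline wander; corrupted indices are recorded
in the ground truth.

**What the generator does not emulate.** ECG morphology (P/T waves,
arrhythmia), respiratory modulation of the waveforms, wave-shape change
with posture or vascular tone (only amplitudes and timings respond to CV
state), drifts in sensor gain, and pulse-wave reflection physics. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its statistical procedures recover known structure — not that the
regression models would attain any particular accuracy on human data.

## Pre-conditioning

Processing is period-by-period throughout. Defaults are the published
values and live in `PipelineConfig`:

* Zero-phase smoothing: ECG and BP through a 1st-order Butterworth low-pass
  at 20 Hz, BCG and PPG through a 2nd-order band-pass 0.5–10 Hz
  (forward–backward, so the effective response is the squared magnitude
  with zero group delay).
* R waves by the Pan–Tompkins chain: 5–15 Hz band-pass, differentiation,
  squaring, 150 ms moving-window integration, adaptive signal/noise
  thresholds with a 200 ms refractory period and a search-back at 1.66× the
  running RR; the R time is refined to the ECG maximum within ±50 ms.
* Gating at 10% of the cardiac period before each R wave. The "cardiac
  period" for a beat is the RR interval immediately preceding its R wave
  (the following interval for the first beat) — the causal reading. Beat i
  spans [gate_i, gate_{i+1}), so n R waves give n−1 complete beats.
* Amplitude rejection: a beat is removed (from all channels) when its
  peak-to-peak armband or scale BCG amplitude lies outside 3 scaled MADs
  (scaling 1.4826) of the period median. The comparison is strict, so a
  zero MAD (half the beats identical) still catches spikes while an
  all-identical series removes nothing.
* 10-beat exponential moving average across aligned beats, sample-wise:
  y_k = αx_k + (1−α)y_{k−1} with α = 2/(n+1); the first beat passes
  unchanged. Beats are aligned at their gates and truncated/edge-padded to
  the period's median beat length. The smoothing is applied beat-wise to
  the BCG channels only.

The MAD scaling factor 1.4826 is the normal consistency constant
1/Φ⁻¹(3/4); `limbbcg.robust.normal_consistency_constant()` recomputes it.

## Armband → scale transformation

Under a rigid-body assumption the armband accelerometer and the scale
strain gauge observe the same motion in different derivatives, so the
acceleration is integrated twice (cumulative trapezoid, zero initial
conditions) and the drift that integration amplifies is removed with a
zero-phase 4th-order Butterworth high-pass. The cut-off is the average of
the 2nd and 3rd peaks of the BCG power spectrum — the heart-rate harmonics —
i.e. 2.5× the heart rate. Spectral estimation: Welch periodogram on the
integrated signal, segment length 4× the expected cardiac period, 50%
overlap, linear detrend, peak picking restricted to 0.5–10 Hz. The
fundamental is taken from the median spacing of the harmonic comb (the
lowest harmonics of a displacement BCG can be weak, so the lowest peak is
not a reliable fundamental), and F2/F3 are the peaks nearest 2× and 3× the
fundamental. When the spectrum is flat (in-band maximum below 5× the
in-band median; periodic BCG sits at 15–25, noise near 1.5) or the
harmonics cannot be resolved, the cut-off falls back to 2.5× a supplied
heart-rate estimate, with a warning.

**Beat quality.** Aligned scale-type beats are compared with the period
ensemble average s̄ (mean across beats; m is the scalar mean of s̄):

1. deviation ratio ‖s_i − s̄‖/‖s̄ − m‖ > 1;
2. Pearson correlation between s_i and s̄ below 0.5;
3. a distortion peak in the second derivative between the I and K waves
   with prominence above 0.25.

A beat flagged by *any* criterion is removed (the criteria each describe a
defect). Criterion 3 needed two numerical decisions. First, a prominence
threshold on a raw second derivative is unit-dependent, and any clean beat's
intrinsic I/J/K curvature already carries large prominence, so the test is
applied to the *residual* curvature d²s_i − d²s_ref, normalized by the peak
reference curvature in the I–K window — a clean beat then scores ≈ 0 and an
added bump scores its own curvature relative to the wave's. Second, the
reference curvature d²s_ref is the pointwise *median* across beats rather
than the curvature of s̄: a minority of distorted beats cannot poison the
median, while they visibly bend the mean. Second derivatives are central
differences on a 20 Hz low-pass-smoothed beat; the I/K delimiters come from
labeling the ensemble average. Periods with fewer than 3 beats are skipped
with a warning.

## Fiducials and features

The J wave is the earliest global maximum of the beat after the R wave; I
and K are the nearest local minima on either side, found on a 20 Hz
low-pass-smoothed copy (a local minimum is a sample no higher than both
neighbours and strictly below the peak). A beat with a monotone edge on
either side of J is unlabelable and excluded. Amplitudes are signed and
referenced to the beat mean, which makes them offset-invariant.

The PPG foot is the intersecting tangent: the tangent at the maximum
first-derivative point of the systolic upstroke intersected with the
horizontal through the preceding minimum. The slope and baseline are
averaged over ±3 ms and ±6 ms neighbourhoods respectively, since single
samples of a derivative are noise-prone. The foot paired with a beat is the
first foot after that beat's R wave.

Sixteen features per beat: PTT_I/J/K (foot minus wave time), T_IJ, T_JK,
T_IK, T_JJ (next beat's J minus this beat's J; undefined for a period's
last beat, which then drops out of T_JJ-dependent analyses only), A_I, A_J,
A_K, A_IJ = A_J − A_I, A_JK = A_J − A_K, the stroke-volume surrogates
A_IJ·PTT_I² and A_JK·PTT_I², and RMS and energy E = Σs² over the gated
beat's raw samples (so E = n·RMS² identically). Reference CV parameters per
beat: DP/SP as the min/max of the gated BP waveform, PP their difference,
SV/CO/TPR as within-gate means of the recorded reference series.

Features are computed on the EMA-smoothed, quality-passed beats: the
processing order is pre-conditioning → transformation/quality → features.

## Regression analysis

Per subject and period, each feature series is cleaned by the sliding
windowed-MAD rule: each block of 3 consecutive samples is inspected against
a 9-sample window (3 before + the block + 3 after; the nearest full window
at the series edges), removing samples more than 3 scaled MADs from the
window median. The inspection advances 3 samples at a time, per the rule's
literal phrasing. A beat flagged in any feature series is dropped. Periods
losing more than 75% of their gated beats are excluded; subjects with fewer
than 6 usable periods are excluded.

For each target parameter, the representative window in a period is the 11
consecutive retained beats whose mean is extremal in that target's
published direction for that period (ties to the earliest window); the same
beats provide the paired feature means and SDs, preserving the
feature–target pairing. "Stable extremum" is operationalized as the
extremal sliding mean, which a single spiking beat cannot relocate. Each
representative expands into 100 parametric-bootstrap samples — every
variable drawn as the mean of 11 independent normal draws with the window
mean and SD — merged across periods (up to 900 per subject). Ordinary least
squares is then fitted for every single feature and every unordered pair
(16 + 120 = 136 candidates per target; collinear pairs are skipped with a
note), and each model's validity is the Pearson correlation between the
measured representatives and its predictions across the subject's periods
(≥ 3 required). Models at r ≥ 0.7 are flagged acceptable; predictors are
annotated with a static physiological-relevance tag (transit times for
pressures, T_JJ for rate-driven targets, amplitude×PTT² for stroke volume),
never silently filtered. No multiple-testing correction is applied — the
exhaustive search is a descriptive screen and its optimism is inherent to
the reported train/eval correlations. The cohort summary reports, per
target and model order, the feature set with the best across-subject mean
evaluation correlation, as mean ± SE.

## Reproducibility and orchestration

A single master seed fans out to per-stage seeds through a stable
CRC-based derivation, so stages are independently reproducible and a full
`run` is bit-identical under a fixed seed. Every stage writes delimited
text with a fixed float format; the configuration round-trips through YAML.
The CLI verbs (`synth`, `preprocess`, `transform`, `extract`, `analyze`,
`run`) are thin wrappers over the library; the numbered scripts under
`analysis/` run the same stages as a narrative sequence and write their
tables under `results/`.

## Known limitations

* The generator's linear feature–CV coupling makes regression recovery
  exact by construction; real couplings are nonlinear and state-dependent.
* Band-pass filtering at 0.5–10 Hz systematically shifts detected wave
  times by a few milliseconds in an amplitude-dependent way; the default
  templates keep this below ~2% of the coupling slope, but sharper or more
  overlapped morphologies would see larger biases.
* The quality criteria flag genuinely deviating ramp-transition beats as
  well as injected artifacts; at full protocol durations this affects a
  few percent of beats.
* Subject-level regression only: no cross-subject calibration or
  coefficient transfer is attempted.
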