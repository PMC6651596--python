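"""Single-beat waveform synthesis for all five channels.

Beat templates are analytic so fiducial ground truth is closed-form:

* ECG: a narrow Gaussian R spike (morphology beyond the R wave is out of
  scope; only R timing matters downstream).
* Scale (displacement) BCG: three Gaussian bumps — negative I, dominant
  positive J, negative K — the canonical systolic complex.
* Arterial BP: a raised-cosine systolic upstroke reaching SP exactly,
  decaying back toward DP; the within-beat minimum equals DP and the
  maximum equals SP at sample precision.
* PPG: a logistic upstroke whose intersecting-tangent foot is closed-form
  (the tangent at the half-rise point meets the baseline 2*tau before the
  half-rise time), followed by a tapered decay.
* Armband acceleration: the second time-derivative of the limb displacement
  (equal to the scale BCG, optionally passed through a first-order
  "body compliance" low-pass); computed at assembly over the whole record.

Features are tied to the cardiovascular state through a configurable linear
coupling map (PTT_I falls with DP; the J amplitude and the J-K amplitude
span grow with PP; the I depth shrinks as DP rises), so regression recovery
has a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError
from .protocol import BeatCV

#: feature name -> (intercept, {cv parameter: slope}); evaluated linearly.
CouplingMap = dict[str, tuple[float, dict[str, float]]]


def default_coupling() -> CouplingMap:
    """Default linear coupling between cardiovascular state and morphology.

    PTT_I (s) = 0.35 - 0.0011 * DP      (transit time shortens as DP rises)
    A_J (units) = 0.02 * PP             (J amplitude tracks pulse pressure)
    A_I (units) = -0.50 + 0.0025 * DP   (I trough shallows as DP rises)
    A_K (units) = 0.2143 - 0.01714 * PP (deepens with PP: A_JK grows with PP)

    The K coupling is balanced against the default I/J wave areas so the
    rendered complex has near-zero net area: like a real displacement BCG it
    is oscillatory with little sub-heart-rate content, which keeps the
    post-integration high-pass from eating into the complex itself.
    """
    return {
        "ptt_i": (0.35, {"dp": -0.0011}),
        "a_j": (0.0, {"pp": 0.02}),
        "a_i": (-0.50, {"dp": 0.0025}),
        "a_k": (0.2143, {"pp": -0.01714}),
    }


def eval_coupling(coupling: CouplingMap, name: str, cv: BeatCV) -> float:
    intercept, slopes = coupling[name]
    return intercept + sum(s * getattr(cv, p) for p, s in slopes.items())


@dataclass
class WaveSpec:
    """A Gaussian bump: delay after the R wave (s) and width sigma (s)."""

    delay_s: float
    width_s: float


@dataclass
class MorphologyConfig:
    r_offset_s: float = 0.08          # R wave position within the beat window
    ecg_r_width_s: float = 0.008
    ecg_r_amp: float = 1.0            # mV
    i_wave: WaveSpec = field(default_factory=lambda: WaveSpec(0.10, 0.020))
    j_wave: WaveSpec = field(default_factory=lambda: WaveSpec(0.19, 0.024))
    k_wave: WaveSpec = field(default_factory=lambda: WaveSpec(0.28, 0.028))
    ppg_tau_s: float = 0.02           # logistic rise time constant
    ppg_amp: float = 1.0
    ppg_decay_s: float = 0.30
    bp_rise_frac: float = 0.30        # systolic upstroke as fraction of the beat
    bp_decay_frac: float = 0.35       # diastolic decay time constant fraction
    #: Beat-to-beat SD (s) of independent J/K-wave timing jitter, emulating
    #: intra-beat variability of the later systolic waves; the I wave and the
    #: PPG foot keep their configured coupling exactly.
    timing_jitter_sd_s: float = 0.008
    #: Optional first-order low-pass "body compliance" distortion (Hz) applied
    #: to the limb displacement before differentiation; None = rigid body.
    compliance_cutoff_hz: float | None = None
    coupling: CouplingMap = field(default_factory=default_coupling)

    def __post_init__(self) -> None:
        if not self.i_wave.delay_s < self.j_wave.delay_s < self.k_wave.delay_s:
            raise ConfigurationError("wave delays must be ordered I < J < K")


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synthesize_beat(
    cv: BeatCV, morph: MorphologyConfig, fs: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Render one beat (duration 60/hr s) for the directly-synthesized channels.

    Returns ``(channels, truth)`` where channels holds ecg, bp,
    bcg_scale_disp and ppg sample arrays of equal length, and truth holds
    beat-relative fiducial times/amplitudes: r_time, i/j/k time and amp
    (amplitudes referenced to the beat mean of the displacement), and the
    closed-form intersecting-tangent ppg_foot_time.

    The acceleration channel is derived at assembly time from the full
    concatenated displacement so that beat boundaries add no edge artifacts.
    """
    if not 30.0 < cv.hr < 180.0:
        raise ConfigurationError(f"heart rate {cv.hr} outside (30, 180) beats/min")
    n = int(round(fs * 60.0 / cv.hr))
    t = np.arange(n) / fs
    r = morph.r_offset_s

    ecg = morph.ecg_r_amp * _gauss(t, r, morph.ecg_r_width_s)

    a_i = eval_coupling(morph.coupling, "a_i", cv)
    a_j = eval_coupling(morph.coupling, "a_j", cv)
    a_k = eval_coupling(morph.coupling, "a_k", cv)
    dj = dk = 0.0
    if rng is not None and morph.timing_jitter_sd_s > 0:
        sd = morph.timing_jitter_sd_s
        dj, dk = np.clip(rng.normal(0.0, sd, size=2), -2.5 * sd, 2.5 * sd)
    disp = (
        a_i * _gauss(t, r + morph.i_wave.delay_s, morph.i_wave.width_s)
        + a_j * _gauss(t, r + morph.j_wave.delay_s + dj, morph.j_wave.width_s)
        + a_k * _gauss(t, r + morph.k_wave.delay_s + dk, morph.k_wave.width_s)
    )

    # BP: raised-cosine upstroke hitting SP exactly at sample i1, tapered
    # exponential decay back to DP (reached exactly at the first sample).
    i1 = max(1, int(round(morph.bp_rise_frac * n)))
    w = np.empty(n)
    w[: i1 + 1] = 0.5 - 0.5 * np.cos(np.pi * np.arange(i1 + 1) / i1)
    if i1 + 1 < n:
        td = t[i1 + 1:] - t[i1]
        taper = 1.0 - td / (t[-1] - t[i1] + 1.0 / fs)
        w[i1 + 1:] = np.exp(-td / (morph.bp_decay_frac * n / fs)) * taper
    bp = cv.dp + cv.pp * w

    # PPG: logistic upstroke; intersecting-tangent foot is closed-form.
    ptt_i = eval_coupling(morph.coupling, "ptt_i", cv)
    if ptt_i <= 0:
        raise ConfigurationError("coupling yields non-positive PTT_I")
    foot_time = r + morph.i_wave.delay_s + ptt_i
    tau = morph.ppg_tau_s
    t_half = foot_time + 2.0 * tau
    rise = 1.0 / (1.0 + np.exp(-(t - t_half) / tau))
    t_pk = t_half + 4.0 * tau
    decay = np.ones(n)
    after = t > t_pk
    if after.any():
        td = t[after] - t_pk
        span = max(t[-1] - t_pk, 2.0 / fs)
        decay[after] = np.exp(-td / morph.ppg_decay_s) * (1.0 - td / (span + 1.0 / fs))
    ppg = morph.ppg_amp * rise * decay
    # Emit the PPG AC-coupled (zero mean per beat), as optical front-ends do;
    # the intersecting-tangent foot is invariant under the shift, and the
    # pre-conditioning band-pass then adds no undershoot of its own.
    ppg -= ppg.mean()

    # Ground truth: read the realized extrema off the rendered displacement
    # so that, noise-free, truth coincides with the waveform to the sample.
    mean = float(disp.mean())
    j_idx = int(np.argmax(disp))
    i_idx = int(np.argmin(disp[:j_idx]))
    k_idx = j_idx + int(np.argmin(disp[j_idx:]))
    truth = {
        "r_time": r,
        "i_time": i_idx / fs, "i_amp": float(disp[i_idx] - mean),
        "j_time": j_idx / fs, "j_amp": float(disp[j_idx] - mean),
        "k_time": k_idx / fs, "k_amp": float(disp[k_idx] - mean),
        "ppg_foot_time": foot_time,
    }
    channels = {"ecg": ecg, "bp": bp, "bcg_scale_disp": disp, "ppg": ppg}
    return channels, truth
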