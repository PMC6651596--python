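"""Fiducial labeling and characteristic-feature extraction.

The J wave is the maximum peak of the (displacement-type) BCG beat after the
ECG R wave; the I and K waves are the local minima immediately before and
after it. The PPG foot comes from the intersecting tangent method: the
tangent at the point of maximum upstroke slope intersected with the
horizontal through the preceding waveform minimum.

Sixteen characteristic features are computed per beat: the three BCG-to-PPG
pulse transit times (PTT_I, PTT_J, PTT_K), the intra-beat wave intervals
(T_IJ, T_JK, T_IK), the inter-beat J-J interval (T_JJ), the signed wave
amplitudes (A_I, A_J, A_K) referenced to the beat mean, the amplitude spans
(A_IJ = A_J - A_I, A_JK = A_J - A_K), the stroke-volume surrogates
A_IJ*PTT_I^2 and A_JK*PTT_I^2, and the waveform RMS and energy E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ProcessingError, UnlabelableBeat

#: Canonical feature order for all downstream tables.
FEATURE_NAMES = (
    "PTT_I", "PTT_J", "PTT_K",
    "T_IJ", "T_JK", "T_IK", "T_JJ",
    "A_I", "A_J", "A_K", "A_IJ", "A_JK",
    "A_IJ*PTT_I^2", "A_JK*PTT_I^2",
    "RMS", "E",
)


@dataclass
class FiducialSet:
    """I/J/K times (s, beat-relative) and signed amplitudes, plus PPG foot."""

    i_time: float
    j_time: float
    k_time: float
    i_amp: float
    j_amp: float
    k_amp: float
    ppg_foot_time: float | None = None

    def validate(self) -> None:
        if not self.i_time < self.j_time < self.k_time:
            raise ProcessingError("fiducial times must satisfy I < J < K")
        if not (self.j_amp > self.i_amp and self.j_amp > self.k_amp):
            raise ProcessingError("J must be the dominant wave")


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz is None or cutoff_hz >= fs / 2 or len(x) < 15:
        return np.asarray(x, dtype=float)
    b, a = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs)
    return sps.filtfilt(b, a, x)


def label_ijk(
    bcg_beat: np.ndarray,
    fs: float,
    r_index: int = 0,
    smooth_hz: float = 20.0,
) -> FiducialSet:
    """Label the I, J, K waves of one gated displacement-BCG beat.

    J is the earliest global maximum after the R wave (sample ``r_index``);
    I and K are the nearest local minima on either side, found on a 20 Hz
    low-pass-smoothed copy for noise robustness. Amplitudes are read off the
    smoothed beat after subtracting the beat mean. A beat with no local
    minimum on a side of J (a monotone edge) is unlabelable.
    """
    beat = np.asarray(bcg_beat, dtype=float)
    if len(beat) < 8 or r_index >= len(beat) - 2:
        raise UnlabelableBeat("beat too short to label")
    s = _smooth(beat, fs, smooth_hz)
    baseline = float(s.mean())
    start = max(int(r_index) + 1, 1)
    j = start + int(np.argmax(s[start:]))  # argmax -> earliest maximal sample

    def local_min_before(idx: int) -> int | None:
        for m in range(idx - 1, 0, -1):
            if s[m] <= s[m - 1] and s[m] <= s[m + 1] and s[m] < s[idx]:
                return m
        return None

    def local_min_after(idx: int) -> int | None:
        for m in range(idx + 1, len(s) - 1):
            if s[m] <= s[m - 1] and s[m] <= s[m + 1] and s[m] < s[idx]:
                return m
        return None

    i = local_min_before(j)
    k = local_min_after(j)
    if i is None or k is None:
        raise UnlabelableBeat("no local minimum flanking the J wave")
    return FiducialSet(
        i_time=i / fs, j_time=j / fs, k_time=k / fs,
        i_amp=float(s[i] - baseline),
        j_amp=float(s[j] - baseline),
        k_amp=float(s[k] - baseline),
    )


def detect_ppg_foot(
    ppg_beat: np.ndarray, fs: float, smooth_hz: float = 20.0
) -> float:
    """PPG foot time (s, beat-relative) by the intersecting tangent method.

    The tangent at the maximum first-derivative point of the systolic
    upstroke is intersected with the horizontal line through the preceding
    waveform minimum. A non-positive maximum slope means there is no
    upstroke and the beat is excluded.
    """
    beat = np.asarray(ppg_beat, dtype=float)
    if len(beat) < 8 or np.ptp(beat) == 0.0:
        raise UnlabelableBeat("flat PPG beat")
    s = _smooth(beat, fs, smooth_hz)
    pk = int(np.argmax(s))
    if pk < 2:
        raise UnlabelableBeat("PPG maximum at the beat edge")
    mn = int(np.argmin(s[:pk]))
    upstroke = slice(mn, pk + 1)
    d = np.gradient(s, 1.0 / fs)
    imax = mn + int(np.argmax(d[upstroke]))
    # Average the slope and baseline over a few milliseconds: the tangent
    # point and the preceding minimum are noise-prone single samples.
    half = max(1, int(round(0.003 * fs)))
    slope = float(np.mean(d[max(0, imax - half):imax + half + 1]))
    if slope <= 0.0:
        raise UnlabelableBeat("non-positive PPG upstroke slope")
    baseline = float(np.mean(s[max(0, mn - 2 * half):mn + 2 * half + 1]))
    return imax / fs - (float(s[imax]) - baseline) / slope


def extract_features(
    fiducials: FiducialSet,
    next_beat_j_time: float | None,
    bcg_beat_samples: np.ndarray,
) -> dict[str, float]:
    """Compute the 16 characteristic features of one labeled beat.

    PTT_x = ppg_foot_time - x_time; T_JJ needs the next beat's J time (in
    the same time base) and is NaN when unavailable, in which case the beat
    drops out of T_JJ-dependent analyses only. RMS and E are computed over
    the gated beat's raw samples: RMS = sqrt(mean(s^2)), E = sum(s^2),
    hence E = n * RMS^2 identically.
    """
    f = fiducials
    if f.ppg_foot_time is None:
        raise ProcessingError("fiducials lack a PPG foot time")
    s = np.asarray(bcg_beat_samples, dtype=float)
    ptt_i = f.ppg_foot_time - f.i_time
    rms = float(np.sqrt(np.mean(s**2)))
    energy = float(np.sum(s**2))
    feats = {
        "PTT_I": ptt_i,
        "PTT_J": f.ppg_foot_time - f.j_time,
        "PTT_K": f.ppg_foot_time - f.k_time,
        "T_IJ": f.j_time - f.i_time,
        "T_JK": f.k_time - f.j_time,
        "T_IK": f.k_time - f.i_time,
        "T_JJ": (next_beat_j_time - f.j_time
                 if next_beat_j_time is not None else np.nan),
        "A_I": f.i_amp,
        "A_J": f.j_amp,
        "A_K": f.k_amp,
        "A_IJ": f.j_amp - f.i_amp,
        "A_JK": f.j_amp - f.k_amp,
        "RMS": rms,
        "E": energy,
    }
    feats["A_IJ*PTT_I^2"] = feats["A_IJ"] * ptt_i**2
    feats["A_JK*PTT_I^2"] = feats["A_JK"] * ptt_i**2
    return {name: feats[name] for name in FEATURE_NAMES}


def compute_reference_cv(
    bp_beat: np.ndarray,
    sv_beat: np.ndarray,
    co_beat: np.ndarray,
    tpr_beat: np.ndarray,
) -> dict[str, float]:
    """Reference CV parameters for one gated beat.

    DP and SP are the minimum and maximum of the BP waveform within the
    gate, PP their difference; SV, CO and TPR are the within-gate means of
    the recorded reference series.
    """
    bp = np.asarray(bp_beat, dtype=float)
    if bp.size == 0:
        raise ProcessingError("empty gate")
    dp = float(bp.min())
    sp = float(bp.max())
    return {
        "dp": dp, "sp": sp, "pp": sp - dp,
        "sv": float(np.mean(sv_beat)),
        "co": float(np.mean(co_beat)),
        "tpr": float(np.mean(tpr_beat)),
    }
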