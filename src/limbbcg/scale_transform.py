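"""Armband-acceleration to weighing-scale (displacement) BCG transformation.

Under a rigid-body assumption the armband accelerometer and the scale strain
gauge observe the same limb motion in different derivatives, so the armband
BCG is double-integrated in time (trapezoidal rule) and the unbounded
low-frequency drift that integration amplifies is removed with a zero-phase
4th-order Butterworth high-pass. The cut-off sits between the 2nd and 3rd
spectral peaks of the BCG — the heart-rate harmonics — i.e. at
(F2 + F3)/2 = 2.5x the heart rate, estimated from a Welch spectrum with a
heart-rate fallback when the harmonic peaks are not resolvable.

Beat quality of scale-type BCG beats is assessed against the period ensemble
average s_bar: (1) deviation ratio ||s_i - s_bar|| / ||s_bar - m|| > 1 with
m the scalar mean of s_bar; (2) correlation with s_bar below 0.5; (3) a
distortion peak in the second derivative between the I and K waves with
normalized prominence above 0.25. A beat flagged by any criterion is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, signal as sps

from .errors import ConfigurationError, ProcessingError, UnlabelableBeat
from .fiducials import label_ijk


@dataclass
class SpectralPeaks:
    """Harmonic peak frequencies of the BCG power spectrum."""

    f1: float
    f2: float
    f3: float
    powers: tuple[float, float, float]
    resolution_hz: float
    fallback_used: bool = False


def double_integrate(accel: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integration applied twice, zero initial state."""
    accel = np.asarray(accel, dtype=float)
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    vel = integrate.cumulative_trapezoid(accel, dx=1.0 / fs, initial=0.0)
    return integrate.cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)


def estimate_hpf_cutoff(
    bcg_segment: np.ndarray,
    fs: float,
    hr_hint_hz: float | None = None,
    hr_multiple: float = 2.5,
    band: tuple[float, float] = (0.5, 10.0),
) -> tuple[float, SpectralPeaks]:
    """Cut-off frequency for post-integration drift removal.

    Welch power spectrum (segment length 4x the expected cardiac period,
    50% overlap, linear detrend), peak picking restricted to the BCG band;
    the fundamental is the lowest substantial peak and F2/F3 the peaks
    nearest its 2nd and 3rd harmonics. Cutoff = (F2 + F3)/2. When the
    harmonics cannot be resolved the cutoff falls back to ``hr_multiple``
    times the heart-rate frequency (from ``hr_hint_hz``), with a warning.
    """
    x = np.asarray(bcg_segment, dtype=float)
    period_s = 1.0 / hr_hint_hz if hr_hint_hz else 1.0
    nperseg = int(round(4.0 * period_s * fs))
    nperseg = max(256, min(nperseg, len(x)))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="linear")
    resolution = float(freqs[1] - freqs[0])

    def _fallback(reason: str) -> tuple[float, SpectralPeaks]:
        if hr_hint_hz is None:
            raise ProcessingError(
                f"{reason} and no heart-rate hint for the fallback cutoff")
        warnings.warn(f"{reason}; falling back to {hr_multiple} x heart rate")
        cutoff = hr_multiple * hr_hint_hz
        peaks = SpectralPeaks(hr_hint_hz, 2 * hr_hint_hz, 3 * hr_hint_hz,
                              (np.nan, np.nan, np.nan), resolution,
                              fallback_used=True)
        return cutoff, peaks

    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any() or np.ptp(x) == 0.0:
        return _fallback("degenerate spectrum")
    fb, pb = freqs[in_band], psd[in_band]
    # A discernible harmonic comb towers over the in-band median level
    # (x15-25 on periodic BCG); a flat noise-like spectrum sits near 1.5.
    if float(pb.max()) < 5.0 * float(np.median(pb)):
        return _fallback("no discernible fundamental (flat spectrum)")
    idx, _ = sps.find_peaks(pb)
    # Discard window sidelobes and noise wiggles; the harmonic comb of a
    # periodic BCG spans orders of magnitude, so the floor is generous.
    idx = idx[pb[idx] >= 1e-4 * pb[idx].max()] if len(idx) else idx
    if len(idx) < 3:
        return _fallback("fewer than three spectral peaks in band")
    # Fundamental: the comb spacing. The lowest harmonics can be weak (the
    # BCG wave amplitudes nearly cancel at low frequency), so the median
    # spacing of the detected peaks is more reliable than the lowest peak.
    spacing = float(np.median(np.diff(fb[idx])))
    if spacing <= 0:
        return _fallback("degenerate peak spacing")
    near_f1 = idx[np.abs(fb[idx] - spacing) <= 0.5 * spacing]
    f1 = float(fb[near_f1[np.argmax(pb[near_f1])]]) if len(near_f1) else spacing

    def _harmonic(k: int) -> tuple[float, float] | None:
        target = k * f1
        cand = idx[np.abs(fb[idx] - target) <= 0.4 * f1]
        if len(cand) == 0:
            return None
        best = cand[np.argmin(np.abs(fb[cand] - target))]
        return float(fb[best]), float(pb[best])

    h2, h3 = _harmonic(2), _harmonic(3)
    if h2 is None or h3 is None:
        return _fallback("2nd/3rd harmonic peaks not resolvable")
    f2, p2 = h2
    f3, p3 = h3
    if not f1 < f2 < f3:
        return _fallback("harmonic peaks not ordered")
    p1 = float(np.interp(f1, fb, pb))
    cutoff = 0.5 * (f2 + f3)
    return cutoff, SpectralPeaks(f1, f2, f3, (p1, p2, p3), resolution)


def highpass_drift_removal(
    displacement: np.ndarray, cutoff_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass removing post-integration drift."""
    if not 0.0 < cutoff_hz < fs / 2.0:
        raise ConfigurationError(f"cutoff {cutoff_hz} Hz outside (0, {fs / 2})")
    x = np.asarray(displacement, dtype=float)
    b, a = sps.butter(order, cutoff_hz, btype="highpass", fs=fs)
    return sps.filtfilt(b, a, x)


def transform_armband(
    accel_period: np.ndarray,
    fs: float,
    hr_hint_hz: float | None = None,
    hpf_order: int = 4,
    hr_multiple: float = 2.5,
) -> tuple[np.ndarray, float, SpectralPeaks]:
    """Transform one period of armband acceleration into a synthetic scale BCG.

    Composition: trapezoidal double integration, spectral cut-off estimation
    on the integrated signal (heart-rate fallback), zero-phase 4th-order
    high-pass drift removal. Returns (synthetic scale BCG, cutoff, peaks).
    """
    accel = np.asarray(accel_period, dtype=float)
    if np.ptp(accel) == 0.0:
        peaks = SpectralPeaks(np.nan, np.nan, np.nan,
                              (np.nan, np.nan, np.nan), np.nan, True)
        return np.zeros_like(accel), np.nan, peaks
    disp = double_integrate(accel, fs)
    cutoff, peaks = estimate_hpf_cutoff(
        disp, fs, hr_hint_hz=hr_hint_hz, hr_multiple=hr_multiple)
    synth = highpass_drift_removal(disp, cutoff, fs, order=hpf_order)
    return synth, cutoff, peaks


# --- beat quality ----------------------------------------------------------

def _second_derivative(x: np.ndarray, fs: float, smooth_hz: float = 20.0
                       ) -> np.ndarray:
    if smooth_hz and smooth_hz < fs / 2 and len(x) >= 15:
        b, a = sps.butter(2, smooth_hz, btype="lowpass", fs=fs)
        x = sps.filtfilt(b, a, x)
    return np.gradient(np.gradient(x) * fs) * fs


def assess_beat_quality(
    beats: np.ndarray,
    fs: float,
    r_index: int = 0,
    deviation_ratio_threshold: float = 1.0,
    corr_threshold: float = 0.5,
    prominence_threshold: float = 0.25,
) -> pd.DataFrame | None:
    """Per-beat quality report for aligned scale-type BCG beats.

    ``beats`` is (n_beats, length). Criterion 1 flags a beat whose deviation
    from the ensemble average exceeds the ensemble's own spread
    (||s_i - s_bar|| / ||s_bar - m|| > 1); criterion 2 flags low waveform
    similarity (Pearson r with s_bar < 0.5); criterion 3 flags a distortion
    peak in the residual curvature d2(s_i) - d2(s_bar) between the ensemble
    I and K waves, normalized by the ensemble's own peak curvature, with
    prominence above 0.25. removed = any criterion fired. Fewer than 3 beats:
    the period is skipped (None) with a warning.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.ndim != 2 or len(beats) < 3:
        warnings.warn("fewer than 3 beats in period; quality assessment skipped")
        return None
    s_bar = beats.mean(axis=0)
    m = float(s_bar.mean())
    denom = float(np.linalg.norm(s_bar - m))
    ratios = np.linalg.norm(beats - s_bar, axis=1) / max(denom, 1e-30)

    sb = s_bar - s_bar.mean()
    sb_norm = float(np.linalg.norm(sb))
    corrs = np.empty(len(beats))
    for k, b in enumerate(beats):
        bc = b - b.mean()
        denom_k = float(np.linalg.norm(bc)) * sb_norm
        corrs[k] = float(bc @ sb) / denom_k if denom_k > 0 else 0.0

    # Criterion 3: residual curvature between the ensemble's I and K waves.
    # The reference curvature is the pointwise median across beats, which a
    # minority of distorted beats cannot poison (the ensemble mean can).
    distortion = np.zeros(len(beats), dtype=bool)
    try:
        fid = label_ijk(s_bar, fs, r_index=r_index)
        i_idx = int(round(fid.i_time * fs))
        k_idx = int(round(fid.k_time * fs))
        d2 = np.asarray([_second_derivative(b, fs) for b in beats])
        d2_ref = np.median(d2, axis=0)
        ref = float(np.max(np.abs(d2_ref[i_idx:k_idx + 1])))
        if ref > 0 and k_idx - i_idx >= 3:
            for kk in range(len(beats)):
                resid = np.abs(d2[kk] - d2_ref)[i_idx:k_idx + 1] / ref
                pk, _ = sps.find_peaks(resid, prominence=prominence_threshold)
                # An off-ensemble curvature ridge may peak at the window edge.
                edge = max(resid[0], resid[-1]) > 2 * prominence_threshold
                distortion[kk] = bool(len(pk)) or edge
    except UnlabelableBeat:
        warnings.warn("ensemble average unlabelable; distortion criterion skipped")

    removed = ((ratios > deviation_ratio_threshold)
               | (corrs < corr_threshold)
               | distortion)
    return pd.DataFrame({
        "deviation_ratio": ratios,
        "ensemble_correlation": corrs,
        "distortion_flag": distortion,
        "removed": removed,
    })
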