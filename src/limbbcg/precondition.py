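"""Signal pre-conditioning.

Processing is period-by-period: period segmentation, zero-phase Butterworth
smoothing (ECG/BP: 1st-order low-pass at 20 Hz; BCG/PPG: 2nd-order band-pass
0.5-10 Hz), Pan-Tompkins R-wave detection, beat gating at 10% of the cardiac
period before each R wave, scaled-MAD rejection of beats with extraordinary
BCG amplitude, and a 10-beat exponential moving average across aligned beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import FilterSpec
from .errors import ConfigurationError, DataError, ProcessingError
from .robust import MAD_SCALE, mad_outlier_mask
from .synth.assemble import SubjectRecord


# --- period segmentation ---------------------------------------------------

def segment_periods(
    record: SubjectRecord,
    expected_labels: tuple[str, ...] | None = None,
) -> list[tuple[str, dict[str, np.ndarray]]]:
    """Split the record into per-period channel views.

    The views partition the annotated extent under the half-open sample
    convention. When ``expected_labels`` is given, a missing or out-of-order
    label is a data error.
    """
    if not record.periods:
        raise DataError("record has no period annotations")
    if expected_labels is not None:
        got = tuple(lab for lab, _, _ in record.periods)
        if got != tuple(expected_labels):
            raise DataError(f"period labels {got} != expected {tuple(expected_labels)}")
    prev_end = 0
    out = []
    for label, start, end in record.periods:
        if start != prev_end or end <= start:
            raise DataError("period annotations overlap or are unordered")
        prev_end = end
        out.append((label, {ch: x[start:end] for ch, x in record.channels.items()}))
    if prev_end != record.n_samples:
        raise DataError("period annotations do not cover the record")
    return out


# --- zero-phase filtering --------------------------------------------------

def zero_phase_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Forward-backward Butterworth filtering (zero phase, squared magnitude)."""
    spec.validate_for_rate(fs)
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * max(spec.order * 2, 1):
        raise ProcessingError(f"signal too short ({len(x)}) for order-{spec.order} filter")
    wn = spec.corners if spec.kind == "bandpass" else spec.corners[0]
    b, a = sps.butter(spec.order, wn, btype=spec.kind, fs=fs)
    if spec.zero_phase:
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


# --- R-wave detection (Pan-Tompkins) --------------------------------------

def detect_r_waves(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns R times in seconds.

    Classic chain: 5-15 Hz band-pass, differentiation, squaring, 150 ms
    moving-window integration, adaptive signal/noise thresholds with a 200 ms
    refractory period and a missed-beat search-back at 1.66x the running RR.
    The R time is refined to the ECG maximum within +-50 ms of each detection.
    Returns an empty array when nothing resembling a QRS is present.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(fs):
        return np.array([])
    if np.ptp(ecg) == 0.0:
        return np.array([])
    b, a = sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs)
    filt = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(filt) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if len(peaks) == 0:
        return np.array([])

    # Adaptive thresholding over integrated peaks.
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    threshold = npki + 0.25 * (spki - npki)
    accepted: list[int] = []
    recent_rr: list[float] = []
    last = None
    i = 0
    while i < len(peaks):
        p = peaks[i]
        if mwi[p] > threshold:
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if last is not None:
                recent_rr.append((p - last) / fs)
                recent_rr = recent_rr[-8:]
            last = p
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # Search-back: if the expected beat is overdue, accept the
            # largest candidate above half threshold since the last beat.
            if last is not None and recent_rr:
                rr = float(np.mean(recent_rr))
                if (p - last) / fs > 1.66 * rr and mwi[p] > 0.5 * threshold:
                    accepted.append(p)
                    spki = 0.25 * mwi[p] + 0.75 * spki
                    recent_rr.append((p - last) / fs)
                    recent_rr = recent_rr[-8:]
                    last = p
        threshold = npki + 0.25 * (spki - npki)
        i += 1

    if not accepted:
        return np.array([])
    # Refine to the ECG maximum near each integrated-peak detection.
    half = int(round(0.050 * fs))
    r_samples = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        r_samples.append(lo + int(np.argmax(ecg[lo:hi])))
    r_samples = np.unique(r_samples)
    return r_samples / fs


# --- beat gating -----------------------------------------------------------

@dataclass
class BeatSegment:
    """One gated beat: channel slices between consecutive gate locations."""

    beat_index: int
    r_time: float
    gate_start: int          # sample, 0-based inclusive
    gate_end: int            # sample, exclusive
    rr_s: float              # cardiac period used for the gate
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def amplitude(self, channel: str) -> float:
        """Peak-to-peak amplitude of the named channel within the gate."""
        return float(np.ptp(self.channels[channel]))


def gate_beats(
    channels: dict[str, np.ndarray],
    r_times: np.ndarray,
    fs: float,
    fraction: float = 0.1,
) -> list[BeatSegment]:
    """Gate beats at ``fraction`` of the cardiac period before each R wave.

    The cardiac period for beat i is the RR interval immediately preceding
    its R wave (the following interval for the first beat). Beat i spans
    [gate_i, gate_{i+1}) so n R waves yield n-1 complete beats. Returns an
    empty list for fewer than two R waves.
    """
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        return []
    if np.any(np.diff(r_times) <= 0):
        raise DataError("r_times must be strictly increasing")
    rr = np.diff(r_times)
    rr_for = np.concatenate([[rr[0]], rr])  # preceding RR; first uses following
    gates = np.round((r_times - fraction * rr_for) * fs).astype(int)
    n_total = len(next(iter(channels.values())))
    gates = np.clip(gates, 0, n_total)
    beats = []
    for i in range(len(r_times) - 1):
        s, e = int(gates[i]), int(gates[i + 1])
        if e <= s:
            continue
        beats.append(BeatSegment(
            beat_index=i, r_time=float(r_times[i]), gate_start=s, gate_end=e,
            rr_s=float(rr_for[i]),
            channels={ch: x[s:e] for ch, x in channels.items()},
        ))
    return beats


# --- amplitude-based beat rejection ---------------------------------------

def reject_amplitude_outliers(
    beats: list[BeatSegment],
    channel: str,
    multiplier: float = 3.0,
    scale: float = MAD_SCALE,
) -> tuple[list[BeatSegment], list[int]]:
    """Remove beats whose channel amplitude is an extraordinary outlier.

    A beat is removed iff its peak-to-peak amplitude lies outside
    ``multiplier`` scaled MADs (scaling factor 1.4826) around the median
    amplitude. Removal applies to the whole beat across all channels.
    """
    if len(beats) < 5:
        warnings.warn("fewer than 5 beats; amplitude rejection skipped")
        return list(beats), []
    amps = np.array([b.amplitude(channel) for b in beats])
    mask = mad_outlier_mask(amps, multiplier=multiplier, scale=scale)
    removed = [b.beat_index for b, m in zip(beats, mask) if m]
    retained = [b for b, m in zip(beats, mask) if not m]
    return retained, removed


# --- exponential moving average across beats -------------------------------

def align_beats(
    beats: list[BeatSegment], channels: tuple[str, ...] | None = None
) -> tuple[dict[str, np.ndarray], int]:
    """Stack beats into (n_beats, length) arrays at the median beat length.

    Longer beats are truncated, shorter ones are edge-padded with their last
    sample (less disruptive to ensemble statistics than zero padding).
    """
    if not beats:
        raise ProcessingError("no beats to align")
    lengths = [b.gate_end - b.gate_start for b in beats]
    target = int(np.median(lengths))
    if channels is None:
        channels = tuple(beats[0].channels)
    stacks = {}
    for ch in channels:
        rows = []
        for b in beats:
            x = b.channels[ch]
            if len(x) >= target:
                rows.append(x[:target])
            else:
                rows.append(np.concatenate([x, np.full(target - len(x), x[-1])]))
        stacks[ch] = np.asarray(rows)
    return stacks, target


def ema_smooth_beats(
    beats: list[BeatSegment],
    n: int = 10,
    channels: tuple[str, ...] = ("bcg_arm_accel", "bcg_scale_disp"),
) -> list[BeatSegment]:
    """Span-n exponential moving average across aligned beats, sample-wise.

    y_k = alpha*x_k + (1-alpha)*y_{k-1} with alpha = 2/(n+1); the first beat
    passes unchanged. Only the named channels are smoothed; others keep
    their aligned samples. Returns new BeatSegments of the common length.
    """
    if n < 1:
        raise ConfigurationError("EMA span must be >= 1")
    if not beats:
        return []
    stacks, target = align_beats(beats)
    alpha = 2.0 / (n + 1.0)
    smoothed = {}
    for ch, stack in stacks.items():
        if ch in channels:
            y = stack.astype(float).copy()
            for k in range(1, len(y)):
                y[k] = alpha * y[k] + (1.0 - alpha) * y[k - 1]
            smoothed[ch] = y
        else:
            smoothed[ch] = stack
    out = []
    for k, b in enumerate(beats):
        out.append(BeatSegment(
            beat_index=b.beat_index, r_time=b.r_time,
            gate_start=b.gate_start, gate_end=b.gate_start + target,
            rr_s=b.rr_s,
            channels={ch: smoothed[ch][k] for ch in smoothed},
        ))
    return out
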