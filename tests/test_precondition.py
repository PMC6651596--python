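"""Pre-conditioning: filters, R detection, gating, rejection, EMA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from limbbcg.config import FilterSpec
from limbbcg.errors import DataError, ProcessingError, ConfigurationError
from limbbcg.precondition import (BeatSegment, detect_r_waves, ema_smooth_beats,
                                  gate_beats, reject_amplitude_outliers,
                                  segment_periods, zero_phase_filter)

FS = 1000.0
BAND = FilterSpec("bandpass", 2, (0.5, 10.0))
LOW = FilterSpec("lowpass", 1, (20.0,))


# --- segmentation ----------------------------------------------------------

def test_segment_periods_partitions_record(clean_subject):
    rec, _ = clean_subject
    views = segment_periods(rec, expected_labels=[l for l, _, _ in rec.periods])
    assert len(views) == 9
    total = sum(len(v["ecg"]) for _, v in views)
    assert total == rec.n_samples
    # Half-open convention: each boundary sample belongs to the next period.
    labels = [l for l, _, _ in rec.periods]
    for lab_b, start, _ in rec.periods[1:]:
        _, chans = views[labels.index(lab_b)]
        assert chans["ecg"][0] == rec.channels["ecg"][start]


def test_segment_periods_missing_label_is_error(clean_subject):
    rec, _ = clean_subject
    with pytest.raises(DataError):
        segment_periods(rec, expected_labels=("R1", "CP"))


# --- zero-phase filtering --------------------------------------------------

def test_bandpass_passes_5hz_with_zero_lag():
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 5.0 * t)
    y = zero_phase_filter(x, BAND, FS)
    mid = slice(int(2 * FS), int(8 * FS))
    gain = np.ptp(y[mid]) / np.ptp(x[mid])
    assert 0.9 < gain <= 1.0
    lags = sps.correlation_lags(len(x[mid]), len(y[mid]))
    assert lags[np.argmax(sps.correlate(x[mid], y[mid]))] == 0


def test_lowpass_preserves_dc():
    x = np.full(5000, 3.7)
    assert np.allclose(zero_phase_filter(x, LOW, FS), 3.7)


def test_lowpass_attenuation_matches_analytic_butterworth():
    """Forward-backward 1st-order LP: gain = |H|^2 analytically."""
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * 50.0 * t)
    y = zero_phase_filter(x, LOW, FS)
    mid = slice(int(2 * FS), int(8 * FS))
    gain = np.ptp(y[mid]) / np.ptp(x[mid])
    analytic = 1.0 / (1.0 + (50.0 / 20.0) ** 2)   # squared magnitude, order 1
    assert gain == pytest.approx(analytic, rel=0.05)


def test_too_short_signal_raises():
    with pytest.raises(ProcessingError):
        zero_phase_filter(np.ones(5), BAND, FS)


# --- R-wave detection ------------------------------------------------------

def _spike_train(hr_bpm: float, dur_s: float, noise_sd: float = 0.0,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur_s * FS)) / FS
    r_times = np.arange(0.5, dur_s - 0.3, 60.0 / hr_bpm)
    ecg = np.zeros_like(t)
    for rt in r_times:
        ecg += np.exp(-0.5 * ((t - rt) / 0.008) ** 2)
    if noise_sd:
        ecg += rng.normal(0.0, noise_sd, len(t))
    return ecg, r_times


def test_detects_all_clean_spikes_within_10ms():
    ecg, truth = _spike_train(60.0, 30.0)
    det = detect_r_waves(ecg, FS)
    assert len(det) == len(truth)
    assert np.max(np.abs(det - truth)) <= 0.010


def test_flatline_yields_no_detections():
    assert len(detect_r_waves(np.zeros(30000), FS)) == 0


def test_noisy_detection_recall_and_precision():
    ecg, truth = _spike_train(90.0, 30.0, noise_sd=0.10, seed=1)  # ~10 dB SNR
    det = detect_r_waves(ecg, FS)
    tp = sum(np.min(np.abs(det - t)) <= 0.05 for t in truth)
    recall = tp / len(truth)
    precision = sum(np.min(np.abs(truth - d)) <= 0.05 for d in det) / len(det)
    assert recall >= 0.95 and precision >= 0.95


# --- gating ----------------------------------------------------------------

def test_gate_formula_example():
    chans = {"x": np.zeros(3500)}
    beats = gate_beats(chans, np.array([1.0, 2.0, 3.0]), FS, 0.1)
    assert [b.gate_start for b in beats] == [900, 1900]
    assert [b.gate_end for b in beats] == [1900, 2900]


def test_n_rwaves_give_n_minus_one_gates():
    r = 0.5 + 0.8 * np.arange(12)
    chans = {"x": np.zeros(int((r[-1] + 1) * FS))}
    assert len(gate_beats(chans, r, FS)) == len(r) - 1


def test_single_r_wave_gives_no_beats():
    assert gate_beats({"x": np.zeros(2000)}, np.array([1.0]), FS) == []


@given(st.lists(st.floats(0.4, 1.6), min_size=2, max_size=30))
def test_gates_monotone_and_non_overlapping(rrs):
    r = 0.5 + np.cumsum(np.asarray(rrs))
    chans = {"x": np.zeros(int((r[-1] + 2) * FS))}
    beats = gate_beats(chans, r, FS)
    bounds = [(b.gate_start, b.gate_end) for b in beats]
    for (s1, e1), (s2, e2) in zip(bounds[:-1], bounds[1:]):
        assert s1 < e1 <= s2 < e2
    for b in beats:  # each gate contains its R wave
        assert b.gate_start <= int(b.r_time * FS) < b.gate_end


# --- amplitude rejection ---------------------------------------------------

def _beats_from_amps(amps):
    out = []
    for i, a in enumerate(amps):
        out.append(BeatSegment(i, 0.5 + i, i * 100, (i + 1) * 100, 1.0,
                               {"bcg": np.array([0.0, float(a)])}))
    return out


def test_single_huge_amplitude_removed():
    retained, removed = reject_amplitude_outliers(
        _beats_from_amps([10, 10, 10, 10, 100]), "bcg")
    assert removed == [4]
    assert [b.beat_index for b in retained] == [0, 1, 2, 3]


def test_identical_amplitudes_nothing_removed():
    _, removed = reject_amplitude_outliers(_beats_from_amps([7] * 8), "bcg")
    assert removed == []


@given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_rejection_is_affine_equivariant(a, b):
    amps = [10, 11, 10, 12, 11, 10, 60, 11]
    _, removed1 = reject_amplitude_outliers(_beats_from_amps(amps), "bcg")
    # ptp amplitude is |a|-scaled and offset-free; removal set is unchanged
    _, removed2 = reject_amplitude_outliers(
        _beats_from_amps([a * x for x in amps]), "bcg")
    assert removed1 == removed2 == [6]


def test_rejection_is_idempotent():
    beats = _beats_from_amps([10, 11, 10, 12, 11, 10, 60, 11])
    retained, _ = reject_amplitude_outliers(beats, "bcg")
    _, removed_again = reject_amplitude_outliers(retained, "bcg")
    assert removed_again == []


# --- EMA -------------------------------------------------------------------

def _scaled_beats(scales, template=None):
    template = np.sin(np.linspace(0, np.pi, 50)) if template is None else template
    return [BeatSegment(i, 0.5 + i, i * 50, (i + 1) * 50, 1.0,
                        {"bcg_scale_disp": s * template})
            for i, s in enumerate(scales)]


def test_identical_beats_are_fixed_point():
    beats = _scaled_beats([2.0] * 6)
    out = ema_smooth_beats(beats, 10, ("bcg_scale_disp",))
    for b_in, b_out in zip(beats, out):
        assert np.allclose(b_out.channels["bcg_scale_disp"],
                           b_in.channels["bcg_scale_disp"])


def test_span_one_is_identity():
    beats = _scaled_beats([1, 3, 2, 5, 4])
    out = ema_smooth_beats(beats, 1, ("bcg_scale_disp",))
    for b_in, b_out in zip(beats, out):
        assert np.allclose(b_out.channels["bcg_scale_disp"],
                           b_in.channels["bcg_scale_disp"])


def test_step_change_follows_scalar_recursion():
    """Amplitude step A->B: smoothed amplitude obeys the span-n recursion."""
    n = 10
    alpha = 2.0 / (n + 1.0)
    scales = [1.0] * 5 + [3.0] * 15
    out = ema_smooth_beats(_scaled_beats(scales), n, ("bcg_scale_disp",))
    # Independent scalar oracle of the same recursion.
    y = scales[0]
    expected = [y]
    for x in scales[1:]:
        y = alpha * x + (1 - alpha) * y
        expected.append(y)
    template_max = np.sin(np.linspace(0, np.pi, 50)).max()
    got = [b.channels["bcg_scale_disp"].max() for b in out]
    assert np.allclose(got, np.asarray(expected) * template_max)


def test_invalid_span_rejected():
    with pytest.raises(ConfigurationError):
        ema_smooth_beats(_scaled_beats([1, 2]), 0)
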