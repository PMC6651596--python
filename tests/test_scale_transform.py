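"""Acceleration-to-displacement transformation and beat quality."""

import warnings

import numpy as np
import pytest

from limbbcg.errors import ConfigurationError
from limbbcg.precondition import align_beats, gate_beats, segment_periods
from limbbcg.scale_transform import (assess_beat_quality, double_integrate,
                                     estimate_hpf_cutoff,
                                     highpass_drift_removal, transform_armband)
from limbbcg.synth import (MorphologyConfig, NoiseConfig, default_protocol,
                           generate_subject, synthesize_beat)
from limbbcg.synth.protocol import derive_cv

FS = 1000.0


def _periodic_bcg(hr_bpm: float, dur_s: float = 60.0) -> np.ndarray:
    cv = derive_cv(80.0, 40.0, 70.0, hr_bpm)
    channels, _ = synthesize_beat(cv, MorphologyConfig(), FS)
    reps = int(np.ceil(dur_s * FS / len(channels["bcg_scale_disp"]))) + 1
    return np.tile(channels["bcg_scale_disp"], reps)[: int(dur_s * FS)]


# --- double integration ----------------------------------------------------

def test_constant_acceleration_gives_parabola():
    a = 2.5
    t = np.arange(int(FS)) / FS
    disp = double_integrate(np.full(len(t), a), FS)
    expected = 0.5 * a * t**2
    err = np.max(np.abs(disp[1:] - expected[1:])) / expected[-1]
    assert err < 1e-6


def test_zero_in_zero_out():
    assert np.all(double_integrate(np.zeros(1000), FS) == 0.0)


def test_round_trip_from_finite_difference_oracle():
    """accel = 2nd finite difference of a known displacement: recovered
    displacement matches up to a linear trend, residual < 0.5% RMS."""
    t = np.arange(int(5 * FS)) / FS
    disp = np.sin(2 * np.pi * 1.3 * t) + 0.4 * np.sin(2 * np.pi * 3.1 * t)
    accel = np.gradient(np.gradient(disp) * FS) * FS
    rec = double_integrate(accel, FS)
    A = np.column_stack([t, np.ones_like(t)])
    resid = rec - disp - A @ np.linalg.lstsq(A, rec - disp, rcond=None)[0]
    assert np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(disp**2)) < 0.005


# --- cutoff estimation -----------------------------------------------------

@pytest.mark.parametrize("hr_bpm", [50.0, 60.0, 75.0, 90.0, 120.0])
def test_cutoff_is_two_point_five_times_heart_rate(hr_bpm):
    f0 = hr_bpm / 60.0
    cutoff, peaks = estimate_hpf_cutoff(_periodic_bcg(hr_bpm), FS, hr_hint_hz=f0)
    assert not peaks.fallback_used
    assert cutoff / f0 == pytest.approx(2.5, abs=peaks.resolution_hz / f0)


def test_90bpm_cutoff_in_hz():
    cutoff, peaks = estimate_hpf_cutoff(_periodic_bcg(90.0), FS, hr_hint_hz=1.5)
    assert cutoff == pytest.approx(3.75, abs=peaks.resolution_hz)


def test_white_noise_takes_heart_rate_fallback():
    rng = np.random.default_rng(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cutoff, peaks = estimate_hpf_cutoff(rng.standard_normal(60000), FS,
                                            hr_hint_hz=1.0)
    assert peaks.fallback_used
    assert cutoff == pytest.approx(2.5)


# --- drift removal ---------------------------------------------------------

def test_ramp_is_suppressed():
    t = np.arange(int(20 * FS)) / FS
    ramp = 3.0 * t
    out = highpass_drift_removal(ramp, 2.5, FS)
    assert np.sqrt(np.mean(out**2)) < 0.01 * np.sqrt(np.mean(ramp**2))


def test_passband_fidelity_above_cutoff():
    t = np.arange(int(20 * FS)) / FS
    x = np.sin(2 * np.pi * 6.0 * t)
    out = highpass_drift_removal(x, 2.5, FS)
    assert np.corrcoef(x, out)[0, 1] > 0.99


def test_zero_input_zero_output_and_invalid_cutoff():
    assert np.allclose(highpass_drift_removal(np.zeros(5000), 2.5, FS), 0.0)
    with pytest.raises(ConfigurationError):
        highpass_drift_removal(np.ones(5000), 0.0, FS)


# --- full transformation ----------------------------------------------------

@pytest.fixture(scope="module")
def rigid_subject():
    """Deterministic rigid-body subject: no channel noise, no beat-to-beat
    variability — isolates the transformation round trip."""
    proto = default_protocol(duration_scale=0.2, ramp_s=5.0, cv_noise_sd=0.0)
    morph = MorphologyConfig(timing_jitter_sd_s=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_subject(proto, morph, NoiseConfig.noise_free(), 21)


def test_rigid_body_round_trip_beats_raw_acceleration(rigid_subject):
    """Noise-free: per-period r >= 0.95 and strictly above raw |r|."""
    rec, gt = rigid_subject
    for label, chans in segment_periods(rec):
        hr_hz = gt.beats[gt.beats.period == label]["hr"].mean() / 60.0
        synth, cutoff, peaks = transform_armband(
            chans["bcg_arm_accel"], FS, hr_hint_hz=hr_hz)
        true = chans["bcg_scale_disp"]
        r = np.corrcoef(synth, true)[0, 1]
        r_raw = abs(np.corrcoef(chans["bcg_arm_accel"], true)[0, 1])
        assert r >= 0.95, f"{label}: r={r:.3f}"
        assert r > r_raw


def test_compliance_distortion_degrades_but_not_below_06():
    proto = default_protocol(duration_scale=0.2, ramp_s=5.0, cv_noise_sd=0.0)
    morph = MorphologyConfig(timing_jitter_sd_s=0.0, compliance_cutoff_hz=8.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec, gt = generate_subject(proto, morph, NoiseConfig.noise_free(), 21)
    rs = []
    for label, chans in segment_periods(rec):
        hr_hz = gt.beats[gt.beats.period == label]["hr"].mean() / 60.0
        synth, _, _ = transform_armband(chans["bcg_arm_accel"], FS,
                                        hr_hint_hz=hr_hz)
        rs.append(np.corrcoef(synth, chans["bcg_scale_disp"])[0, 1])
    assert min(rs) >= 0.6
    assert max(rs) < 0.99   # distortion visibly degrades the match


def test_zero_acceleration_transforms_to_zero():
    synth, cutoff, peaks = transform_armband(np.zeros(30000), FS, hr_hint_hz=1.0)
    assert np.all(synth == 0.0)


# --- beat quality -----------------------------------------------------------

def _aligned_scale_beats(clean_subject, label="R1"):
    rec, gt = clean_subject
    lo = [s for l, s, _ in rec.periods if l == label][0]
    tb = gt.beats[gt.beats.period == label]
    r = tb.r_time.to_numpy() - lo / FS
    chans = dict(segment_periods(rec))[label]
    beats = gate_beats({"bcg": chans["bcg_scale_disp"]}, r, FS, 0.1)
    stacks, _ = align_beats(beats, ("bcg",))
    r_idx = int(round(0.1 * np.median(np.diff(r)) * FS))
    return stacks["bcg"], r_idx


def test_beat_equal_to_ensemble_is_retained(clean_subject):
    stack, r_idx = _aligned_scale_beats(clean_subject)
    base = np.tile(stack.mean(axis=0), (5, 1))
    rep = assess_beat_quality(base, FS, r_index=r_idx)
    assert rep is not None
    assert np.allclose(rep.deviation_ratio, 0.0, atol=1e-12)
    assert np.allclose(rep.ensemble_correlation, 1.0)
    assert not rep.removed.any()


def test_bump_between_i_and_k_fires_distortion(clean_subject, morph):
    stack, r_idx = _aligned_scale_beats(clean_subject)
    base = np.tile(stack.mean(axis=0), (6, 1)).copy()
    t = np.arange(base.shape[1]) / FS
    center = 0.1 + morph.r_offset_s + 0.5 * (morph.i_wave.delay_s
                                             + morph.k_wave.delay_s)
    bump = 0.5 * np.ptp(base[0]) * np.exp(-0.5 * ((t - center) / 0.008) ** 2)
    base[2] += bump
    rep = assess_beat_quality(base, FS, r_index=r_idx)
    assert bool(rep.distortion_flag.iloc[2])
    assert bool(rep.removed.iloc[2])
    assert not rep.distortion_flag.drop(index=2).any()


def test_triple_amplitude_beat_removed_by_deviation_ratio(clean_subject):
    stack, r_idx = _aligned_scale_beats(clean_subject)
    s_bar0 = stack.mean(axis=0)
    base = np.tile(s_bar0, (6, 1)).copy()
    base[1] = 3.0 * s_bar0
    rep = assess_beat_quality(base, FS, r_index=r_idx)
    assert rep.deviation_ratio.iloc[1] > 1.0
    assert bool(rep.removed.iloc[1])


def test_flag_count_monotone_in_bump_height(clean_subject):
    stack, r_idx = _aligned_scale_beats(clean_subject)
    t = np.arange(stack.shape[1]) / FS
    center = 0.1 + 0.08 + 0.21
    counts = []
    for h in (0.1, 0.3, 0.6, 1.0):
        base = np.tile(stack.mean(axis=0), (8, 1)).copy()
        bump = h * np.ptp(base[0]) * np.exp(-0.5 * ((t - center) / 0.008) ** 2)
        for k in (1, 3, 5):
            base[k] += bump
        rep = assess_beat_quality(base, FS, r_index=r_idx)
        counts.append(int(rep.distortion_flag.sum()))
    assert counts == sorted(counts)


def test_too_few_beats_skips_period(clean_subject):
    stack, r_idx = _aligned_scale_beats(clean_subject)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert assess_beat_quality(stack[:2], FS, r_index=r_idx) is None
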