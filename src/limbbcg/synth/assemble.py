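"""Subject-record assembly: beat concatenation, noise, and artifact injection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..config import derive_seed
from ..errors import ConfigurationError, DataError
from .morphology import CouplingMap, MorphologyConfig, synthesize_beat
from .protocol import BeatCV, CV_PARAMS, ProtocolConfig, make_cv_trajectories

#: Waveform channels carrying measurement noise.
WAVEFORM_CHANNELS = ("ecg", "bp", "bcg_arm_accel", "bcg_scale_disp", "ppg")
#: Reference series recorded alongside the waveforms (beatwise constant).
AUX_CHANNELS = ("sv", "co", "tpr")


@dataclass
class SubjectRecord:
    """Synchronized channels plus ordered period annotations.

    channels maps channel name to an amplitude series; all series share one
    length and the sampling rate. periods is an ordered list of
    (label, start_sample, end_sample) with 0-based half-open ranges that
    partition the record.
    """

    subject_id: str
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    periods: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise DataError("all channels must have equal length")
        n = lengths.pop()
        prev_end = 0
        for label, start, end in self.periods:
            if start != prev_end or end <= start:
                raise DataError("periods must be ordered, non-overlapping, contiguous")
            prev_end = end
        if self.periods and self.periods[-1][2] != n:
            raise DataError("periods must cover the record extent")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class GroundTruth:
    """Per-beat generator truth: the test oracle for every downstream stage.

    beats has one row per beat: beat, period, start_sample, end_sample,
    r_time, i/j/k time (s, absolute) and amp, ppg_foot_time, the six CV
    parameters plus hr, and corruption flags.
    """

    beats: pd.DataFrame
    seed: int
    coupling: CouplingMap

    @property
    def corrupted(self) -> list[int]:
        return self.beats.index[self.beats["corrupted"]].tolist()


@dataclass
class NoiseConfig:
    """Per-channel additive band-limited noise at a configured SNR (dB).

    None disables noise on a channel. The band limit keeps noise within the
    physiological band rather than dominated by unfilterable high frequencies.
    """

    snr_db: dict[str, float | None] = field(default_factory=lambda: {
        "ecg": 30.0, "bp": 40.0, "bcg_arm_accel": 25.0,
        "bcg_scale_disp": 25.0, "ppg": 30.0,
    })
    band_limit_hz: float = 100.0

    @classmethod
    def noise_free(cls) -> "NoiseConfig":
        return cls(snr_db={ch: None for ch in WAVEFORM_CHANNELS})

    @classmethod
    def uniform(cls, snr_db: float) -> "NoiseConfig":
        return cls(snr_db={ch: snr_db for ch in WAVEFORM_CHANNELS})


@dataclass
class ArtifactConfig:
    """Deliberate beat corruption exercising rejection and quality criteria."""

    rate: float = 0.05
    types: tuple[str, ...] = ("spike", "bump", "wander")
    spike_factor: float = 5.0
    bump_rel_height: float = 0.5     # fraction of the beat's I-to-J span
    bump_width_s: float = 0.008
    wander_rel_amp: float = 1.0
    wander_freq_hz: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 0.5:
            raise ConfigurationError("artifact rate must be in [0, 0.5]")
        unknown = set(self.types) - {"spike", "bump", "wander"}
        if unknown:
            raise ConfigurationError(f"unknown artifact types: {unknown}")


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band_hz: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if band_hz >= fs / 2:
        return white
    b, a = sps.butter(4, band_hz, btype="lowpass", fs=fs)
    return sps.filtfilt(b, a, white)


def assemble_subject(
    trajectories: pd.DataFrame,
    morph: MorphologyConfig,
    noise: NoiseConfig,
    seed: int,
    subject_id: str = "S00",
    fs: float = 1000.0,
    lead_in_s: float = 1.0,
    lead_out_s: float = 0.5,
) -> tuple[SubjectRecord, GroundTruth]:
    """Concatenate per-beat waveforms into a full annotated subject record.

    Beat onsets are re-derived from the sample-rounded beat lengths so the
    exported ground-truth times are exact on the sample grid. The armband
    acceleration is the second central difference of the limb displacement
    (the scale BCG, optionally low-passed by the configured body-compliance
    filter) computed over the whole record. Deterministic under a fixed seed.
    """
    if trajectories.empty:
        raise DataError("empty trajectory")
    rng = np.random.default_rng(seed)
    lead_in = int(round(lead_in_s * fs))
    lead_out = int(round(lead_out_s * fs))

    segs: dict[str, list[np.ndarray]] = {
        ch: [] for ch in ("ecg", "bp", "bcg_scale_disp", "ppg", *AUX_CHANNELS)
    }
    truth_rows = []
    period_first_sample: dict[str, int] = {}
    cursor = lead_in
    for row in trajectories.itertuples(index=False):
        cv = BeatCV(dp=row.dp, sp=row.sp, pp=row.pp, sv=row.sv,
                    co=row.co, tpr=row.tpr, hr=row.hr)
        channels, truth = synthesize_beat(cv, morph, fs, rng=rng)
        n = len(channels["ecg"])
        for ch in ("ecg", "bp", "bcg_scale_disp", "ppg"):
            segs[ch].append(channels[ch])
        for ch in AUX_CHANNELS:
            segs[ch].append(np.full(n, getattr(cv, ch)))
        period_first_sample.setdefault(row.period, cursor)
        t0 = cursor / fs
        truth_rows.append({
            "beat": int(row.beat), "period": row.period,
            "start_sample": cursor, "end_sample": cursor + n,
            "r_time": t0 + truth["r_time"],
            "i_time": t0 + truth["i_time"], "i_amp": truth["i_amp"],
            "j_time": t0 + truth["j_time"], "j_amp": truth["j_amp"],
            "k_time": t0 + truth["k_time"], "k_amp": truth["k_amp"],
            "ppg_foot_time": t0 + truth["ppg_foot_time"],
            **{q: getattr(cv, q) for q in CV_PARAMS}, "hr": cv.hr,
            "corrupted": False, "artifact": "",
        })
        cursor += n

    total = cursor + lead_out
    channels_full: dict[str, np.ndarray] = {}
    first_bp = trajectories.iloc[0]["dp"]
    pads = {"ecg": 0.0, "bp": first_bp, "bcg_scale_disp": 0.0, "ppg": 0.0}
    for ch in ("ecg", "bp", "bcg_scale_disp", "ppg"):
        body = np.concatenate(segs[ch])
        channels_full[ch] = np.concatenate([
            np.full(lead_in, pads[ch]), body, np.full(lead_out, pads[ch])])
    for ch in AUX_CHANNELS:
        body = np.concatenate(segs[ch])
        channels_full[ch] = np.concatenate([
            np.full(lead_in, body[0]), body, np.full(lead_out, body[-1])])

    limb = channels_full["bcg_scale_disp"]
    if morph.compliance_cutoff_hz is not None:
        b, a = sps.butter(1, morph.compliance_cutoff_hz, btype="lowpass", fs=fs)
        limb = sps.lfilter(b, a, limb)
    channels_full["bcg_arm_accel"] = np.gradient(np.gradient(limb) * fs) * fs

    for ch in WAVEFORM_CHANNELS:
        snr = noise.snr_db.get(ch)
        if snr is None:
            continue
        sig_power = float(np.var(channels_full[ch]))
        if sig_power == 0.0:
            continue
        w = _band_limited_noise(rng, total, fs, noise.band_limit_hz)
        w *= np.sqrt(sig_power / 10.0 ** (snr / 10.0)) / max(w.std(), 1e-30)
        channels_full[ch] = channels_full[ch] + w

    # Period ranges: each period starts at its first beat's start sample,
    # except the first which absorbs the lead-in; the last absorbs the tail.
    labels = list(dict.fromkeys(trajectories["period"]))
    starts = [0 if i == 0 else period_first_sample[lab]
              for i, lab in enumerate(labels)]
    ends = starts[1:] + [total]
    periods = list(zip(labels, starts, ends))

    record = SubjectRecord(subject_id=subject_id, sampling_rate_hz=fs,
                           channels=channels_full, periods=periods)
    beats = pd.DataFrame(truth_rows).set_index("beat")
    return record, GroundTruth(beats=beats, seed=seed, coupling=morph.coupling)


def inject_artifacts(
    record: SubjectRecord,
    truth: GroundTruth,
    cfg: ArtifactConfig,
    seed: int,
) -> tuple[SubjectRecord, GroundTruth]:
    """Corrupt a random fraction of beats; uncorrupted samples are untouched.

    Spikes scale the whole beat's displacement (and, linearity obliging, its
    acceleration) by a large factor; bumps add a narrow Gaussian between the
    I and K waves (with its analytic second derivative on the acceleration);
    wander adds a sub-hertz sinusoid. Corrupted beat indices are recorded in
    the ground truth.
    """
    if cfg.rate == 0.0 or not cfg.types:
        return record, truth
    rng = np.random.default_rng(seed)
    beats = truth.beats
    n_beats = len(beats)
    n_corrupt = int(round(cfg.rate * n_beats))
    if n_corrupt == 0:
        return record, truth
    picked = np.sort(rng.choice(n_beats, size=n_corrupt, replace=False))
    kinds = rng.choice(list(cfg.types), size=n_corrupt)

    fs = record.sampling_rate_hz
    disp = record.channels["bcg_scale_disp"].copy()
    accel = record.channels["bcg_arm_accel"].copy()
    new_beats = beats.copy()
    for pos, kind in zip(picked, kinds):
        row = beats.iloc[pos]
        s, e = int(row["start_sample"]), int(row["end_sample"])
        t = np.arange(s, e) / fs
        if kind == "spike":
            disp[s:e] *= cfg.spike_factor
            accel[s:e] *= cfg.spike_factor
        elif kind == "bump":
            center = 0.5 * (row["i_time"] + row["k_time"])
            height = cfg.bump_rel_height * (row["j_amp"] - row["i_amp"])
            sig = cfg.bump_width_s
            g = height * np.exp(-0.5 * ((t - center) / sig) ** 2)
            disp[s:e] += g
            accel[s:e] += g * (((t - center) / sig) ** 2 - 1.0) / sig**2
        else:  # wander
            amp = cfg.wander_rel_amp * (row["j_amp"] - row["i_amp"])
            w = 2.0 * np.pi * cfg.wander_freq_hz
            disp[s:e] += amp * np.sin(w * (t - t[0]))
            accel[s:e] += -amp * w**2 * np.sin(w * (t - t[0]))
        idx = beats.index[pos]
        new_beats.loc[idx, "corrupted"] = True
        new_beats.loc[idx, "artifact"] = kind

    channels = dict(record.channels)
    channels["bcg_scale_disp"] = disp
    channels["bcg_arm_accel"] = accel
    new_record = SubjectRecord(subject_id=record.subject_id,
                               sampling_rate_hz=fs, channels=channels,
                               periods=list(record.periods))
    return new_record, GroundTruth(beats=new_beats, seed=truth.seed,
                                   coupling=truth.coupling)


def generate_subject(
    protocol: ProtocolConfig,
    morph: MorphologyConfig,
    noise: NoiseConfig,
    seed: int,
    subject_id: str = "S00",
    artifacts: ArtifactConfig | None = None,
    fs: float = 1000.0,
) -> tuple[SubjectRecord, GroundTruth]:
    """Full generation for one subject: trajectory, assembly, artifacts."""
    traj = make_cv_trajectories(protocol, derive_seed(seed, "trajectory"))
    record, truth = assemble_subject(
        traj, morph, noise, derive_seed(seed, "assembly"),
        subject_id=subject_id, fs=fs)
    if artifacts is not None:
        record, truth = inject_artifacts(
            record, truth, artifacts, derive_seed(seed, "artifacts"))
    return record, truth
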