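"""End-to-end orchestration: pre-conditioning, transformation, features,
regression — with per-rule removal logging and reproducible seeding.

Two analysis tracks run in parallel for every subject: the measured
weighing-scale BCG ("scale") and the synthetic scale BCG transformed from
the armband acceleration ("synthetic"). Both share the ECG gating, the
reference CV parameters and the PPG foot; they differ only in the BCG
channel feeding fiducial labeling and features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, derive_seed
from .errors import DataError, ProcessingError, UnlabelableBeat
from .fiducials import (FEATURE_NAMES, compute_reference_cv, detect_ppg_foot,
                        extract_features, label_ijk)
from .precondition import (align_beats, detect_r_waves, ema_smooth_beats,
                           gate_beats, reject_amplitude_outliers,
                           segment_periods, zero_phase_filter)
from .regression import (apply_exclusions, cohort_summary, evaluate_models,
                         fit_all_regressions, make_representatives,
                         merge_bootstrap, models_to_frame,
                         remove_feature_outliers)
from .scale_transform import assess_beat_quality, transform_armband
from .synth.assemble import SubjectRecord
from .synth.protocol import CV_PARAMS, PERIOD_LABELS

SOURCES = ("scale", "synthetic")
_SOURCE_CHANNEL = {"scale": "bcg_scale_disp", "synthetic": "bcg_synth"}


@dataclass
class SubjectResult:
    subject_id: str
    features: dict[str, pd.DataFrame]          # per source: one row per beat
    quality: dict[str, pd.DataFrame]
    removal_log: pd.DataFrame                  # per period/rule removal counts
    removal_fractions: dict[str, dict[str, float]]   # source -> period -> frac


@dataclass
class PipelineResult:
    config: PipelineConfig
    subjects: list[SubjectResult]
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    models: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, pd.DataFrame] = field(default_factory=dict)
    retained: dict[str, set] = field(default_factory=dict)


def process_subject(record: SubjectRecord, config: PipelineConfig,
                    sources: tuple[str, ...] = SOURCES) -> SubjectResult:
    """Pre-condition, transform and featurize one subject, period by period."""
    fs = record.sampling_rate_hz
    feature_rows: dict[str, list[dict]] = {s: [] for s in sources}
    quality_rows: dict[str, list[pd.DataFrame]] = {s: [] for s in sources}
    log_rows: list[dict] = []
    fractions: dict[str, dict[str, float]] = {s: {} for s in sources}

    for label, chans in segment_periods(record):
        missing = [c for c in ("ecg", "bp", "bcg_arm_accel", "bcg_scale_disp",
                               "ppg") if c not in chans]
        if missing:
            raise DataError(f"period {label}: missing channel(s) {missing}")
        filt = {
            "ecg": zero_phase_filter(chans["ecg"], config.ecg_bp_filter, fs),
            "bp": zero_phase_filter(chans["bp"], config.ecg_bp_filter, fs),
            "bcg_arm_accel": zero_phase_filter(
                chans["bcg_arm_accel"], config.bcg_ppg_filter, fs),
            "bcg_scale_disp": zero_phase_filter(
                chans["bcg_scale_disp"], config.bcg_ppg_filter, fs),
            "ppg": zero_phase_filter(chans["ppg"], config.bcg_ppg_filter, fs),
        }
        for aux in ("sv", "co", "tpr"):
            if aux in chans:
                filt[aux] = chans[aux]

        r_times = detect_r_waves(filt["ecg"], fs)
        if len(r_times) < 3:
            warnings.warn(f"period {label}: too few R waves; period skipped")
            for s in sources:
                fractions[s][label] = 1.0
            continue
        hr_hz = 1.0 / float(np.median(np.diff(r_times)))

        if "synthetic" in sources:
            synth, cutoff, peaks = transform_armband(
                chans["bcg_arm_accel"], fs, hr_hint_hz=hr_hz,
                hpf_order=config.hpf_order,
                hr_multiple=config.cutoff_hr_multiple)
            filt["bcg_synth"] = synth

        beats = gate_beats(filt, r_times, fs, config.gating_fraction)
        n_gated = len(beats)
        if n_gated < config.window_width:
            warnings.warn(f"period {label}: only {n_gated} beats; period skipped")
            for s in sources:
                fractions[s][label] = 1.0
            continue

        retained, removed_arm = reject_amplitude_outliers(
            beats, "bcg_arm_accel", config.mad_multiplier, config.mad_scale)
        retained, removed_scale = reject_amplitude_outliers(
            retained, "bcg_scale_disp", config.mad_multiplier, config.mad_scale)
        removed_amp = set(removed_arm) | set(removed_scale)

        smooth_channels = tuple(c for c in
                                ("bcg_arm_accel", "bcg_scale_disp", "bcg_synth")
                                if c in filt)
        smoothed = ema_smooth_beats(retained, config.ema_span, smooth_channels)

        for source in sources:
            ch = _SOURCE_CHANNEL[source]
            stack = np.asarray([b.channels[ch] for b in smoothed])
            r_idx = int(round(np.median(
                [(b.r_time - b.gate_start / fs) * fs for b in smoothed])))
            report = assess_beat_quality(
                stack, fs, r_index=r_idx,
                deviation_ratio_threshold=config.deviation_ratio_threshold,
                corr_threshold=config.ensemble_corr_threshold,
                prominence_threshold=config.prominence_threshold)
            if report is None:
                fractions[source][label] = 1.0
                continue
            report.insert(0, "beat_index",
                          [b.beat_index for b in smoothed])
            report.insert(0, "period", label)
            quality_rows[source].append(report)
            removed_quality = {b.beat_index
                               for b, rm in zip(smoothed, report["removed"]) if rm}

            # Fiducials and features on quality-passed, EMA-smoothed beats.
            passed = [b for b in smoothed if b.beat_index not in removed_quality]
            labeled: dict[int, tuple] = {}
            n_unlabelable = 0
            for b in passed:
                try:
                    fid = label_ijk(b.channels[ch], fs,
                                    r_index=int(round(
                                        (b.r_time - b.gate_start / fs) * fs)))
                    fid.ppg_foot_time = detect_ppg_foot(b.channels["ppg"], fs)
                except UnlabelableBeat:
                    n_unlabelable += 1
                    continue
                labeled[b.beat_index] = (b, fid)

            for idx, (b, fid) in labeled.items():
                nxt = labeled.get(idx + 1)
                next_j = None
                if nxt is not None:
                    nb, nfid = nxt
                    next_j = nfid.j_time + (nb.gate_start - b.gate_start) / fs
                try:
                    feats = extract_features(fid, next_j, b.channels[ch])
                    cv = compute_reference_cv(
                        b.channels["bp"], b.channels["sv"],
                        b.channels["co"], b.channels["tpr"])
                except ProcessingError:
                    n_unlabelable += 1
                    continue
                feature_rows[source].append({
                    "subject_id": record.subject_id, "period": label,
                    "beat_index": idx, **feats, **cv})

            n_removed = len(removed_amp) + len(removed_quality) + n_unlabelable
            fractions[source][label] = n_removed / n_gated
            log_rows.append({
                "subject_id": record.subject_id, "period": label,
                "source": source, "n_gated": n_gated,
                "removed_amplitude": len(removed_amp),
                "removed_quality": len(removed_quality),
                "unlabelable": n_unlabelable,
            })

    features = {
        s: (pd.DataFrame(feature_rows[s]) if feature_rows[s]
            else pd.DataFrame(columns=["subject_id", "period", "beat_index",
                                       *FEATURE_NAMES, *CV_PARAMS]))
        for s in sources
    }
    quality = {
        s: (pd.concat(quality_rows[s], ignore_index=True) if quality_rows[s]
            else pd.DataFrame())
        for s in sources
    }
    return SubjectResult(
        subject_id=record.subject_id, features=features, quality=quality,
        removal_log=pd.DataFrame(log_rows), removal_fractions=fractions)


def clean_features(features: pd.DataFrame, config: PipelineConfig
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Windowed-MAD outlier removal per period across all feature series.

    A beat is dropped when any of its feature series flags it; the returned
    fractions count the dropped share per period (merged later with the
    pre-conditioning removal fractions for the exclusion rules).
    """
    kept_frames = []
    fractions: dict[str, float] = {}
    for period, grp in features.groupby("period", sort=False):
        grp = grp.sort_values("beat_index")
        bad: set[int] = set()
        for col in FEATURE_NAMES:
            series = grp[col].to_numpy(dtype=float)
            finite = np.isfinite(series)
            _, removed = remove_feature_outliers(
                series[finite], config.mad_multiplier, config.mad_scale)
            finite_pos = np.flatnonzero(finite)
            bad.update(int(grp["beat_index"].iloc[finite_pos[i]])
                       for i in removed)
        fractions[period] = len(bad) / len(grp) if len(grp) else 1.0
        kept_frames.append(grp[~grp["beat_index"].isin(bad)])
    cleaned = pd.concat(kept_frames, ignore_index=True) if kept_frames \
        else features.iloc[0:0]
    return cleaned, fractions


def analyze_cohort(results: list[SubjectResult], config: PipelineConfig,
                   sources: tuple[str, ...] = SOURCES) -> PipelineResult:
    """Feature cleaning, exclusions, bootstrap regression, cohort summary."""
    out = PipelineResult(config=config, subjects=results)
    for source in sources:
        cleaned_tables = []
        combined_fracs: dict[tuple[str, str], float] = {}
        for res in results:
            feats = res.features[source]
            if feats.empty:
                for per in PERIOD_LABELS:
                    combined_fracs[(res.subject_id, per)] = 1.0
                continue
            cleaned, clean_fracs = clean_features(feats, config)
            cleaned_tables.append(cleaned)
            for per in res.removal_fractions[source]:
                pre = res.removal_fractions[source].get(per, 1.0)
                post = clean_fracs.get(per, 1.0)
                # Combined share of gated beats removed by any rule.
                combined_fracs[(res.subject_id, per)] = min(
                    1.0, 1.0 - (1.0 - pre) * (1.0 - post))
        retained = apply_exclusions(
            combined_fracs, config.removal_fraction_threshold,
            config.min_periods)
        out.retained[source] = retained
        if not cleaned_tables:
            out.features[source] = pd.DataFrame()
            out.models[source] = pd.DataFrame()
            out.summary[source] = pd.DataFrame()
            continue
        all_feats = pd.concat(cleaned_tables, ignore_index=True)
        mask = [(s, p) in retained
                for s, p in zip(all_feats["subject_id"], all_feats["period"])]
        all_feats = all_feats[np.asarray(mask, dtype=bool)]
        out.features[source] = all_feats

        model_frames = []
        for subject_id, table in all_feats.groupby("subject_id"):
            reps = make_representatives(table, subject_id,
                                        width=config.window_width)
            for target in CV_PARAMS:
                n_reps = sum(r.target == target for r in reps)
                if n_reps < 3:
                    continue
                seed = derive_seed(config.master_seed,
                                   f"boot:{source}:{subject_id}:{target}")
                try:
                    boot = merge_bootstrap(reps, target, config.n_bootstrap,
                                           config.window_width, seed)
                    models = fit_all_regressions(boot, target,
                                                 max_order=config.max_model_order)
                except DataError as exc:
                    warnings.warn(f"{subject_id}/{target}: {exc}")
                    continue
                models = evaluate_models(models, reps, config.r_threshold)
                model_frames.append(models_to_frame(models, subject_id))
        out.models[source] = (pd.concat(model_frames, ignore_index=True)
                              if model_frames else pd.DataFrame())
        out.summary[source] = (cohort_summary(out.models[source])
                               if len(out.models[source]) else pd.DataFrame())
    return out


def run_pipeline(records: list[SubjectRecord], config: PipelineConfig,
                 out_dir: str | Path | None = None,
                 sources: tuple[str, ...] = SOURCES) -> PipelineResult:
    """Run the full chain on a list of subject records; optionally persist.

    Outputs (per source): a per-beat feature table, a beat-quality table,
    a ranked model report and a cohort summary; plus a removal log and the
    effective configuration. Bit-reproducible under a fixed master seed.
    """
    results = [process_subject(rec, config, sources) for rec in records]
    out = analyze_cohort(results, config, sources)
    if out_dir is not None:
        write_outputs(out, out_dir, sources)
    return out


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  sources: tuple[str, ...] = SOURCES) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ff = "%.8g"
    for source in sources:
        if source in result.features and len(result.features[source]):
            result.features[source].to_csv(
                out_dir / f"features_{source}.csv", index=False, float_format=ff)
        if source in result.models and len(result.models[source]):
            result.models[source].to_csv(
                out_dir / f"models_{source}.csv", index=False, float_format=ff)
        if source in result.summary and len(result.summary[source]):
            result.summary[source].to_csv(
                out_dir / f"summary_{source}.csv", index=False, float_format=ff)
        qual = [r.quality[source] for r in result.subjects
                if len(r.quality[source])]
        if qual:
            pd.concat(qual, ignore_index=True).to_csv(
                out_dir / f"quality_{source}.csv", index=False, float_format=ff)
    logs = [r.removal_log for r in result.subjects if len(r.removal_log)]
    if logs:
        pd.concat(logs, ignore_index=True).to_csv(
            out_dir / "removal_log.csv", index=False, float_format=ff)
    (out_dir / "config.yaml").write_text(result.config.to_yaml())
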