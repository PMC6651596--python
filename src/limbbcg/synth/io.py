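"""Delimited-text persistence for subject records and ground truth.

One CSV signal table per subject (sample_index plus one column per channel),
a YAML sidecar with the sampling rate, subject id and ordered half-open
period ranges, and a ground-truth CSV keyed by beat index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..errors import DataError
from .assemble import GroundTruth, SubjectRecord

SIGNALS_SUFFIX = "_signals.csv"
ANNOT_SUFFIX = "_annotations.yaml"
TRUTH_SUFFIX = "_truth.csv"


def write_subject(
    record: SubjectRecord,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    float_format: str = "%.8g",
) -> Path:
    """Write signals, annotation sidecar and (optionally) ground truth.

    Returns the signal-table path. The fixed float format keeps repeated
    runs byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = record.subject_id

    df = pd.DataFrame({"sample_index": np.arange(record.n_samples)})
    for name, series in record.channels.items():
        df[name] = series
    sig_path = out_dir / f"{base}{SIGNALS_SUFFIX}"
    df.to_csv(sig_path, index=False, float_format=float_format)

    sidecar = {
        "subject_id": record.subject_id,
        "sampling_rate_hz": float(record.sampling_rate_hz),
        "periods": [
            {"label": lab, "start": int(s), "end": int(e)}
            for lab, s, e in record.periods
        ],
    }
    (out_dir / f"{base}{ANNOT_SUFFIX}").write_text(
        yaml.safe_dump(sidecar, sort_keys=False))

    if truth is not None:
        truth.beats.to_csv(out_dir / f"{base}{TRUTH_SUFFIX}",
                           float_format=float_format)
    return sig_path


def read_subject(
    out_dir: str | Path, subject_id: str
) -> tuple[SubjectRecord, GroundTruth | None]:
    """Read a subject written by :func:`write_subject`."""
    out_dir = Path(out_dir)
    sig_path = out_dir / f"{subject_id}{SIGNALS_SUFFIX}"
    ann_path = out_dir / f"{subject_id}{ANNOT_SUFFIX}"
    if not sig_path.exists() or not ann_path.exists():
        raise DataError(f"missing subject files for {subject_id!r} in {out_dir}")
    df = pd.read_csv(sig_path)
    sidecar = yaml.safe_load(ann_path.read_text())
    channels = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "sample_index"}
    record = SubjectRecord(
        subject_id=sidecar["subject_id"],
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        channels=channels,
        periods=[(p["label"], int(p["start"]), int(p["end"]))
                 for p in sidecar["periods"]],
    )
    truth = None
    truth_path = out_dir / f"{subject_id}{TRUTH_SUFFIX}"
    if truth_path.exists():
        beats = pd.read_csv(truth_path, index_col="beat")
        beats["artifact"] = beats["artifact"].fillna("")
        truth = GroundTruth(beats=beats, seed=-1, coupling={})
    return record, truth


def list_subjects(out_dir: str | Path) -> list[str]:
    out_dir = Path(out_dir)
    return sorted(p.name[: -len(SIGNALS_SUFFIX)]
                  for p in out_dir.glob(f"*{SIGNALS_SUFFIX}"))
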