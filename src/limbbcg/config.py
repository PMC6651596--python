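"""Pipeline configuration.

Every numeric constant of the processing chain lives here with its published
default: the filter specifications, the 10% pre-R gating fraction, the
3 x 1.4826 scaled-MAD outlier rule, the 10-beat EMA span, the 4th-order
post-integration high-pass, the beat-quality thresholds (deviation ratio 1,
ensemble correlation 0.5, distortion prominence 0.25), the 11-sample extremum
window, the 100-draw parametric bootstrap, the 75% period-removal threshold,
the 6-period minimum per subject, and the r >= 0.7 model-acceptance bar.
All are overridable and a config round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from .errors import ConfigurationError


@dataclass
class FilterSpec:
    """A Butterworth filter specification.

    kind is one of "lowpass", "highpass", "bandpass"; corners in Hz
    (one corner for low/high-pass, two for band-pass). zero_phase selects
    forward-backward application (zero group delay, squared magnitude).
    """

    kind: str
    order: int
    corners: tuple[float, ...]
    zero_phase: bool = True

    def __post_init__(self) -> None:
        self.corners = tuple(float(c) for c in self.corners)
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(self.corners) != n_expected:
            raise ConfigurationError(
                f"{self.kind} filter needs {n_expected} corner(s), got {self.corners}"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def validate_for_rate(self, fs: float) -> None:
        for c in self.corners:
            if not 0.0 < c < fs / 2.0:
                raise ConfigurationError(
                    f"corner {c} Hz outside (0, {fs / 2}) for fs={fs}"
                )


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis pipeline (published defaults)."""

    sampling_rate_hz: float = 1000.0
    # Pre-conditioning
    ecg_bp_filter: FilterSpec = field(
        default_factory=lambda: FilterSpec("lowpass", 1, (20.0,))
    )
    bcg_ppg_filter: FilterSpec = field(
        default_factory=lambda: FilterSpec("bandpass", 2, (0.5, 10.0))
    )
    gating_fraction: float = 0.1
    mad_multiplier: float = 3.0
    mad_scale: float = 1.4826
    ema_span: int = 10
    # Armband -> scale transformation and beat quality
    hpf_order: int = 4
    cutoff_hr_multiple: float = 2.5
    deviation_ratio_threshold: float = 1.0
    ensemble_corr_threshold: float = 0.5
    prominence_threshold: float = 0.25
    # Regression analysis
    window_width: int = 11
    n_bootstrap: int = 100
    removal_fraction_threshold: float = 0.75
    min_periods: int = 6
    r_threshold: float = 0.7
    max_model_order: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.ecg_bp_filter, dict):
            self.ecg_bp_filter = FilterSpec(**self.ecg_bp_filter)
        if isinstance(self.bcg_ppg_filter, dict):
            self.bcg_ppg_filter = FilterSpec(**self.bcg_ppg_filter)
        for name in (
            "gating_fraction",
            "mad_multiplier",
            "mad_scale",
            "deviation_ratio_threshold",
            "ensemble_corr_threshold",
            "prominence_threshold",
            "removal_fraction_threshold",
            "r_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("ema_span", "hpf_order", "window_width", "n_bootstrap",
                     "min_periods", "max_model_order"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        self.ecg_bp_filter.validate_for_rate(self.sampling_rate_hz)
        self.bcg_ppg_filter.validate_for_rate(self.sampling_rate_hz)

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ecg_bp_filter", "bcg_ppg_filter"):
            d[key]["corners"] = list(d[key]["corners"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


def derive_seed(master_seed: int, label: str) -> int:
    """Fan a master seed out to a per-stage seed, stably and below 2**31.

    Stages are independently reproducible: the same (master seed, label) pair
    always maps to the same stage seed.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31)
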