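"""Protocol definition and beat-resolved cardiovascular trajectories.

The protocol alternates rest and intervention periods:
R1, cold pressor (CP), R2, mental arithmetic (MA), R3, slow breathing (SB),
R4, breath hold (BH), R5. Interventions shift the cardiovascular parameters
relative to the rest baseline with known signs: the pressures (DP, PP, SP)
and TPR rise under CP, MA, and BH and fall under SB; SV falls under every
intervention; CO rises under CP and MA and falls slightly under SB and BH.
Those signs are exactly the published extremum-direction table, which the
extremum-window search downstream consumes.

Four primary parameters are simulated directly (DP, PP, SV, HR); the rest are
derived so the physiological identities hold by construction:
SP = DP + PP, CO = SV * HR / 1000, TPR = MAP / CO with MAP = DP + PP/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

PERIOD_LABELS = ("R1", "CP", "R2", "MA", "R3", "SB", "R4", "BH", "R5")
REST_LABELS = ("R1", "R2", "R3", "R4", "R5")
INTERVENTION_LABELS = ("CP", "MA", "SB", "BH")

#: Simulated directly by the generator.
PRIMARY_PARAMS = ("dp", "pp", "sv", "hr")
#: The six cardiovascular parameters targeted by the regression analysis.
CV_PARAMS = ("dp", "pp", "sp", "sv", "co", "tpr")

#: Published within-period extremum direction for each CV parameter
#: ("min" or "max"), per period.
EXTREMUM_DIRECTIONS: dict[str, dict[str, str]] = {
    "dp": {"R1": "min", "CP": "max", "R2": "min", "MA": "max", "R3": "min",
           "SB": "min", "R4": "min", "BH": "max", "R5": "min"},
    "pp": {"R1": "min", "CP": "max", "R2": "min", "MA": "max", "R3": "min",
           "SB": "min", "R4": "min", "BH": "max", "R5": "min"},
    "sp": {"R1": "min", "CP": "max", "R2": "min", "MA": "max", "R3": "min",
           "SB": "min", "R4": "min", "BH": "max", "R5": "min"},
    "sv": {"R1": "max", "CP": "min", "R2": "max", "MA": "min", "R3": "max",
           "SB": "min", "R4": "max", "BH": "min", "R5": "max"},
    "co": {"R1": "min", "CP": "max", "R2": "min", "MA": "max", "R3": "min",
           "SB": "min", "R4": "min", "BH": "min", "R5": "min"},
    "tpr": {"R1": "min", "CP": "max", "R2": "min", "MA": "max", "R3": "min",
            "SB": "min", "R4": "min", "BH": "max", "R5": "min"},
}


@dataclass
class BeatCV:
    """Per-beat cardiovascular state.

    dp/sp/pp in mmHg, sv in mL, co in L/min, tpr in mmHg*min/L, hr in
    beats/min. PP = SP - DP and CO ~ SV*HR/1000 are structural identities.
    """

    dp: float
    sp: float
    pp: float
    sv: float
    co: float
    tpr: float
    hr: float

    def validate(self, co_rtol: float = 1e-6) -> None:
        if not (self.dp > 0 and self.pp > 0 and self.sv > 0
                and self.co > 0 and self.tpr > 0):
            raise ConfigurationError(f"non-positive cardiovascular value: {self}")
        if abs(self.pp - (self.sp - self.dp)) > 1e-9 * max(1.0, self.sp):
            raise ConfigurationError("pp != sp - dp")
        if abs(self.co - self.sv * self.hr / 1000.0) > co_rtol * self.co:
            raise ConfigurationError("co inconsistent with sv*hr/1000")


def derive_cv(dp: float, pp: float, sv: float, hr: float) -> BeatCV:
    """Complete a cardiovascular state from the four primary parameters."""
    sp = dp + pp
    co = sv * hr / 1000.0
    map_ = dp + pp / 3.0  # standard mean-arterial-pressure estimate
    tpr = map_ / co
    return BeatCV(dp=dp, sp=sp, pp=pp, sv=sv, co=co, tpr=tpr, hr=hr)


@dataclass
class InterventionEffect:
    """Fractional steady-state shifts of the primary parameters in a period.

    effects maps a primary parameter name to a signed fraction of baseline
    (e.g. +0.15 means a 15% rise at full effect); ramp_s is the onset ramp
    duration at the period boundary.
    """

    effects: dict[str, float] = field(default_factory=dict)
    ramp_s: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.effects) - set(PRIMARY_PARAMS)
        if unknown:
            raise ConfigurationError(f"effects on unknown parameters: {unknown}")
        if self.ramp_s < 0:
            raise ConfigurationError("ramp_s must be >= 0")


@dataclass
class PeriodSpec:
    label: str
    duration_s: float
    effect: InterventionEffect = field(default_factory=InterventionEffect)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("period duration must be positive")


@dataclass
class ProtocolConfig:
    """The nine-period protocol plus the baseline state and beat noise."""

    periods: list[PeriodSpec]
    baseline_dp: float = 80.0
    baseline_pp: float = 40.0
    baseline_sv: float = 70.0
    baseline_hr: float = 60.0
    #: Beat-to-beat multiplicative noise SD (fraction of the local mean) applied
    #: independently to each primary parameter.
    cv_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.cv_noise_sd < 0:
            raise ConfigurationError("cv_noise_sd must be >= 0")
        self.baseline().validate()

    def baseline(self) -> BeatCV:
        return derive_cv(self.baseline_dp, self.baseline_pp,
                         self.baseline_sv, self.baseline_hr)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.periods)

    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.periods))


#: Default intervention effects (fraction of baseline at full effect).
#: Chosen so every derived parameter's sign matches the published direction
#: table; magnitudes are typical young-adult responses to these maneuvers.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "CP": {"dp": 0.15, "pp": 0.20, "sv": -0.10, "hr": 0.15},
    "MA": {"dp": 0.12, "pp": 0.08, "sv": -0.08, "hr": 0.12},
    "SB": {"dp": -0.08, "pp": -0.12, "sv": -0.08, "hr": 0.04},
    "BH": {"dp": 0.10, "pp": 0.18, "sv": -0.08, "hr": -0.02},
}

#: Published period durations (seconds); breath hold is not reported by the
#: protocol and defaults to 60 s, exposed as configuration.
DEFAULT_DURATIONS_S: dict[str, float] = {
    "R1": 90.0, "CP": 120.0, "R2": 90.0, "MA": 180.0, "R3": 90.0,
    "SB": 180.0, "R4": 90.0, "BH": 60.0, "R5": 90.0,
}


def default_protocol(
    bh_duration_s: float = 60.0,
    duration_scale: float = 1.0,
    ramp_s: float = 10.0,
    cv_noise_sd: float = 0.02,
    effects: dict[str, dict[str, float]] | None = None,
) -> ProtocolConfig:
    """The nine-period protocol with published durations and default effects.

    duration_scale shrinks every period proportionally for small test runs.
    """
    effects = DEFAULT_EFFECTS if effects is None else effects
    periods = []
    for label in PERIOD_LABELS:
        dur = bh_duration_s if label == "BH" else DEFAULT_DURATIONS_S[label]
        eff = InterventionEffect(effects=dict(effects.get(label, {})), ramp_s=ramp_s)
        periods.append(PeriodSpec(label, dur * duration_scale, eff))
    cfg = ProtocolConfig(periods=periods, cv_noise_sd=cv_noise_sd)
    validate_directions(cfg)
    return cfg


def _steady_state_values(protocol: ProtocolConfig, label: str) -> dict[str, float]:
    """Derived CV values at full effect in the named period."""
    spec = next(p for p in protocol.periods if p.label == label)
    base = {
        "dp": protocol.baseline_dp, "pp": protocol.baseline_pp,
        "sv": protocol.baseline_sv, "hr": protocol.baseline_hr,
    }
    vals = {q: base[q] * (1.0 + spec.effect.effects.get(q, 0.0))
            for q in PRIMARY_PARAMS}
    cv = derive_cv(vals["dp"], vals["pp"], vals["sv"], vals["hr"])
    return {q: getattr(cv, q) for q in CV_PARAMS}


def validate_directions(protocol: ProtocolConfig) -> None:
    """Check that nonzero steady-state shifts match the direction table.

    A missing period or parameter cell, or a sign conflicting with the table,
    is a configuration error.
    """
    if set(protocol.labels) != set(PERIOD_LABELS):
        raise ConfigurationError(
            f"protocol must contain the nine periods {PERIOD_LABELS}, "
            f"got {protocol.labels}"
        )
    baseline = {q: getattr(protocol.baseline(), q) for q in CV_PARAMS}
    for param in CV_PARAMS:
        table = EXTREMUM_DIRECTIONS.get(param)
        if table is None or set(table) != set(PERIOD_LABELS):
            raise ConfigurationError(f"direction table incomplete for {param!r}")
        for label in INTERVENTION_LABELS:
            value = _steady_state_values(protocol, label)[param]
            shift = value - baseline[param]
            if abs(shift) < 1e-9 * abs(baseline[param]):
                continue
            expected = +1 if table[label] == "max" else -1
            if np.sign(shift) != expected:
                raise ConfigurationError(
                    f"{param} shift in {label} has sign {np.sign(shift):+.0f}, "
                    f"direction table requires {table[label]!r}"
                )


def ramp_multiplier(
    t: float, boundaries: list[float], targets: list[float], ramps: list[float]
) -> float:
    """Piecewise-linear onset multiplier at time ``t``.

    Period k (starting at boundaries[k]) ramps linearly from the previous
    period's target multiplier to its own over ramps[k] seconds, then holds.
    """
    k = int(np.searchsorted(boundaries, t, side="right")) - 1
    k = max(0, min(k, len(targets) - 1))
    prev = 1.0 if k == 0 else targets[k - 1]
    if ramps[k] <= 0:
        return targets[k]
    frac = min(1.0, (t - boundaries[k]) / ramps[k])
    return prev + (targets[k] - prev) * frac


def make_cv_trajectories(
    protocol: ProtocolConfig, seed: int
) -> pd.DataFrame:
    """Generate the per-beat cardiovascular trajectory for one subject.

    Returns a DataFrame with one row per beat: ``beat``, ``period``,
    ``t_onset`` (s, noise-free nominal), the four primary parameters with
    beat-to-beat noise applied, and the derived sp/co/tpr. Deterministic
    under a fixed seed.
    """
    validate_directions(protocol)
    rng = np.random.default_rng(seed)
    boundaries = np.concatenate([[0.0], np.cumsum(
        [p.duration_s for p in protocol.periods])])
    starts = list(boundaries[:-1])
    total = boundaries[-1]
    base = {
        "dp": protocol.baseline_dp, "pp": protocol.baseline_pp,
        "sv": protocol.baseline_sv, "hr": protocol.baseline_hr,
    }
    targets = {
        q: [1.0 + p.effect.effects.get(q, 0.0) for p in protocol.periods]
        for q in PRIMARY_PARAMS
    }
    ramps = [p.effect.ramp_s for p in protocol.periods]

    rows = []
    t = 0.0
    beat = 0
    while t < total:
        k = int(np.searchsorted(boundaries, t, side="right")) - 1
        k = min(k, len(protocol.periods) - 1)
        label = protocol.periods[k].label
        vals = {}
        for q in PRIMARY_PARAMS:
            m = ramp_multiplier(t, starts, targets[q], ramps)
            noise = rng.normal(0.0, protocol.cv_noise_sd) if protocol.cv_noise_sd else 0.0
            vals[q] = base[q] * m * (1.0 + noise)
        cv = derive_cv(vals["dp"], vals["pp"], vals["sv"], vals["hr"])
        rows.append({"beat": beat, "period": label, "t_onset": t,
                     **{q: getattr(cv, q) for q in CV_PARAMS}, "hr": cv.hr})
        t += 60.0 / cv.hr
        beat += 1
    return pd.DataFrame(rows)
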