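"""Feature cleaning, extremum windows, parametric bootstrap and regression.

Per subject and period, feature time series are cleaned with a sliding
9-sample scaled-MAD rule; periods losing more than 75% of their beats and
subjects with fewer than 6 usable periods are excluded. For each target
cardiovascular parameter the 11 consecutive beats whose mean is extremal in
the published per-period direction form the representative window; the same
beats provide the paired feature representatives (joint sampling). Each
representative is expanded into 100 parametric-bootstrap samples (each the
mean of 11 normal draws with the window mean and SD), merged across periods
(up to 900 per subject), and ordinary least squares is fitted exhaustively
for every single feature and every feature pair. Model validity is the
Pearson correlation between the measured representatives and the model
predictions across the subject's periods; r >= 0.7 marks an acceptable
model, and predictors are annotated with their physiological-relevance tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .fiducials import FEATURE_NAMES
from .robust import MAD_SCALE, scaled_mad
from .synth.protocol import CV_PARAMS, EXTREMUM_DIRECTIONS

#: Physiologically relevant predictors per target, from the mechanistic
#: account of the BCG (transit times track BP; wave amplitudes track pulse
#: pressure; the J-J interval tracks heart rate; amplitude x PTT^2 tracks
#: stroke volume). Used for annotation only, never for silent filtering.
RELEVANT_FEATURES: dict[str, tuple[str, ...]] = {
    "dp": ("PTT_I", "PTT_J", "A_I"),
    "pp": ("PTT_I", "PTT_J", "A_IJ", "A_JK", "A_J"),
    "sp": ("PTT_I", "PTT_J", "A_JK", "A_K", "A_IJ*PTT_I^2"),
    "sv": ("A_J", "A_JK", "T_JJ", "RMS", "A_IJ*PTT_I^2", "A_JK*PTT_I^2"),
    "co": ("T_JJ", "PTT_I", "PTT_J"),
    "tpr": ("T_JJ", "PTT_I", "PTT_J", "A_IJ*PTT_I^2", "A_JK*PTT_I^2"),
}


# --- feature-series outlier removal ---------------------------------------

def remove_feature_outliers(
    series: np.ndarray,
    multiplier: float = 3.0,
    scale: float = MAD_SCALE,
) -> tuple[np.ndarray, list[int]]:
    """Sliding windowed-MAD outlier removal over a feature time series.

    Each block of 3 consecutive samples is inspected against a 9-sample
    window (the block plus 3 samples before and 3 after); a sample is an
    outlier iff it deviates more than ``multiplier`` scaled MADs from the
    window median. At the series edges the nearest full 9-sample window is
    used. Series shorter than 9 pass through with a warning. Returns the
    cleaned series and the removed indices.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 9:
        warnings.warn("series shorter than 9 samples; outlier removal skipped")
        return x.copy(), []
    removed: list[int] = []
    for block in range(0, n, 3):
        lo = min(max(block - 3, 0), n - 9)
        win = x[lo:lo + 9]
        med = np.median(win)
        smad = scaled_mad(win, scale)  # zero MAD => strict comparison to median
        for i in range(block, min(block + 3, n)):
            if np.abs(x[i] - med) > multiplier * smad:
                removed.append(i)
    keep = np.setdiff1d(np.arange(n), removed)
    return x[keep], removed


# --- period / subject exclusion -------------------------------------------

def apply_exclusions(
    removal_fractions: dict[tuple[str, str], float],
    removal_threshold: float = 0.75,
    min_periods: int = 6,
) -> set[tuple[str, str]]:
    """Retain (subject, period) pairs surviving the published exclusion rules.

    A period is excluded when more than ``removal_threshold`` of its beats
    were removed; a subject is excluded when fewer than ``min_periods``
    periods remain.
    """
    for frac in removal_fractions.values():
        if not 0.0 <= frac <= 1.0:
            raise DataError("removal fractions must lie in [0, 1]")
    retained = {key for key, frac in removal_fractions.items()
                if frac <= removal_threshold}
    by_subject: dict[str, int] = {}
    for subj, _ in retained:
        by_subject[subj] = by_subject.get(subj, 0) + 1
    return {(subj, per) for subj, per in retained
            if by_subject.get(subj, 0) >= min_periods}


# --- extremum windows and representatives ----------------------------------

@dataclass
class RepresentativePoint:
    """Window mean/SD of one period's target parameter and features."""

    subject_id: str
    period: str
    target: str
    window: tuple[int, int]                  # [start, end) in retained-beat order
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def locate_extremum_window(
    values: np.ndarray, direction: str, width: int = 11
) -> tuple[int, float, float]:
    """Find the ``width`` consecutive samples with the extremal sliding mean.

    direction is "min" or "max"; ties break to the earliest window. Returns
    (start index, window mean, window SD). A series shorter than the window
    cannot provide a representative.
    """
    x = np.asarray(values, dtype=float)
    if direction not in ("min", "max"):
        raise ConfigurationError(f"direction must be min or max, got {direction!r}")
    if len(x) < width:
        raise DataError(f"series length {len(x)} < window width {width}")
    means = np.convolve(x, np.ones(width) / width, mode="valid")
    start = int(np.argmax(means)) if direction == "max" else int(np.argmin(means))
    win = x[start:start + width]
    return start, float(win.mean()), float(win.std(ddof=1))


def make_representatives(
    beat_table: pd.DataFrame,
    subject_id: str,
    targets: tuple[str, ...] = CV_PARAMS,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    width: int = 11,
) -> list[RepresentativePoint]:
    """Representative points for every (period, target) of one subject.

    ``beat_table`` holds the retained beats of one subject with period
    labels, target CV columns and feature columns. For each target the
    window location is defined by that target's published extremum direction
    in the period; features are averaged over the same beats so the
    feature-target pairing is preserved.
    """
    reps: list[RepresentativePoint] = []
    for period, group in beat_table.groupby("period", sort=False):
        for target in targets:
            direction = EXTREMUM_DIRECTIONS[target][period]
            sub = group.dropna(subset=[target, *feature_names])
            if len(sub) < width:
                continue
            start, _, _ = locate_extremum_window(
                sub[target].to_numpy(), direction, width)
            win = sub.iloc[start:start + width]
            means = {c: float(win[c].mean()) for c in (target, *feature_names)}
            sds = {c: float(win[c].std(ddof=1)) for c in (target, *feature_names)}
            reps.append(RepresentativePoint(
                subject_id=subject_id, period=period, target=target,
                window=(start, start + width), means=means, sds=sds))
    return reps


# --- parametric bootstrap ---------------------------------------------------

def parametric_bootstrap(
    rep: RepresentativePoint,
    n_boot: int = 100,
    n_inner: int = 11,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo expansion of one representative point.

    Each variable is modeled as normal with the window mean and SD; each
    bootstrap sample is the average of ``n_inner`` independent draws, and
    ``n_boot`` samples are generated. Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, mean in rep.means.items():
        sd = rep.sds[name]
        if not np.isfinite(sd) or sd < 0:
            raise DataError(f"invalid SD for {name}: {sd}")
        draws = rng.normal(mean, sd, size=(n_boot, n_inner))
        out[name] = draws.mean(axis=1)
    df = pd.DataFrame(out)
    df.insert(0, "period", rep.period)
    return df


def merge_bootstrap(
    reps: list[RepresentativePoint],
    target: str,
    n_boot: int = 100,
    n_inner: int = 11,
    seed: int = 0,
) -> pd.DataFrame:
    """Merge the per-period bootstrap sets of one subject for one target."""
    frames = []
    for k, rep in enumerate(r for r in reps if r.target == target):
        frames.append(parametric_bootstrap(rep, n_boot, n_inner, seed + k))
    if not frames:
        raise DataError(f"no representatives for target {target!r}")
    return pd.concat(frames, ignore_index=True)


# --- exhaustive regression ---------------------------------------------------

@dataclass
class RegressionModel:
    target: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray          # per predictor
    intercept: float
    train_r: float
    eval_r: float = np.nan
    n_eval_periods: int = 0
    relevant: bool = False
    acceptable: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.predictors)].to_numpy(dtype=float)
        return X @ self.coefficients + self.intercept


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def fit_all_regressions(
    boot: pd.DataFrame,
    target: str,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    max_order: int = 2,
) -> list[RegressionModel]:
    """Ordinary least squares for every feature subset of size 1..max_order.

    With 16 features and max_order 2 this is 16 univariate plus 120
    bivariate candidates. Rank-deficient (collinear) designs are skipped
    with a note. Training r is the Pearson correlation between fitted and
    observed target values over the bootstrap samples.
    """
    if boot["period"].nunique() < 2:
        raise DataError("need >= 2 distinct periods to fit regressions")
    y = boot[target].to_numpy(dtype=float)
    models: list[RegressionModel] = []
    subsets: list[tuple[str, ...]] = []
    for order in range(1, max_order + 1):
        subsets.extend(combinations(feature_names, order))
    for predictors in subsets:
        X = boot[list(predictors)].to_numpy(dtype=float)
        design = np.column_stack([X, np.ones(len(X))])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(f"collinear design skipped: {predictors}")
            continue
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ beta
        models.append(RegressionModel(
            target=target, predictors=predictors,
            coefficients=beta[:-1], intercept=float(beta[-1]),
            train_r=_pearson(pred, y),
            relevant=all(p in RELEVANT_FEATURES.get(target, ()) for p in predictors),
        ))
    return models


def evaluate_models(
    models: list[RegressionModel],
    reps: list[RepresentativePoint],
    r_threshold: float = 0.7,
) -> list[RegressionModel]:
    """Test models on the measured representatives across periods.

    eval_r is the Pearson correlation between the measured target
    representatives and the model predictions over the subject's retained
    periods; fewer than 3 representative points leaves the model unrated.
    Models are returned ranked by eval_r (descending, NaN last) and flagged
    acceptable when eval_r >= r_threshold.
    """
    if not models:
        return []
    target = models[0].target
    mine = [r for r in reps if r.target == target]
    if len(mine) < 3:
        warnings.warn(f"fewer than 3 representative points for {target!r}; "
                      "evaluation skipped")
        return sorted(models, key=lambda m: -m.train_r)
    table = pd.DataFrame([r.means for r in mine])
    measured = table[target].to_numpy(dtype=float)
    for m in models:
        pred = m.predict(table)
        m.eval_r = _pearson(measured, pred)
        m.n_eval_periods = len(mine)
        m.acceptable = bool(np.isfinite(m.eval_r) and m.eval_r >= r_threshold)
    return sorted(models, key=lambda m: (-(m.eval_r if np.isfinite(m.eval_r)
                                           else -np.inf), m.predictors))


def models_to_frame(models: list[RegressionModel],
                    subject_id: str | None = None) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append({
            **({"subject_id": subject_id} if subject_id is not None else {}),
            "target": m.target,
            "order": len(m.predictors),
            "predictors": "+".join(m.predictors),
            "coefficients": ";".join(f"{c:.8g}" for c in m.coefficients),
            "intercept": m.intercept,
            "train_r": m.train_r,
            "eval_r": m.eval_r,
            "n_eval_periods": m.n_eval_periods,
            "relevant": m.relevant,
            "acceptable": m.acceptable,
        })
    return pd.DataFrame(rows)


def cohort_summary(all_models: pd.DataFrame) -> pd.DataFrame:
    """Cohort table: per target and order, the best feature set by mean eval r.

    For each target and model order the candidate feature set maximizing the
    across-subject mean eval r is reported with mean +- SE, mirroring a
    per-subject develop/evaluate analysis summarized over the cohort.
    """
    rows = []
    for (target, order), grp in all_models.groupby(["target", "order"]):
        agg = grp.groupby("predictors")["eval_r"].agg(["mean", "sem", "count"])
        agg = agg[agg["count"] == agg["count"].max()]
        best = agg["mean"].idxmax()
        rows.append({
            "target": target, "order": order, "predictors": best,
            "eval_r_mean": float(agg.loc[best, "mean"]),
            "eval_r_se": float(agg.loc[best, "sem"]),
            "n_subjects": int(agg.loc[best, "count"]),
        })
    return pd.DataFrame(rows)
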