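"""Outlier windows, exclusions, extremum windows, bootstrap, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from limbbcg.errors import ConfigurationError, DataError
from limbbcg.fiducials import FEATURE_NAMES
from limbbcg.regression import (RepresentativePoint, apply_exclusions,
                                evaluate_models, fit_all_regressions,
                                locate_extremum_window, merge_bootstrap,
                                parametric_bootstrap, remove_feature_outliers)
from limbbcg.robust import scaled_mad
from limbbcg.synth.protocol import EXTREMUM_DIRECTIONS


# --- windowed-MAD outlier removal ------------------------------------------

def brute_force_window_rule(x, multiplier=3.0):
    """Independent re-implementation of the sliding 9-sample rule."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    removed = []
    for block in range(0, n, 3):
        lo = min(max(block - 3, 0), n - 9)
        win = x[lo:lo + 9]
        med = np.median(win)
        smad = scaled_mad(win)
        for i in range(block, min(block + 3, n)):
            if abs(x[i] - med) > multiplier * smad:
                removed.append(i)
    return removed


def test_single_spike_in_constant_series():
    x = np.full(30, 5.0)
    x[15] = 50.0
    cleaned, removed = remove_feature_outliers(x)
    assert removed == [15]
    assert len(cleaned) == 29


def test_gentle_ramp_keeps_everything():
    _, removed = remove_feature_outliers(np.linspace(0.0, 1.0, 40))
    assert removed == []


def test_identical_series_mad_zero_guard():
    _, removed = remove_feature_outliers(np.full(20, 3.3))
    assert removed == []


def test_short_series_passes_through():
    with pytest.warns(UserWarning):
        cleaned, removed = remove_feature_outliers(np.arange(5.0))
    assert removed == [] and len(cleaned) == 5


@given(st.lists(st.floats(-50, 50), min_size=9, max_size=100),
       st.randoms(use_true_random=False))
def test_matches_brute_force_oracle(values, rnd):
    x = np.asarray(values)
    # sprinkle occasional spikes so the rule actually fires sometimes
    if len(x) > 12 and rnd.random() < 0.5:
        x[rnd.randrange(len(x))] += 500.0
    _, removed = remove_feature_outliers(x)
    assert removed == brute_force_window_rule(x)


# --- exclusions -------------------------------------------------------------

def test_period_threshold_and_subject_minimum():
    fracs = {("A", p): 0.0 for p in "123456789"}
    fracs[("A", "1")] = 0.8           # excluded (> 0.75)
    fracs[("A", "2")] = 0.5           # retained
    fracs.update({("B", p): 0.0 for p in "12345"})   # only 5 periods
    retained = apply_exclusions(fracs)
    assert ("A", "1") not in retained and ("A", "2") in retained
    assert len([k for k in retained if k[0] == "A"]) == 8
    assert not any(k[0] == "B" for k in retained)


def test_six_periods_is_enough():
    fracs = {("C", p): 0.0 for p in "123456"}
    assert len(apply_exclusions(fracs)) == 6


def test_no_removal_retains_all_nine():
    fracs = {("D", p): 0.0 for p in "123456789"}
    assert len(apply_exclusions(fracs)) == 9


def test_invalid_fraction_rejected():
    with pytest.raises(DataError):
        apply_exclusions({("A", "1"): 1.2})


# --- extremum windows --------------------------------------------------------

def test_rising_series_max_window_is_last():
    x = np.linspace(0, 1, 30)
    start, mean, sd = locate_extremum_window(x, "max", 11)
    assert start == 30 - 11
    assert mean == pytest.approx(x[-11:].mean())


def test_constant_series_tie_breaks_to_first_window():
    start, mean, sd = locate_extremum_window(np.full(25, 2.0), "min", 11)
    assert start == 0 and sd == 0.0


def test_direction_table_cells():
    assert EXTREMUM_DIRECTIONS["sv"]["CP"] == "min"
    assert EXTREMUM_DIRECTIONS["co"]["BH"] == "min"
    assert EXTREMUM_DIRECTIONS["dp"]["CP"] == "max"


def test_short_series_is_data_error():
    with pytest.raises(DataError):
        locate_extremum_window(np.arange(5.0), "max", 11)

    with pytest.raises(ConfigurationError):
        locate_extremum_window(np.arange(20.0), "sideways", 11)


# --- parametric bootstrap ----------------------------------------------------

def _rep(period="R1", mean=100.0, sd=10.0, target="dp"):
    return RepresentativePoint(
        subject_id="S", period=period, target=target, window=(0, 11),
        means={"dp": mean, "PTT_I": 0.25}, sds={"dp": sd, "PTT_I": 0.005})


def test_zero_sd_degenerates_to_the_mean():
    boot = parametric_bootstrap(_rep(sd=0.0), n_boot=100, seed=1)
    assert np.all(boot["dp"] == 100.0)


def test_bootstrap_sd_is_sigma_over_sqrt_11():
    boot = parametric_bootstrap(_rep(mean=100.0, sd=10.0), n_boot=100, seed=2)
    expected_sd = 10.0 / np.sqrt(11.0)
    se = expected_sd / np.sqrt(2 * (100 - 1))   # SE of a sample SD
    assert boot["dp"].std(ddof=1) == pytest.approx(expected_sd, abs=3 * 5 * se)


def test_merged_counts_100_per_period():
    reps9 = [_rep(period=f"P{k}") for k in range(9)]
    assert len(merge_bootstrap(reps9, "dp", seed=3)) == 900
    assert len(merge_bootstrap(reps9[:1], "dp", seed=3)) == 100


def test_negative_sd_is_data_error():
    bad = _rep()
    bad.sds["dp"] = -1.0
    with pytest.raises(DataError):
        parametric_bootstrap(bad)


# --- exhaustive regression ---------------------------------------------------

def _boot_frame(n=300, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 16)), columns=FEATURE_NAMES)
    df.insert(0, "period", np.repeat([f"P{k}" for k in range(3)], n // 3))
    return df


def test_constructed_target_recovers_slope_and_candidate_count():
    df = _boot_frame()
    rng = np.random.default_rng(1)
    df["dp"] = 2.0 * df["PTT_I"] + rng.normal(0, 1e-6, len(df))
    models = fit_all_regressions(df, "dp")
    assert len(models) == 16 + 120
    uni = next(m for m in models if m.predictors == ("PTT_I",))
    assert uni.coefficients[0] == pytest.approx(2.0, rel=0.01)
    assert uni.train_r == pytest.approx(1.0, abs=1e-6)
    assert all(len(set(m.predictors)) == len(m.predictors) for m in models)


def test_bivariate_train_r_at_least_best_univariate():
    df = _boot_frame(seed=5)
    rng = np.random.default_rng(6)
    df["sv"] = df["A_J"] - 0.5 * df["T_JJ"] + rng.normal(0, 0.3, len(df))
    models = fit_all_regressions(df, "sv")
    best_uni = max(m.train_r for m in models if len(m.predictors) == 1)
    best_bi = max(m.train_r for m in models if len(m.predictors) == 2)
    assert best_bi >= best_uni


def test_single_period_is_data_error():
    df = _boot_frame()
    df["period"] = "P0"
    df["dp"] = 1.0
    with pytest.raises(DataError):
        fit_all_regressions(df, "dp")


# --- model evaluation --------------------------------------------------------

def _models_and_reps(transform):
    rng = np.random.default_rng(3)
    df = _boot_frame(seed=3)
    df["dp"] = 3.0 * df["PTT_I"] + rng.normal(0, 1e-9, len(df))
    models = fit_all_regressions(df, "dp")
    reps = []
    for k, v in enumerate((0.1, 0.25, 0.4, 0.55)):
        means = {name: 0.0 for name in FEATURE_NAMES}
        means["PTT_I"] = v
        means["dp"] = transform(3.0 * v)
        reps.append(RepresentativePoint("S", f"P{k}", "dp", (0, 11),
                                        means=means,
                                        sds={n: 0.0 for n in means}))
    return models, reps


def test_perfect_predictions_give_r_one():
    models, reps = _models_and_reps(lambda y: y)
    ranked = evaluate_models(models, reps)
    top = next(m for m in ranked if m.predictors == ("PTT_I",))
    assert top.eval_r == pytest.approx(1.0)
    assert top.acceptable


def test_pearson_r_is_affine_invariant():
    models, reps = _models_and_reps(lambda y: 2.5 * y + 7.0)
    ranked = evaluate_models(models, reps)
    assert next(m for m in ranked if m.predictors == ("PTT_I",)).eval_r \
        == pytest.approx(1.0)


def test_anticorrelated_measurements_give_minus_one():
    models, reps = _models_and_reps(lambda y: -y + 5.0)
    ranked = evaluate_models(models, reps)
    assert next(m for m in ranked if m.predictors == ("PTT_I",)).eval_r \
        == pytest.approx(-1.0)
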