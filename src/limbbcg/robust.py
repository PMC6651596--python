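"""Robust statistics used throughout the pipeline.

The scaled median absolute deviation (MAD) with scaling factor 1.4826 is the
robust spread estimate behind every outlier rule in the pipeline (beat-amplitude
rejection and feature-series cleaning). The scaling factor is the normal
consistency constant 1/Phi^-1(3/4), which makes the scaled MAD a consistent
estimator of the standard deviation for Gaussian data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Normal consistency factor for the MAD, rounded to the conventional 4 decimals.
MAD_SCALE = 1.4826


def normal_consistency_constant() -> float:
    """Return 1/Phi^-1(0.75), the exact MAD-to-sigma scaling under normality."""
    return 1.0 / stats.norm.ppf(0.75)


def scaled_mad(x: np.ndarray, scale: float = MAD_SCALE) -> float:
    """Scaled median absolute deviation of ``x`` (a robust sigma estimate)."""
    x = np.asarray(x, dtype=float)
    return scale * float(np.median(np.abs(x - np.median(x))))


def mad_outlier_mask(
    x: np.ndarray,
    multiplier: float = 3.0,
    scale: float = MAD_SCALE,
) -> np.ndarray:
    """Boolean mask of samples outside ``multiplier`` scaled MADs of the median.

    The comparison is strict, so a zero MAD (at least half the samples equal
    to the median) flags every sample deviating from the median — a minority
    of spikes in an otherwise constant series is still caught — while an
    all-identical series flags nothing.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    smad = scaled_mad(x, scale)
    return np.abs(x - med) > multiplier * smad
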