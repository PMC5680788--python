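"""Method-agreement statistics: regression, Bland-Altman, RMSE, CoV.

The estimator is compared against reference blood-gas saturation with the
standard battery: ordinary least squares of estimate on reference,
Bland-Altman bias and 95% limits of agreement with a t-based confidence
interval on the bias and a proportional-bias regression (differences on
pairwise means), root-mean-square error, and the duplicate-measurement
coefficient of variation for reference reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodComparison",
    "linear_regression",
    "bland_altman",
    "rmse",
    "coefficient_of_variation",
    "compare_methods",
]


@dataclass(frozen=True)
class MethodComparison:
    """All agreement statistics for one estimator against one reference."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bias: float
    bias_sd: float
    bias_ci_low: float
    bias_ci_high: float
    bias_p: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_p: float
    rmse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def _paired(est, ref, min_n=3):
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1-D vectors")
    if len(est) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(est)}")
    return est, ref


def linear_regression(est, ref):
    """OLS of estimate on reference: (slope, intercept, r_squared, p_value).

    The p-value tests the slope against zero.
    """
    est, ref = _paired(est, ref)
    if np.ptp(ref) == 0:
        raise ValueError("reference has zero variance")
    fit = stats.linregress(ref, est)
    return fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue


def bland_altman(est, ref, alpha: float = 0.05):
    """Bland-Altman agreement of two methods.

    Returns a dict with the mean difference (``bias``), its SD, a t-based
    ``(1-alpha)`` confidence interval for the bias, a one-sample t-test of
    the bias against zero, limits of agreement bias +/- 1.96 SD, and the
    proportional-bias regression of differences on pairwise means.
    """
    est, ref = _paired(est, ref)
    diff = est - ref
    mean = (est + ref) / 2.0
    n = len(diff)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    if sd > 0:
        t_p = float(stats.ttest_1samp(diff, 0.0).pvalue)
    else:
        t_p = 1.0 if bias == 0 else 0.0
    if np.ptp(mean) > 0 and sd > 0:
        prop = stats.linregress(mean, diff)
        prop_slope, prop_p = float(prop.slope), float(prop.pvalue)
    else:
        prop_slope, prop_p = 0.0, 1.0
    return {
        "bias": bias,
        "bias_sd": sd,
        "bias_ci": (bias - tcrit * sem, bias + tcrit * sem),
        "loa": (bias - 1.96 * sd, bias + 1.96 * sd),
        "bias_p": t_p,
        "prop_bias_slope": prop_slope,
        "prop_bias_p": prop_p,
    }


def rmse(est, ref) -> float:
    """Root-mean-square difference between paired vectors."""
    est, ref = _paired(est, ref, min_n=1)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def coefficient_of_variation(replicate_pairs) -> float:
    """Within-subject CoV for duplicate measurements.

    ``replicate_pairs`` is an (n, 2) array of repeated readings.  Computed
    as the root-mean-square within-pair SD divided by the grand mean — the
    standard formula for duplicate reproducibility.
    """
    pairs = np.asarray(replicate_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 1:
        raise ValueError("replicate_pairs must be an (n, 2) array with n >= 1")
    grand_mean = pairs.mean()
    if grand_mean == 0:
        raise ValueError("grand mean is zero; CoV undefined")
    within_sd_sq = pairs.var(axis=1, ddof=1)  # per-pair SD^2
    return float(np.sqrt(within_sd_sq.mean()) / grand_mean)


def compare_methods(est, ref) -> MethodComparison:
    """Run the full battery and collect it into one record."""
    est, ref = _paired(est, ref)
    slope, intercept, r2, p = linear_regression(est, ref)
    ba = bland_altman(est, ref)
    return MethodComparison(
        n=len(est),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        bias=ba["bias"],
        bias_sd=ba["bias_sd"],
        bias_ci_low=ba["bias_ci"][0],
        bias_ci_high=ba["bias_ci"][1],
        bias_p=ba["bias_p"],
        loa_low=ba["loa"][0],
        loa_high=ba["loa"][1],
        prop_bias_slope=ba["prop_bias_slope"],
        prop_bias_p=ba["prop_bias_p"],
        rmse=rmse(est, ref),
    )
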