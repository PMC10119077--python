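"""Test-retest reproducibility (bias, VAR), reliability (ICC), and
cross-method agreement of regional DVR estimates.

For n subjects scanned twice, per-subject relative bias is

    bias_i = (DVR_retest_i - DVR_test_i) / DVR_test_i * 100  [%]

VAR is the sample SD of those biases, and reliability is a two-session
one-way intraclass correlation,

    ICC = (BSMSS - WSMSS) / (BSMSS + WSMSS),

where BSMSS/WSMSS are the between-/within-subject mean sums of squares.
Under a variance-components model this estimates
sigma_b^2 / (sigma_b^2 + sigma_w^2); it can be negative (and is reported
as computed) when subjects are less distinguishable than sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "RegressionResult",
    "trt_bias",
    "trt_variability",
    "icc",
    "dvr_regression",
    "test_retest_report",
    "pooled_test_retest",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("R^2 out of [0, 1]")


def trt_bias(test: np.ndarray, retest: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-subject percent bias of retest vs test, and their mean."""
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.size < 1:
        raise ValueError("test/retest must be equal-length, non-empty")
    if np.any(t <= 0):
        raise ValueError("test values must be positive (ratio denominator)")
    per = (r - t) / t * 100.0
    return per, float(np.mean(per))


def trt_variability(per_subject_biases: np.ndarray) -> float:
    """VAR: sample SD (n-1 denominator) of the per-subject biases, in %."""
    b = np.asarray(per_subject_biases, dtype=float)
    if b.size < 2:
        raise ValueError("VAR needs at least 2 subjects")
    return float(np.std(b, ddof=1))


def icc(test: np.ndarray, retest: np.ndarray) -> float:
    """Two-session one-way ICC, (BSMSS - WSMSS) / (BSMSS + WSMSS)."""
    bs, ws = icc_mean_squares(test, retest)
    denom = bs + ws
    if denom <= 0:
        raise ValueError("ICC undefined: all values identical")
    return float((bs - ws) / denom)


def icc_mean_squares(test: np.ndarray, retest: np.ndarray) -> tuple[float, float]:
    """Between- and within-subject mean sums of squares (k = 2 sessions)."""
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    if t.shape != r.shape or t.size < 2:
        raise ValueError("need >= 2 subjects with both sessions")
    n = t.size
    k = 2
    subj_mean = (t + r) / 2.0
    grand = np.mean(np.concatenate([t, r]))
    bsmss = k * np.sum((subj_mean - grand) ** 2) / (n - 1)
    wsmss = np.sum((t - subj_mean) ** 2 + (r - subj_mean) ** 2) / (n * (k - 1))
    return float(bsmss), float(wsmss)


def dvr_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of one method's DVRs on another's across regions/subjects."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired DVR values")
    if np.var(x) == 0:
        raise ValueError("zero variance in the independent DVRs")
    reg = linregress(x, y)
    return RegressionResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
    )


def test_retest_report(
    dvr_test: pd.DataFrame, dvr_retest: pd.DataFrame
) -> pd.DataFrame:
    """Per-region test-retest summary table.

    Inputs are (subject x region) DVR tables with matching index/columns.
    Output rows carry mean DVR per session, ICC, mean bias %, and VAR %,
    one row per region — the layout of a per-region reliability table.
    """
    if not dvr_test.columns.equals(dvr_retest.columns) or not dvr_test.index.equals(
        dvr_retest.index
    ):
        raise ValueError("test/retest tables must share subjects and regions")
    rows = []
    for region in dvr_test.columns:
        t = dvr_test[region].to_numpy()
        r = dvr_retest[region].to_numpy()
        per, mean_bias = trt_bias(t, r)
        try:
            region_icc = icc(t, r) if t.size > 1 else np.nan
        except ValueError:  # degenerate: zero total variance
            region_icc = np.nan
        rows.append(
            {
                "region": region,
                "dvr_test_mean": float(np.mean(t)),
                "dvr_test_sd": float(np.std(t, ddof=1)) if t.size > 1 else np.nan,
                "dvr_retest_mean": float(np.mean(r)),
                "dvr_retest_sd": float(np.std(r, ddof=1)) if r.size > 1 else np.nan,
                "icc": region_icc,
                "bias_pct": mean_bias,
                "var_pct": trt_variability(per) if per.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def pooled_test_retest(
    dvr_test: pd.DataFrame, dvr_retest: pd.DataFrame
) -> dict[str, float]:
    """Whole-method summary, under both defensible aggregations.

    ``*_regional_mean`` averages the per-region statistics; ``*_pooled``
    computes each statistic once on the stacked region-x-subject data.
    Both are emitted, labelled, since summary tables in the literature
    rarely say which was used.
    """
    report = test_retest_report(dvr_test, dvr_retest)
    t = dvr_test.to_numpy().ravel()
    r = dvr_retest.to_numpy().ravel()
    per, mean_bias = trt_bias(t, r)
    return {
        "icc_regional_mean": float(report["icc"].mean()),
        "bias_pct_regional_mean": float(report["bias_pct"].mean()),
        "var_pct_regional_mean": float(report["var_pct"].mean()),
        "icc_pooled": icc(t, r),
        "bias_pct_pooled": mean_bias,
        "var_pct_pooled": trt_variability(per),
    }
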