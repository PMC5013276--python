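"""Quantification utilities: ΔΔCt fold changes, RTCA normalization, t-tests.

ΔΔCt relative quantification: per record ΔCt = target Ct - housekeeping Ct;
ΔΔCt = mean ΔCt(treated) - mean ΔCt(control); fold change = 2^(-ΔΔCt),
reported relative to control = 1. With several housekeeping genes their Ct
values are combined by arithmetic mean per sample before referencing.

RTCA (impedance) series are normalized well-by-well to the cell-index value
at the transfection time point.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"


def combine_housekeeping(table: pd.DataFrame, housekeeping_cols: list[str]) -> pd.Series:
    """Arithmetic mean of several reference-gene Ct columns, per record."""
    missing = [c for c in housekeeping_cols if c not in table.columns]
    if missing:
        raise ValueError(f"housekeeping column(s) absent: {missing}")
    return table[housekeeping_cols].mean(axis=1)


def ddct_fold_change(
    table: pd.DataFrame,
    control: str = CONTROL,
    treated: str = TREATED,
) -> tuple[pd.Series, float, float]:
    """ΔΔCt relative quantification.

    ``table`` needs columns condition, target_ct, housekeeping_ct. Returns
    (per-record ΔCt, ΔΔCt, fold change 2^(-ΔΔCt)). Errors when a condition
    has no records.
    """
    for col in ("condition", "target_ct", "housekeeping_ct"):
        if col not in table.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    delta_ct = table["target_ct"] - table["housekeeping_ct"]
    by_condition = delta_ct.groupby(table["condition"])
    for cond in (control, treated):
        if cond not in by_condition.groups:
            raise ValueError(f"condition {cond!r} has no records")
    ddct = float(by_condition.get_group(treated).mean() - by_condition.get_group(control).mean())
    fold = float(2.0 ** (-ddct))
    logger.info("ddct_fold_change: ddCt=%.4f fold=%.4f", ddct, fold)
    return delta_ct, ddct, fold


def rtca_normalize(series: pd.DataFrame, transfection_time: float) -> pd.DataFrame:
    """Normalize each well's cell-index trace to its value at transfection.

    ``series`` is time (index) x wells. The transfection time must lie on
    the time grid; a zero index at transfection is an error naming the well.
    """
    if transfection_time not in series.index:
        raise ValueError(f"transfection time {transfection_time} not on the time grid")
    baseline = series.loc[transfection_time]
    zero_wells = baseline[baseline == 0]
    if len(zero_wells):
        raise ValueError(f"zero index at transfection time for well(s): {list(zero_wells.index)}")
    return series.div(baseline, axis=1)


def two_group_test(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    paired: bool = False,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-tailed Student t-test (t, p); paired variant on the differences.

    ``equal_var=False`` gives Welch's correction for the unpaired case.
    Zero variance with equal means returns (0.0, 1.0) by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal-length samples")
        if x.size < 2:
            raise ValueError("paired test needs n >= 2")
        diffs = x - y
        if np.ptp(diffs) == 0:
            return (0.0, 1.0) if diffs[0] == 0 else (np.inf * np.sign(diffs[0]), 0.0)
        res = stats.ttest_rel(x, y)
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("each group needs n >= 2")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if x[0] == y[0]:
                return (0.0, 1.0)
            return (np.inf * np.sign(x[0] - y[0]), 0.0)
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
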