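"""Target-network z-score signature and Kaplan-Meier / log-rank analysis.

The signature score of a sample is the sum, over a small gene set (the
four-gene network AKT2, GNA12, GYS1, SRF in the motivating analysis), of
per-gene z-scores computed across the cohort with the population (divide-
by-n) standard deviation. Cohorts are dichotomized at the median score into
high and low groups, follow-up is administratively censored at a horizon
(default 5 years for distant relapse-free survival), and group survival is
compared with the Kaplan-Meier estimator and the unweighted (Mantel-
Haenszel) two-group log-rank test. No multiple-testing correction is
applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


def gene_zscores(expr: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Per-gene cohort z-scores, population SD, probes averaged first.

    ``expr`` is genes x samples; duplicate index entries are treated as
    multiple probes of one gene and averaged before standardization.
    Raises for a missing gene or a zero-SD gene (named).
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    collapsed = expr.groupby(level=0).mean() if expr.index.duplicated().any() else expr
    missing = [g for g in genes if g not in collapsed.index]
    if missing:
        raise ValueError(f"gene(s) absent from expression matrix: {missing}")
    sub = collapsed.loc[list(genes)]
    mean = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=0)
    zero = sigma[sigma == 0]
    if len(zero):
        raise ValueError(f"zero-SD gene(s): {list(zero.index)}")
    return sub.sub(mean, axis=0).div(sigma, axis=0)


def network_score(z: pd.DataFrame, genes: list[str] | None = None) -> pd.Series:
    """Per-sample signature score: sum of z-scores over the gene set."""
    if genes is not None:
        missing = [g for g in genes if g not in z.index]
        if missing:
            raise ValueError(f"gene(s) absent from z matrix: {missing}")
        z = z.loc[list(genes)]
    if z.shape[0] == 0:
        raise ValueError("empty gene set")
    return z.sum(axis=0)


def minmax_normalize(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rescale to [0, 1] by (v - min) / (max - min); errors on zero range."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector (zero range)")
    out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median: score > median -> high, <= median -> low.

    The inclusive tie rule (ties at the median go to the low group) keeps
    the split deterministic.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = scores.median()
    return pd.Series(np.where(scores > med, HIGH, LOW), index=scores.index, name="group")


def truncate_followup(surv: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon``.

    Observations with time > horizon become censored at the horizon;
    records lacking survival information (missing time or event) are
    dropped and logged. Event indicators are untouched otherwise.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    out = surv.copy()
    informative = out["time"].notna() & out["event"].notna()
    n_dropped = int((~informative).sum())
    if n_dropped:
        logger.info("truncate_followup: dropping %d records without survival information", n_dropped)
    out = out[informative].copy()
    over = out["time"] > horizon
    out.loc[over, "event"] = 0
    out.loc[over, "time"] = horizon
    return out


@dataclass
class KMResult:
    """Per-group product-limit curves."""

    times: dict[str, np.ndarray]  # event/censor timeline per group
    survival: dict[str, np.ndarray]  # S(t) on that timeline, starts at 1
    at_risk: dict[str, np.ndarray]

    def survival_at(self, group: str, t: float) -> float:
        """Step-function value S(t) for one group."""
        times, surv = self.times[group], self.survival[group]
        idx = np.searchsorted(times, t, side="right") - 1
        return 1.0 if idx < 0 else float(surv[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    group_sizes: dict[str, int]


def km_estimate(surv: pd.DataFrame, groups: pd.Series | None = None) -> KMResult:
    """Kaplan-Meier product-limit estimate, optionally per group.

    Tied deaths and censorings at the same time are resolved with the
    standard convention (deaths first). Errors on an empty group.
    """
    if len(surv) == 0:
        raise ValueError("empty survival table")
    if groups is None:
        groups = pd.Series("all", index=surv.index)
    times, survival, at_risk = {}, {}, {}
    for name in pd.unique(groups):
        sub = surv[groups == name]
        if len(sub) == 0:
            raise ValueError(f"group {name!r} has no observations")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        times[name] = timeline
        survival[name] = kmf.survival_function_["KM_estimate"].to_numpy()
        at_risk[name] = kmf.event_table["at_risk"].reindex(timeline).to_numpy()
    return KMResult(times=times, survival=survival, at_risk=at_risk)


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> LogRankResult:
    """Unweighted two-group log-rank (Mantel-Haenszel) chi-square, 1 df."""
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {list(names)}")
    a = surv[groups == names[0]]
    b = surv[groups == names[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes={str(names[0]): len(a), str(names[1]): len(b)},
    )


def correlate_score_with_readout(
    scores: pd.Series | np.ndarray,
    readout: pd.Series | np.ndarray,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation (r, two-sided p) between signature scores and a readout.

    Used to relate the mRNA signature to protein/phosphoprotein levels.
    Pairs with a missing value are excluded; zero variance is an error.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(readout, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and readout must be paired (same length)")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or readout")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def signature_survival_analysis(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    genes: list[str],
    horizon: float | None = 5.0,
) -> dict:
    """End-to-end: z-score signature -> median split -> KM + log-rank.

    ``surv`` must carry sample_id/time/event; samples are matched to the
    expression columns by id. Returns a dict with the per-sample scores,
    normalized scores, group labels, KMResult and LogRankResult.
    """
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    common = [s for s in expr.columns if s in surv.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared between expression and survival tables")
    expr = expr[common]
    surv = surv.loc[common]
    z = gene_zscores(expr, genes)
    score = network_score(z)
    normalized = minmax_normalize(score)
    groups = median_split(score)
    if horizon is not None:
        surv = truncate_followup(surv, horizon)
        groups = groups.loc[surv.index]
        score_kept = score.loc[surv.index]
    else:
        score_kept = score
    km = km_estimate(surv, groups)
    lr = logrank_test(surv, groups)
    logger.info(
        "signature_survival_analysis: %d samples, chi2=%.3f p=%.4g",
        len(surv), lr.chi_square, lr.p_value,
    )
    return {
        "score": score,
        "normalized": normalized,
        "groups": groups,
        "survival_table": surv,
        "km": km,
        "logrank": lr,
        "score_used": score_kept,
    }
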