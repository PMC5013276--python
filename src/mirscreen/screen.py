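"""Scoring and classification of miRNAs from a mimic-screen readout matrix.

The screen measures, for each transfected miRNA mimic, the change in
expression/phosphorylation of a panel of signalling and cell-cycle proteins.
Each protein is annotated as oncogenic or tumor-suppressing and assigned to a
pathway group (PI3K, MAPK, cell cycle). A miRNA whose readout profile
correlates negatively with the oncogenic/tumor-suppressor class vector
represses oncogenes and/or de-represses tumor suppressors, i.e. behaves as a
tumor-suppressor miRNA; a positive correlation marks an oncomiR. A
coefficient-of-variation filter removes flat, low-signal profiles before the
correlation is interpreted.

Conventions: the class vector encodes oncogenic proteins as +1 and
tumor-suppressor proteins as -1, so the published cutoff |r| >= 0.5 applies
directly and the scheme is symmetric under relabeling. Cutoffs are
inclusive. Correlation is Pearson by default (point-biserial against a +/-1
vector), with Spearman as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

logger = logging.getLogger(__name__)

ONCOGENIC = "oncogenic"
TUMOR_SUPPRESSOR = "tumor_suppressor"
ONCOMIR = "oncomiR"
UNCLASSIFIED = "unclassified"
PATHWAYS = ("PI3K", "MAPK", "cell_cycle")


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check the protein annotation table (index protein_id, columns cls, pathway)."""
    for col in ("cls", "pathway"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks required column {col!r}")
    bad = set(annotation["cls"]) - {ONCOGENIC, TUMOR_SUPPRESSOR}
    if bad:
        raise ValueError(f"unknown protein classes {sorted(bad)}")
    if annotation.index.duplicated().any():
        raise ValueError("duplicated protein ids in annotation")


def class_vector(annotation: pd.DataFrame, proteins: list[str] | pd.Index) -> np.ndarray:
    """Signed class vector in matrix column order: +1 oncogenic, -1 tumor suppressor.

    Raises if a protein is unannotated or if all proteins share one class
    (the correlation against a constant vector would be degenerate).
    """
    validate_annotation(annotation)
    missing = [p for p in proteins if p not in annotation.index]
    if missing:
        raise ValueError(f"unannotated protein(s): {missing}")
    cvec = np.array([1.0 if annotation.loc[p, "cls"] == ONCOGENIC else -1.0 for p in proteins])
    if len(np.unique(cvec)) < 2:
        raise ValueError("degenerate class vector: all proteins share one class")
    return cvec


def mirna_cv(row: np.ndarray | pd.Series) -> float:
    """Coefficient of variation of one miRNA's readout profile.

    sample SD / |mean| over the finite entries. A zero mean yields +inf
    (the profile is maximally non-flat relative to its level and passes any
    finite cutoff); fewer than two finite values is an error.
    """
    values = np.asarray(row, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("CV needs at least 2 finite values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if mean == 0.0:
        return np.inf
    return float(sd / abs(mean))


def mirna_correlation(
    row: np.ndarray | pd.Series, cvec: np.ndarray, method: str = "pearson"
) -> float:
    """Correlation between a readout profile and the signed class vector.

    Returns NaN (flagged missing) when the profile has zero variance, in
    which case the miRNA is left unclassified downstream.
    """
    values = np.asarray(row, dtype=float)
    cvec = np.asarray(cvec, dtype=float)
    mask = np.isfinite(values) & np.isfinite(cvec)
    x, c = values[mask], cvec[mask]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if np.ptp(c) == 0:
        raise ValueError("class vector is constant on the observed entries")
    if np.ptp(x) == 0:
        return np.nan
    if method == "pearson":
        return float(stats.pearsonr(x, c).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, c).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def classify_mirnas(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    cv_cutoff: float = 0.25,
    corr_cutoff: float = 0.5,
    method: str = "pearson",
) -> pd.DataFrame:
    """Label each miRNA tumor_suppressor / oncomiR / unclassified.

    A miRNA is a tumor suppressor iff CV >= cv_cutoff and r <= -corr_cutoff,
    an oncomiR iff CV >= cv_cutoff and r >= +corr_cutoff (cutoffs
    inclusive). Returns a DataFrame indexed by miRNA with columns
    ``cv``, ``r``, ``label``.
    """
    cvec = class_vector(annotation, matrix.columns)
    if method == "pearson":
        cvs, rs = _scores_vectorized(matrix.to_numpy(dtype=float), cvec)
    else:
        cvs = np.empty(len(matrix))
        rs = np.empty(len(matrix))
        for i, (_, row) in enumerate(matrix.iterrows()):
            cvs[i] = mirna_cv(row)
            rs[i] = mirna_correlation(row, cvec, method=method)
    labels = np.where(
        (cvs >= cv_cutoff) & (rs <= -corr_cutoff),
        TUMOR_SUPPRESSOR,
        np.where((cvs >= cv_cutoff) & (rs >= corr_cutoff), ONCOMIR, UNCLASSIFIED),
    )
    labels[~np.isfinite(rs)] = UNCLASSIFIED
    out = pd.DataFrame({"cv": cvs, "r": rs, "label": labels}, index=matrix.index)
    counts = out["label"].value_counts().to_dict()
    logger.info(
        "classify_mirnas: %d miRNAs, cv>=%g & |r|>=%g -> %s",
        len(out), cv_cutoff, corr_cutoff, counts,
    )
    return out


def _scores_vectorized(values: np.ndarray, cvec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise CV and Pearson r against the class vector, NaN-aware.

    Same semantics as :func:`mirna_cv` / :func:`mirna_correlation` applied
    per row (pairwise exclusion of missing values), vectorized for large
    screens.
    """
    mask = np.isfinite(values)
    n = mask.sum(axis=1)
    if (n < 2).any():
        bad = int(np.argmax(n < 2))
        raise ValueError(f"row {bad} has fewer than 2 finite values")
    x = np.where(mask, values, 0.0)
    sum_x = x.sum(axis=1)
    mean_x = sum_x / n
    ss_x = (np.where(mask, (values - mean_x[:, None]) ** 2, 0.0)).sum(axis=1)
    sd = np.sqrt(ss_x / (n - 1))
    with np.errstate(divide="ignore"):
        cvs = np.where(mean_x == 0.0, np.inf, sd / np.abs(mean_x))

    if (n < 3).any():
        bad = int(np.argmax(n < 3))
        raise ValueError(f"row {bad} has fewer than 3 finite values for correlation")
    c = np.where(mask, cvec[None, :], 0.0)
    mean_c = c.sum(axis=1) / n
    dc = np.where(mask, cvec[None, :] - mean_c[:, None], 0.0)
    ss_c = (dc**2).sum(axis=1)
    if (ss_c == 0).any():
        raise ValueError("class vector is constant on some row's observed entries")
    dx = np.where(mask, values - mean_x[:, None], 0.0)
    cov = (dx * dc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(ss_x == 0.0, np.nan, cov / np.sqrt(ss_x * ss_c))
    return cvs, rs


def pathway_coregulation(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Direction of each miRNA's net effect on each pathway group.

    The signed effect of a readout change is the change multiplied by the
    protein's class sign (+1 oncogenic, -1 tumor suppressor); a negative
    mean signed effect over a pathway's proteins means the miRNA pushes that
    pathway down. Returns a miRNA x pathway frame of {down, up, neutral}.
    """
    validate_annotation(annotation)
    cvec = np.array(
        [1.0 if annotation.loc[p, "cls"] == ONCOGENIC else -1.0 for p in matrix.columns]
    )
    pathways = annotation.loc[matrix.columns, "pathway"]
    out = {}
    for pw in pd.unique(pathways):
        cols = pathways[pathways == pw].index
        if len(cols) == 0:
            raise ValueError(f"pathway {pw!r} has no proteins")
        signed = matrix[cols].to_numpy() * cvec[[matrix.columns.get_loc(c) for c in cols]]
        means = np.nanmean(signed, axis=1)
        out[pw] = np.where(means < 0, "down", np.where(means > 0, "up", "neutral"))
    return pd.DataFrame(out, index=matrix.index)


def select_candidates(results: pd.DataFrame, coreg: pd.DataFrame) -> list[str]:
    """Tumor-suppressor miRNAs pushing every pathway group down, by ascending r.

    ``results`` comes from :func:`classify_mirnas` and ``coreg`` from
    :func:`pathway_coregulation` on the same matrix.
    """
    ts = results[results["label"] == TUMOR_SUPPRESSOR]
    if ts.empty:
        return []
    all_down = coreg.loc[ts.index].eq("down").all(axis=1)
    selected = ts[all_down.reindex(ts.index, fill_value=False)]
    ordered = selected.sort_values("r", kind="mergesort")
    logger.info("select_candidates: %d tumor-suppressor candidates", len(ordered))
    return list(ordered.index)


@dataclass
class ClusterOrdering:
    """Leaf ordering and merge record of an agglomerative clustering."""

    order: list[str]
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_mirnas(matrix: pd.DataFrame) -> ClusterOrdering:
    """Average-linkage hierarchical clustering of miRNA readout profiles.

    Euclidean distance, average linkage. Missing values are imputed to the
    row mean before clustering (logged). Leaf order is a deterministic
    traversal putting the lower-height subtree first at every merge
    (leaves count as height 0; ties break toward the earlier-formed node).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        n_missing = int((~np.isfinite(values)).sum())
        logger.info("cluster_mirnas: imputing %d missing values to row means", n_missing)
        row_means = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
        idx = np.where(~np.isfinite(values))
        values[idx] = row_means[idx[0]]
    Z = linkage(values, method="average", metric="euclidean")
    order = [matrix.index[i] for i in _leaf_order(Z)]
    return ClusterOrdering(order=order, linkage=Z)


def _leaf_order(Z: np.ndarray) -> list[int]:
    """Leaf traversal: at each internal node, visit the lower-height child first."""
    n = Z.shape[0] + 1

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        first, second = (a, b)
        if (height(b), b) < (height(a), a):
            first, second = (b, a)
        stack.append(second)  # LIFO: first child is visited first
        stack.append(first)
    return order
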