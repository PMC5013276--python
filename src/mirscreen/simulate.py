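"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators stand in for the study's external data sources so every
downstream stage is testable offline:

* a mimic-screen readout matrix with planted tumor-suppressor miRNAs and
  oncomiRs on an annotated protein panel plus Gaussian noise (RPPA
  log-ratio readouts are conventionally near-normal);
* per-database target-prediction tables where each database detects true
  targets and decoys as independent Bernoulli events (recall / false-
  positive rate) and detected records are drawn to pass the database's
  published cutoff;
* an expression cohort with exponential event times whose hazard is
  log-linear in the min-max-normalized signature score, with independent
  censoring — the simplest process under which a median split yields
  separable survival curves;
* qPCR Ct tables whose noiseless ΔΔCt reproduces a requested fold change.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import ONCOGENIC, ONCOMIR, PATHWAYS, TUMOR_SUPPRESSOR
from . import survival as _surv

NEUTRAL = "neutral"

SIGNATURE_GENES = ("AKT2", "GNA12", "GYS1", "SRF")


@dataclass
class ScreenSimSpec:
    """Conditions of the emulated mimic screen (733 miRNAs x 16 proteins)."""

    n_mirnas: int = 733
    n_proteins: int = 16
    n_onco_proteins: int = 11
    n_planted_ts: int = 20
    n_planted_onco: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_proteins, self.n_onco_proteins) <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.n_onco_proteins < self.n_proteins):
            raise ValueError("need at least one oncogenic and one tumor-suppressor protein")
        if self.n_planted_ts < 0 or self.n_planted_onco < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_planted_ts + self.n_planted_onco > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_screen(spec: ScreenSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (readout matrix, protein annotation, truth labels).

    Planted tumor-suppressor miRNAs shift oncogenic proteins by
    -effect_size and tumor-suppressor proteins by +effect_size (oncomiRs
    mirrored); every entry additionally carries Normal(0, noise_sd) noise.
    The truth frame labels each miRNA tumor_suppressor / oncomiR / neutral.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = [f"miR-{i + 1:04d}" for i in range(spec.n_mirnas)]
    proteins = [f"P{j + 1:02d}" for j in range(spec.n_proteins)]
    cls = [ONCOGENIC] * spec.n_onco_proteins + [TUMOR_SUPPRESSOR] * (
        spec.n_proteins - spec.n_onco_proteins
    )
    pathway = [PATHWAYS[j % len(PATHWAYS)] for j in range(spec.n_proteins)]
    annotation = pd.DataFrame({"cls": cls, "pathway": pathway}, index=pd.Index(proteins, name="protein_id"))
    cvec = np.where(np.array(cls) == ONCOGENIC, 1.0, -1.0)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_mirnas, spec.n_proteins))
    planted = rng.choice(spec.n_mirnas, size=spec.n_planted_ts + spec.n_planted_onco, replace=False)
    ts_rows = planted[: spec.n_planted_ts]
    onco_rows = planted[spec.n_planted_ts:]
    values[ts_rows] += -spec.effect_size * cvec
    values[onco_rows] += spec.effect_size * cvec

    truth = pd.Series(NEUTRAL, index=pd.Index(mirnas, name="mirna_id"), name="truth_label")
    truth.iloc[ts_rows] = TUMOR_SUPPRESSOR
    truth.iloc[onco_rows] = ONCOMIR
    matrix = pd.DataFrame(values, index=pd.Index(mirnas, name="mirna_id"), columns=proteins)
    return matrix, annotation, truth.to_frame()


def gen_prediction_tables(
    mirna: str,
    true_targets: list[str],
    decoys: list[str],
    per_db_recall: float,
    per_db_fpr: float,
    seed: int = 0,
    db_names: tuple[str, ...] = ("TargetScan", "DIANA", "PITA", "miRWalk"),
) -> dict[str, pd.DataFrame]:
    """One prediction table per database with planted detection structure.

    A true target is detected by each database independently with
    probability ``per_db_recall``; a decoy with ``per_db_fpr``. Detected
    records are given scores/flags that pass the database's published
    cutoff (conserved site for TargetScan-like tables, miTG > 0.7 for
    DIANA-like, ddG < -10 for PITA-like); undetected genes appear as
    sub-threshold records, except in the unfiltered miRWalk-like table
    where presence itself is detection.
    """
    if not true_targets:
        raise ValueError("true_targets must be non-empty")
    if set(true_targets) & set(decoys):
        raise ValueError("true_targets and decoys overlap")
    if not (0 <= per_db_recall <= 1 and 0 <= per_db_fpr <= 1):
        raise ValueError("per_db_recall and per_db_fpr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(true_targets) + list(decoys)
    p_detect = np.array([per_db_recall] * len(true_targets) + [per_db_fpr] * len(decoys))
    tables: dict[str, pd.DataFrame] = {}
    for db in db_names:
        detected = rng.random(len(genes)) < p_detect
        if db == "miRWalk":
            records = pd.DataFrame(
                {
                    "mirna_id": mirna,
                    "gene": [g for g, d in zip(genes, detected) if d],
                    "db_name": db,
                    "score": np.nan,
                    "conserved": pd.NA,
                }
            )
        else:
            if db == "DIANA":
                score = np.where(
                    detected, rng.uniform(0.71, 1.0, len(genes)), rng.uniform(0.0, 0.7, len(genes))
                )
                conserved = pd.NA
            elif db == "PITA":
                score = np.where(
                    detected,
                    rng.uniform(-30.0, -10.01, len(genes)),
                    rng.uniform(-10.0, 0.0, len(genes)),
                )
                conserved = pd.NA
            else:  # TargetScan-like: conservation flag is the filter
                score = np.nan
                conserved = detected
            records = pd.DataFrame(
                {
                    "mirna_id": mirna,
                    "gene": genes,
                    "db_name": db,
                    "score": score,
                    "conserved": conserved,
                }
            )
        tables[db] = records
    return tables


@dataclass
class CohortSimSpec:
    """Conditions of the emulated survival cohort.

    ``log_hazard_per_unit_score`` multiplies the min-max-normalized
    signature score (range [0, 1]) inside the exponential hazard, so it is
    the log hazard ratio between the extreme patients. The default cohort
    size matches the larger validation cohorts of expression-array studies
    (a few hundred patients); baseline hazard and follow-up are on a
    years scale.
    """

    n_samples: int = 216
    n_genes: int = 200
    signature_genes: tuple[str, ...] = SIGNATURE_GENES
    log_hazard_per_unit_score: float = 1.0
    baseline_hazard: float = 0.08
    censor_rate: float = 0.2
    followup_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("cohort needs >= 2 samples and >= 1 gene")
        if len(self.signature_genes) == 0 or len(self.signature_genes) > self.n_genes:
            raise ValueError("signature_genes must be non-empty and fit in n_genes")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.followup_max <= 0:
            raise ValueError("followup_max must be > 0")


def gen_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (expression matrix genes x samples, survival table, truth).

    Gene g of sample i is Normal(mean_g, sd_g) with gene-level means and
    SDs on a log2-microarray-like scale. The event hazard of sample i is
    baseline_hazard * exp(log_hazard_per_unit_score * normalized_score_i);
    censoring is independent (uniform over follow-up for a censor_rate
    fraction, administrative at followup_max otherwise).
    """
    rng = np.random.default_rng(spec.seed)
    extra = [f"gene-{i + 1:04d}" for i in range(spec.n_genes - len(spec.signature_genes))]
    genes = list(spec.signature_genes) + extra
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    gene_means = rng.uniform(5.0, 12.0, size=spec.n_genes)
    gene_sds = rng.uniform(0.5, 2.0, size=spec.n_genes)
    values = rng.normal(
        gene_means[:, None], gene_sds[:, None], size=(spec.n_genes, spec.n_samples)
    )
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    z = _surv.gene_zscores(expr, list(spec.signature_genes))
    score = _surv.network_score(z)
    normalized = _surv.minmax_normalize(score)
    hazard = spec.baseline_hazard * np.exp(
        spec.log_hazard_per_unit_score * normalized.to_numpy()
    )
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.where(
        rng.random(spec.n_samples) < spec.censor_rate,
        rng.uniform(0.0, spec.followup_max, spec.n_samples),
        spec.followup_max,
    )
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame({"sample_id": samples, "time": time, "event": event})
    truth = {
        "score": score,
        "normalized_score": normalized,
        "hazard": pd.Series(hazard, index=samples),
        "spec": spec,
    }
    return expr, surv, truth


def gen_ct_table(
    n_samples: int,
    true_fold_change: float,
    ct_noise_sd: float,
    seed: int = 0,
    housekeeping_ct: float = 20.0,
    base_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Ct table whose noiseless ΔΔCt gives exactly ``true_fold_change``.

    Control samples have ΔCt = base_delta_ct; treated samples have
    ΔCt = base_delta_ct - log2(true_fold_change). Independent Gaussian
    noise (``ct_noise_sd``) is added to every Ct reading.
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be > 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    treated_delta = base_delta_ct - np.log2(true_fold_change)
    for cond, delta in (("control", base_delta_ct), ("treated", treated_delta)):
        for i in range(n_samples):
            hk = housekeeping_ct + rng.normal(0.0, ct_noise_sd)
            target = hk + delta + rng.normal(0.0, ct_noise_sd)
            rows.append(
                {
                    "sample_id": f"{cond}-{i + 1:03d}",
                    "condition": cond,
                    "target_ct": target,
                    "housekeeping_ct": hk,
                    "replicate": i + 1,
                }
            )
    return pd.DataFrame(rows)
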