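# mirscreen

Analysis pipeline for nominating tumor-suppressor microRNAs from a
functional mimic screen and evaluating their target network in patient
cohorts. It covers three stages that, chained together, take a miRNA mimic
screen with a reverse-phase protein array (RPPA) readout all the way to a
survival-stratifying gene signature:

1. **Screen scoring** (`mirscreen.screen`). Each transfected miRNA's readout
   profile across an annotated protein panel is scored by its coefficient of
   variation, CV = s / |x̄| (a flatness filter, default cutoff 0.25), and its
   Pearson correlation *r* with the signed protein class vector (+1
   oncogenic, −1 tumor suppressor). A miRNA with CV ≥ 0.25 and r ≤ −0.5 is
   called a **tumor-suppressor miRNA**; r ≥ +0.5 an **oncomiR**; anything
   else stays unclassified. Candidates are tumor-suppressor miRNAs whose mean
   signed effect is negative in all three pathway groups (PI3K, MAPK, cell
   cycle). Average-linkage hierarchical clustering provides the heatmap row
   ordering.
2. **Consensus target prediction** (`mirscreen.targets`). Per-database
   exports are filtered with each database's own rule — TargetScan: conserved
   sites only; DIANA-microT: miTG score > 0.7; PITA: ddG < −10; miRWalk:
   unfiltered — and genes predicted by ≥ 2 of the 4 databases form the
   consensus target set, which is then annotated with pathway membership from
   a GMT collection.
3. **Signature survival analysis** (`mirscreen.survival`). The target-network
   expression of sample *j* is the sum of per-gene z-scores,
   score_j = Σ_g (x_gj − x̄_g)/σ_g, with σ the population (divide-by-n) SD and
   multiple probes per gene averaged first. Cohorts are split at the median
   score, follow-up is administratively censored at a horizon (default 5
   years), and the high/low groups are compared by Kaplan–Meier curves and
   the two-group log-rank test.

`mirscreen.qpcr` adds the bench-side quantification utilities (ΔΔCt relative
quantification with fold = 2^(−ΔΔCt), RTCA impedance normalization to the
transfection time point, paired/unpaired two-tailed t-tests), and
`mirscreen.simulate` generates synthetic screens, prediction tables, survival
cohorts and Ct tables with planted ground truth so the whole pipeline can be
exercised and calibrated without any external downloads.

The package is aimed at computational biologists re-analyzing functional
miRNA screens or validating multi-gene signatures against survival cohorts.

## Worked example

```python
import numpy as np
from mirscreen import *
from mirscreen.simulate import SIGNATURE_GENES

# 733 x 16 synthetic screen with 20 planted tumor-suppressor miRNAs + 20 oncomiRs
matrix, annotation, truth = gen_screen(ScreenSimSpec(seed=1))
results = classify_mirnas(matrix, annotation)                 # CV 0.25, |r| 0.5
coreg = pathway_coregulation(matrix, annotation)
candidates = select_candidates(results, coreg)
print("classified:", results["label"].value_counts().to_dict())
print("candidates:", len(candidates), "first:", candidates[:3])

# four prediction databases, recall 0.9 / FPR 0.05 per database
tables = gen_prediction_tables("miR-0001", list(SIGNATURE_GENES),
                               [f"decoy-{i}" for i in range(33)], 0.9, 0.05, seed=1)
rules = {r.db_name: r for r in DEFAULT_DB_RULES}
filtered = {db: filter_database(t, rules[db]) for db, t in tables.items()}
cons = consensus(filtered, min_databases=2)
print("consensus genes:", sorted(cons["gene"]))

# 216-patient cohort whose hazard rises with the 4-gene signature score
expr, surv, _ = gen_cohort(CohortSimSpec(seed=1, log_hazard_per_unit_score=2.0))
res = signature_survival_analysis(expr, surv, list(SIGNATURE_GENES), horizon=5.0)
lr = res["logrank"]
print(f"log-rank chi2 = {lr.chi_square:.3f}, p = {lr.p_value:.4g}, groups = {lr.group_sizes}")
```

Output:

```
classified: {'unclassified': 664, 'oncomiR': 38, 'tumor_suppressor': 31}
candidates: 29 first: ['miR-0052', 'miR-0302', 'miR-0638']
consensus genes: ['AKT2', 'GNA12', 'GYS1', 'SRF', 'decoy-32']
log-rank chi2 = 7.762, p = 0.005334, groups = {'high': 108, 'low': 108}
```

The classifier recovers all 40 planted miRNAs (the extra calls are the
expected ≈5% false-positive rate of the |r| ≥ 0.5 cutoff on 16-protein
noise profiles); the two-of-four consensus recovers the four planted target
genes plus one decoy that slipped past two databases; and the median split
of the signature score separates survival (p ≈ 0.005) in a cohort simulated
with a strong score-dependent hazard.

The same stages are available from a shell:

```sh
mirscreen --seed 1 --out-dir out simulate
mirscreen --out-dir out screen --matrix out/screen_matrix.tsv \
    --annotation out/protein_annotation.tsv
mirscreen --out-dir out survival --expr out/cohort_expression.tsv \
    --surv out/cohort_survival.tsv --genes AKT2,GNA12,GYS1,SRF --horizon 5
```

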