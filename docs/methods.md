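# Methods

## Screen scoring model

The screen stage assumes a matrix of per-miRNA readout changes (Δ values,
log-ratio-like) over a protein panel in which every protein carries exactly
one class label (oncogenic or tumor suppressor) and one pathway group (PI3K,
MAPK or cell cycle), with both classes represented. The class vector encodes
oncogenic proteins as +1 and tumor-suppressor proteins as −1; this makes the
correlation of a readout profile with the class vector a point-biserial
statistic whose sign carries the biology (negative = represses oncogenes
and/or de-represses tumor suppressors = tumor-suppressor miRNA) and keeps
the scheme symmetric under relabeling: negating the matrix swaps the two
miRNA labels and leaves CV untouched.

Two decisions here were genuinely open and are package choices, not given:

* **CV is computed per miRNA** across its protein readouts, with the
  absolute mean in the denominator. The filter's purpose is to remove flat,
  low-signal miRNA profiles before interpreting a correlation; a per-protein
  CV would not serve a per-miRNA selection. A profile with exactly zero mean
  gets CV = +∞ and passes any finite cutoff — it is maximally non-flat
  relative to its level. Sample SD (ddof = 1) is used.
* **Correlation is Pearson** against the ±1 vector (Spearman exposed as an
  option). Missing readouts are excluded pairwise; a zero-variance profile
  has no defined correlation and is flagged missing, leaving the miRNA
  unclassified.

Cutoffs (CV ≥ 0.25, |r| ≥ 0.5 by default) are inclusive: a value exactly at
the cutoff is kept. Candidate selection further requires a negative mean
signed effect (Δ × class sign) in every pathway group, and orders candidates
by ascending r (most strongly tumor-suppressive first).

Clustering for heatmap ordering is agglomerative with average linkage on
Euclidean distance. Rows with missing values are imputed to their row mean
before clustering (and this is logged). Leaf order is a deterministic
traversal that visits the lower-height child first at every merge, breaking
ties toward the earlier-formed node, so the ordering is reproducible across
runs and platforms.

## Consensus target prediction

Databases are consumed as flat, pre-exported tables — never queried live —
which pins database versions and keeps the stage testable offline. Score
thresholds are strict (exclusive): miTG 0.7 itself is dropped, ddG −10
itself is dropped, because the rules are comparative ("greater than" /
"less than"), not "at least". Duplicate (miRNA, gene) records within one
database collapse to the best score before filtering — highest for a
greater-than rule, lowest for a less-than rule, conservation flags
OR-combined — since duplicate transcript-level records of one gene should
count once, at their strongest evidence. Pathway annotation is a set-
membership lookup against a GMT collection with exact, case-sensitive
symbol matching; it is not an enrichment test and computes no p-values.

## Signature and survival

Per-gene z-scores use the **population** SD (divide by n), matching the
convention of z-score signature analyses on patient cohorts; multiple
probes of one gene are averaged before standardization. The signature score
is the plain sum of z-scores over the gene set; min–max normalization to
[0, 1] is available for cross-cohort comparability and is what the cohort
simulator's hazard acts on. Both transformations are affine-invariant per
gene, so per-gene rescaling of the expression matrix changes neither groups
nor test results.

The median split sends scores strictly above the median to the high group
and everything else (ties included) to the low group — a deterministic,
reproducible tie rule. Follow-up handling is administrative censoring at a
configurable horizon (default 5 years): observations beyond the horizon are
censored at the horizon rather than deleted, and records lacking survival
information are dropped and logged. Kaplan–Meier estimation resolves tied
deaths and censorings with the universal deaths-first convention; the group
comparison is the unweighted (Mantel–Haenszel) two-group log-rank
chi-square with 1 df. KM and log-rank are computed with lifelines; the test
suite checks both against hand-written product-limit and Σ(O−E)²/V oracles
to 1e-10. No multiple-testing correction is applied anywhere in the
pipeline. Cox regression and hazard-ratio estimation are deliberately out
of scope.

## Quantification utilities

ΔΔCt: ΔCt = target Ct − housekeeping Ct per record; ΔΔCt is the difference
of condition means; fold = 2^(−ΔΔCt), so the control condition is 1 by
construction. When several reference genes are supplied their Ct values are
combined by arithmetic mean per sample before referencing. RTCA traces are
divided well-wise by the value at the transfection time point (idempotent;
a zero baseline is an error naming the well). The two-group test is the
equal-variance Student t by default — Welch available via ``equal_var=False``
— two-tailed, with the degenerate all-equal case returning (t = 0, p = 1)
by convention. End-point pairing across replicate wells is the intended use
of the paired variant for RTCA comparisons.

## Synthetic data: what it emulates and what it does not

* **Screen generator**: planted tumor-suppressor miRNAs shift oncogenic
  proteins by −effect and tumor-suppressor proteins by +effect (oncomiRs
  mirrored) on top of i.i.d. Gaussian noise — RPPA log-ratio readouts are
  conventionally near-normal. Defaults are the study-scale conditions:
  733 miRNAs × 16 proteins (11 oncogenic / 5 tumor-suppressor, pathways
  assigned round-robin), 20 planted miRNAs of each kind, effect 1.0, noise
  SD 0.3. The generator does **not** reproduce the correlation structure
  among real panel proteins (signalling proteins co-vary), so measured
  specificity on synthetic screens bounds, rather than equals, behavior on
  real screens.
* **Prediction generator**: each database detects each true target with
  probability `per_db_recall` and each decoy with `per_db_fpr`,
  independently — databases as independent voters, which is exactly the
  assumption under which a ≥2-of-4 consensus has the closed-form inclusion
  probability P(Bin(4, recall) ≥ 2) that the tests verify. Detected records
  are drawn to pass the database's published cutoff (conserved flag;
  miTG ~ U(0.71, 1); ddG ~ U(−30, −10.01)), undetected ones to fail it;
  in the unfiltered miRWalk-like table presence itself is detection. Real
  databases are correlated (shared seed-match logic), so real consensus
  specificity will be worse than the independent model suggests.
* **Cohort generator**: gene expression is Gaussian per gene with means
  U(5, 12) and SDs U(0.5, 2) on a log2-microarray-like scale; event times
  are exponential with hazard = baseline × exp(β × normalized score), i.e.
  proportional hazards log-linear in the min–max-normalized signature score
  — the simplest process under which a median split yields separable KM
  curves. Censoring is independent: a `censor_rate` fraction of patients
  get a U(0, follow-up) censoring time, the rest are administratively
  censored at maximum follow-up. Defaults: 216 patients (the scale of the
  larger microarray validation cohorts), 200 genes, 4 signature genes,
  baseline hazard 0.08/year, follow-up 10 years, censor rate 0.2. β = 0
  gives the exact null used for calibration. Real cohorts have correlated
  genes and non-exponential baselines; the calibration results transfer
  because the log-rank null only needs exchangeability of groups, but
  power numbers are specific to this process.
* **Ct generator**: control ΔCt is fixed at 5 cycles around a housekeeping
  level of 20; the treated ΔCt is offset by −log2(fold); Gaussian noise is
  added per Ct reading. With noise, 2^(−ΔΔCt) is slightly upward-biased
  (lognormal mean); the tests therefore check consistency (shrinking error
  with n), not unbiasedness.

## Numerical and testing choices

Problem sizes in the default suite and the acceptance script — 50 screens
of 733×16, 500 prediction-table seeds, 200 null cohorts, 50 effect cohorts,
30–50 seeds for power curves — were chosen as the smallest sizes at which
the binomial/KS confidence intervals in the assertions are decisive.
The end-to-end survival separation property is operationalized as the
high-score group ending follow-up with survival at or below the low
group's (a pointwise-dominance check at every event time would be violated
by the first early event falling in the low group, which happens with
appreciable probability under any finite effect). The log-rank power
monotonicity check uses a well-separated effect grid (β = 0, 1, 2.5) so
Monte-Carlo noise at 30 seeds per point cannot reorder it.

Known limitations: no GEO/TCGA ingestion (inputs are local TSV/GMT); no
enrichment statistics; no multi-group (>2) log-rank; no amplification-
efficiency correction for qPCR; the screen classifier's published headline
counts on the original laboratory screen depend on that screen's data and
on 2011-era database exports and are not reproducible from this package's
synthetic inputs.
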