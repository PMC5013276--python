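"""Consensus miRNA-target prediction filtering.

Each prediction database is consumed as a pre-exported flat table and reduced
to a gene set by its own published filtering rule; genes predicted by at
least ``min_databases`` of the filtered databases form the consensus target
set, which can then be annotated with pathway membership.

The default rules mirror the common practice for these four databases:
TargetScan restricted to conservedly-targeted sites, DIANA-microT restricted
to miTG scores above 0.7, PITA restricted to ddG accessibility scores below
-10, and miRWalk taken unfiltered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["mirna_id", "gene", "db_name", "score", "conserved"]


@dataclass(frozen=True)
class DatabaseRule:
    """Per-database filtering rule.

    ``direction`` is ``"greater_than"`` or ``"less_than"`` with a strict
    (exclusive) ``threshold``, or ``None`` together with a ``None``
    threshold for an unfiltered database. ``require_conserved`` keeps only
    records flagged as conserved target sites.
    """

    db_name: str
    score_field: str | None = None  # {"miTG", "ddG", None}
    direction: str | None = None  # {"greater_than", "less_than", None}
    threshold: float | None = None
    require_conserved: bool = False

    def __post_init__(self) -> None:
        if (self.direction is None) != (self.threshold is None):
            raise ValueError(
                f"rule {self.db_name!r}: direction and threshold must both be set or both None"
            )
        if self.direction not in (None, "greater_than", "less_than"):
            raise ValueError(f"rule {self.db_name!r}: unknown direction {self.direction!r}")
        if self.direction is not None and self.score_field is None:
            raise ValueError(f"rule {self.db_name!r}: a thresholded rule needs a score_field")


DEFAULT_DB_RULES: tuple[DatabaseRule, ...] = (
    DatabaseRule("TargetScan", require_conserved=True),
    DatabaseRule("DIANA", score_field="miTG", direction="greater_than", threshold=0.7),
    DatabaseRule("PITA", score_field="ddG", direction="less_than", threshold=-10.0),
    DatabaseRule("miRWalk"),
)


def _collapse_duplicates(records: pd.DataFrame, rule: DatabaseRule) -> pd.DataFrame:
    """Collapse duplicate (mirna, gene) records to the best-scoring one.

    Best means highest for greater_than rules, lowest for less_than rules;
    for unscored rules the first record wins (they carry no information to
    rank by). Conservation flags are OR-combined.
    """
    if not records.duplicated(subset=["mirna_id", "gene"]).any():
        return records
    records = records.copy()
    if "conserved" in records.columns:
        records["conserved"] = records.groupby(["mirna_id", "gene"])["conserved"].transform(
            lambda s: bool(s.astype("boolean").fillna(False).any())
        )
    if rule.direction is not None and "score" in records.columns:
        ascending = rule.direction == "less_than"
        records = records.sort_values(
            "score", ascending=ascending, na_position="last", kind="mergesort"
        )
    return records.drop_duplicates(subset=["mirna_id", "gene"], keep="first")


def filter_database(table: pd.DataFrame, rule: DatabaseRule) -> set[str]:
    """Apply one database's rule and return the surviving gene set.

    Thresholds are strict: a DIANA miTG score of exactly 0.7 or a PITA ddG
    of exactly -10 is dropped. Unscored records pass a rule without a
    direction; records lacking a score cannot pass a thresholded rule.
    """
    records = table[table["db_name"] == rule.db_name] if "db_name" in table.columns else table
    records = _collapse_duplicates(records, rule)
    if rule.require_conserved:
        if "conserved" not in records.columns:
            raise ValueError(f"rule {rule.db_name!r} requires a 'conserved' column")
        records = records[records["conserved"].astype("boolean").fillna(False).astype(bool)]
    if rule.direction is not None and len(records):
        has_scores = "score" in records.columns and records["score"].notna().any()
        if not has_scores:
            raise ValueError(
                f"rule {rule.db_name!r} references score field {rule.score_field!r} "
                "absent from the records"
            )
        if rule.direction == "greater_than":
            records = records[records["score"] > rule.threshold]
        else:
            records = records[records["score"] < rule.threshold]
    genes = set(records["gene"])
    logger.info("filter_database %s: %d records -> %d genes", rule.db_name, len(table), len(genes))
    return genes


def consensus(filtered: dict[str, set[str]], min_databases: int = 2) -> pd.DataFrame:
    """Genes supported by at least ``min_databases`` filtered databases.

    Returns a DataFrame with columns ``gene``, ``supporting_dbs`` (sorted
    list) and ``n_dbs``, ordered by descending support then gene name.
    """
    if min_databases < 1:
        raise ValueError(f"min_databases must be >= 1, got {min_databases}")
    if min_databases > len(filtered):
        raise ValueError(
            f"min_databases={min_databases} exceeds the {len(filtered)} databases supplied"
        )
    support: dict[str, list[str]] = {}
    for db in sorted(filtered):
        for gene in filtered[db]:
            support.setdefault(gene, []).append(db)
    rows = [
        {"gene": gene, "supporting_dbs": dbs, "n_dbs": len(dbs)}
        for gene, dbs in support.items()
        if len(dbs) >= min_databases
    ]
    out = pd.DataFrame(rows, columns=["gene", "supporting_dbs", "n_dbs"])
    out = out.sort_values(["n_dbs", "gene"], ascending=[False, True]).reset_index(drop=True)
    logger.info("consensus: %d genes at >= %d databases", len(out), min_databases)
    return out


def annotate_pathways(targets: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Attach the list of pathway sets containing each consensus gene."""
    if len(sets) == 0:
        logger.warning("annotate_pathways: empty gene-set collection; all annotations empty")
    out = targets.copy()
    out["pathways"] = [sets.sets_containing(g) for g in out["gene"]]
    return out


def in_pathways(annotated: pd.DataFrame, pathway_names: list[str] | None = None) -> pd.DataFrame:
    """Keep only targets belonging to at least one (named) pathway set."""
    if pathway_names is None:
        mask = annotated["pathways"].map(len) > 0
    else:
        wanted = set(pathway_names)
        mask = annotated["pathways"].map(lambda ps: bool(wanted.intersection(ps)))
    return annotated[mask].reset_index(drop=True)


def venn_counts(filtered: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive-region counts of the databases' gene sets.

    Keys are sorted tuples of database names; the value counts genes present
    in exactly those databases. All 2^k - 1 regions are reported (zeros
    included) and the counts sum to the union size.
    """
    if len(filtered) < 2:
        raise ValueError("venn_counts needs at least 2 sets")
    names = sorted(filtered)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(filtered[n] for n in combo))
            outside = set.union(set(), *(filtered[n] for n in names if n not in combo))
            counts[combo] = len(inside - outside)
    return counts
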