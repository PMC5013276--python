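"""Readers and writers for the tabular formats the pipeline consumes.

All delimited files are tab-separated UTF-8 with ``.`` as the decimal mark and
``NA`` for missing values, matching the GEO-style matrices the analysis was
designed around. Gene and protein identifiers are opaque, case-sensitive
strings; no symbol remapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


def read_matrix(path: str | Path, orientation: str = "rows") -> pd.DataFrame:
    """Read a delimited numeric matrix with one header row and one id column.

    Parameters
    ----------
    path
        Tab-separated file; first column holds row identifiers.
    orientation
        ``"rows"`` returns the file as-is; ``"columns"`` transposes it so
        that the file's columns become the returned rows.

    Returns
    -------
    pandas.DataFrame
        Float matrix. Non-numeric cells (including ``NA``) become NaN,
        the explicit missing-value flag.

    Raises
    ------
    ParseError
        On a malformed header, duplicated identifiers (the offending line
        number is named) or an empty matrix.
    """
    if orientation not in ("rows", "columns"):
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                          keep_default_na=False, header=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ParseError(f"{path}: empty matrix (shape {raw.shape[0]}x{raw.shape[1]})")
    if any(c == "" or c is None for c in raw.columns):
        raise ParseError(f"{path}: malformed header line 1 (blank column id)")
    dup_cols = raw.columns[raw.columns.duplicated()]
    if len(dup_cols):
        raise ParseError(f"{path}: duplicated column id {dup_cols[0]!r} in header (line 1)")
    dup_mask = raw.index.duplicated()
    if dup_mask.any():
        pos = int(dup_mask.argmax())
        raise ParseError(
            f"{path}: duplicated row id {raw.index[pos]!r} at line {pos + 2}"
        )
    values = raw.apply(pd.to_numeric, errors="coerce")
    values.index.name = raw.index.name
    if orientation == "columns":
        values = values.T
    logger.info("read_matrix %s: %d rows x %d cols", path, *values.shape)
    return values


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_matrix` parses back."""
    matrix.to_csv(Path(path), sep="\t", na_rep=NA_TOKEN, index_label=matrix.index.name or "id")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> unique member genes."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def sets_containing(self, gene: str) -> list[str]:
        return [name for name, genes in self.sets.items() if gene in genes]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Raises :class:`ParseError` for lines with fewer than three fields or a
    repeated set name.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno} has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}: duplicated set name {name!r} at line {lineno}")
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}: duplicate genes in set {name!r} at line {lineno}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in the dialect :func:`read_gmt` parses back."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fields = [name, desc, *genes] if genes else [name, desc, ""]
            fh.write("\t".join(fields) + "\n")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table: columns sample_id, time, event (tab-separated).

    Times must be finite and non-negative; event must be 0 (censored) or 1.
    Rows with missing time or event are kept as NaN for the caller's
    follow-up handling to drop explicitly.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str},
                     na_values=[NA_TOKEN], keep_default_na=False)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicated sample_id {dup!r}")
    valid = df["time"].dropna()
    if (valid < 0).any():
        raise ParseError(f"{path}: negative survival time")
    ev = df["event"].dropna()
    if not ev.isin([0, 1]).all():
        raise ParseError(f"{path}: event values must be 0 or 1")
    return df


def write_survival_table(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(Path(path), sep="\t", index=False, na_rep=NA_TOKEN)
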