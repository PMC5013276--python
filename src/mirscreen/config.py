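"""Run configuration with the pipeline's published default cutoffs.

Defaults: coefficient-of-variation cutoff 0.25 and correlation cutoff
|r| = 0.5 for the screen classifier, a two-of-four database consensus rule,
and a 5-year follow-up horizon for distant relapse-free survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .targets import DEFAULT_DB_RULES, DatabaseRule


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


@dataclass
class RunConfig:
    seed: int = 0
    cv_cutoff: float = 0.25
    corr_cutoff: float = 0.5
    min_databases: int = 2
    db_rules: tuple[DatabaseRule, ...] = DEFAULT_DB_RULES
    followup_years: float = 5.0
    out_dir: str = "mirscreen_out"

    def __post_init__(self) -> None:
        problems = []
        if self.cv_cutoff < 0:
            problems.append(f"cv_cutoff must be >= 0 (got {self.cv_cutoff})")
        if not (0 < self.corr_cutoff <= 1):
            problems.append(f"corr_cutoff must be in (0, 1] (got {self.corr_cutoff})")
        if self.min_databases < 1:
            problems.append(f"min_databases must be >= 1 (got {self.min_databases})")
        if self.followup_years <= 0:
            problems.append(f"followup_years must be > 0 (got {self.followup_years})")
        if problems:
            raise ConfigError("; ".join(problems))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing fields take the documented defaults."""
    if path is None:
        return RunConfig()
    with open(Path(path), encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    rules = data.pop("db_rules", None)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "db_rules"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown fields {sorted(unknown)}")
    cfg_kwargs = dict(data)
    if rules is not None:
        cfg_kwargs["db_rules"] = tuple(DatabaseRule(**r) for r in rules)
    return RunConfig(**cfg_kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config file that :func:`load_config` parses back equal."""
    data = asdict(config)
    data["db_rules"] = [asdict(r) for r in config.db_rules]
    with open(Path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
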