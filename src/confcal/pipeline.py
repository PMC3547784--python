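"""End-to-end analysis runs: records in, report bundle out.

A run takes judgment records — either read from a CSV or generated by
the synthetic cohort generator — validates them, and writes a bundle of
tidy result tables: per-judge calibration summaries, pooled stratum
summaries, calibration-curve point tables, group comparisons and
factorial ANOVAs, plus a JSON manifest echoing the configuration so the
run can be reproduced exactly. All randomness flows from the single
configured seed; identical configuration yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .calibration import DEFAULT_EDGES, summarise_by_judge, summarise_strata
from .comparisons import anova_report, compare_groups
from .curves import curves_by_stratum
from .synthetic_data import (
    DIFFICULT,
    EASY,
    GROUPS,
    RECORD_COLUMNS,
    AT_RISK,
    NOT_AT_RISK,
    CohortConfig,
    generate_cohort,
    read_records,
    write_records,
)

logger = logging.getLogger("confcal")

DEFAULT_STRATA: tuple[tuple[str, ...], ...] = (
    ("group",),
    ("time_pressure",),
    ("difficulty", "time_pressure"),
)


class ValidationError(ValueError):
    """Record validation failed in strict mode."""


@dataclass(frozen=True)
class Issue:
    row: Optional[int]
    column: Optional[str]
    message: str


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Exactly one of ``records_path`` (pre-existing judgment CSV) or
    ``cohort`` (synthetic-generation parameters) must be set.
    """

    records_path: Optional[str] = None
    cohort: Optional[CohortConfig] = None
    edges: tuple[float, ...] = DEFAULT_EDGES
    min_confidence: float = 0.5
    strata: tuple[tuple[str, ...], ...] = DEFAULT_STRATA
    output_dir: str = "confcal_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.records_path is None) == (self.cohort is None):
            raise ValueError("exactly one of records_path or cohort must be set")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load a run configuration from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    cohort = raw.pop("cohort", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(RunConfig)}})
    if cohort is not None:
        cfg.cohort = CohortConfig(**cohort)
    if "edges" in raw:
        cfg.edges = tuple(raw["edges"])
    cfg.strata = tuple(tuple(s) for s in cfg.strata)
    return cfg


def validate_records(
    source: Union[str, Path, pd.DataFrame], strict: bool = False
) -> tuple[pd.DataFrame, list[Issue]]:
    """Schema-check a judgment-record table.

    Returns the table plus a list of issues (out-of-range confidence,
    unknown category labels, duplicated judge x scenario pairs), each
    naming the offending row. In strict mode any issue raises
    :class:`ValidationError`.
    """
    records = source if isinstance(source, pd.DataFrame) else read_records(source)
    issues: list[Issue] = []
    for i, value in records["confidence"].items():
        if not 0 <= value <= 100:
            issues.append(Issue(i, "confidence", f"confidence {value} outside [0, 100]"))
    categorical = {
        "group": set(GROUPS),
        "difficulty": {EASY, DIFFICULT},
        "judgment": {AT_RISK, NOT_AT_RISK},
    }
    for column, allowed in categorical.items():
        bad = records.index[~records[column].isin(allowed)]
        for i in bad:
            issues.append(Issue(int(i), column, f"invalid {column} value {records.at[i, column]!r}"))
    dupes = records.index[records.duplicated(subset=["judge_id", "scenario_id"], keep="first")]
    for i in dupes:
        issues.append(
            Issue(
                int(i),
                None,
                f"duplicate (judge_id, scenario_id) pair "
                f"({records.at[i, 'judge_id']}, {records.at[i, 'scenario_id']})",
            )
        )
    if strict and issues:
        raise ValidationError(
            "; ".join(f"row {x.row}: {x.message}" for x in issues[:10])
        )
    return records, issues


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of the bundle files."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "input"
    try:
        if config.cohort is not None:
            cohort = dataclasses.replace(config.cohort, seed=config.seed)
            records = generate_cohort(cohort)
            outputs["records"] = outdir / "records.csv"
            write_records(records, outputs["records"])
        else:
            records = read_records(config.records_path)
        records, issues = validate_records(records, strict=True)

        stage = "calibration"
        per_judge = summarise_by_judge(records, config.edges)
        outputs["per_judge"] = outdir / "per_judge.csv"
        _write_csv(per_judge, outputs["per_judge"])

        stratum_frames = [
            summarise_strata(records, by, config.edges) for by in config.strata
        ]
        strata_table = pd.concat(stratum_frames, ignore_index=True)
        outputs["strata"] = outdir / "strata.csv"
        _write_csv(strata_table, outputs["strata"])

        stage = "curves"
        curve_frames = []
        excluded: dict[str, float] = {}
        for by in config.strata:
            table, exc = curves_by_stratum(records, by, config.edges, config.min_confidence)
            table.insert(0, "stratum", "+".join(by))
            curve_frames.append(table)
            for key, frac in exc.items():
                excluded["+".join(f"{c}={v}" for c, v in zip(by, key))] = frac
        outputs["curves"] = outdir / "curves.csv"
        _write_csv(pd.concat(curve_frames, ignore_index=True), outputs["curves"])

        stage = "comparisons"
        comparisons = pd.concat(
            [compare_groups(per_judge), anova_report(records)], ignore_index=True
        )
        outputs["comparisons"] = outdir / "comparisons.csv"
        _write_csv(comparisons, outputs["comparisons"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "confcal_version": __version__,
        "seed": config.seed,
        "config": {
            "records_path": config.records_path,
            "cohort": config.cohort.to_dict() if config.cohort else None,
            "edges": list(config.edges),
            "min_confidence": config.min_confidence,
            "strata": [list(s) for s in config.strata],
        },
        "n_records": int(len(records)),
        "n_judges": int(records["judge_id"].nunique()),
        "validation_issues": len(issues),
        "excluded_fraction_by_curve": excluded,
        "outputs": {k: p.name for k, p in outputs.items()},
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %d records, %d judges", len(records), manifest["n_judges"])
    return outputs
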