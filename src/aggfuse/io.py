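"""Readers and writers for feature tables, cubes, measures and reports.

All files are plain text: comma-separated UTF-8 CSV with a mandatory
header and '.' decimals, or JSON.  Generator / run configuration can be
given as YAML or JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from .fusion import EvaluationReport, ProbabilityCube
from .measures import FuzzyMeasure
from .synthetic import CLASS_LABELS, FeatureSpec, GeneratorConfig, default_feature_specs

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_feature_table",
    "write_feature_table",
    "read_probability_cube",
    "write_probability_cube",
    "read_measure",
    "write_measure",
    "write_report",
    "read_report",
    "load_generator_config",
]


class SchemaError(ValueError):
    """Input file violates the expected tabular schema."""


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature table CSV.

    Requires ``participant_id`` and ``label`` columns and exactly one row
    per (participant, class); label values must be low/medium/high.
    """
    table = pd.read_csv(path)
    missing = {"participant_id", "label"} - set(table.columns)
    if missing:
        raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
    bad = set(table["label"].unique()) - set(CLASS_LABELS)
    if bad:
        raise SchemaError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")
    counts = table.groupby(["participant_id", "label"]).size()
    if (counts != 1).any():
        dup = counts[counts != 1].index.tolist()[:5]
        raise SchemaError(
            f"expected one row per (participant, class); offending: {dup}"
        )
    if table[ [c for c in table.columns if c not in ("participant_id", "label")] ].isna().any().any():
        raise SchemaError("feature table contains missing values")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_probability_cube(path: str | Path) -> ProbabilityCube:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return ProbabilityCube.from_json(path.read_text())
    return ProbabilityCube.from_long_frame(pd.read_csv(path))


def write_probability_cube(cube: ProbabilityCube, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(cube.to_json())
    else:
        cube.to_long_frame().to_csv(path, index=False)


def read_measure(path: str | Path) -> FuzzyMeasure:
    return FuzzyMeasure.from_dict(json.loads(Path(path).read_text()))


def write_measure(measure: FuzzyMeasure, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(measure.to_dict(), indent=2, sort_keys=True))


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write a ranking CSV plus a JSON twin with full metadata.

    The CSV at ``path`` holds the ranking sorted by mean accuracy
    descending (alphabetical tie-break); ``path`` with a ``.json`` suffix
    holds entries, per-repetition traces and metadata.  Byte output is
    deterministic for fixed inputs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.ranking.to_csv(path, index=False)
    path.with_suffix(".json").write_text(report.to_json())
    log.info("wrote report to %s (+ .json)", path)


def read_report(path: str | Path) -> EvaluationReport:
    """Read back a report from the JSON twin written by :func:`write_report`."""
    return EvaluationReport.from_json(Path(path).with_suffix(".json").read_text())


def load_generator_config(path: str | Path | None, seed: int = 0) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML/JSON file (or defaults).

    Recognized keys: ``n_participants``, ``effect_scale``,
    ``participant_sd``, ``seed`` and an optional ``features`` list of
    per-feature overrides ``{name, base, sd, pattern, distribution}``.
    """
    if path is None:
        return GeneratorConfig(seed=seed)
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    specs = {s.name: s for s in default_feature_specs()}
    for item in data.pop("features", []) or []:
        name = item["name"]
        if name not in specs:
            raise SchemaError(f"unknown feature {name!r} in config")
        fields = {k: v for k, v in item.items() if k != "name"}
        if "pattern" in fields:
            fields["pattern"] = tuple(float(x) for x in fields["pattern"])
        specs[name] = replace(specs[name], **fields)
    known = {"n_participants", "effect_scale", "participant_sd", "seed", "n_classes"}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    data.setdefault("seed", seed)
    return GeneratorConfig(feature_specs=tuple(specs.values()), **data)
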