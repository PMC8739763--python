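"""Reading and writing of rate tables, scenario configs, and run manifests.

Rate tables travel as long-format CSV with columns ``age_lo, age_hi, field,
value, units``.  Values are annual rates per person-year; transplant rates
may instead be given per 100 person-years with ``units =
per_100_person_years`` and are divided by 100 on read.  Scalar transplant
rates use the full 0-90 bracket.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .parameters import (
    AGE_MAX,
    AGE_MIN,
    BRACKET_FIELDS,
    SCALAR_FIELDS,
    RateTable,
    ScenarioConfig,
    TableValidationError,
)

CSV_COLUMNS = ("age_lo", "age_hi", "field", "value", "units")
_UNITS = ("per_person_year", "per_100_person_years")


def write_rate_table(table: RateTable, path) -> None:
    """Serialize ``table`` to long-format CSV (annual per-person-year units)."""
    rows = []
    for name in BRACKET_FIELDS:
        arr = getattr(table, name)
        for (lo, hi), value in zip(table.age_brackets, arr):
            rows.append(
                {"age_lo": lo, "age_hi": hi, "field": name,
                 "value": value, "units": "per_person_year"}
            )
    for name in SCALAR_FIELDS:
        rows.append(
            {"age_lo": AGE_MIN, "age_hi": AGE_MAX, "field": name,
             "value": getattr(table, name), "units": "per_person_year"}
        )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def read_rate_table(path) -> RateTable:
    """Parse and validate a long-format rate-table CSV.

    Raises :class:`TableValidationError` naming missing brackets, unknown
    fields, bad units, or negative values (with their row numbers).
    """
    frame = pd.read_csv(path)
    got = tuple(frame.columns)
    if set(got) != set(CSV_COLUMNS):
        raise TableValidationError(
            f"expected columns {CSV_COLUMNS}, got {got}"
        )
    bad_units = frame.loc[~frame["units"].isin(_UNITS)]
    if len(bad_units):
        raise TableValidationError(
            f"unknown units {sorted(bad_units['units'].unique())}; "
            f"expected one of {_UNITS}"
        )
    negative = frame.index[frame["value"] < 0].tolist()
    if negative:
        raise TableValidationError(
            f"negative rate values at data rows {negative}"
        )
    known = set(BRACKET_FIELDS) | set(SCALAR_FIELDS)
    unknown = sorted(set(frame["field"]) - known)
    if unknown:
        raise TableValidationError(f"unknown rate fields: {unknown}")

    values = frame["value"].to_numpy(dtype=float).copy()
    values[frame["units"].to_numpy() == "per_100_person_years"] /= 100.0
    frame = frame.assign(value=values)

    kwargs: dict = {}
    brackets: tuple[tuple[int, int], ...] | None = None
    for name in BRACKET_FIELDS:
        sub = frame[frame["field"] == name].sort_values("age_lo")
        if sub.empty:
            raise TableValidationError(f"missing rate field {name!r}")
        field_brackets = tuple(
            (int(lo), int(hi)) for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        )
        _check_coverage(name, field_brackets)
        if brackets is None:
            brackets = field_brackets
        elif field_brackets != brackets:
            raise TableValidationError(
                f"field {name!r} uses different age brackets than "
                f"{BRACKET_FIELDS[0]!r}"
            )
        kwargs[name] = sub["value"].to_numpy()
    for name in SCALAR_FIELDS:
        sub = frame[frame["field"] == name]
        if sub.empty:
            raise TableValidationError(f"missing rate field {name!r}")
        if len(sub) != 1:
            raise TableValidationError(
                f"scalar field {name!r} must appear exactly once, got {len(sub)}"
            )
        kwargs[name] = float(sub["value"].iloc[0])
    return RateTable(age_brackets=brackets, **kwargs)


def _check_coverage(name: str, brackets: tuple[tuple[int, int], ...]) -> None:
    gaps = []
    cursor = AGE_MIN
    for lo, hi in brackets:
        if lo > cursor:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < AGE_MAX:
        gaps.append((cursor, AGE_MAX))
    if gaps:
        raise TableValidationError(
            f"field {name!r} does not cover ages "
            + ", ".join(f"[{lo}, {hi})" for lo, hi in gaps)
        )


# ---------------------------------------------------------------------------
# Scenario configuration files
# ---------------------------------------------------------------------------

def read_scenario_config(path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise TableValidationError(f"{path}: expected a mapping of config fields")
    valid = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise TableValidationError(f"{path}: unknown config fields {unknown}")
    return ScenarioConfig(**data)


def write_scenario_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir, *, seed: int | None, config_echo: dict, inputs: list = ()
) -> Path:
    """Write ``manifest.json`` recording inputs, seed, and package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "txseq",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "config": config_echo,
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
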