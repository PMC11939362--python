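"""File formats and configuration loading.

Cell fields travel as comma-separated CSV, human-facing summary and
comparison tables as TSV in the published column order.  Fuzzy variables
load from a YAML file (units, universe, per-grade breakpoints), rules from
a plain-text file (four antecedent tokens + consequent per line).  All
files are UTF-8 with "." as the decimal separator.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fuzzy as fz
from .metrics import REQUIRED_COLUMNS
from .pipeline import PeriodConditions

__all__ = [
    "packaged_path",
    "load_variables",
    "load_rules",
    "read_cell_field",
    "write_cell_field",
    "read_schedule",
    "write_schedule",
    "write_summary_table",
    "write_comparison_table",
    "config_digest",
]

log = logging.getLogger(__name__)

SCHEDULE_COLUMNS = ("period", "discharge_m3s", "water_level_m", "manning",
                    "temperature_C")


class ParseError(ValueError):
    """Malformed delimited input; the message names the file, row and column."""


def packaged_path(name: str) -> Path:
    """Path of a packaged default data file."""
    return Path(str(resources.files("spawnhab").joinpath("data", name)))


def load_variables(path: str | Path | None = None) -> dict[str, fz.FuzzyVariable]:
    """Load fuzzy variables (four factors + hsi) from YAML; defaults packaged."""
    path = Path(path) if path is not None else packaged_path("variables.yml")
    raw = yaml.safe_load(path.read_text())
    expected = set(fz.INPUT_FACTORS) | {"hsi"}
    if set(raw) != expected:
        raise fz.ConfigurationError(
            f"{path}: expected variables {sorted(expected)}, got {sorted(raw)}"
        )
    out = {}
    for name, cfg in raw.items():
        try:
            sets = {
                label: fz.FuzzySet.from_breakpoints(label, bps)
                for label, bps in cfg["sets"].items()
            }
            out[name] = fz.FuzzyVariable(
                name=name, units=str(cfg["units"]),
                universe=tuple(float(v) for v in cfg["universe"]), sets=sets,
            )
        except (KeyError, TypeError) as exc:
            raise fz.ConfigurationError(f"{path}: malformed variable {name!r}") from exc
    return out


def load_rules(path: str | Path | None = None, tag: str = "4-factor") -> fz.RuleBase:
    """Load a rule base from a rule file; default is the packaged four-factor base."""
    path = Path(path) if path is not None else packaged_path("rules_4factor.txt")
    return fz.RuleBase.from_text(path.read_text(), tag=tag)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, c]!r} in column "
                f"{c!r}, row {row}"
            )
        df[c] = coerced
    return df


def read_cell_field(path: str | Path) -> pd.DataFrame:
    """Read a cell-field CSV (cell_id, area_m2, depth_m, velocity_ms, ...)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, REQUIRED_COLUMNS, path)
    numeric = [c for c in df.columns
               if c in REQUIRED_COLUMNS + ("grain_d_m", "hsi", "x_m", "y_m")]
    df = _require_numeric(df, numeric, path)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ParseError(f"{path}: duplicate cell id {dup!r}")
    return df


def write_cell_field(field: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    field.to_csv(path, index=False)


def read_schedule(path: str | Path) -> list[PeriodConditions]:
    """Read a semi-monthly schedule CSV into PeriodConditions records."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SCHEDULE_COLUMNS, path)
    df = _require_numeric(df, SCHEDULE_COLUMNS[1:], path)
    if df["period"].duplicated().any():
        dup = df.loc[df["period"].duplicated(), "period"].iloc[0]
        raise ParseError(f"{path}: duplicate period {dup!r}")
    return [
        PeriodConditions(
            period=str(r.period),
            discharge_m3s=float(r.discharge_m3s),
            water_level_m=float(r.water_level_m),
            manning=float(r.manning),
            temperature_C=float(r.temperature_C),
        )
        for r in df.itertuples()
    ]


def write_schedule(schedule: list[PeriodConditions], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "period": c.period,
                "discharge_m3s": c.discharge_m3s,
                "water_level_m": c.water_level_m,
                "manning": c.manning,
                "temperature_C": c.temperature_C,
            }
            for c in schedule
        ]
    ).to_csv(path, index=False)


def write_summary_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the per-period summary table as TSV (published layout)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def write_comparison_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def config_digest(*paths: str | Path) -> str:
    """Short digest of configuration files, for run logs."""
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:12]
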