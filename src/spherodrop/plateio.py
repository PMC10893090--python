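"""Shared I/O: plate-map CSV, image folders, configs, and result bundles.

Plate maps are plain CSV (comma-separated, UTF-8, mandatory header, "."
decimal separator) with columns::

    plate,well,x_mm,y_mm,doses,target_volume_uL,expected_cells

Writing then reading a plan is lossless. Well names are validated against
the plate format and must be unique per plate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spherodrop.planner import (
    DispensePlan,
    PlatePosition,
    parse_well_name,
)

PLATE_MAP_COLUMNS = [
    "plate",
    "well",
    "x_mm",
    "y_mm",
    "doses",
    "target_volume_uL",
    "expected_cells",
]


def write_plate_map(plan: DispensePlan, path: str | Path) -> None:
    """Write a dispense plan to plate-map CSV."""
    rows = [
        {
            "plate": p.plate,
            "well": p.well,
            "x_mm": p.x_mm,
            "y_mm": p.y_mm,
            "doses": plan.doses_per_position,
            "target_volume_uL": plan.target_volume,
            "expected_cells": plan.expected_cells_per_drop,
        }
        for p in plan.positions
    ]
    pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS).to_csv(path, index=False)


def read_plate_map(path: str | Path, plate_format: int | None = None) -> DispensePlan:
    """Read a plate-map CSV back into a dispense plan.

    Validates the header, well names (against ``plate_format`` when given,
    otherwise inferred from the largest well coordinate), and per-plate
    well uniqueness. Malformed rows raise with their line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path} is missing columns {missing}")
    if plate_format is None:
        plate_format = 96 if len(df) and _fits_96(df) else 384
    seen: set[tuple[int, str]] = set()
    positions: list[PlatePosition] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            parse_well_name(str(row["well"]), plate_format)
            plate = int(row["plate"])
            pos = PlatePosition(
                plate=plate,
                well=str(row["well"]),
                x_mm=float(row["x_mm"]),
                y_mm=float(row["y_mm"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"plate map {path} line {line}: {exc}") from exc
        key = (plate, pos.well)
        if key in seen:
            raise ValueError(
                f"plate map {path} line {line}: duplicate well {pos.well!r} on plate {plate}"
            )
        seen.add(key)
        positions.append(pos)
    if df.empty:
        raise ValueError(f"plate map {path} has no rows")
    doses = int(df["doses"].iloc[0])
    return DispensePlan(
        positions=tuple(positions),
        doses_per_position=doses,
        expected_cells_per_drop=float(df["expected_cells"].iloc[0]),
        target_volume=float(df["target_volume_uL"].iloc[0]),
    )


def _fits_96(df: pd.DataFrame) -> bool:
    try:
        for w in df["well"]:
            parse_well_name(str(w), 96)
    except ValueError:
        return False
    return len(df) <= 96 * (df["plate"].nunique() or 1)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict (sorted-key JSON, sha256)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_json_report(payload: dict, path: str | Path) -> None:
    """Write a result report as JSON, converting numpy scalars to Python."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(f"cannot serialize {type(obj)!r}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
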