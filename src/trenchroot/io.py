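"""Tabular I/O and run configuration.

All files are plain CSV (UTF-8, comma delimiter, ``.`` decimal) with
depths in meters; a cm import flag converts at the boundary because
field sheets commonly record depth in cm.  Deposited spreadsheet data
(XLSX) is brought into the pipeline with a one-shot converter driven by
an explicit sheet/column mapping, since workbook layouts vary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import CubeObservation, ROOT_CLASSES
from .mapping import RldMap, TrenchGrid

__all__ = [
    "CUBE_COLUMNS",
    "RunConfig",
    "read_cube_counts",
    "write_cube_counts",
    "read_trench_grid",
    "write_trench_grid",
    "write_rld_map",
    "load_config",
    "import_s1",
    "provenance",
]

log = logging.getLogger("trenchroot")

#: Required columns of a cube-counts CSV; rld_measured is optional.
CUBE_COLUMNS = [
    "cube_id",
    "variety",
    "das",
    "depth_m",
    "distance_cm",
    "replicate",
    "root_class",
    "ni_h",
    "ni_t",
    "ni_l",
    "face_area_m2",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with the calibrated defaults built in."""

    model: str = "geometric_all"
    min_count: int = 3
    averaging_keys: tuple = ("variety", "das", "depth_z", "distance_cm", "root_class")
    constants: dict = dc_field(default_factory=dict)  # per-kind {slope_a, intercept_b}
    simulate: dict = dc_field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    rounding: str = "table"  # 'table' or 'full'

    _KNOWN = {
        "model",
        "min_count",
        "averaging_keys",
        "constants",
        "simulate",
        "seed",
        "output_dir",
        "rounding",
    }


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - RunConfig._KNOWN
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "averaging_keys" in raw:
        raw["averaging_keys"] = tuple(raw["averaging_keys"])
    return RunConfig(**raw)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_cube_counts(
    path: Union[str, Path], depth_unit: str = "m"
) -> list[CubeObservation]:
    """Read a cube-counts CSV into typed observations.

    Malformed rows raise with their (1-based, header-inclusive) line
    number.  ``depth_unit='cm'`` converts depths on import.
    """
    if depth_unit not in ("m", "cm"):
        raise ValueError("depth_unit must be 'm' or 'cm'")
    df = pd.read_csv(path)
    _require_columns(df, CUBE_COLUMNS, path)
    scale = 0.01 if depth_unit == "cm" else 1.0
    out = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rld = row.get("rld_measured", np.nan)
            obs = CubeObservation(
                cube_id=str(row["cube_id"]),
                depth_z=float(row["depth_m"]) * scale,
                ni_h=float(row["ni_h"]),
                ni_t=float(row["ni_t"]),
                ni_l=float(row["ni_l"]),
                face_area=float(row["face_area_m2"]),
                variety=str(row["variety"]),
                das=int(row["das"]),
                distance_cm=float(row["distance_cm"]),
                replicate=int(row["replicate"]),
                root_class=str(row["root_class"]),
                rld_measured=None if pd.isna(rld) else float(rld),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
        out.append(obs)
    log.info("read %d cube observations from %s", len(out), path)
    return out


def write_cube_counts(cubes: Sequence[CubeObservation], path: Union[str, Path]) -> None:
    """Write observations back to the cube-counts CSV layout (lossless)."""
    df = pd.DataFrame(
        {
            "cube_id": [c.cube_id for c in cubes],
            "variety": [c.variety for c in cubes],
            "das": [c.das for c in cubes],
            "depth_m": [c.depth_z for c in cubes],
            "distance_cm": [c.distance_cm for c in cubes],
            "replicate": [c.replicate for c in cubes],
            "root_class": [c.root_class for c in cubes],
            "ni_h": [c.ni_h for c in cubes],
            "ni_t": [c.ni_t for c in cubes],
            "ni_l": [c.ni_l for c in cubes],
            "face_area_m2": [c.face_area for c in cubes],
            "rld_measured": [
                np.nan if c.rld_measured is None else c.rld_measured for c in cubes
            ],
        }
    )
    df.to_csv(path, index=False)


def read_trench_grid(path: Union[str, Path], cell_size: float = 0.05) -> TrenchGrid:
    """Read a long-format grid CSV (depth_row, lateral_col, count).

    Missing (row, col) combinations are zero cells; the grid extends to
    the largest indices present.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["depth_row", "lateral_col", "count"], path)
    if df.empty:
        raise ValueError(f"{path}: empty grid file")
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    n_rows = int(df["depth_row"].max()) + 1
    n_cols = int(df["lateral_col"].max()) + 1
    counts = np.zeros((n_rows, n_cols), dtype=float)
    counts[df["depth_row"].to_numpy(int), df["lateral_col"].to_numpy(int)] = df[
        "count"
    ].to_numpy()
    meta_cols = [
        c for c in df.columns if c not in ("depth_row", "lateral_col", "count")
    ]
    metadata = {c: df[c].iloc[0] for c in meta_cols}
    if "cell_size_m" in metadata:
        cell_size = float(metadata.pop("cell_size_m"))
    return TrenchGrid(counts=counts, cell_size=cell_size, metadata=metadata)


def write_trench_grid(grid: TrenchGrid, path: Union[str, Path]) -> None:
    """Write a grid in the long CSV format read_trench_grid expects."""
    rows, cols = np.nonzero(np.ones_like(grid.counts))
    df = pd.DataFrame(
        {
            "depth_row": rows,
            "lateral_col": cols,
            "count": grid.counts[rows, cols],
            "cell_size_m": grid.cell_size,
        }
    )
    df.to_csv(path, index=False)


def write_rld_map(rld_map: RldMap, path: Union[str, Path]) -> None:
    """Write an RLD map as a CSV matrix (rows = depth bins, header = columns)."""
    pd.DataFrame(rld_map.values).to_csv(path, index=False)


def import_s1(
    xlsx_path: Union[str, Path],
    sheet: Union[str, int],
    column_map: dict,
    out_csv: Optional[Union[str, Path]] = None,
    depth_unit: str = "m",
) -> pd.DataFrame:
    """One-shot converter from a deposited XLSX workbook to cube-counts CSV.

    ``column_map`` maps the workbook's column headers to the cube-counts
    schema (keys are CUBE_COLUMNS names plus optional ``rld_measured``).
    The mapping is explicit because deposited workbook layouts are not
    standardised.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{xlsx_path}: columns not found: {missing}")
    out = pd.DataFrame({dst: df[src] for dst, src in column_map.items()})
    _require_columns(out, CUBE_COLUMNS, xlsx_path)
    if depth_unit == "cm":
        out["depth_m"] = out["depth_m"] * 0.01
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def provenance(config: RunConfig, extra: Optional[dict] = None) -> dict:
    """Provenance record (version, config hash, seed) for reproducibility."""
    from . import __version__

    cfg = {
        "model": config.model,
        "min_count": config.min_count,
        "averaging_keys": list(config.averaging_keys),
        "constants": config.constants,
        "seed": config.seed,
    }
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]
    rec = {"version": __version__, "config_hash": digest, **cfg}
    if extra:
        rec.update(extra)
    log.info("provenance: %s", json.dumps(rec, sort_keys=True, default=str))
    return rec
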