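"""Trench-grid processing: 2-D RLD maps, depth profiles and summaries.

Root impacts on a trench face are counted in a square mesh (5 cm cells
by default).  Each cell's count becomes a RID, a calibrated model turns
it into an RLD at the cell's midpoint depth, and the resulting map is
summarised as a depth profile, a total root length per ground area
(rectangle-rule integral from the surface to the root front) and a
root-length:shoot-biomass ratio.

Conventions: depth increases downward, row 0 is at the surface, indices
are 0-based, and row i covers the half-open depth bin
``[origin + i*cell, origin + (i+1)*cell)`` with its midpoint as the
representative depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .geometry import RldModel, get_model

__all__ = [
    "TrenchGrid",
    "RldMap",
    "grid_to_rid",
    "map_rld",
    "depth_profile",
    "total_root_length",
    "root_front",
    "root_shoot_ratio",
]


@dataclass(frozen=True)
class TrenchGrid:
    """Impact counts on a trench face, binned on a square mesh."""

    counts: np.ndarray  # (rows, cols), row 0 at the surface
    cell_size: float = 0.05  # m
    origin_depth: float = 0.0  # m, top of row 0
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        object.__setattr__(self, "counts", counts)

    @property
    def depths(self) -> np.ndarray:
        """Midpoint depth of each row, m."""
        i = np.arange(self.counts.shape[0])
        return self.origin_depth + (i + 0.5) * self.cell_size


@dataclass(frozen=True)
class RldMap:
    """Per-cell RLD (m m^-3) derived from a trench grid."""

    values: np.ndarray  # (rows, cols)
    model_kind: str
    cell_size: float
    origin_depth: float = 0.0
    metadata: dict = dc_field(default_factory=dict)

    @property
    def depths(self) -> np.ndarray:
        i = np.arange(self.values.shape[0])
        return self.origin_depth + (i + 0.5) * self.cell_size


def grid_to_rid(grid: TrenchGrid) -> np.ndarray:
    """Per-cell RID: count over cell area (impacts m^-2)."""
    return grid.counts / grid.cell_size**2


def map_rld(grid: TrenchGrid, model: Union[RldModel, str]) -> RldMap:
    """Apply a calibrated model cell-wise using each row's midpoint depth.

    Only depth-dependent or constant models are usable here: a trench
    exposes a single vertical plane, so the per-cube Pv model
    (``geometric_pv``) has no orientation information to draw on.
    """
    if isinstance(model, str):
        model = get_model(model)
    if model.kind == "geometric_pv":
        raise ValueError(
            "geometric_pv needs three-face cube counts; a trench grid has one plane"
        )
    rid = grid_to_rid(grid)
    co = model.slope_a * grid.depths + model.intercept_b  # vector over rows
    values = rid * co[:, None]
    return RldMap(
        values=values,
        model_kind=model.kind,
        cell_size=grid.cell_size,
        origin_depth=grid.origin_depth,
        metadata=dict(grid.metadata),
    )


def depth_profile(rld_map: RldMap) -> pd.DataFrame:
    """Row-wise mean RLD across lateral positions.

    Returns a DataFrame with columns ``depth`` (row midpoints, m) and
    ``rld_mean`` (m m^-3).
    """
    if rld_map.values.size == 0:
        raise ValueError("empty map")
    return pd.DataFrame(
        {"depth": rld_map.depths, "rld_mean": rld_map.values.mean(axis=1)}
    )


def root_front(obj: Union[TrenchGrid, RldMap]) -> float:
    """Bottom depth of the deepest row with any roots (0 if none), m."""
    values = obj.counts if isinstance(obj, TrenchGrid) else obj.values
    nonzero_rows = np.nonzero(np.any(values > 0, axis=1))[0]
    if len(nonzero_rows) == 0:
        return 0.0
    return obj.origin_depth + (nonzero_rows[-1] + 1) * obj.cell_size


def total_root_length(rld_map: RldMap) -> float:
    """Total root length per ground area, m m^-2.

    Rectangle-rule integral of the depth profile from the surface to the
    root front: sum over rows of (mean RLD x bin thickness).  Rows below
    the deepest non-zero row contribute nothing by construction.
    """
    profile = depth_profile(rld_map)
    return float((profile["rld_mean"] * rld_map.cell_size).sum())


def root_shoot_ratio(total_length: float, shoot_biomass: float) -> float:
    """Total root length (m m^-2) per unit shoot biomass (g m^-2), m g^-1."""
    if shoot_biomass <= 0:
        raise ValueError("shoot_biomass must be > 0")
    if total_length < 0:
        raise ValueError("total_length must be >= 0")
    return total_length / shoot_biomass
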