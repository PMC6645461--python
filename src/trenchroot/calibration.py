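"""Data preparation and model calibration.

The calibration pipeline turns raw cube counts into a tidy table and
fits the depth relations that define the geometric models:

1. drop cubes with fewer than a minimum number of roots on any face
   (such cubes cannot quantify preferential orientation),
2. average replicate cubes sampled at the same (variety, date, depth,
   distance) position,
3. regress Pv (or CO) on depth across the retained, averaged cubes, or
   fit the empirical through-origin RLD-on-RID slope.

Calibration tables are plain :class:`pandas.DataFrame` objects with the
columns listed in :data:`CALIBRATION_COLUMNS`; no custom container is
introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geometry import (
    CubeObservation,
    OrientationUndefinedError,
    compute_pv,
    co_from_pv,
    PvDiscontinuityWarning,
)

__all__ = [
    "CALIBRATION_COLUMNS",
    "GROUP_KEYS",
    "LinearFit",
    "filter_min_roots",
    "build_calibration_table",
    "average_replicates",
    "fit_linear",
    "calibrate_orientation_depth",
    "calibrate_fine_constant",
    "calibrate_empirical_slope",
]

#: Columns of a tidy calibration table (one row per averaged cube/class).
CALIBRATION_COLUMNS = [
    "cube_id",
    "variety",
    "das",
    "depth_z",
    "distance_cm",
    "root_class",
    "rid_h",
    "rid_t",
    "rid_l",
    "rid_vertical",
    "pv",
    "co",
    "rld_measured",
    "n_replicates",
]

#: Replicate-averaging keys: cubes sharing these are repeated
#: measurements of the same sampling position.
GROUP_KEYS = ["variety", "das", "depth_z", "distance_cm", "root_class"]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary or through-origin least-squares fit of y on x.

    For through-origin fits ``r2`` is the squared Pearson correlation
    between fitted and observed values (the centered convention); the
    uncentered R^2 natural to a no-intercept model, which is typically
    larger, is reported separately as ``r2_uncentered``.
    """

    slope: float
    intercept: float
    r2: float
    n: int
    through_origin: bool = False
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    r2_uncentered: Optional[float] = None

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def filter_min_roots(
    cubes: Sequence[CubeObservation], min_count: int = 3
) -> list[CubeObservation]:
    """Drop cubes with fewer than ``min_count`` roots on any face.

    Cubes with very few impacts on one face cannot quantify preferential
    root orientation; the default threshold of three roots per face
    excludes them.  A face with exactly ``min_count`` impacts is
    retained.  Idempotent; returns a subset of the input.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [c for c in cubes if c.min_count >= min_count]


def _cube_rows(cubes: Iterable[CubeObservation]) -> pd.DataFrame:
    rows = []
    for c in cubes:
        rows.append(
            {
                "cube_id": c.cube_id,
                "variety": c.variety,
                "das": c.das,
                "depth_z": c.depth_z,
                "distance_cm": c.distance_cm,
                "root_class": c.root_class,
                "face_area": c.face_area,
                "rid_h": c.ni_h / c.face_area,
                "rid_t": c.ni_t / c.face_area,
                "rid_l": c.ni_l / c.face_area,
                "rld_measured": np.nan if c.rld_measured is None else c.rld_measured,
            }
        )
    return pd.DataFrame(rows)


def _finish_orientation(df: pd.DataFrame) -> pd.DataFrame:
    """Attach rid_vertical, pv and co columns computed from the RID triple."""
    denom = df["rid_t"] + df["rid_l"]
    if (denom == 0).any():
        bad = df.loc[denom == 0, "cube_id"].tolist()
        raise OrientationUndefinedError(
            f"cubes with no vertical-face impacts (filter first): {bad}"
        )
    df = df.copy()
    df["rid_vertical"] = 0.5 * denom
    df["pv"] = 2.0 * df["rid_h"] / denom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PvDiscontinuityWarning)
        df["co"] = co_from_pv(df["pv"].to_numpy())
    return df


def build_calibration_table(
    cubes: Sequence[CubeObservation], min_count: int = 3, average: bool = True
) -> pd.DataFrame:
    """Filter, optionally replicate-average, and derive orientation columns.

    Returns a tidy calibration table (see :data:`CALIBRATION_COLUMNS`).
    """
    kept = filter_min_roots(cubes, min_count=min_count)
    if not kept:
        return pd.DataFrame(columns=CALIBRATION_COLUMNS)
    if average:
        return average_replicates(kept)
    df = _finish_orientation(_cube_rows(kept))
    df["n_replicates"] = 1
    return df[CALIBRATION_COLUMNS]


def average_replicates(cubes: Sequence[CubeObservation]) -> pd.DataFrame:
    """Average repeated measurements at the same sampling position.

    Replicates share (variety, date, depth, distance, root class); their
    face RIDs and measured RLD are averaged arithmetically and the
    orientation indices are recomputed from the averaged RID triple.
    The number of source replicates is recorded per row.

    Raises
    ------
    ValueError
        If cubes within one group disagree on face area (their RIDs
        would not be commensurate).
    """
    df = _cube_rows(cubes)
    if df.empty:
        return pd.DataFrame(columns=CALIBRATION_COLUMNS)
    for _, grp in df.groupby(GROUP_KEYS, dropna=False):
        if grp["face_area"].nunique() > 1:
            raise ValueError(
                "conflicting face areas within a replicate group: "
                f"{grp['cube_id'].tolist()}"
            )
    agg = (
        df.groupby(GROUP_KEYS, dropna=False)
        .agg(
            cube_id=("cube_id", "first"),
            rid_h=("rid_h", "mean"),
            rid_t=("rid_t", "mean"),
            rid_l=("rid_l", "mean"),
            rld_measured=("rld_measured", "mean"),
            n_replicates=("cube_id", "size"),
        )
        .reset_index()
    )
    agg = _finish_orientation(agg)
    return agg[CALIBRATION_COLUMNS]


def fit_linear(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> LinearFit:
    """Least-squares line fit, ordinary or through the origin.

    Through-origin slope is sum(x*y)/sum(x^2) (the OLS solution without
    an intercept).  Ordinary fits require non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points")
    if through_origin:
        if not np.any(x != 0):
            raise ValueError("singular fit: all x are zero")
        res = sm.OLS(y, x[:, None]).fit()
        fitted = res.fittedvalues
        # centered R^2: squared Pearson correlation of fitted vs observed
        if np.std(fitted) > 0 and np.std(y) > 0:
            r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        else:
            r2 = 0.0
        return LinearFit(
            slope=float(res.params[0]),
            intercept=0.0,
            r2=r2,
            n=n,
            through_origin=True,
            slope_se=float(res.bse[0]),
            intercept_se=0.0,
            r2_uncentered=float(res.rsquared),
        )
    if np.ptp(x) == 0:
        raise ValueError("singular fit: x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = 1.0 if np.ptp(y) == 0 else float(res.rsquared)  # constant y fits itself
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=r2,
        n=n,
        through_origin=False,
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
    )


def _subset_class(table: pd.DataFrame, root_class: Optional[str]) -> pd.DataFrame:
    if root_class is None:
        return table
    return table[table["root_class"] == root_class]


def calibrate_orientation_depth(
    table: pd.DataFrame, target: str = "co", root_class: Optional[str] = None
) -> LinearFit:
    """OLS regression of Pv or CO on depth across a calibration table.

    This is the calibration that produces the depth-dependent geometric
    models: CO(z) = slope * z + intercept.
    """
    if target not in ("pv", "co"):
        raise ValueError("target must be 'pv' or 'co'")
    sub = _subset_class(table, root_class)
    if sub["depth_z"].nunique() < 2:
        raise ValueError("singular fit: need at least two distinct depths")
    return fit_linear(sub["depth_z"].to_numpy(), sub[target].to_numpy())


def calibrate_fine_constant(table: pd.DataFrame) -> float:
    """Mean per-cube CO over retained fine-root rows.

    Fine roots (< 1 mm) stay near-isotropic at all depths, so their
    model uses a single constant CO rather than a depth regression.
    """
    fine = table[table["root_class"] == "fine"]
    if fine.empty:
        raise ValueError("no fine-root rows in calibration table")
    return float(fine["co"].mean())


def calibrate_empirical_slope(table: pd.DataFrame, root_class: str = "all") -> LinearFit:
    """Through-origin fit of measured RLD on vertical-plane RID.

    This is the empirical model: a single RLD/RID slope with no
    orientation or depth correction.
    """
    sub = _subset_class(table, root_class).dropna(subset=["rld_measured"])
    if len(sub) < 2:
        raise ValueError("need at least two rows with measured RLD")
    return fit_linear(
        sub["rid_vertical"].to_numpy(),
        sub["rld_measured"].to_numpy(),
        through_origin=True,
    )
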