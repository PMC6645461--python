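"""Core estimation mathematics: RID, the vertical orientation index Pv,
the orientation coefficient CO, and the calibrated RLD models.

Root length density (RLD, m of root per m^3 of soil) is estimated from
root intersection density (RID, impacts per m^2 of exposed soil plane)
as ``RLD = RID * CO`` where CO is an orientation coefficient accounting
for the anisotropy of root growth directions.  CO is derived from the
vertical preferential-orientation index

    Pv = 2 * RID_h / (RID_t + RID_l)

computed from impact counts on the horizontal (h), vertical-transversal
(t) and vertical-longitudinal (l) faces of a soil cube.  Pv = 1 means an
isotropic root field (CO = 2, the classical stereological factor for
line processes); Pv < 1 means roots run preferentially parallel to the
reference vertical plane, Pv > 1 perpendicular to it.

Units are fixed throughout: RID in impacts m^-2, RLD in m m^-3, depth in
meters, positive downward.  Unit conversion happens only at the I/O
boundary (:mod:`trenchroot.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "CubeObservation",
    "OrientationResult",
    "RldModel",
    "RldEstimate",
    "BUILTIN_MODELS",
    "MODEL_KINDS",
    "ROOT_CLASSES",
    "OrientationUndefinedError",
    "PvDiscontinuityWarning",
    "compute_rid",
    "compute_pv",
    "co_from_pv",
    "rld_from_rid",
    "orientation_from_cube",
    "evaluate_model",
    "get_model",
]

ROOT_CLASSES = ("fine", "thick", "all")
MODEL_KINDS = (
    "empirical_all",
    "geometric_all",
    "geometric_fine",
    "geometric_thick",
    "geometric_pv",
)

#: |Pv - 1| below this is treated as exact isotropy (CO = 2).
PV_ISOTROPY_TOL = 1e-9

#: The two printed CO branches disagree just above Pv = 1 (the Pv > 1
#: branch tends to 19/15 as Pv -> 1+, not 2).  A diagnostic warning is
#: emitted inside this band.
PV_DISCONTINUITY_BAND = 1.05


class OrientationUndefinedError(ValueError):
    """Raised when Pv cannot be computed (no impacts on vertical faces)."""


class PvDiscontinuityWarning(UserWarning):
    """Pv fell in (1, 1.05], where the piecewise CO rule is discontinuous."""


@dataclass(frozen=True)
class CubeObservation:
    """Impact counts on the three exposed faces of one soil cube.

    The field protocol extracts 0.1 m soil cubes from a trench face,
    exposing a horizontal, a vertical-transversal and a
    vertical-longitudinal plane (face area 0.01 m^2 each by default).
    ``rld_measured`` is set only for calibration cubes whose roots were
    washed out and measured.
    """

    cube_id: str
    depth_z: float  # m, midpoint of the sampling depth, positive downward
    ni_h: float
    ni_t: float
    ni_l: float
    face_area: float = 0.01  # m^2
    variety: str = ""
    das: int = 0  # days after sowing
    distance_cm: float = 0.0  # sampling distance from the stalk base
    replicate: int = 1
    root_class: str = "all"  # fine: d < 1 mm, thick: d > 1 mm
    rld_measured: Optional[float] = None  # m m^-3, calibration cubes only

    def __post_init__(self) -> None:
        if self.ni_h < 0 or self.ni_t < 0 or self.ni_l < 0:
            raise ValueError(f"cube {self.cube_id!r}: negative impact count")
        if self.face_area <= 0:
            raise ValueError(f"cube {self.cube_id!r}: face_area must be > 0")
        if self.depth_z <= 0:
            raise ValueError(f"cube {self.cube_id!r}: depth_z must be > 0")
        if self.root_class not in ROOT_CLASSES:
            raise ValueError(
                f"cube {self.cube_id!r}: root_class {self.root_class!r} "
                f"not in {ROOT_CLASSES}"
            )

    @property
    def min_count(self) -> float:
        return min(self.ni_h, self.ni_t, self.ni_l)


@dataclass(frozen=True)
class OrientationResult:
    """RID triple plus the derived orientation quantities for one cube.

    ``rid_vertical`` is the predictor used for estimation: the mean of
    the two vertical-face RIDs when both were observed, or the single
    trench-face RID for grid data.
    """

    rid_h: float
    rid_t: float
    rid_l: float
    rid_vertical: float
    pv: float
    co: float


@dataclass(frozen=True)
class RldModel:
    """One calibrated RLD = f(RID, depth) estimator.

    CO is linear in depth, ``CO(z) = slope_a * z + intercept_b``; the
    constant models have ``slope_a = 0``.  ``geometric_pv`` carries no
    constants: its CO is computed per cube from the observed Pv.
    """

    kind: str
    slope_a: float = 0.0  # per meter
    intercept_b: float = 0.0
    applies_to: str = "all"

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def depth_dependent(self) -> bool:
        return self.slope_a != 0.0

    def co_at(self, depth_z: Optional[float] = None) -> float:
        """CO multiplier at a given depth (depth ignored for constant models)."""
        if self.kind == "geometric_pv":
            raise ValueError("geometric_pv has no depth-based CO; use co_from_pv")
        if self.depth_dependent:
            if depth_z is None:
                raise ValueError(f"model {self.kind!r} requires a depth")
            if depth_z <= 0:
                raise ValueError("depth_z must be > 0")
            return self.slope_a * depth_z + self.intercept_b
        return self.intercept_b


#: The four calibrated models with their published constants.  The
#: empirical model's 1.83 is a direct RLD/RID slope fitted through the
#: origin; the geometric models express CO as a linear function of depth
#: (all roots and thick roots) or a constant (fine roots, which stay
#: near-isotropic at all depths).
BUILTIN_MODELS: dict[str, RldModel] = {
    "empirical_all": RldModel("empirical_all", 0.0, 1.83, "all"),
    "geometric_all": RldModel("geometric_all", 0.471, 1.87, "all"),
    "geometric_fine": RldModel("geometric_fine", 0.0, 2.08, "fine"),
    "geometric_thick": RldModel("geometric_thick", 1.937, 1.42, "thick"),
    "geometric_pv": RldModel("geometric_pv", 0.0, 0.0, "all"),
}


def get_model(kind: str) -> RldModel:
    """Look up a built-in calibrated model by kind."""
    try:
        return BUILTIN_MODELS[kind]
    except KeyError:
        raise ValueError(
            f"unknown model {kind!r}; expected one of {sorted(BUILTIN_MODELS)}"
        ) from None


@dataclass(frozen=True)
class RldEstimate:
    """A single RLD estimate (m m^-3) with its provenance."""

    rld: float
    model_kind: str
    depth_z: Optional[float] = None


def compute_rid(ni: float, face_area: float) -> float:
    """Root intersection density: impact count per unit plane area.

    Parameters
    ----------
    ni : number of root impacts counted on the plane (>= 0).
    face_area : exposed plane area in m^2 (> 0).

    Returns
    -------
    RID in impacts m^-2.
    """
    if face_area <= 0:
        raise ValueError("face_area must be > 0")
    if ni < 0:
        raise ValueError("impact count must be >= 0")
    return ni / face_area


def compute_pv(rid_h: float, rid_t: float, rid_l: float) -> float:
    """Vertical preferential-orientation index Pv = 2*RID_h/(RID_t+RID_l).

    Raises
    ------
    OrientationUndefinedError
        If both vertical-face RIDs are zero: the cube carries no
        orientation information and must be filtered out.
    """
    if rid_h < 0 or rid_t < 0 or rid_l < 0:
        raise ValueError("RID values must be >= 0")
    denom = rid_t + rid_l
    if denom == 0:
        raise OrientationUndefinedError(
            "RID_t + RID_l = 0: preferential orientation is undefined"
        )
    return 2.0 * rid_h / denom


def _co_scalar(pv: float) -> float:
    if abs(pv - 1.0) <= PV_ISOTROPY_TOL:
        return 2.0
    if pv < 1.0:
        return (3.0 * pv * pv + 2.0 * pv + 1.0) / (2.0 * pv + 1.0)
    return (16.0 * pv * pv + 2.0 * pv + 1.0) / (10.0 * pv + 5.0)


def co_from_pv(pv: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Orientation coefficient CO for a given Pv (scalar or array).

    Piecewise rule::

        Pv < 1:  CO = (3 Pv^2 + 2 Pv + 1) / (2 Pv + 1)
        Pv = 1:  CO = 2                     (isotropy)
        Pv > 1:  CO = (16 Pv^2 + 2 Pv + 1) / (10 Pv + 5)

    Both branches equal 1 at Pv = 0 extremes of their ranges; the lower
    branch tends to 2 as Pv -> 1-, but the upper branch tends to 19/15
    as Pv -> 1+, so the published rule is discontinuous at isotropy.
    The formulas are implemented literally; a
    :class:`PvDiscontinuityWarning` is emitted for Pv in (1, 1.05] where
    the two branches disagree materially.
    """
    arr = np.asarray(pv, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Pv must be >= 0")
    in_band = (arr > 1.0 + PV_ISOTROPY_TOL) & (arr <= PV_DISCONTINUITY_BAND)
    if np.any(in_band):
        warnings.warn(
            "Pv in (1, 1.05]: the piecewise CO rule is discontinuous at "
            "Pv = 1 (upper branch -> 19/15, not 2); interpret CO with care",
            PvDiscontinuityWarning,
            stacklevel=2,
        )
    lower = (3.0 * arr**2 + 2.0 * arr + 1.0) / (2.0 * arr + 1.0)
    upper = (16.0 * arr**2 + 2.0 * arr + 1.0) / (10.0 * arr + 5.0)
    out = np.where(
        np.abs(arr - 1.0) <= PV_ISOTROPY_TOL,
        2.0,
        np.where(arr < 1.0, lower, upper),
    )
    if np.isscalar(pv) or np.ndim(pv) == 0:
        return float(out)
    return out


def rld_from_rid(rid: float, co: float) -> float:
    """RLD = RID * CO (m m^-3 from impacts m^-2)."""
    if rid < 0:
        raise ValueError("RID must be >= 0")
    if co <= 0:
        raise ValueError("CO must be > 0")
    return rid * co


def orientation_from_cube(cube: CubeObservation) -> OrientationResult:
    """Compute the full orientation result (RID triple, Pv, CO) for a cube.

    The estimation predictor ``rid_vertical`` is the arithmetic mean of
    the two vertical-face RIDs (symmetric in t/l and lower-variance than
    either face alone).
    """
    rid_h = compute_rid(cube.ni_h, cube.face_area)
    rid_t = compute_rid(cube.ni_t, cube.face_area)
    rid_l = compute_rid(cube.ni_l, cube.face_area)
    pv = compute_pv(rid_h, rid_t, rid_l)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PvDiscontinuityWarning)
        co = co_from_pv(pv)
    return OrientationResult(
        rid_h=rid_h,
        rid_t=rid_t,
        rid_l=rid_l,
        rid_vertical=0.5 * (rid_t + rid_l),
        pv=pv,
        co=float(co),
    )


def evaluate_model(
    model: Union[RldModel, str],
    rid: float,
    depth_z: Optional[float] = None,
    orientation: Optional[OrientationResult] = None,
) -> RldEstimate:
    """Estimate RLD from a vertical-plane RID with a calibrated model.

    Parameters
    ----------
    model : an :class:`RldModel` or a built-in model kind name.
    rid : vertical-plane root intersection density, impacts m^-2.
    depth_z : sampling depth in m; required for depth-dependent models.
    orientation : full orientation result; required for ``geometric_pv``,
        whose CO is computed per cube from the observed Pv.
    """
    if isinstance(model, str):
        model = get_model(model)
    if rid < 0:
        raise ValueError("RID must be >= 0")
    if model.kind == "geometric_pv":
        if orientation is None:
            raise ValueError("geometric_pv requires an OrientationResult")
        co = orientation.co
    else:
        co = model.co_at(depth_z)
    return RldEstimate(rld=rld_from_rid(rid, co), model_kind=model.kind, depth_z=depth_z)
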