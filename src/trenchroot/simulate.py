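"""Monte Carlo root-segment fields with known true RLD.

The simulator scatters straight line segments of fixed length in a
periodic 3-D soil box with a prescribed total length density (the true
RLD) and a controllable orientation law, then observes them exactly the
way the field protocol does: by counting segment crossings through
virtual planes, three-face soil cubes, and trench grids.  Because the
true RLD and the orientation law are known by construction, the fields
serve as geometric oracles for the RID -> RLD estimation chain — in the
isotropic limit the classical stereological ratio RLD/RID = 2 must be
recovered — and as fixture generators for the calibration and
validation pipeline.

Periodic wrapping (rather than clipping or rejection at the walls)
keeps the length density exact in every sub-window, so crossing counts
are unbiased everywhere in the box.

Orientation laws
----------------
``isotropic``
    directions uniform on the upper hemisphere.
``vertical_power(kappa)``
    density of |cos theta| proportional to |cos theta|**kappa; kappa = 0
    is isotropic, larger kappa concentrates directions toward the
    vertical, kappa in (-1, 0) toward the horizontal plane.
``axis_mixture(fx, fy, fz)``
    segments exactly parallel to the axes with the given length
    fractions; crossing densities have closed forms (a plane normal to
    an axis sees exactly that axis' length density), so expected Pv is
    2*fz/(fx+fy).
``depth_linear_pv(alpha, beta)``
    depth-graded anisotropy: each segment's target Pv is alpha*z + beta
    at its midpoint depth z, realised by inverting the vertical_power
    family's Pv(kappa) map.  This emulates root systems that grow more
    vertically with depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import beta as beta_fn

from .geometry import CubeObservation, compute_pv, co_from_pv

__all__ = [
    "Isotropic",
    "VerticalPower",
    "AxisMixture",
    "DepthLinearPv",
    "SegmentField",
    "VirtualObservation",
    "IsotropyResult",
    "generate_field",
    "count_crossings",
    "virtual_cube_sample",
    "virtual_trench_grid",
    "isotropy_oracle",
    "generate_tabular",
    "pv_of_kappa",
    "kappa_for_pv",
    "pv_from_co",
]

PLANE_AXIS = {"t": 0, "l": 1, "h": 2}  # face label -> normal axis


@dataclass(frozen=True)
class Isotropic:
    pass


@dataclass(frozen=True)
class VerticalPower:
    kappa: float

    def __post_init__(self):
        if self.kappa <= -1:
            raise ValueError("kappa must be > -1")


@dataclass(frozen=True)
class AxisMixture:
    fx: float
    fy: float
    fz: float

    def __post_init__(self):
        f = (self.fx, self.fy, self.fz)
        if any(v < 0 for v in f) or not math.isclose(sum(f), 1.0, abs_tol=1e-9):
            raise ValueError("axis fractions must be >= 0 and sum to 1")


@dataclass(frozen=True)
class DepthLinearPv:
    alpha: float  # per meter
    beta: float  # Pv at the surface

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("surface Pv (beta) must be > 0")


OrientationSpec = Union[Isotropic, VerticalPower, AxisMixture, DepthLinearPv]


def pv_of_kappa(kappa: float) -> float:
    """Expected Pv of a vertical_power(kappa) field (closed form).

    For a line process the crossing density through a plane with unit
    normal n is the length density times E|u . n|.  With |cos theta|
    distributed as u**kappa on [0, 1]:

        E|u_z| = (kappa+1)/(kappa+2)
        E|u_x| = (2/pi) * (kappa+1)/2 * B((kappa+1)/2, 3/2)

    and Pv = E|u_z| / E|u_x| (= 1 at kappa = 0, monotone in kappa).
    """
    if kappa <= -1:
        raise ValueError("kappa must be > -1")
    e_uz = (kappa + 1.0) / (kappa + 2.0)
    e_ux = (2.0 / math.pi) * 0.5 * (kappa + 1.0) * beta_fn((kappa + 1.0) / 2.0, 1.5)
    return e_uz / e_ux


def kappa_for_pv(pv: float) -> float:
    """Invert :func:`pv_of_kappa` numerically (Pv monotone in kappa)."""
    if pv <= 0:
        raise ValueError("Pv must be > 0")
    lo, hi = -1.0 + 1e-9, 1e4
    if not (pv_of_kappa(lo) < pv < pv_of_kappa(hi)):
        raise ValueError(f"Pv={pv} outside the representable range")
    return brentq(lambda k: pv_of_kappa(k) - pv, lo, hi, xtol=1e-12)


def pv_from_co(co: float, branch: str = "auto") -> float:
    """Invert the piecewise CO(Pv) rule.

    CO is monotone on each branch, but their ranges overlap: the lower
    branch (Pv < 1) spans [1, 2) and the upper branch (Pv > 1) spans
    (19/15, inf), so a CO in (19/15, 2] has a preimage on both sides of
    isotropy.  ``branch='auto'`` resolves the ambiguity toward the
    near-isotropic convention (lower branch for CO < 2, Pv = 1 at
    CO = 2); pass ``'lower'`` or ``'upper'`` to force a side.
    """
    import warnings as _warnings

    from .geometry import PvDiscontinuityWarning

    if branch not in ("auto", "lower", "upper"):
        raise ValueError("branch must be 'auto', 'lower' or 'upper'")
    if branch == "auto":
        if co < 1.0:
            raise ValueError("CO must be >= 1 on the lower branch")
        if abs(co - 2.0) <= 1e-12:
            return 1.0
        branch = "lower" if co < 2.0 else "upper"
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", PvDiscontinuityWarning)
        if branch == "lower":
            if not 1.0 <= co <= 2.0:
                raise ValueError("lower-branch CO lies in [1, 2]")
            if co == 2.0:
                return 1.0
            return brentq(lambda p: co_from_pv(p) - co, 0.0, 1.0, xtol=1e-13)
        if co <= 19.0 / 15.0:
            raise ValueError("upper-branch CO exceeds 19/15")
        # start just outside the isotropy tolerance band around Pv = 1
        return brentq(lambda p: co_from_pv(p) - co, 1.0 + 1e-8, 1e6, xtol=1e-10)


@dataclass(frozen=True)
class SegmentField:
    """A simulated field of root segments in a periodic box."""

    box: tuple[float, float, float]  # extents in m; z positive downward
    midpoints: np.ndarray  # (n, 3), inside the box
    directions: np.ndarray  # (n, 3), unit vectors
    segment_length: float  # m, identical for all segments
    orientation: OrientationSpec
    seed: int

    @property
    def n_segments(self) -> int:
        return len(self.midpoints)

    @property
    def volume(self) -> float:
        return self.box[0] * self.box[1] * self.box[2]

    @property
    def true_rld(self) -> float:
        """Exact total segment length per box volume, m m^-3."""
        return self.n_segments * self.segment_length / self.volume


@dataclass(frozen=True)
class VirtualObservation:
    """Crossing count through one virtual plane window."""

    plane: str  # 'h', 't' or 'l'
    offset: float  # plane coordinate along its normal axis, m
    window_area: float  # m^2
    count: int
    rid: float  # impacts m^-2


@dataclass(frozen=True)
class IsotropyResult:
    """Stereological check on a simulated field."""

    ratio: float  # true RLD / mean RID over the three plane orientations
    pv: float  # 2*RID_h / (RID_t + RID_l) from the pooled plane counts
    rid_h: float
    rid_t: float
    rid_l: float


def _sample_directions(
    spec: OrientationSpec, z: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(z)
    if isinstance(spec, AxisMixture):
        axes = rng.choice(3, size=n, p=[spec.fx, spec.fy, spec.fz])
        d = np.zeros((n, 3))
        d[np.arange(n), axes] = 1.0
        return d
    if isinstance(spec, Isotropic):
        uz = rng.uniform(0.0, 1.0, n)
    elif isinstance(spec, VerticalPower):
        uz = rng.uniform(0.0, 1.0, n) ** (1.0 / (spec.kappa + 1.0))
    elif isinstance(spec, DepthLinearPv):
        pv = spec.alpha * z + spec.beta
        if np.any(pv <= 0):
            raise ValueError("depth_linear_pv produces non-positive Pv in the box")
        # invert Pv -> kappa on a grid (Pv(kappa) is smooth and monotone)
        kgrid = np.concatenate(
            [-1 + np.geomspace(1e-6, 1.0, 200), np.geomspace(1e-4, 200.0, 400)]
        )
        kgrid = np.unique(kgrid)
        pvgrid = np.array([pv_of_kappa(k) for k in kgrid])
        kappa = np.interp(pv, pvgrid, kgrid)
        uz = rng.uniform(0.0, 1.0, n) ** (1.0 / (kappa + 1.0))
    else:
        raise TypeError(f"unknown orientation spec {spec!r}")
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(np.clip(1.0 - uz**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), uz])


def generate_field(
    rld_target: float,
    orientation: OrientationSpec = Isotropic(),
    box: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    segment_length: float = 0.02,
) -> SegmentField:
    """Scatter segments with the requested length density and orientation.

    Midpoints are uniform in the box; the segment count is the nearest
    integer to ``rld_target * volume / segment_length``, so the realised
    :attr:`SegmentField.true_rld` matches the request to within one
    segment's length.  Identical inputs and seed give identical fields.
    """
    if rld_target <= 0:
        raise ValueError("rld_target must be > 0")
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    if any(b <= 0 for b in box):
        raise ValueError("box extents must be > 0")
    if segment_length >= min(box):
        raise ValueError("segment_length must be smaller than the box")
    volume = box[0] * box[1] * box[2]
    n = int(round(rld_target * volume / segment_length))
    if n == 0:
        raise ValueError("rld_target too small: zero segments")
    rng = np.random.default_rng(seed)
    mid = rng.uniform(0.0, 1.0, (n, 3)) * np.asarray(box)
    dirs = _sample_directions(orientation, mid[:, 2], rng)
    return SegmentField(
        box=tuple(box),
        midpoints=mid,
        directions=dirs,
        segment_length=segment_length,
        orientation=orientation,
        seed=seed,
    )


def count_crossings(
    field: SegmentField,
    plane: str,
    offset: float,
    window: Optional[Sequence[tuple[float, float]]] = None,
) -> VirtualObservation:
    """Count segments crossing a plane window, with periodic wrapping.

    Parameters
    ----------
    plane : 'h' (normal z), 't' (normal x) or 'l' (normal y).
    offset : plane coordinate along its normal axis, within the box.
    window : ((lo, hi), (lo, hi)) intervals along the two in-plane axes
        in ascending axis order; None means the full box cross-section.
        Membership uses half-open intervals [lo, hi).

    A segment crosses if its two endpoints straddle the plane (or one of
    its periodic images) and the crossing point, wrapped into the box,
    falls inside the window.  Segments are shorter than the box, so each
    contributes at most one crossing per plane.
    """
    if plane not in PLANE_AXIS:
        raise ValueError("plane must be one of 'h', 't', 'l'")
    axis = PLANE_AXIS[plane]
    if not 0.0 <= offset <= field.box[axis]:
        raise ValueError("plane offset outside the box")
    others = [a for a in (0, 1, 2) if a != axis]
    if window is None:
        window = [(0.0, field.box[a]) for a in others]
    window = [tuple(map(float, w)) for w in window]
    for (lo, hi), a in zip(window, others):
        if not (0.0 <= lo < hi <= field.box[a]):
            raise ValueError("window outside the box")
    area = (window[0][1] - window[0][0]) * (window[1][1] - window[1][0])

    pts = _plane_crossing_points(field, plane, offset)
    inside = np.ones(len(pts), dtype=bool)
    for (lo, hi), a in zip(window, others):
        inside &= (pts[:, a] >= lo) & (pts[:, a] < hi)
    count = int(inside.sum())
    return VirtualObservation(plane, offset, area, count, count / area)


def _plane_crossing_points(
    field: SegmentField, plane: str, offset: float
) -> np.ndarray:
    """Wrapped in-box coordinates of every segment-plane crossing."""
    axis = PLANE_AXIS[plane]
    half = 0.5 * field.segment_length * field.directions
    a_pts = field.midpoints - half
    b_pts = field.midpoints + half
    za, zb = a_pts[:, axis], b_pts[:, axis]
    lo_c, hi_c = np.minimum(za, zb), np.maximum(za, zb)
    box_a = field.box[axis]
    kmin = np.ceil((lo_c - offset) / box_a)
    kmax = np.floor((hi_c - offset) / box_a)
    crosses = (kmax >= kmin) & (zb != za)
    idx = np.nonzero(crosses)[0]
    if len(idx) == 0:
        return np.empty((0, 3))
    t = (offset + kmin[idx] * box_a - za[idx]) / (zb[idx] - za[idx])
    pts = a_pts[idx] + t[:, None] * (b_pts[idx] - a_pts[idx])
    return np.mod(pts, np.asarray(field.box))


def _clipped_length_in_box(
    field: SegmentField, lo: np.ndarray, hi: np.ndarray
) -> float:
    """Exact total segment length inside an axis-aligned sub-box.

    Each segment is shifted to its periodic image nearest the sub-box
    center before slab clipping; valid while the sub-box plus a segment
    length fits inside the field box, which holds for 0.1 m cubes in a
    1 m box.
    """
    center = 0.5 * (lo + hi)
    box = np.asarray(field.box)
    shift = np.round((center - field.midpoints) / box) * box
    mid = field.midpoints + shift
    half = 0.5 * field.segment_length * field.directions
    a_pts, b_pts = mid - half, mid + half
    d = b_pts - a_pts
    t0 = np.zeros(len(mid))
    t1 = np.ones(len(mid))
    for ax in range(3):
        da = d[:, ax]
        aa = a_pts[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            tl = (lo[ax] - aa) / da
            th = (hi[ax] - aa) / da
        tlo = np.where(da >= 0, tl, th)
        thi = np.where(da >= 0, th, tl)
        par_in = (da == 0) & (aa >= lo[ax]) & (aa <= hi[ax])
        tlo = np.where(da == 0, np.where(par_in, 0.0, 1.0), tlo)
        thi = np.where(da == 0, np.where(par_in, 1.0, 0.0), thi)
        t0 = np.maximum(t0, tlo)
        t1 = np.minimum(t1, thi)
    frac = np.clip(t1 - t0, 0.0, None)
    return float(frac.sum() * field.segment_length)


def virtual_cube_sample(
    field: SegmentField,
    depth_z: float,
    cube_edge: float = 0.1,
    center_xy: Optional[tuple[float, float]] = None,
    cube_id: str = "sim",
    root_class: str = "all",
    **metadata,
) -> CubeObservation:
    """Observe the field through a three-face soil cube at a given depth.

    Emulates the two-cube, six-face protocol: impacts are counted on
    both faces of each opposite pair (top/bottom horizontal, the two
    transversal, the two longitudinal faces) and the pair counts are
    averaged, then rounded to whole impacts.  The cube's true RLD (exact
    clipped segment length over the cube volume) is recorded as
    ``rld_measured``, standing in for the washed-root measurement.

    ``depth_z`` is the cube's center depth; the cube must fit in the box.
    """
    e = cube_edge
    if center_xy is None:
        center_xy = (field.box[0] / 2.0, field.box[1] / 2.0)
    lo = np.array([center_xy[0] - e / 2, center_xy[1] - e / 2, depth_z - e / 2])
    hi = lo + e
    if np.any(lo < 0) or np.any(hi > np.asarray(field.box)):
        raise ValueError("cube outside the box")
    others = {"h": (0, 1), "t": (1, 2), "l": (0, 2)}
    counts = {}
    for face, axis in PLANE_AXIS.items():
        win = [(lo[a], hi[a]) for a in others[face]]
        c1 = count_crossings(field, face, lo[axis], win).count
        c2 = count_crossings(field, face, hi[axis], win).count
        counts[face] = int(round(0.5 * (c1 + c2)))
    rld_true = _clipped_length_in_box(field, lo, hi) / e**3
    return CubeObservation(
        cube_id=cube_id,
        depth_z=depth_z,
        ni_h=counts["h"],
        ni_t=counts["t"],
        ni_l=counts["l"],
        face_area=e * e,
        root_class=root_class,
        rld_measured=rld_true,
        **metadata,
    )


def virtual_trench_grid(
    field: SegmentField,
    plane: str = "t",
    offset: float = 0.5,
    cell_size: float = 0.05,
) -> np.ndarray:
    """Count crossings on a vertical trench plane binned into grid cells.

    Returns a (depth rows x lateral columns) integer count matrix with
    row 0 at the surface, emulating the 5 cm mesh grid pressed against a
    trench face.
    """
    if plane not in ("t", "l"):
        raise ValueError("a trench plane is vertical: use 't' or 'l'")
    axis = PLANE_AXIS[plane]
    lateral_axis = 1 - axis  # the other horizontal axis
    n_rows = int(field.box[2] / cell_size)
    n_cols = int(field.box[lateral_axis] / cell_size)
    pts = _plane_crossing_points(field, plane, offset)
    counts, _, _ = np.histogram2d(
        pts[:, 2],
        pts[:, lateral_axis],
        bins=[n_rows, n_cols],
        range=[[0.0, n_rows * cell_size], [0.0, n_cols * cell_size]],
    )
    return counts.astype(int)


def isotropy_oracle(
    rld_target: float = 10000.0,
    seed: int = 0,
    box: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_offsets: int = 5,
    segment_length: float = 0.02,
) -> IsotropyResult:
    """Stereological consistency check on an isotropic field.

    Generates an isotropic field, counts crossings through full-box
    cross sections at several offsets per plane orientation, and returns
    the ratio of the true RLD to the mean RID.  For isotropic line
    processes the expected ratio is 2 — the constant the estimation
    chain uses at isotropy — and the pooled Pv is 1 by symmetry.
    """
    field = generate_field(rld_target, Isotropic(), box, seed, segment_length)
    rids = {}
    for face, axis in PLANE_AXIS.items():
        vals = []
        for i in range(n_offsets):
            off = (i + 0.5) / n_offsets * field.box[axis]
            vals.append(count_crossings(field, face, off).rid)
        rids[face] = float(np.mean(vals))
    mean_rid = float(np.mean(list(rids.values())))
    if mean_rid == 0:
        raise ValueError("no crossings observed; increase rld_target")
    pv = compute_pv(rids["h"], rids["t"], rids["l"])
    return IsotropyResult(
        ratio=field.true_rld / mean_rid,
        pv=pv,
        rid_h=rids["h"],
        rid_t=rids["t"],
        rid_l=rids["l"],
    )


def generate_tabular(
    model_or_pv,
    depths: Sequence[float],
    n_per_depth: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    rld_median: float = 3000.0,
    rld_sigma: float = 0.6,
    face_area: float = 0.01,
    root_class: str = "all",
    variety: str = "synthetic",
    das: int = 60,
    distance_cm: float = 10.0,
):
    """Generate a calibration table that satisfies the model by construction.

    Each row represents one averaged cube: Pv is set to ``alpha*z +
    beta`` (plus optional Gaussian noise) when a Pv(Z) pair is given, or
    derived from the model's CO(z) when an :class:`RldModel` is given;
    CO follows from the piecewise rule; measured RLD is drawn lognormal
    (median ``rld_median``, log-sd ``rld_sigma`` — field RLDs span
    orders of magnitude); and the RID triple is back-computed so that
    RLD = RID_v * CO and Pv = 2 RID_h / (RID_t + RID_l) hold exactly
    with RID_t = RID_l = RID_v.  Whole-impact counts at the given face
    area are stored alongside (columns ni_h/ni_t/ni_l) for pipelines
    that start from counts; the float columns stay exact so noiseless
    tables reproduce the generating coefficients to machine precision.

    Returns a DataFrame in calibration-table layout.
    """
    from .geometry import RldModel  # local to avoid cycle in type hints
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    depths = np.asarray(list(depths), dtype=float)
    z = np.repeat(depths, n_per_depth)
    n = len(z)
    if isinstance(model_or_pv, RldModel):
        co = np.array([model_or_pv.co_at(zi) for zi in z])
        if noise_sd > 0:
            co = co + rng.normal(0.0, noise_sd, n)
        if np.any(co < 1.0):
            raise ValueError("noise produced CO < 1; reduce noise_sd")
        pv = np.array([pv_from_co(c) for c in co])
    else:
        alpha, beta = model_or_pv
        pv = alpha * z + beta
        if noise_sd > 0:
            pv = pv + rng.normal(0.0, noise_sd, n)
        if np.any(pv <= 0):
            raise ValueError("parameters produce non-positive Pv")
        import warnings as _warnings

        from .geometry import PvDiscontinuityWarning

        with _warnings.catch_warnings():
            # tables are consistent by construction; the discontinuity
            # diagnostic is for observed data
            _warnings.simplefilter("ignore", PvDiscontinuityWarning)
            co = np.asarray(co_from_pv(pv))
    rld = rng.lognormal(math.log(rld_median), rld_sigma, n)
    rid_v = rld / co
    rid_h = 0.5 * pv * (2.0 * rid_v)  # Pv = 2 rid_h / (rid_t + rid_l)
    rows = pd.DataFrame(
        {
            "cube_id": [f"sim-{i:04d}" for i in range(n)],
            "variety": variety,
            "das": das,
            "depth_z": z,
            "distance_cm": distance_cm,
            "root_class": root_class,
            "rid_h": rid_h,
            "rid_t": rid_v,
            "rid_l": rid_v,
            "rid_vertical": rid_v,
            "pv": pv,
            "co": co,
            "rld_measured": rld,
            "n_replicates": 1,
            "ni_h": np.rint(rid_h * face_area).astype(int),
            "ni_t": np.rint(rid_v * face_area).astype(int),
            "ni_l": np.rint(rid_v * face_area).astype(int),
            "face_area": face_area,
        }
    )
    return rows
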