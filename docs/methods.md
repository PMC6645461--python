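# Methods

## The estimation model

The package estimates root length density (RLD, m m⁻³) from root
intersection density (RID, impacts m⁻²) as `RLD = RID_v · CO`, where
`RID_v` is the intersection density on a vertical soil plane and CO is
an orientation coefficient. The underlying picture is a stereological
one: roots are treated as a spatial line process, and the density of
intersections a plane records is the length density times the mean
absolute cosine of the angle between root direction and the plane
normal. For an isotropic line process every plane orientation sees
`RID = RLD / 2`, so CO = 2 exactly at isotropy.

Anisotropy is quantified per soil cube by the vertical
preferential-orientation index `Pv = 2·RID_h / (RID_t + RID_l)`
computed from the three orthogonal exposed faces (horizontal,
vertical-transversal, vertical-longitudinal). Pv = 1 is isotropy; Pv < 1
means roots run preferentially parallel to the reference vertical plane,
Pv > 1 perpendicular to it. CO follows from Pv through a piecewise
rational rule (see README) implemented literally in
`trenchroot.geometry.co_from_pv`.

**Known discontinuity.** The two non-isotropic branches do not meet at
Pv = 1: the lower branch tends to 2 (consistent with the isotropic
value) while the upper branch tends to 19/15 ≈ 1.27. We keep the
branches exactly as published and emit a `PvDiscontinuityWarning`
whenever an observed Pv falls in (1, 1.05], where the disagreement is
material. A side effect worth knowing: the two branch ranges overlap
(the lower branch spans [1, 2), the upper (19/15, ∞)), so a CO value in
(19/15, 2) has preimages on both sides of isotropy; the numerical
inverse `pv_from_co` resolves ties toward the near-isotropic (lower)
branch unless a branch is forced. A further consequence is that CO
computed literally from the piecewise rule can *decrease* as Pv crosses
1 from below, so a CO-versus-depth regression on data straddling
isotropy can have a smaller (even negative) slope than the same
regression computed on Pv. The depth-calibrated model constants shipped
with the package are stored as published, not re-derived, precisely to
insulate users from this quirk.

**Calibrated models.** Four estimators are built in, with constants
stored exactly as published: `empirical_all` (RLD = 1.83·RID),
`geometric_all` (CO = 0.471·Z + 1.87), `geometric_fine` (CO = 2.08) and
`geometric_thick` (CO = 1.937·Z + 1.42), with Z the depth in meters,
positive downward. `geometric_pv` computes CO per cube from the
observed Pv instead of depth. The fine/thick split is a 1 mm diameter
threshold and is a property of the input labels, never inferred.

## Calibration pipeline

1. **Minimum-count filter.** Cubes with fewer than 3 impacts on any
   face are discarded: with so few roots the orientation index is
   essentially noise. A face with exactly 3 is retained. The rule is
   applied per root-class row, so a cube can be retained for all roots
   while its thick-root row (lower counts) is dropped.
2. **Replicate averaging.** Cubes sharing (variety, date, depth,
   distance, root class) are repeated measurements of one sampling
   position; their face RIDs and measured RLD are averaged
   arithmetically and Pv/CO are recomputed from the averaged RID triple.
   The group size is carried so totals remain reconstructible.
3. **Depth regressions.** Pv (or CO) is regressed on depth by unweighted
   ordinary least squares (statsmodels). The fine-root model is the
   mean per-cube CO rather than a regression, since fine-root
   orientation barely depends on depth.
4. **Empirical slope.** The empirical model is a through-origin OLS fit
   of measured RLD on vertical-plane RID. For through-origin fits we
   report the centered R² (squared Pearson correlation between fitted
   and observed values) because the uncentered convention natural to
   no-intercept models typically inflates R²; the uncentered value is
   exposed alongside (`LinearFit.r2_uncentered`) for auditability.

## Validation statistics

Between measured (m) and calculated (c) RLD, with n pairs:

* `NE = 1 − Σ(cᵢ−mᵢ)² / Σ(mᵢ−m̄)²` — Nash–Sutcliffe efficiency,
  (−∞, 1], 1 ideal; equals R² when c are OLS-fitted values of m.
* `NRMSE = 100/(max m − min m) · √(Σ(cᵢ−mᵢ)²/n)` — percent of the
  observed range; < 10 % very good, > 25 % poor. The radical is part of
  the definition (it is a *root*-mean-square error); a no-root variant
  is available behind a flag for auditing since some renderings of the
  formula omit it.
* `MB = 100·Σ(cᵢ−mᵢ)/(n·m̄)` — mean bias percent, negative =
  underestimation.
* `d = 1 − Σ|cᵢ−mᵢ| / Σ(|mᵢ−c̄| + |cᵢ−c̄|)` — index of agreement,
  [−1, 1]. Both denominator terms deviate from the mean of the
  *calculated* values; the classical index centers on the observed mean,
  but we keep the convention used by the validation tables this package
  reproduces.

The report regresses calculated on measured by default (slope > 1 reads
as overestimation); a flag swaps the direction. Display rounding (two
decimals for slope/R²/NE, three for d, integers for the percentages) is
applied only at serialization; full precision is kept internally.

## The segment-field simulator

`trenchroot.simulate` scatters straight segments of fixed length
(default 0.02 m) with uniform midpoints in a periodic box (default
1 m³) at a prescribed length density, then observes them exactly as the
field protocol does: plane crossing counts, three-face 0.1 m cubes
(both faces of each opposite pair counted and averaged, mimicking the
two-cube six-face sampling), and 5 cm trench grids. Design choices:

* **Periodic wrapping** rather than clipping or rejection at the walls,
  so the length density — and therefore every expected crossing
  density — is exact in any sub-window; edge effects would otherwise
  bias cubes and grid cells near the boundary.
* **Fixed segment length.** Crossing statistics of a line process
  depend only on length density and orientation, not on how length is
  divided into segments, so a length distribution would add variance
  without adding generality.
* **Counts are Poisson-like by construction** (independent uniform
  positions); no overdispersion knob is provided.
* **Orientation laws.** `isotropic`; `vertical_power(kappa)` with
  |cos θ| density ∝ |cos θ|^κ (κ = 0 isotropic, κ → ∞ vertical, κ ∈
  (−1, 0) horizontal), whose expected Pv has the closed form
  `Pv(κ) = E|u_z|/E|u_x|` with `E|u_z| = (κ+1)/(κ+2)` and `E|u_x| =
  (κ+1)/π · B((κ+1)/2, 3/2)`; `axis_mixture(fx, fy, fz)` with
  axis-parallel segments in given length fractions (expected Pv =
  2fz/(fx+fy), a closed-form test oracle); and
  `depth_linear_pv(alpha, beta)`, which targets Pv = α·z + β at each
  segment's depth by inverting Pv(κ).
* **True cube RLD** is the exact clipped segment length inside the cube
  volume (slab clipping of the nearest periodic image), standing in for
  the washed-root measurement.

The isotropic field is an *exact* oracle: RLD/RID → 2 on every plane
orientation, which validates both the simulator and the CO = 2 constant
the estimators rest on. The anisotropic branches of the CO rule are
**not** claimed unbiased for these orientation laws — the published
rule's underlying orientation family is unstated — so anisotropic
fields validate pipeline plumbing and qualitative behaviour (Pv rising
with depth), not branch-level unbiasedness.

The tabular generator builds calibration tables that satisfy the model
by construction: Pv = α·Z + β (plus optional Gaussian noise), CO from
the piecewise rule, measured RLD lognormal with median 3000 m m⁻³ and
log-sd 0.6 (field RLDs span roughly 0–20,000 m m⁻³ and are strongly
right-skewed), RID back-computed so RLD = RID_v·CO holds exactly, and
whole-impact counts at 0.01 m² faces stored alongside. Noiseless tables
therefore reproduce their generating coefficients to machine precision,
which is what the exact-recovery tests assert. Depth levels default to
six evenly spaced midpoints from 0.1 to 1.1 m, matching the calibration
sampling design.

What the generator does *not* emulate: root branching topology and
curvature, diameter-dependent orientation within a class, spatial
clustering around the stalk, counting error by the field operator, and
any soil heterogeneity. Passing tests on synthetic data therefore show
the estimation chain is internally consistent and recovers known
parameters under the model's own assumptions — not that the calibrated
constants transfer to soils or crops unlike those they were fitted on.

## Profile mapping conventions

Grid cells are square (default 0.05 m). A cell's depth is its row
midpoint; depth bins are half-open `[z, z+cell)`, row 0 at the surface,
depth increasing downward. RID per cell is count/cell²; a constant- or
depth-CO model is applied row-wise (the per-cube Pv model is
unavailable on a single plane and is rejected). The depth profile is
the lateral mean per row; total root length per ground area is the
rectangle-rule sum Σ(mean RLD × cell height), which runs to the root
front automatically since deeper rows are zero; the root front is the
bottom edge of the deepest non-zero row. Maps from the two trench
distances (10 and 30 cm) are kept separate and may be averaged with
equal weight — how the original field maps merged them is not
documented, so the package makes no claim there.

## Numerical choices

* Isotropy tolerance: |Pv − 1| ≤ 1e−9 maps to CO = 2 exactly.
* Discontinuity diagnostic band: Pv ∈ (1, 1.05].
* `kappa_for_pv` and `pv_from_co` invert monotone scalar maps with
  Brent's method (xtol 1e−12 / 1e−10); `depth_linear_pv` sampling uses
  a 600-point monotone interpolation grid of Pv(κ) over κ ∈ (−1, 200].
* Cube counts from averaged opposite faces are rounded to whole
  impacts, matching what a field operator records.
* Degenerate inputs raise rather than propagate NaN: zero vertical-face
  RID (undefined Pv), constant observations (undefined NE/NRMSE),
  single-depth calibration tables (singular regression).

## Problem sizes

The test suite and the reproduction script use an isotropic field of
10,000 m m⁻³ in a 1 m³ box (500,000 segments, ≈ 5,000 expected
crossings per full plane, Monte Carlo error on the RLD/RID ratio well
under the ±0.05 acceptance band), parameter-recovery runs of 100
replicates at n = 70 cubes each, and end-to-end pipelines at
4,000–5,000 m m⁻³ with 24 virtual cubes and a 20×20 trench grid. These
sizes give sampling errors comfortably inside the asserted tolerances
while keeping the whole suite fast.

## Known limitations

* The piecewise CO rule is discontinuous at Pv = 1 as published; CO
  regressions across the discontinuity are unreliable (see above).
* The calibrated constants are specific to the crop, soil and seasons
  they were fitted in; for different soils the calibration module
  should be re-run on local cube data.
* Thick-root estimates are noisy at low counts — the minimum-count
  filter removes the worst cubes but cannot make three impacts
  informative.
* The simulator's oracles are exact only at isotropy.
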