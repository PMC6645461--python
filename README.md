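# trenchroot

Root length density estimation from root counts on trench profiles and
soil cubes, for field phenotyping of crop root systems (developed around
pearl millet grown on deep sandy Sahelian soils, but recalibratable to
other crops and soils).

Root length density (RLD, m of root per m³ of soil) determines the soil
volume a root system explores, hence the water and nutrients available
to the plant — but measuring it directly means washing roots out of soil
monoliths. In the trench method one instead counts **root intersection
density** (RID, root impacts per m² of exposed soil plane) on the face
of a trench dug next to the plant, which takes minutes per profile. The
two are linked by

```
RLD = RID · CO
```

where CO is an **orientation coefficient** that corrects for root
anisotropy. For an isotropic root field CO = 2 (the classical
stereological factor for line processes). In general CO is derived from
the vertical preferential-orientation index measured on three orthogonal
faces of a 0.1 m soil cube (horizontal *h*, vertical-transversal *t*,
vertical-longitudinal *l*):

```
Pv = 2·RID_h / (RID_t + RID_l)

Pv < 1 : CO = (3Pv² + 2Pv + 1) / (2Pv + 1)      (roots parallel to the plane)
Pv = 1 : CO = 2                                  (isotropic)
Pv > 1 : CO = (16Pv² + 2Pv + 1) / (10Pv + 5)    (roots perpendicular)
```

Because root orientation in the field depends mainly on depth, the
package ships four calibrated estimators: an empirical all-roots model
`RLD = 1.83·RID`; depth-dependent geometric models `RLD =
(0.471·Z + 1.87)·RID` for all roots and `RLD = (1.937·Z + 1.42)·RID`
for thick roots (diameter > 1 mm); and a constant `RLD = 2.08·RID` for
fine roots (< 1 mm), which stay near-isotropic at all depths. A
recalibration pipeline (minimum-count filtering, replicate averaging,
depth regressions), validation statistics (Nash–Sutcliffe efficiency,
normalized RMSE, mean bias, index of agreement), 2-D RLD profile
mapping, and a Monte Carlo segment-field simulator with known true RLD
complete the toolkit.

## Worked example

A soil cube sampled at 0.40 m depth shows 12 impacts on its horizontal
face and 9 and 11 on its two vertical faces (0.01 m² each):

```python
from trenchroot import CubeObservation, orientation_from_cube, evaluate_model

cube = CubeObservation("T1-30cm-z0.4", depth_z=0.4, ni_h=12, ni_t=9, ni_l=11,
                       variety="Souna3", das=60, root_class="all")
ori = orientation_from_cube(cube)
print(f"RID_v = {ori.rid_vertical:.0f} impacts/m^2, Pv = {ori.pv:.2f}")
est = evaluate_model("geometric_all", ori.rid_vertical, cube.depth_z)
print(f"geometric_all RLD at 0.40 m: {est.rld:.0f} m/m^3")
```

prints

```
RID_v = 1000 impacts/m^2, Pv = 1.20
geometric_all RLD at 0.40 m: 2058 m/m^3
```

The vertical-face RID is 1000 impacts/m²; Pv = 1.2 says roots at this
depth run slightly perpendicular to the trench plane; the calibrated
all-roots model applies CO(0.40 m) = 0.471·0.40 + 1.87 ≈ 2.06, giving
about 2060 m of root per m³ of soil.

The same chain is available from the shell — `trenchroot estimate`,
`calibrate`, `validate`, `map` and `simulate`; see `trenchroot --help`.
For example, mapping a trench grid CSV to an RLD map, a depth profile
and the total root length per m² of ground:

```bash
trenchroot map --grid grid.csv --model geometric_all --out-prefix plot1
```

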