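"""Segment-field simulator: construction invariants and the crossing oracle."""

import math

import numpy as np
import pytest

from trenchroot import (
    AxisMixture,
    DepthLinearPv,
    Isotropic,
    SegmentField,
    VerticalPower,
    count_crossings,
    generate_field,
    generate_tabular,
    isotropy_oracle,
    virtual_cube_sample,
    virtual_trench_grid,
)
from trenchroot.simulate import (
    PLANE_AXIS,
    kappa_for_pv,
    pv_from_co,
    pv_of_kappa,
)
from trenchroot.geometry import co_from_pv


def brute_force_crossings(field, plane, offset, window=None):
    """Independent O(n) re-implementation of the crossing count."""
    axis = PLANE_AXIS[plane]
    others = [a for a in (0, 1, 2) if a != axis]
    if window is None:
        window = [(0.0, field.box[a]) for a in others]
    count = 0
    for mid, direc in zip(field.midpoints, field.directions):
        a = mid - 0.5 * field.segment_length * direc
        b = mid + 0.5 * field.segment_length * direc
        if a[axis] == b[axis]:
            continue
        lo, hi = sorted((a[axis], b[axis]))
        k = math.ceil((lo - offset) / field.box[axis])
        while offset + k * field.box[axis] <= hi:
            t = (offset + k * field.box[axis] - a[axis]) / (b[axis] - a[axis])
            point = a + t * (b - a)
            ok = True
            for (wlo, whi), ax in zip(window, others):
                coord = point[ax] % field.box[ax]
                if not (wlo <= coord < whi):
                    ok = False
            if ok:
                count += 1
            k += 1
    return count


def manual_field(midpoints, directions, length=0.1, box=(1.0, 1.0, 1.0)):
    return SegmentField(
        box=box,
        midpoints=np.atleast_2d(np.asarray(midpoints, float)),
        directions=np.atleast_2d(np.asarray(directions, float)),
        segment_length=length,
        orientation=Isotropic(),
        seed=0,
    )


class TestGenerateField:
    def test_total_length_matches_request(self):
        f = generate_field(5000.0, Isotropic(), seed=1)
        assert f.true_rld == pytest.approx(5000.0, abs=f.segment_length)
        assert np.allclose(np.linalg.norm(f.directions, axis=1), 1.0)
        assert np.all((f.midpoints >= 0) & (f.midpoints <= 1))

    def test_axis_mixture_length_fractions(self):
        f = generate_field(2000.0, AxisMixture(0.25, 0.25, 0.5), seed=2)
        frac_z = np.mean(f.directions[:, 2] == 1.0)
        assert frac_z == pytest.approx(0.5, abs=0.02)

    def test_same_seed_identical_fields(self):
        f1 = generate_field(1000.0, VerticalPower(2.0), seed=9)
        f2 = generate_field(1000.0, VerticalPower(2.0), seed=9)
        assert np.array_equal(f1.midpoints, f2.midpoints)
        assert np.array_equal(f1.directions, f2.directions)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_field(0.0)
        with pytest.raises(ValueError):
            generate_field(100.0, box=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            generate_field(100.0, segment_length=2.0)


class TestCountCrossings:
    def test_single_vertical_segment_crosses_horizontal_plane(self):
        f = manual_field([0.5, 0.5, 0.5], [0.0, 0.0, 1.0])
        assert count_crossings(f, "h", 0.5).count == 1
        assert count_crossings(f, "h", 0.8).count == 0

    def test_horizontal_segment_misses_horizontal_plane(self):
        f = manual_field([0.5, 0.5, 0.5], [1.0, 0.0, 0.0])
        assert count_crossings(f, "h", 0.5).count == 0
        assert count_crossings(f, "t", 0.5).count == 1

    def test_periodic_wrapping_counts_image_crossings(self):
        # segment straddling the box boundary crosses the plane at 0.0
        f = manual_field([0.5, 0.5, 0.99], [0.0, 0.0, 1.0])
        assert count_crossings(f, "h", 0.0).count == 1

    def test_window_restriction(self):
        f = manual_field([0.25, 0.25, 0.5], [0.0, 0.0, 1.0])
        hit = count_crossings(f, "h", 0.5, window=[(0.0, 0.5), (0.0, 0.5)])
        miss = count_crossings(f, "h", 0.5, window=[(0.5, 1.0), (0.5, 1.0)])
        assert (hit.count, miss.count) == (1, 0)

    def test_window_outside_box_rejected(self):
        f = manual_field([0.5, 0.5, 0.5], [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            count_crossings(f, "h", 0.5, window=[(0.0, 1.5), (0.0, 1.0)])

    @pytest.mark.parametrize("plane", ["h", "t", "l"])
    def test_matches_brute_force_enumeration(self, plane, rng):
        f = generate_field(300.0, VerticalPower(1.5), seed=11, segment_length=0.15)
        for offset in rng.uniform(0.0, 1.0, 3):
            fast = count_crossings(f, plane, float(offset)).count
            assert fast == brute_force_crossings(f, plane, float(offset))

    def test_matches_brute_force_in_windows(self, rng):
        f = generate_field(400.0, Isotropic(), seed=13, segment_length=0.12)
        win = [(0.2, 0.7), (0.1, 0.9)]
        for plane in ("h", "t", "l"):
            fast = count_crossings(f, plane, 0.37, window=win).count
            assert fast == brute_force_crossings(f, plane, 0.37, window=win)

    def test_axis_mixture_expected_rid_closed_form(self):
        # a plane normal to z sees exactly the z-parallel length density
        f = generate_field(6000.0, AxisMixture(0.25, 0.25, 0.5), seed=4)
        rid_h = np.mean(
            [count_crossings(f, "h", off).rid for off in (0.25, 0.5, 0.75)]
        )
        assert rid_h == pytest.approx(0.5 * f.true_rld, rel=0.03)


class TestIsotropyOracle:
    def test_ratio_two_and_pv_one_for_isotropic_field(self):
        res = isotropy_oracle(10000.0, seed=5)
        assert res.ratio == pytest.approx(2.0, abs=0.05)
        assert res.pv == pytest.approx(1.0, abs=0.05)

    def test_purely_vertical_field_ratio_one_on_horizontal_plane(self):
        f = generate_field(3000.0, AxisMixture(0.0, 0.0, 1.0), seed=6)
        rid_h = count_crossings(f, "h", 0.5).rid
        assert f.true_rld / rid_h == pytest.approx(1.0, rel=0.02)

    def test_purely_vertical_field_has_no_vertical_plane_crossings(self):
        f = generate_field(3000.0, AxisMixture(0.0, 0.0, 1.0), seed=6)
        assert count_crossings(f, "t", 0.5).count == 0


class TestVerticalPowerLaw:
    def test_pv_kappa_roundtrip_and_isotropic_point(self):
        assert pv_of_kappa(0.0) == pytest.approx(1.0)
        for pv in (0.5, 1.0, 1.8, 3.0):
            assert pv_of_kappa(kappa_for_pv(pv)) == pytest.approx(pv, abs=1e-9)

    def test_pv_monotone_in_kappa(self):
        kappas = np.linspace(-0.9, 10.0, 40)
        pvs = [pv_of_kappa(k) for k in kappas]
        assert np.all(np.diff(pvs) > 0)

    def test_simulated_pv_matches_closed_form(self):
        f = generate_field(8000.0, VerticalPower(3.0), seed=8)
        rids = {p: count_crossings(f, p, 0.5).rid for p in "htl"}
        pv = 2 * rids["h"] / (rids["t"] + rids["l"])
        assert pv == pytest.approx(pv_of_kappa(3.0), rel=0.05)


class TestVirtualCube:
    def test_empty_region_gives_zero_counts(self):
        f = manual_field([0.1, 0.1, 0.1], [0.0, 0.0, 1.0], length=0.05)
        cube = virtual_cube_sample(f, depth_z=0.8, center_xy=(0.8, 0.8))
        assert (cube.ni_h, cube.ni_t, cube.ni_l) == (0, 0, 0)
        assert cube.rld_measured == 0.0

    def test_true_rld_is_clipped_length_over_volume(self):
        # one 0.05 m segment fully inside the 0.1 m cube
        f = manual_field([0.5, 0.5, 0.5], [0.0, 0.0, 1.0], length=0.05)
        cube = virtual_cube_sample(f, depth_z=0.5, center_xy=(0.5, 0.5))
        assert cube.rld_measured == pytest.approx(0.05 / 0.1**3)
        assert cube.ni_h == 0  # segment does not reach the cube faces

    def test_cube_outside_box_rejected(self, isotropic_field):
        with pytest.raises(ValueError):
            virtual_cube_sample(isotropic_field, depth_z=0.01)

    def test_isotropic_cubes_have_mean_pv_near_one(self, isotropic_field):
        pvs = []
        for i, (cx, cy) in enumerate(
            [(0.2, 0.2), (0.2, 0.8), (0.8, 0.2), (0.8, 0.8), (0.5, 0.5)]
        ):
            for z in (0.2, 0.5, 0.8):
                c = virtual_cube_sample(
                    isotropic_field, z, center_xy=(cx, cy), cube_id=f"c{i}-{z}"
                )
                pvs.append(2 * c.ni_h / (c.ni_t + c.ni_l))
        assert np.mean(pvs) == pytest.approx(1.0, abs=0.15)

    def test_cube_true_rld_near_field_density(self, isotropic_field):
        c = virtual_cube_sample(isotropic_field, 0.5, center_xy=(0.5, 0.5))
        # 0.001 m^3 cube of a 5000 m/m^3 field holds ~5 m of root
        assert c.rld_measured == pytest.approx(5000.0, rel=0.5)


class TestTrenchGrid:
    def test_grid_totals_match_full_plane_count(self, isotropic_field):
        grid = virtual_trench_grid(isotropic_field, plane="t", offset=0.5)
        full = count_crossings(isotropic_field, "t", 0.5).count
        assert grid.sum() == full
        assert grid.shape == (20, 20)

    def test_vertical_plane_required(self, isotropic_field):
        with pytest.raises(ValueError):
            virtual_trench_grid(isotropic_field, plane="h")


class TestGenerateTabular:
    def test_noiseless_table_consistent_by_construction(self):
        t = generate_tabular((0.3408, 0.905), [0.1, 0.5, 0.9], n_per_depth=3)
        assert np.allclose(t["pv"], 0.3408 * t["depth_z"] + 0.905)
        assert np.allclose(t["co"], co_from_pv(t["pv"].to_numpy()))
        assert np.allclose(t["rld_measured"], t["rid_vertical"] * t["co"])
        assert np.allclose(
            t["pv"], 2 * t["rid_h"] / (t["rid_t"] + t["rid_l"])
        )

    def test_seed_determinism_bit_identical(self):
        a = generate_tabular((0.3, 1.0), [0.2, 0.6], noise_sd=0.05, seed=21)
        b = generate_tabular((0.3, 1.0), [0.2, 0.6], noise_sd=0.05, seed=21)
        assert a.equals(b)

    def test_model_driven_table_round_trips_co(self):
        from trenchroot import get_model

        model = get_model("geometric_all")
        t = generate_tabular(model, [0.1, 0.5, 1.0], n_per_depth=2)
        expected = model.slope_a * t["depth_z"] + model.intercept_b
        assert np.allclose(t["co"], expected)

    def test_negative_pv_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_tabular((-2.0, 0.5), [0.5, 1.0])


def test_pv_from_co_inverts_both_branches():
    import warnings

    for pv in (0.2, 0.7, 1.0):
        assert pv_from_co(co_from_pv(pv), branch="lower") == pytest.approx(pv, abs=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pv in (1.4, 1.5, 2.5):
            assert pv_from_co(co_from_pv(pv), branch="upper") == pytest.approx(
                pv, abs=1e-6
            )
    # the branch ranges overlap in (19/15, 2); auto resolves near-isotropically
    assert pv_from_co(2.0) == 1.0
    assert pv_from_co(1.9) < 1.0
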