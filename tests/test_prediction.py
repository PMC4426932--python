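"""Error maps, abutment detection, GAC injection and back-projection."""

import numpy as np
import pytest

import gacdose as gd
from gacdose import prediction as pred
from gacdose import synthetic as syn
from gacdose.exceptions import GeometryError, ValidationError


def _plane(values, origin=(-20.0, -20.0), spacing=(1.0, 1.0)):
    return gd.DosePlane2D(origin=origin, spacing=spacing, values=values)


@pytest.fixture(scope="module")
def fixture():
    return syn.gen_plan_fixture(gd.SyntheticConfig(seed=2))


@pytest.fixture(scope="module")
def clean_fixture():
    return syn.gen_plan_fixture(gd.SyntheticConfig(seed=2, error_blobs=()))


class TestErrorMap:
    def test_identical_planes_give_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random((41, 41)) + 0.5
        emap = pred.compute_error_map(_plane(vals), _plane(vals.copy()))
        assert np.all(emap.e == 0.0)
        assert emap.mask.any()

    def test_uniform_scaling_gives_constant_error(self):
        rng = np.random.default_rng(1)
        vals = rng.random((41, 41)) + 0.5
        emap = pred.compute_error_map(_plane(vals), _plane(vals * 1.05))
        assert np.abs(emap.e[emap.mask] - 0.05).max() < 1e-12

    def test_sparse_diode_recovers_smooth_error(self, fixture):
        """7-mm diode sampling of the blob field interpolates within 0.5%."""
        emap = pred.compute_error_map(
            fixture.planned_planes[0], fixture.measured_planes[0]
        )
        uu, vv = np.meshgrid(emap.u, emap.v)
        true = fixture.error_field(uu, vv)
        assert np.abs(emap.e[emap.mask] - true[emap.mask]).max() < 0.005

    def test_disjoint_planes_rejected(self):
        a = _plane(np.ones((11, 11)), origin=(0.0, 0.0))
        b = _plane(np.ones((5, 5)), origin=(500.0, 500.0))
        with pytest.raises(GeometryError):
            pred.compute_error_map(a, b)


class TestDetectAbutments:
    def _beam(self, left, right, mu_split=(60.0, 40.0)):
        segs = (
            gd.Segment(mu=mu_split[0], left=np.full(19, -40.0), right=np.full(19, left)),
            gd.Segment(mu=mu_split[1], left=np.full(19, left), right=np.full(19, right)),
        )
        return gd.BeamSpec(gantry_angle=0.0, beam_mu=sum(mu_split), segments=segs)

    def test_single_step_located(self):
        u0 = -30.0
        vals = np.zeros((81, 81))
        cols = np.arange(81) * 1.0 + (-40.0) >= 12.0
        vals[:, cols] = 1.0
        vals[:, ~cols] = 0.6
        simap = pred.SegmentIntensityMap(plane=_plane(vals, origin=(u0 - 10, -40.0)))
        found = pred.detect_abutments(simap, self._beam(12.0, 40.0))
        per_leaf = found.for_leaf(10)
        steps = [a for a in per_leaf if abs(a.x - 12.0) <= 0.5]
        assert len(steps) == 1

    def test_uniform_map_gives_empty_set(self):
        simap = pred.SegmentIntensityMap(plane=_plane(np.ones((41, 41))))
        beam = self._beam(0.0, 20.0)
        assert len(pred.detect_abutments(simap, beam)) == 0

    def test_fixture_abutments_matched_to_segments(self, fixture):
        """All generator boundaries found within 1 mm, right MU fractions."""
        for bi in range(len(fixture.plan.beams)):
            found = pred.detect_abutments(fixture.simaps[bi], fixture.plan.beams[bi])
            det = {
                (a.leaf_index, round(a.x)): a for a in found
            }
            for leaf, x, seg_idx, mu_frac in fixture.true_abutments[bi]:
                a = det[(leaf, round(x))]
                assert abs(a.x - x) < 1.0
                assert a.segment_index == seg_idx
                assert a.mu_fraction == pytest.approx(mu_frac, abs=1e-12)


class TestApplyGac:
    @pytest.fixture()
    def zero_emap(self):
        mask = np.ones((61, 61), dtype=bool)
        return pred.ErrorMap2D(
            origin=(-30.0, -30.0), spacing=(1.0, 1.0),
            e=np.zeros((61, 61)), mask=mask,
        )

    def _table(self, delta):
        grid = gd.make_abutment_grid()
        return gd.GACTable(
            angles=np.array([0.0, 180.0]),
            leaf_indices=grid.leaf_indices,
            x_nodes=grid.abutment_x,
            delta=np.stack([
                np.zeros((19, 9)), np.full((19, 9), delta)
            ]),
        )

    def test_zero_table_is_identity(self, zero_emap):
        abuts = pred.AbutmentSet([pred.Abutment(10, 0.0, 1.0, 0)])
        out = pred.apply_gac(zero_emap, abuts, self._table(0.0), 180.0)
        assert np.array_equal(out.e, zero_emap.e)

    def test_band_injection_full_mu(self, zero_emap):
        abuts = pred.AbutmentSet([pred.Abutment(10, 0.0, 1.0, 0)])
        out = pred.apply_gac(zero_emap, abuts, self._table(0.05), 180.0, band_mm=2.0)
        band = out.e[np.abs(out.v) < 5.0][:, np.abs(out.u) <= 1.0]
        assert np.all(band == pytest.approx(0.05, abs=1e-12))
        outside = out.e[:, np.abs(out.u) > 1.0]
        assert np.all(outside == 0.0)

    def test_band_scales_with_mu_fraction(self, zero_emap):
        abuts = pred.AbutmentSet([pred.Abutment(10, 0.0, 0.4, 0)])
        out = pred.apply_gac(zero_emap, abuts, self._table(0.05), 180.0)
        assert out.e.max() == pytest.approx(0.02, abs=1e-12)

    def test_positive_delta_never_decreases_error(self, zero_emap):
        rng = np.random.default_rng(4)
        base = pred.ErrorMap2D(
            origin=(-30.0, -30.0), spacing=(1.0, 1.0),
            e=rng.normal(0, 0.01, (61, 61)), mask=np.ones((61, 61), bool),
        )
        abuts = pred.AbutmentSet(
            [pred.Abutment(10, 0.0, 1.0, 0), pred.Abutment(11, -10.0, 0.5, 1)]
        )
        out = pred.apply_gac(base, abuts, self._table(0.03), 180.0)
        assert np.all(out.e >= base.e - 1e-15)


class TestBackproject:
    def test_exact_zero_map_is_identity(self, clean_fixture):
        grid = clean_fixture.beam_grids[0]
        emap = pred.ErrorMap2D(
            origin=(-80.0, -80.0), spacing=(1.0, 1.0),
            e=np.zeros((161, 161)), mask=np.ones((161, 161), bool),
        )
        out = pred.backproject(emap, grid, 45.0, clean_fixture.geometry)
        assert np.array_equal(out.values, grid.values)

    def test_zero_measurement_error_is_identity(self, clean_fixture):
        """A perfect diode measurement leaves the grid unchanged."""
        emap = pred.compute_error_map(
            clean_fixture.planned_planes[0], clean_fixture.measured_planes[0]
        )
        grid = clean_fixture.beam_grids[0]
        out = pred.backproject(emap, grid, 45.0, clean_fixture.geometry)
        assert np.abs(out.values - grid.values).max() <= 1e-12 * grid.values.max()

    def test_uniform_error_scales_every_voxel(self, clean_fixture):
        grid = clean_fixture.beam_grids[0]
        big = np.ones((401, 401))
        emap = pred.ErrorMap2D(
            origin=(-200.0, -200.0), spacing=(1.0, 1.0),
            e=np.full((401, 401), 0.03), mask=big.astype(bool),
        )
        out = pred.backproject(emap, grid, 45.0, clean_fixture.geometry)
        assert np.allclose(out.values, grid.values * 1.03, rtol=1e-12)

    def test_blob_follows_diverging_ray(self, fixture):
        """Corrected/planned ratio along a blob's ray equals 1 + e there."""
        emap = pred.compute_error_map(
            fixture.planned_planes[2], fixture.measured_planes[2]
        )
        grid = fixture.beam_grids[2]  # gantry 180
        out = pred.backproject(emap, grid, 180.0, fixture.geometry)
        # gantry 180: z_b = -z, u = -x * mag; blob 1 center u=10 -> x=-10/mag
        geo = fixture.geometry
        x_ax, y_ax, z_ax = grid.axis(0), grid.axis(1), grid.axis(2)
        iy = int(np.argmin(np.abs(y_ax - 5.0)))
        checked = 0
        for iz, z in enumerate(z_ax):
            mag = geo.sad / (geo.sad + z)
            ix = int(np.argmin(np.abs(x_ax - (-10.0 / mag))))
            planned = grid.values[iz, iy, ix]
            if planned < 0.1 * grid.values.max():
                continue
            u, vv = gd.project_voxel_to_bev(
                (x_ax[ix], y_ax[iy], z), 180.0, geo
            )
            expected = 1.0 + float(fixture.error_field(u, vv))
            ratio = out.values[iz, iy, ix] / planned
            assert ratio == pytest.approx(expected, abs=0.01)
            checked += 1
        assert checked > 10

    def test_linearity_in_error_field(self, clean_fixture):
        """backproject(e1 + e2) = backproject(e1) + backproject(e2) - planned."""
        rng = np.random.default_rng(5)
        shape = (161, 161)
        mask = np.ones(shape, bool)
        e1 = rng.normal(0, 0.02, shape)
        e2 = rng.normal(0, 0.02, shape)
        mk = lambda e: pred.ErrorMap2D(  # noqa: E731
            origin=(-80.0, -80.0), spacing=(1.0, 1.0), e=e, mask=mask
        )
        grid = clean_fixture.beam_grids[1]
        b1 = pred.backproject(mk(e1), grid, 105.0, clean_fixture.geometry)
        b2 = pred.backproject(mk(e2), grid, 105.0, clean_fixture.geometry)
        b12 = pred.backproject(mk(e1 + e2), grid, 105.0, clean_fixture.geometry)
        lhs = b12.values
        rhs = b1.values + b2.values - grid.values
        assert np.abs(lhs - rhs).max() <= 1e-9 * grid.values.max()


class TestPredictDose:
    def test_closure_zero_error_zero_gac(self, clean_fixture):
        fx = clean_fixture
        total = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=None, use_gac=False, geometry=fx.geometry,
        )
        assert np.abs(
            total.values - fx.total_grid.values
        ).max() <= 1e-9 * fx.total_grid.values.max()

    def test_zero_table_matches_no_gac(self, fixture):
        fx = fixture
        grid = gd.make_abutment_grid()
        zero_table = gd.GACTable(
            angles=np.array([0.0]),
            leaf_indices=grid.leaf_indices,
            x_nodes=grid.abutment_x,
            delta=np.zeros((1, 19, 9)),
        )
        with_gac = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=zero_table, use_gac=True, geometry=fx.geometry,
        )
        without = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=None, use_gac=False, geometry=fx.geometry,
        )
        assert np.array_equal(with_gac.values, without.values)

    def test_five_beam_end_to_end_oracle(self, fixture):
        """Predicted total matches the independently composed oracle <=0.5%."""
        fx = fixture
        total = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=None, use_gac=False, geometry=fx.geometry,
        )
        geo = fx.geometry
        ax = fx.beam_grids[0].axis(0)
        ay = fx.beam_grids[0].axis(1)
        az = fx.beam_grids[0].axis(2)
        zz, yy, xx = np.meshgrid(az, ay, ax, indexing="ij")
        oracle = np.zeros_like(fx.total_grid.values)
        for beam, grid in zip(fx.plan.beams, fx.beam_grids):
            th = np.deg2rad(beam.gantry_angle)
            zb = xx * np.sin(th) + zz * np.cos(th)
            xb = xx * np.cos(th) - zz * np.sin(th)
            mag = geo.sad / (geo.sad - zb)
            oracle += grid.values * (1.0 + fx.error_field(xb * mag, yy * mag))
        hi = oracle >= 0.5 * oracle.max()
        rel = np.abs(total.values - oracle)[hi] / oracle[hi]
        assert rel.max() < 0.005

    def test_monotone_gac_effect(self, fixture):
        """A strictly positive GAC delta never decreases any voxel."""
        fx = fixture
        grid = gd.make_abutment_grid()
        pos_table = gd.GACTable(
            angles=np.array([0.0, 180.0]),
            leaf_indices=grid.leaf_indices,
            x_nodes=grid.abutment_x,
            delta=np.stack([np.zeros((19, 9)), np.full((19, 9), 0.05)]),
        )
        base = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=None, use_gac=False, geometry=fx.geometry,
        )
        boosted = pred.predict_dose(
            fx.plan, fx.planned_planes, fx.measured_planes, fx.simaps,
            fx.beam_grids, table=pos_table, use_gac=True, geometry=fx.geometry,
        )
        assert np.all(boosted.values >= base.values - 1e-12)
        assert boosted.values.max() > base.values.max()  # some voxels boosted

    def test_beam_count_mismatch_rejected(self, fixture):
        fx = fixture
        with pytest.raises(ValidationError):
            pred.predict_dose(
                fx.plan, fx.planned_planes[:3], fx.measured_planes, fx.simaps,
                fx.beam_grids, table=None, use_gac=False,
            )
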