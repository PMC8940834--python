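"""Phantom construction and parallel-beam projection."""

import numpy as np
import pytest

import spectdenoise as sd
from spectdenoise.phantom import ParallelProjector


class TestMakePhantom:
    def test_uniform_shell_without_defects(self, small_phantom):
        vals = small_phantom.activity[small_phantom.shell_mask]
        assert vals.size > 0
        assert np.all(vals == vals[0])
        assert np.all(small_phantom.activity >= 0)

    LV32 = sd.LVParams(center_voxel=(15.5, 15.5, 15.5))

    def test_full_severity_defect_zeroes_its_span_only(self):
        d = sd.Defect(theta_center_deg=0, theta_width_deg=80, axial_span=(0.2, 0.8), severity=1.0)
        ph = sd.make_phantom(self.LV32, defects=[d], grid_size=32, seed=0)
        ref = sd.make_phantom(self.LV32, defects=[], grid_size=32, seed=0)
        mask = ph.defect_masks[0]
        assert mask.any()
        assert np.all(ph.activity[mask] == 0.0)
        outside = ~mask
        assert np.array_equal(ph.activity[outside], ref.activity[outside])

    def test_partial_severity_scales_masked_mean(self):
        # brute-force oracle: masked sums over the construction masks
        d = sd.Defect(theta_center_deg=90, theta_width_deg=120, axial_span=(0.1, 0.9), severity=0.5)
        ph = sd.make_phantom(self.LV32, defects=[d], grid_size=32, seed=0)
        inside = ph.activity[ph.defect_masks[0]].mean()
        outside = ph.activity[ph.shell_mask & ~ph.defect_masks[0]].mean()
        assert inside / outside == pytest.approx(0.5, abs=1e-12)

    def test_deterministic_and_mask_roundtrip(self):
        d = sd.Defect(severity=0.7)
        a = sd.make_phantom(defects=[d], grid_size=24, seed=5)
        b = sd.make_phantom(defects=[d], grid_size=24, seed=5)
        assert np.array_equal(a.activity, b.activity)
        assert np.array_equal(a.defect_masks[0], b.defect_masks[0])

    def test_wall_thicker_than_radius_rejected(self):
        lv = sd.LVParams(outer_semi_axes_mm=(20.0, 20.0, 30.0), wall_thickness_mm=25.0)
        with pytest.raises(ValueError, match="wall thickness"):
            sd.make_phantom(lv, grid_size=24)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="grid_size"):
            sd.make_phantom(grid_size=8)


class TestProject:
    def test_zero_phantom_projects_to_zero(self, geom16):
        ph = sd.make_phantom(
            sd.LVParams(center_voxel=(7.5, 7.5, 7.5), outer_semi_axes_mm=(20, 20, 25),
                        wall_thickness_mm=8.0),
            grid_size=16, seed=0, shell_activity=0.0)
        proj = sd.project(ph, geom16)
        assert np.all(proj.expected == 0)

    def test_single_center_voxel_ray_sum(self, geom16):
        # center voxel stays at the rotation center: one pixel per view,
        # value = activity x path length (voxel edge)
        projector = ParallelProjector((16, 16, 16), geom16, 6.4)
        vol_c = np.zeros((16, 16, 16))
        vol_c[7, 7, 9] = 3.0
        proj = projector.forward(vol_c)
        sums = proj.sum(axis=(1, 2))
        assert np.allclose(sums, 3.0 * 6.4, atol=1e-9)
        # all activity lands in detector row 9 (z passes straight through)
        assert np.allclose(proj[:, 9, :].sum(axis=1), 3.0 * 6.4)
        assert np.allclose(np.delete(proj, 9, axis=1), 0.0)
        # at most two adjacent nonzero columns per view (linear splat)
        for v in range(geom16.n_views):
            nz = np.flatnonzero(proj[v, 9])
            assert 1 <= nz.size <= 2
            if nz.size == 2:
                assert nz[1] == nz[0] + 1

    def test_view_sums_equal_total_activity_times_voxel(self, small_phantom):
        geom = sd.AcquisitionGeometry(n_views=16, detector_rows=24, detector_cols=24,
                                      pixel_mm=6.4)
        proj = sd.project(small_phantom, geom)
        expect = small_phantom.activity.sum() * 6.4
        assert np.allclose(proj.expected.sum(axis=(1, 2)), expect, rtol=1e-10)

    def test_linearity(self, geom16):
        rng = np.random.default_rng(2)
        projector = ParallelProjector((16, 16, 16), geom16, 6.4)
        p1 = rng.random((16, 16, 16))
        p2 = rng.random((16, 16, 16))
        lhs = projector.forward(2.0 * p1 + 3.0 * p2)
        rhs = 2.0 * projector.forward(p1) + 3.0 * projector.forward(p2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_adjointness(self, geom16):
        # <A x, y> == <x, A^T y> exactly (sparse transpose pair)
        rng = np.random.default_rng(3)
        projector = ParallelProjector((16, 16, 16), geom16, 6.4)
        x = rng.random((16, 16, 16))
        y = rng.random(geom16.shape)
        lhs = float((projector.forward(x) * y).sum())
        rhs = float((x * projector.back(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSampleCounts:
    def test_total_count_calibration(self, small_phantom):
        # grand total over seeds is Poisson(total), se = sqrt(total)
        geom = sd.AcquisitionGeometry(n_views=16, detector_rows=24, detector_cols=24,
                                      pixel_mm=6.4)
        noiseless = sd.project(small_phantom, geom)
        total = 1e6
        n_seeds = 200
        totals = [sd.sample_counts(noiseless, total, seed=s).total_counts
                  for s in range(n_seeds)]
        se_mean = np.sqrt(total / n_seeds)
        assert abs(np.mean(totals) - total) < 3 * se_mean

    def test_single_bin_concentrates_counts(self, geom16):
        expected = np.zeros(geom16.shape)
        expected[3, 5, 7] = 1.0
        proj = sd.ProjectionSet(geometry=geom16, expected=expected)
        out = sd.sample_counts(proj, 1000, seed=0)
        assert out.counts[3, 5, 7] == out.counts.sum() > 0

    def test_poisson_dispersion_near_one(self, geom16):
        expected = np.full(geom16.shape, 1.0)
        proj = sd.ProjectionSet(geometry=geom16, expected=expected)
        total = float(expected.size * 80)  # per-bin mean 80 >= 50
        draws = np.stack([sd.sample_counts(proj, total, seed=s).counts.ravel()
                          for s in range(150)])
        dispersion = draws.var(axis=0, ddof=1) / draws.mean(axis=0)
        assert abs(dispersion.mean() - 1.0) < 0.02

    def test_reproducible_and_allzero_rejected(self, geom16):
        expected = np.ones(geom16.shape)
        proj = sd.ProjectionSet(geometry=geom16, expected=expected)
        a = sd.sample_counts(proj, 1e4, seed=9)
        b = sd.sample_counts(proj, 1e4, seed=9)
        assert np.array_equal(a.counts, b.counts)
        with pytest.raises(ValueError, match="zero"):
            sd.sample_counts(sd.ProjectionSet(geometry=geom16, expected=np.zeros(geom16.shape)),
                             1e4, seed=0)
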