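"""Binomial dose thinning, cardiac gating, and projection cropping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import spectdenoise as sd
from spectdenoise.lowdose import explode_to_events, rebin_events


def _proj_from(counts):
    geom = sd.AcquisitionGeometry(n_views=counts.shape[0], detector_rows=counts.shape[1],
                                  detector_cols=counts.shape[2], pixel_mm=6.4)
    return sd.ProjectionSet(geometry=geom, counts=counts)


class TestBinomialThin:
    def test_p_one_and_p_zero(self, megacount_proj):
        full = sd.binomial_thin(megacount_proj, 1.0, seed=0)
        assert np.array_equal(full.kept.counts, megacount_proj.counts)
        assert full.rejected.counts.sum() == 0
        none = sd.binomial_thin(megacount_proj, 0.0, seed=0)
        assert none.kept.counts.sum() == 0
        assert np.array_equal(none.rejected.counts, megacount_proj.counts)

    @given(hnp.arrays(np.int64, (2, 4, 4), elements=st.integers(0, 500)),
           st.floats(0.05, 0.95), st.integers(0, 2**31 - 2))
    def test_exact_count_conservation(self, counts, p, seed):
        res = sd.binomial_thin(_proj_from(counts), p, seed)
        assert np.array_equal(res.kept.counts + res.rejected.counts, counts)
        assert np.all(res.kept.counts >= 0)
        assert np.all(res.kept.counts <= counts)

    def test_seed_contract(self, megacount_proj):
        a = sd.binomial_thin(megacount_proj, 0.25, seed=42)
        b = sd.binomial_thin(megacount_proj, 0.25, seed=42)
        assert np.array_equal(a.kept.counts, b.kept.counts)

    def test_dose_fraction_propagates(self, megacount_proj):
        half = sd.binomial_thin(megacount_proj, 0.5, seed=1).kept
        eighth = sd.binomial_thin(half, 0.25, seed=2).kept
        assert eighth.dose_fraction == pytest.approx(0.125)

    def test_invalid_p_rejected(self, megacount_proj):
        with pytest.raises(ValueError, match="probability"):
            sd.binomial_thin(megacount_proj, 1.5, seed=0)

    def test_composability_two_stage_matches_direct(self, megacount_proj):
        # thinning by p then q is distributed as thinning by pq (moments)
        n = megacount_proj.total_counts
        totals_two, totals_one = [], []
        for s in range(60):
            two = sd.binomial_thin(
                sd.binomial_thin(megacount_proj, 0.5, seed=s).kept, 0.5, seed=1000 + s).kept
            one = sd.binomial_thin(megacount_proj, 0.25, seed=2000 + s).kept
            totals_two.append(two.total_counts)
            totals_one.append(one.total_counts)
        se = np.sqrt(n * 0.25 * 0.75 / 60)
        assert abs(np.mean(totals_two) - 0.25 * n) < 3 * se
        assert abs(np.mean(totals_one) - 0.25 * n) < 3 * se

    def test_thinned_poisson_stays_poisson(self):
        # Poisson thinning theorem: index of dispersion stays ~1
        geom = sd.AcquisitionGeometry(n_views=4, detector_rows=16, detector_cols=16,
                                      pixel_mm=6.4)
        draws = []
        for s in range(150):
            counts = np.random.default_rng(s).poisson(160.0, geom.shape).astype(np.int64)
            kept = sd.binomial_thin(sd.ProjectionSet(geometry=geom, counts=counts),
                                    0.5, seed=5000 + s).kept
            draws.append(kept.counts.ravel())
        draws = np.stack(draws)
        dispersion = draws.var(axis=0, ddof=1) / draws.mean(axis=0)
        assert abs(dispersion.mean() - 1.0) < 0.03

    def test_event_list_adapter_matches_bin_totals(self, megacount_proj):
        small = sd.binomial_thin(megacount_proj, 0.01, seed=3).kept
        events = explode_to_events(small, seed=0)
        assert events.shape[0] == small.total_counts
        back = rebin_events(events, small)
        assert np.array_equal(back.counts, small.counts)


class TestSplitGates:
    def test_single_gate_identity(self, megacount_proj):
        out = sd.split_gates(megacount_proj, 1, seed=0)
        assert len(out) == 1
        assert np.array_equal(out[0].counts, megacount_proj.counts)

    def test_gates_sum_to_parent_exactly(self, megacount_proj):
        gates = sd.split_gates(megacount_proj, 8, seed=7)
        assert np.array_equal(sum(g.counts for g in gates), megacount_proj.counts)
        assert [g.gate for g in gates] == list(range(8))

    def test_uniform_gate_fractions(self, megacount_proj):
        gates = sd.split_gates(megacount_proj, 8, seed=3)
        n = megacount_proj.total_counts
        se = np.sqrt(n * 0.125 * 0.875)
        for g in gates:
            assert abs(g.counts.sum() - n * 0.125) < 4 * se

    def test_bad_weights_rejected(self, megacount_proj):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.split_gates(megacount_proj, 4, np.array([0.5, 0.5, 0.5, 0.5]), seed=0)


class TestCropProjections:
    def test_full_range_identity(self, megacount_proj):
        out = sd.crop_projections(megacount_proj, (0, 32))
        assert np.array_equal(out.counts, megacount_proj.counts)

    def test_idempotent(self, megacount_proj):
        once = sd.crop_projections(megacount_proj, (4, 20))
        twice = sd.crop_projections(once, (4, 20))
        assert np.array_equal(once.counts, twice.counts)

    def test_removes_exactly_the_liver_rows(self):
        # phantom with a hot liver blob below the heart: cropping the blob's
        # rows drops exactly the blob's row-sums (brute-force oracle)
        lv = sd.LVParams(center_voxel=(15.5, 15.5, 20.0),
                         outer_semi_axes_mm=(30.0, 30.0, 40.0), wall_thickness_mm=12.0)
        liver = sd.LiverSpec(center_voxel=(15.5, 15.5, 5.0), semi_axes_mm=(20.0, 20.0, 12.0),
                             activity=2.0)
        ph = sd.make_phantom(lv, grid_size=32, seed=0, liver=liver)
        geom = sd.AcquisitionGeometry(n_views=8, detector_rows=32, detector_cols=32,
                                      pixel_mm=6.4)
        proj = sd.project(ph, geom)
        counts = sd.sample_counts(proj, 1e5, seed=0)
        # liver occupies low z rows; keep rows whose z never sees the liver
        liver_rows = np.unique(np.nonzero(ph.liver_mask)[2])
        keep_lo = int(liver_rows.max()) + 1
        cropped = sd.crop_projections(counts, (keep_lo, 32))
        removed = counts.counts[:, :keep_lo, :].sum()
        assert counts.total_counts - cropped.total_counts == removed
        assert cropped.counts[:, keep_lo:, :].sum() == cropped.total_counts

    def test_empty_range_rejected(self, megacount_proj):
        with pytest.raises(ValueError, match="row_range"):
            sd.crop_projections(megacount_proj, (20, 20))
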