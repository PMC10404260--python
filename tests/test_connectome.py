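"""Seed maps, connectivity matrices, global strength, group statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mousefc import connectome, synth
from mousefc.types import AtlasVolume, ConnMatrix, SeedMap, Volume4D


def _vol_from_array(arr):
    return Volume4D(data=np.asarray(arr, dtype=float), tr_s=1.0)


def _toy_atlas(labels):
    return AtlasVolume(labels=np.asarray(labels, dtype=np.int32))


class TestRegionTimeSeries:
    def test_single_voxel_region_equals_its_series(self, rng):
        labels = np.zeros((3, 2, 1), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[1:, :, :] = 2
        data = rng.normal(size=(3, 2, 1, 10))
        rs = connectome.region_time_series(_vol_from_array(data),
                                           _toy_atlas(labels))
        assert np.allclose(rs.values[0], data[0, 0, 0])

    def test_opposite_series_cancel(self):
        labels = np.full((2, 1, 1), 1, dtype=np.int32)
        s = np.sin(np.arange(12.0))
        data = np.stack([s, -s])[:, None, None, :]
        rs = connectome.region_time_series(_vol_from_array(data),
                                           _toy_atlas(labels))
        assert np.allclose(rs.values[0], 0.0)

    def test_matches_bruteforce_average(self, rng):
        labels = rng.integers(0, 5, size=(4, 3, 2)).astype(np.int32)
        data = rng.normal(size=(4, 3, 2, 7))
        rs = connectome.region_time_series(_vol_from_array(data),
                                           _toy_atlas(labels),
                                           region_ids=[1, 2, 3, 4])
        for row, rid in enumerate([1, 2, 3, 4]):
            sel = labels == rid
            if sel.any():
                expected = data[sel].mean(axis=0)
                assert np.allclose(rs.values[row], expected)
            else:
                assert rid in rs.missing
                assert np.isnan(rs.values[row]).all()

    def test_absent_region_flagged_not_zero(self, rng):
        labels = np.full((2, 2, 1), 1, dtype=np.int32)
        data = rng.normal(size=(2, 2, 1, 5))
        rs = connectome.region_time_series(_vol_from_array(data),
                                           _toy_atlas(labels),
                                           region_ids=[1, 9])
        assert rs.missing == [9]
        assert np.isnan(rs.values[1]).all()


class TestSeedMap:
    def test_perfect_and_inverted_correlation(self, rng):
        seed = rng.normal(size=20)
        data = np.stack([seed, -seed, 2.0 * seed + 5.0])[:, None, None, :]
        sm = connectome.seed_correlation_map(_vol_from_array(data), seed)
        assert sm.r[0, 0, 0] == pytest.approx(1.0)
        assert sm.r[1, 0, 0] == pytest.approx(-1.0)
        assert sm.r[2, 0, 0] == pytest.approx(1.0)  # affine invariance

    def test_matches_textbook_pearson(self, rng):
        data = rng.normal(size=(5, 1, 1, 9))
        seed = rng.normal(size=9)
        sm = connectome.seed_correlation_map(_vol_from_array(data), seed)
        for i in range(5):
            expected = stats.pearsonr(data[i, 0, 0], seed).statistic
            assert sm.r[i, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_constant_voxel_is_nan_constant_seed_raises(self, rng):
        data = rng.normal(size=(2, 1, 1, 8))
        data[1] = 3.0
        sm = connectome.seed_correlation_map(_vol_from_array(data),
                                             data[0, 0, 0])
        assert np.isnan(sm.r[1, 0, 0])
        with pytest.raises(ValueError, match="zero-variance seed"):
            connectome.seed_correlation_map(_vol_from_array(data),
                                            np.ones(8))

    def test_out_of_mask_is_nan(self, rng):
        data = rng.normal(size=(2, 2, 1, 8))
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        sm = connectome.seed_correlation_map(_vol_from_array(data),
                                             data[0, 0, 0], mask=mask)
        assert np.isfinite(sm.r[0, 0, 0])
        assert np.isnan(sm.r[1, 1, 0])


class TestThreshold:
    def _map_with(self, r_values, n):
        arr = np.array(r_values, dtype=float).reshape(-1, 1, 1)
        return SeedMap(seed_region_id=1, r=arr, n_timepoints=n)

    def test_r015_survives_at_n310(self):
        # r = 0.15 at n = 310 has p ~ 0.008 < 0.05 via the t transform
        sm = self._map_with([0.15], 310)
        out = connectome.threshold_seed_map(sm, r_min=0.15, alpha=0.05)
        t = 0.15 * np.sqrt(308 / (1 - 0.15 ** 2))
        p = 2 * stats.t.sf(t, 308)
        assert p < 0.05
        assert np.isfinite(out.r[0, 0, 0])

    def test_magnitude_edge_excluded(self):
        sm = self._map_with([0.149], 310)
        out = connectome.threshold_seed_map(sm, r_min=0.15, alpha=0.05)
        assert np.isnan(out.r[0, 0, 0])

    def test_large_r_small_n_fails_significance(self):
        # r = 0.5 at n = 5 has p ~ 0.39: magnitude passes, p does not
        sm = self._map_with([0.5], 5)
        t = 0.5 * np.sqrt(3 / (1 - 0.25))
        p = 2 * stats.t.sf(t, 3)
        assert p > 0.05
        out = connectome.threshold_seed_map(sm, r_min=0.15, alpha=0.05)
        assert np.isnan(out.r[0, 0, 0])

    def test_negative_r_kept_by_magnitude(self):
        sm = self._map_with([-0.5], 310)
        out = connectome.threshold_seed_map(sm, r_min=0.15, alpha=0.05)
        assert out.r[0, 0, 0] == pytest.approx(-0.5)

    @given(st.floats(min_value=0.0, max_value=0.8),
           st.floats(min_value=0.0, max_value=0.15))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotone(self, r_min, bump):
        rng = np.random.default_rng(99)
        sm = self._map_with(rng.uniform(-1, 1, size=40), 100)
        lo = connectome.threshold_seed_map(sm, r_min=r_min)
        hi = connectome.threshold_seed_map(sm, r_min=min(r_min + bump, 0.99))
        kept_lo = np.isfinite(lo.r)
        kept_hi = np.isfinite(hi.r)
        assert not np.any(kept_hi & ~kept_lo)  # raising r_min never adds

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="4 timepoints"):
            connectome.threshold_seed_map(self._map_with([0.2], 3))


class TestConnectivityMatrix:
    def _series(self, values):
        from mousefc.types import RegionSeries
        values = np.asarray(values, dtype=float)
        return RegionSeries(values=values,
                            region_ids=np.arange(1, len(values) + 1))

    def test_identical_rows(self):
        s = np.sin(np.arange(10.0))
        cm = connectome.connectivity_matrix(self._series([s, s]))
        assert np.allclose(cm.values, 1.0)

    def test_orthogonal_rows(self):
        t = np.arange(64.0)
        a = np.sin(2 * np.pi * t / 64)
        b = np.sin(4 * np.pi * t / 64)
        cm = connectome.connectivity_matrix(self._series([a, b]))
        assert abs(cm.values[0, 1]) < 1e-10

    def test_matches_pairwise_oracle(self, rng):
        vals = rng.normal(size=(4, 20))
        cm = connectome.connectivity_matrix(self._series(vals))
        for i in range(4):
            for j in range(4):
                expected = stats.pearsonr(vals[i], vals[j]).statistic
                assert cm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_flagged(self, rng):
        vals = rng.normal(size=(3, 15))
        vals[1] = 7.0
        cm = connectome.connectivity_matrix(self._series(vals))
        assert cm.degenerate_ids == [2]
        assert np.isnan(cm.values[1]).all()
        assert np.isnan(cm.values[:, 1]).all()
        assert cm.values[0, 0] == 1.0

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.normal(size=(5, 30))
        cm1 = connectome.connectivity_matrix(self._series(vals))
        scaled = vals * rng.uniform(0.5, 3.0, size=(5, 1)) \
            + rng.normal(size=(5, 1))
        cm2 = connectome.connectivity_matrix(self._series(scaled))
        assert np.allclose(cm1.values, cm2.values, atol=1e-10)


class TestGlobalStrength:
    def _matrix(self, offdiag):
        n = 3
        m = np.eye(n)
        m[0, 1] = m[1, 0] = offdiag[0]
        m[0, 2] = m[2, 0] = offdiag[1]
        m[1, 2] = m[2, 1] = offdiag[2]
        return ConnMatrix(values=m, region_ids=np.arange(1, 4),
                          n_timepoints=100)

    def test_mean_of_supra_threshold_pairs(self):
        m = self._matrix([0.5, 0.3, 0.1])
        assert connectome.global_connectivity_strength(m, 0.15) \
            == pytest.approx(0.4)

    def test_uniform_matrix(self):
        m = self._matrix([0.23, 0.23, 0.23])
        assert connectome.global_connectivity_strength(m) \
            == pytest.approx(0.23)

    def test_no_qualifying_pairs_gives_nan(self):
        m = self._matrix([0.1, 0.05, -0.4])
        assert np.isnan(connectome.global_connectivity_strength(m))

    def test_threshold_is_strict(self):
        m = self._matrix([0.15, 0.1, 0.0])
        assert np.isnan(connectome.global_connectivity_strength(m, 0.15))

    def test_empty_matrix_rejected(self):
        m = ConnMatrix(values=np.empty((0, 0)), region_ids=np.empty(0),
                       n_timepoints=10)
        with pytest.raises(ValueError, match="empty"):
            connectome.global_connectivity_strength(m)


class TestGroupMaps:
    def _maps(self, arrays):
        return [SeedMap(seed_region_id=1, r=np.asarray(a, dtype=float),
                        n_timepoints=100) for a in arrays]

    def test_identical_nonzero_maps_capped(self):
        maps = self._maps([np.full((2, 2, 1), 0.4)] * 4)
        gm = connectome.group_mean_map(maps)
        assert gm.capped.all()
        assert (gm.p > 0).all()

    def test_symmetric_maps_give_t0_p1(self):
        a = np.full((2, 1, 1), 0.3)
        gm = connectome.group_mean_map(self._maps([a, -a]))
        assert gm.t[0, 0, 0] == pytest.approx(0.0)
        assert gm.p[0, 0, 0] == pytest.approx(1.0)

    def test_matches_scalar_t_oracle(self, rng):
        arrays = rng.uniform(-0.8, 0.8, size=(6, 3, 2, 1))
        gm = connectome.group_mean_map(self._maps(arrays))
        z = np.arctanh(arrays)
        t, p = stats.ttest_1samp(z[:, 1, 1, 0], 0.0)
        assert gm.t[1, 1, 0] == pytest.approx(t)
        assert gm.p[1, 1, 0] == pytest.approx(p)

    def test_single_map_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            connectome.group_mean_map(self._maps([np.zeros((2, 2, 1))]))

    def test_identical_groups_no_difference(self, rng):
        arrays = rng.uniform(-0.5, 0.5, size=(3, 2, 2, 1))
        maps = self._maps(arrays)
        gd = connectome.group_difference_map(maps, self._maps(arrays.copy()))
        assert np.allclose(gd.t[np.isfinite(gd.t)], 0.0)

    def test_offset_groups_sign(self, rng):
        base = rng.uniform(-0.2, 0.2, size=(3, 2, 2, 1))
        za = np.arctanh(base)
        hi = np.tanh(za + 0.3)
        gd = connectome.group_difference_map(self._maps(hi),
                                             self._maps(base))
        assert (gd.t[np.isfinite(gd.t)] > 0).all()

    def test_matches_welch_oracle(self, rng):
        a = rng.uniform(-0.6, 0.6, size=(4, 2, 1, 1))
        b = rng.uniform(-0.6, 0.6, size=(5, 2, 1, 1))
        gd = connectome.group_difference_map(self._maps(a), self._maps(b))
        t, p = stats.ttest_ind(np.arctanh(a[:, 0, 0, 0]),
                               np.arctanh(b[:, 0, 0, 0]), equal_var=False)
        assert gd.t[0, 0, 0] == pytest.approx(t)
        assert gd.p[0, 0, 0] == pytest.approx(p)

    def test_grid_mismatch_rejected(self, rng):
        a = self._maps(rng.uniform(-0.5, 0.5, size=(2, 2, 2, 1)))
        b = self._maps(rng.uniform(-0.5, 0.5, size=(2, 3, 2, 1)))
        with pytest.raises(ValueError, match="grid"):
            connectome.group_difference_map(a, b)


class TestCohortAverage:
    def _cm(self, values):
        values = np.asarray(values, dtype=float)
        return ConnMatrix(values=values,
                          region_ids=np.arange(1, len(values) + 1),
                          n_timepoints=50)

    def test_single_matrix_is_identity_operation(self):
        m = self._cm([[1.0, 0.4], [0.4, 1.0]])
        avg = connectome.cohort_average_matrix([m])
        assert np.allclose(avg.values, m.values)

    def test_opposite_z_values_cancel(self):
        z = 0.3
        r = np.tanh(z)
        a = self._cm([[1.0, r], [r, 1.0]])
        b = self._cm([[1.0, -r], [-r, 1.0]])
        avg = connectome.cohort_average_matrix([a, b])
        assert avg.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        mats = []
        for _ in range(3):
            r = rng.uniform(-0.7, 0.7)
            mats.append(self._cm([[1.0, r], [r, 1.0]]))
        avg = connectome.cohort_average_matrix(mats)
        expected = np.tanh(np.mean([np.arctanh(m.values[0, 1])
                                    for m in mats]))
        assert avg.values[0, 1] == pytest.approx(expected)

    def test_region_order_mismatch_rejected(self):
        a = self._cm([[1.0, 0.2], [0.2, 1.0]])
        b = ConnMatrix(values=a.values.copy(), region_ids=np.array([2, 1]),
                       n_timepoints=50)
        with pytest.raises(ValueError, match="order"):
            connectome.cohort_average_matrix([a, b])


class TestSelfConsistency:
    def test_seed_region_strongest_in_own_map(self, small_study):
        atlas, table, templates = small_study
        vol = synth.simulate_bold_run(atlas, templates["control"], T=200,
                                      noise_sd=0.0, rng_seed=13)
        rs = connectome.region_time_series(vol, atlas)
        seed_row = 0
        sm = connectome.seed_correlation_map(vol, rs.values[seed_row],
                                             mask=atlas.mask)
        means = [np.nanmean(sm.r[atlas.labels == rid])
                 for rid in atlas.region_ids]
        assert np.argmax(means) == seed_row

    def test_mutant_strength_below_control(self, small_study):
        atlas, _, templates = small_study
        strengths = {}
        for cohort in ("control", "mutant"):
            vals = []
            for seed in range(3):
                vol = synth.simulate_bold_run(atlas, templates[cohort],
                                              T=310, rng_seed=seed)
                rs = connectome.region_time_series(vol, atlas)
                cm = connectome.connectivity_matrix(rs)
                vals.append(connectome.global_connectivity_strength(cm))
            strengths[cohort] = np.mean(vals)
        assert strengths["mutant"] < strengths["control"]
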