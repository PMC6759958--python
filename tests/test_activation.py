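"""HRF/design construction, voxel GLM, group statistics, FDR, smoothing,
percent signal change, block-length sweep and cluster tables."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phtremor import Bold4D, StatMap
from phtremor.activation import (
    VoxelGLM,
    cluster_peaks,
    block_length_sweep,
    fdr_threshold,
    fit_glm,
    group_one_sample_t,
    paired_t,
    percent_signal_change,
    smooth_gaussian,
    PEAK_TABLE_COLUMNS,
)
from phtremor.design import HrfParams, build_design, hrf

from conftest import bh_oracle


class TestHrf:
    def test_zero_at_and_before_onset(self):
        assert hrf(0.0) == 0.0
        assert hrf(-5.0) == 0.0

    def test_peak_near_configured_delay_on_dense_grid(self):
        t = np.arange(0.0, 30.0, 0.001)
        h = hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.02)
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HrfParams(peak_delay_s=-1.0)

    def test_undershoot_present(self):
        t = np.arange(0.0, 40.0, 0.01)
        h = hrf(t)
        assert h.min() < 0


class TestBuildDesign:
    def test_zero_before_injection_volume(self):
        d = build_design(242, 2.0, 234.0, 25.0)
        assert np.all(d.regressor[:117] == 0.0)
        assert d.regressor.max() == pytest.approx(1.0)

    def test_zero_block_rejected(self):
        with pytest.raises(ValueError):
            build_design(242, 2.0, 234.0, 0.0)

    def test_onset_outside_scan_rejected(self):
        with pytest.raises(ValueError):
            build_design(100, 2.0, 500.0, 25.0)

    def test_impulse_hrf_reproduces_boxcar(self):
        d = build_design(50, 2.0, 20.0, 10.0, impulse_hrf=True)
        onsets = np.arange(50) * 2.0
        boxcar = ((onsets >= 20.0) & (onsets < 30.0)).astype(float)
        np.testing.assert_allclose(d.regressor, boxcar, atol=1e-12)


def _bold(series_matrix, tr_s=2.0):
    arr = np.asarray(series_matrix, dtype=float)
    return Bold4D(arr[:, None, None, :], tr_s=tr_s)


class TestVoxelGLM:
    def test_noiseless_exact_recovery(self):
        d = build_design(60, 2.0, 40.0, 25.0)
        y = 2.0 * d.regressor + 5.0
        res = VoxelGLM(_bold([y]), d).fit()
        assert res.beta_map.values[0, 0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_constant_series_degenerate_flag(self):
        d = build_design(60, 2.0, 40.0, 25.0)
        res = VoxelGLM(_bold([np.full(60, 7.0)]), d).fit()
        assert res.beta_map.values[0, 0, 0] == pytest.approx(0.0, abs=1e-10)
        assert res.t_map.values[0, 0, 0] == 0.0
        assert res.t_map.degenerate[0, 0, 0]

    def test_t_matches_normal_equations_oracle_10_points(self, rng):
        n = 10
        x = np.concatenate([np.zeros(5), np.ones(5)])
        X = np.column_stack([x, np.ones(n)])
        y = 1.5 * x + rng.normal(0, 1, n)
        # hand-computed OLS + residual-variance t
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        t_oracle = beta[0] / se

        from phtremor.design import TaskDesign

        d = TaskDesign(matrix=X, column_names=["task", "intercept"], tr_s=1.0,
                       onset_s=5.0, block_length_s=5.0)
        res = VoxelGLM(_bold(np.array([y]), tr_s=1.0), d).fit()
        assert res.t_map.values[0, 0, 0] == pytest.approx(t_oracle, rel=1e-10)
        assert res.df == n - 2

    def test_noiseless_design_data_exact_to_1e8(self, rng):
        d = build_design(100, 2.0, 100.0, 25.0)
        coefs = rng.normal(size=(5, d.matrix.shape[1]))
        Y = coefs @ d.matrix.T
        res = VoxelGLM(_bold(Y), d).fit()
        np.testing.assert_allclose(
            res.beta_map.values.ravel(), coefs[:, d.task_index],
            rtol=1e-8, atol=1e-10)


class TestPercentSignalChange:
    def test_constant_series_zero_everywhere(self):
        b = _bold([np.full(20, 100.0)])
        psc = percent_signal_change(b, (0, 10))
        np.testing.assert_allclose(psc.data, 0.0)

    def test_simple_arithmetic(self):
        y = np.full(10, 100.0)
        y[5:] = 102.0
        psc = percent_signal_change(_bold([y]), (0, 5))
        assert psc.data[0, 0, 0, 7] == pytest.approx(2.0)

    def test_epoch_mean_equals_mean_of_per_volume_psc(self, rng):
        y = 100.0 + rng.normal(0, 1, 40)
        psc = percent_signal_change(_bold([y]), (0, 20))
        # an 8-s epoch at TR 2 s = 4 volumes
        epoch = psc.data[0, 0, 0, 24:28]
        assert epoch.mean() == pytest.approx(
            np.mean([psc.data[0, 0, 0, i] for i in range(24, 28)]))

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_signal_change(_bold([np.zeros(10)]), (0, 5))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        v = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(smooth_gaussian(v, 0.0, (1, 1, 1)), v)

    def test_constant_volume_unchanged_in_interior(self):
        v = np.full((16, 16, 16), 3.0)
        s = smooth_gaussian(v, 2.8, (1.7, 1.7, 2.4))
        np.testing.assert_allclose(s[4:12, 4:12, 4:12], 3.0, rtol=1e-6)

    def test_impulse_matches_direct_gaussian_kernel(self):
        v = np.zeros((15, 15, 15))
        v[7, 7, 7] = 1.0
        vox = (1.7, 1.7, 2.4)
        s = smooth_gaussian(v, 2.8, vox)
        sigma_mm = 2.8 / np.sqrt(8 * np.log(2))
        # direct evaluation along each axis through the impulse
        for axis, vsz in enumerate(vox):
            idx = [7, 7, 7]
            prof = []
            for k in range(15):
                idx[axis] = k
                prof.append(s[tuple(idx)])
            d_mm = (np.arange(15) - 7) * vsz
            expect = np.exp(-d_mm**2 / (2 * sigma_mm**2))
            expect /= expect.sum()
            centre_plane = s[7, 7, 7] / expect[7]
            np.testing.assert_allclose(prof, expect * centre_plane, atol=1e-4)
        assert s.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mean_conserved_for_interior_support(self, rng):
        v = np.zeros((20, 20, 20))
        v[8:12, 8:12, 8:12] = rng.normal(size=(4, 4, 4))
        s = smooth_gaussian(v, 2.0, (1.0, 1.0, 1.0))
        assert s.mean() == pytest.approx(v.mean(), rel=1e-6, abs=1e-12)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0, (1, 1, 1))


def _maps(values_list):
    return [StatMap(np.asarray(v, dtype=float).reshape(1, 1, 1), "beta")
            for v in values_list]


class TestGroupStats:
    def test_symmetric_betas_give_zero_t(self):
        t, p = group_one_sample_t(_maps([[-1.0], [1.0]]))
        assert t.values[0, 0, 0] == pytest.approx(0.0)

    def test_hand_formula_oracle(self):
        t, p = group_one_sample_t(_maps([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        assert t.values[0, 0, 0] == pytest.approx(3.0 / (1.5811388 / np.sqrt(5)),
                                                  rel=1e-6)
        assert t.df == 4

    def test_identical_betas_flagged_not_infinite(self):
        t, _ = group_one_sample_t(_maps([[2.0], [2.0], [2.0]]))
        assert np.isfinite(t.values).all()
        assert t.degenerate[0, 0, 0]

    def test_fewer_than_two_maps_rejected(self):
        with pytest.raises(ValueError):
            group_one_sample_t(_maps([[1.0]]))

    def test_paired_identical_pairs_degenerate(self):
        a = _maps([[1.0], [2.0], [3.0]])
        t, _ = paired_t(a, a)
        assert t.degenerate[0, 0, 0]
        assert t.values[0, 0, 0] == 0.0

    def test_paired_hand_formula(self):
        a = _maps([[2.0], [3.0], [4.0], [5.0], [1.0]])
        b = _maps([[1.0], [2.0], [3.0], [4.0], [1.0]])
        t, _ = paired_t(a, b)  # differences [1,1,1,1,0]
        assert t.values[0, 0, 0] == pytest.approx(4.0, rel=1e-6)

    def test_paired_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            paired_t(_maps([[1.0], [2.0]]), _maps([[1.0]]))


class TestFdr:
    def test_worked_example(self):
        pm = StatMap(np.array([0.001, 0.02, 0.03, 0.9]).reshape(4, 1, 1), "p")
        mask, crit = fdr_threshold(pm, q=0.05)
        assert mask.sum() == 3
        assert crit == pytest.approx(0.03)

    def test_all_ones_no_rejections(self):
        pm = StatMap(np.ones((3, 2, 1)), "p")
        mask, crit = fdr_threshold(pm, q=0.05)
        assert mask.sum() == 0
        assert np.isnan(crit)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            q = rng.uniform(0.001, 0.2)
            pm = StatMap(p.reshape(m, 1, 1), "p")
            mask, _ = fdr_threshold(pm, q=q)
            np.testing.assert_array_equal(mask.ravel(), bh_oracle(p, q))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_q(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(size=30)
        pm = StatMap(p.reshape(30, 1, 1), "p")
        m1, _ = fdr_threshold(pm, q=0.01)
        m2, _ = fdr_threshold(pm, q=0.1)
        assert np.all(m2[m1])  # rejections at stricter q are a subset


class TestSweepAndClusters:
    def test_single_candidate_returned(self, rng):
        d = build_design(60, 2.0, 40.0, 25.0)
        Y = 1.0 * d.regressor + rng.normal(0, 0.1, (5, 60))
        mask = np.ones((5, 1, 1), dtype=bool)
        best, table = block_length_sweep(_bold(Y), [25.0], mask, 40.0)
        assert best == 25.0
        assert len(table) == 1

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            block_length_sweep(_bold(rng.normal(size=(2, 30))), [10.0],
                               np.zeros((2, 1, 1), bool), 20.0)

    def test_no_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            block_length_sweep(_bold(rng.normal(size=(2, 30))), [],
                               np.ones((2, 1, 1), bool), 20.0)

    def test_no_suprathreshold_gives_empty_table(self):
        tm = StatMap(np.zeros((6, 6, 6)), "t", df=10)
        table = cluster_peaks(tm, threshold=2.0)
        assert len(table) == 0
        assert list(table.columns) == PEAK_TABLE_COLUMNS

    def test_single_cubic_cluster(self):
        vals = np.zeros((9, 9, 9))
        vals[3:6, 3:6, 3:6] = 5.0
        vals[4, 4, 4] = 9.0
        tm = StatMap(vals, "t", df=10, voxel_size_mm=(1.0, 1.0, 1.0))
        table = cluster_peaks(tm, threshold=2.0)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["cluster_size"] == 27
        assert row["t"] == 9.0
        assert (row["x"], row["y"], row["z"]) == (0.0, 0.0, 0.0)
        assert row["hemisphere"] == "L/R"

    def test_26_connectivity_joins_diagonal_voxels(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0] = 3.0
        vals[1, 1, 1] = 3.0
        table = cluster_peaks(StatMap(vals, "t", df=5), threshold=2.0)
        assert len(table) == 1
        assert table.iloc[0]["cluster_size"] == 2

    def test_min_cluster_filters(self):
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0] = 3.0
        table = cluster_peaks(StatMap(vals, "t", df=5), threshold=2.0,
                              min_cluster=2)
        assert len(table) == 0
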