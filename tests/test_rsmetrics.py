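"""ALFF, ReHo (Kendall's W), seed connectivity, and mixture correction."""

import numpy as np
import pytest
from scipy import stats

from physioeval.datatypes import BoldRun, MetricMap
from physioeval.correction import bandpass_filter
from physioeval.rsmetrics import (
    binarize,
    compute_alff,
    compute_reho,
    fit_null_mixture,
    kendalls_w,
    make_seed_roi,
    mixture_correct,
    normalize_map,
    seed_z_map,
)


def _run_from_matrix(Y, tr=2.0):
    """(n_vox, n_frames) matrix as a 1-D line of voxels."""
    n_vox, n = Y.shape
    return BoldRun(data=Y.reshape(n_vox, 1, 1, n), tr=tr,
                   mask=np.ones((n_vox, 1, 1), bool))


class TestALFF:
    def test_constant_is_zero(self):
        run = _run_from_matrix(np.full((3, 240), 7.0))
        assert np.allclose(compute_alff(run).in_mask(), 0.0)

    def test_band_selectivity(self):
        t = np.arange(240) * 2.0
        Y = np.stack([np.sin(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.2 * t)])
        vals = compute_alff(_run_from_matrix(Y)).in_mask()
        assert vals[0] / vals[1] >= 10

    def test_linear_in_noise_sd(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(100):
            x = rng.standard_normal(240)
            a1 = compute_alff(_run_from_matrix(np.stack([x, 2 * x]))).in_mask()
            ratios.append(a1[1] / a1[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_band_empty_at_tr(self):
        run = _run_from_matrix(np.random.default_rng(0).standard_normal((1, 240)))
        with pytest.raises(ValueError):
            compute_alff(run, band=(0.0001, 0.0005))


class TestNormalizeMap:
    def _map(self, vals):
        v = np.asarray(vals, dtype=float).reshape(-1, 1, 1)
        return MetricMap(values=v, metric="ALFF", mask=np.ones(v.shape, bool))

    def test_zero_mean_unit_sd(self):
        out = normalize_map(self._map([1.0, 2.0, 5.0, 9.0]))
        assert out.in_mask().mean() == pytest.approx(0.0, abs=1e-12)
        assert out.in_mask().std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        once = normalize_map(self._map([1.0, 2.0, 5.0, 9.0]))
        twice = normalize_map(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_affine_invariance(self):
        a = normalize_map(self._map([1.0, 2.0, 5.0, 9.0]))
        b = normalize_map(self._map([3.0 * x + 11.0 for x in [1, 2, 5, 9]]))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_degenerate_map(self):
        with pytest.raises(ValueError):
            normalize_map(self._map([2.0, 2.0, 2.0]))


def _brute_force_w(M):
    """Independent rank-sum computation of Kendall's W with tie correction."""
    M = np.asarray(M, dtype=float)
    K, n = M.shape
    ranks = np.empty_like(M)
    T = 0.0
    for i in range(K):
        order = np.argsort(M[i])
        r = np.empty(n)
        j = 0
        while j < n:
            k = j
            while k + 1 < n and M[i, order[k + 1]] == M[i, order[j]]:
                k += 1
            r[order[j:k + 1]] = (j + k) / 2.0 + 1.0
            t = k - j + 1
            if t > 1:
                T += t ** 3 - t
            j = k + 1
        ranks[i] = r
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return 12.0 * S / (K ** 2 * (n ** 3 - n) - K * T)


class TestKendallsW:
    def test_identical_series(self):
        x = np.sin(np.arange(10.0))
        assert kendalls_w(np.tile(x, (5, 1))) == pytest.approx(1.0)

    def test_reversed_ranks_zero(self):
        x = np.arange(6.0)
        assert kendalls_w(np.stack([x, x[::-1]])) == pytest.approx(0.0)

    def test_explicit_rank_case(self):
        M = np.array([[1, 2, 3, 4], [1, 3, 2, 4], [2, 1, 3, 4]], dtype=float)
        assert kendalls_w(M) == pytest.approx(_brute_force_w(M), abs=1e-12)

    def test_all_constant_undefined(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((3, 5)))


class TestReHo:
    def test_shared_series_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        data = np.tile(x, (6, 6, 6, 1))
        run = BoldRun(data=data, tr=2.0, mask=np.ones((6, 6, 6), bool))
        out = compute_reho(run)
        assert np.allclose(out.values[2:4, 2:4, 2:4], 1.0)

    def test_independent_noise_low(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 8, 6, 240))
        run = BoldRun(data=data, tr=2.0, mask=np.ones((8, 8, 6), bool))
        out = compute_reho(run)
        interior = out.values[2:-2, 2:-2, 2:-2]
        assert np.nanmean(interior) < 0.2

    def test_range(self, sim_run):
        bp = bandpass_filter(sim_run.bold, 0.01, 0.1)
        out = compute_reho(bp)
        vals = out.values[np.isfinite(out.values)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestSeedZMap:
    def _network_run(self, n=240, seed=0):
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(n)
        Y = np.stack([sig, -sig, rng.standard_normal(n)])
        return _run_from_matrix(Y), sig

    def test_identical_voxel_capped(self):
        run, _ = self._network_run()
        roi = np.zeros((3, 1, 1), bool)
        roi[0] = True
        z = seed_z_map(run, roi)
        cap = np.arctanh(1 - 1e-15) * np.sqrt(240 - 3)
        assert z.values[0, 0, 0] == pytest.approx(cap)

    def test_anticorrelated_voxel(self):
        run, _ = self._network_run()
        roi = np.zeros((3, 1, 1), bool)
        roi[0] = True
        z = seed_z_map(run, roi)
        assert z.values[1, 0, 0] < -30

    def test_independent_voxel_unbiased(self):
        rng = np.random.default_rng(3)
        zs = []
        for _ in range(100):
            Y = rng.standard_normal((2, 240))
            run = _run_from_matrix(Y)
            roi = np.zeros((2, 1, 1), bool)
            roi[0] = True
            zs.append(seed_z_map(run, roi).values[1, 0, 0])
        se = np.std(zs) / 10.0
        assert abs(np.mean(zs)) < 3 * se + 1e-9

    def test_seed_roi_radius(self):
        roi = make_seed_roi((5, 5, 3), (3.44, 3.44, 4.6), (11, 11, 7), 4.0)
        assert roi[5, 5, 3]
        assert roi[6, 5, 3] and roi[5, 6, 3]   # 3.44 mm away
        assert not roi[5, 5, 4]                # 4.6 mm away


class TestMixture:
    def test_standard_normal_recovery(self):
        z = np.random.default_rng(0).standard_normal(10000)
        f = fit_null_mixture(z)
        assert abs(f.null_mean) < 0.05
        assert 0.95 < f.null_sd < 1.05

    def test_mixture_weight_recovery(self):
        rng = np.random.default_rng(1)
        weights = []
        for _ in range(20):
            n0 = rng.binomial(10000, 0.9)
            z = np.concatenate([rng.standard_normal(n0),
                                2.0 + rng.gamma(4.0, 1.5, 10000 - n0)])
            weights.append(fit_null_mixture(z).null_weight)
        assert abs(np.mean(weights) - 0.9) < 0.05

    def test_doubled_null_sd(self):
        z = 2.0 * np.random.default_rng(2).standard_normal(10000)
        f = fit_null_mixture(z)
        assert 1.9 < f.null_sd < 2.1

    def test_corrected_map_refits_standard(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([0.4 + 1.5 * rng.standard_normal(9000),
                            4.0 + rng.gamma(3.0, 1.0, 1000)])
        vals = z.reshape(-1, 1, 1)
        zmap = MetricMap(values=vals, metric="z", mask=np.ones(vals.shape, bool))
        fit = fit_null_mixture(zmap.in_mask())
        corrected = mixture_correct(zmap, fit)
        refit = fit_null_mixture(corrected.in_mask())
        assert abs(refit.null_mean) < 0.05
        assert abs(refit.null_sd - 1.0) < 0.05

    def test_correct_arithmetic(self):
        vals = np.array([3.0]).reshape(1, 1, 1)
        zmap = MetricMap(values=vals, metric="z", mask=np.ones(vals.shape, bool))
        from physioeval.datatypes import MixtureFit
        fit = MixtureFit(null_mean=1.0, null_sd=2.0, null_weight=0.9,
                         alt_shape=3.0, alt_scale=1.0, converged=True,
                         n_iter=10, log_likelihood=0.0)
        assert mixture_correct(zmap, fit).values[0, 0, 0] == pytest.approx(1.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_null_mixture(np.random.default_rng(0).standard_normal(100))


class TestBinarize:
    def _map(self, vals):
        v = np.asarray(vals, dtype=float).reshape(-1, 1, 1)
        return MetricMap(values=v, metric="corrected_z",
                         mask=np.ones(v.shape, bool))

    def test_all_below(self):
        assert binarize(self._map([0.4, 0.4]), 0.5).size == 0

    def test_all_above(self):
        assert binarize(self._map([0.6, 0.6]), 0.5).size == 2

    def test_tie_excluded(self):
        assert binarize(self._map([0.5]), 0.5).size == 0
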