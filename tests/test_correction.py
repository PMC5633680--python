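"""Response model, strategy regression, and preprocessing filters."""

import numpy as np
import pytest

from physioeval.datatypes import BoldRun, SIGNALS
from physioeval.correction import (
    apply_strategy,
    bandpass_filter,
    convolve_regressor,
    decimate_to_tr,
    fit_physio_responses,
    gaussian_kernel,
    spatial_smooth,
)
from physioeval.physio import extract_regressors


@pytest.fixture(scope="module")
def run_and_regressors(sim_runs):
    sim = sim_runs[0]
    ft = sim.bold.frame_times
    pet, rvt, crv = extract_regressors(sim.recordings["cardiac"],
                                       sim.recordings["respiratory"],
                                       sim.recordings["co2"], ft)
    return sim, {"PETCO2": pet, "RVT": rvt, "CRV": crv}


def _single_voxel_run(series, tr):
    data = series.reshape(1, 1, 1, -1)
    return BoldRun(data=data, tr=tr, mask=np.ones((1, 1, 1), bool))


class TestGaussianKernel:
    def test_direct_formula(self):
        t = np.arange(0, 41, 2.0)
        k = gaussian_kernel(2.0, 8.0, 4.0, t)
        assert np.allclose(k, 2.0 * np.exp(-((t - 8.0) ** 2) / 32.0))

    def test_zero_amplitude(self):
        assert np.allclose(gaussian_kernel(0.0, 10, 5, np.arange(0, 40, 2.0)), 0)

    def test_narrow_width_is_impulse(self):
        t = np.arange(0, 40, 0.01)
        k = gaussian_kernel(1.0, 10.0, 0.002, t)
        assert k[np.argmin(np.abs(t - 10.0))] == pytest.approx(1.0, abs=1e-6)
        assert k[np.abs(t - 10.0) > 0.05].max() < 1e-12

    def test_latency_beyond_span(self):
        with pytest.raises(ValueError):
            gaussian_kernel(1.0, 50.0, 5.0, np.arange(0, 40, 2.0))


class TestConvolveRegressor:
    def test_impulse_kernel_identity(self):
        x = np.sin(np.arange(100) * 0.3) + 5.0
        out = convolve_regressor(x, np.array([1.0]))
        assert np.allclose(out, x - x.mean())

    def test_constant_regressor_zero(self):
        out = convolve_regressor(np.full(50, 7.0), np.array([0.2, 0.5, 0.1]))
        assert np.allclose(out, 0.0)

    def test_sinusoid_matches_transfer_function(self):
        tr, f = 2.0, 0.03
        n = 400
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * f * t)
        kernel = gaussian_kernel(1.0, 10.0, 5.0, np.arange(0, 40 + tr, tr))
        out = convolve_regressor(x, kernel)
        # frequency-domain oracle: H(f) = sum_j k_j exp(-2*pi*i*f*j*TR)
        H = np.sum(kernel * np.exp(-2j * np.pi * f * np.arange(kernel.size) * tr))
        expected = np.abs(H) * np.sin(2 * np.pi * f * t + np.angle(H))
        m = slice(kernel.size, n)  # past the convolution transient
        err = np.linalg.norm(out[m] - expected[m]) / np.linalg.norm(expected[m])
        assert err < 1e-6


class TestFitResponses:
    def test_exact_model_zero_residual(self, run_and_regressors):
        sim, regs = run_and_regressors
        tr = sim.bold.tr
        t_k = np.arange(0, 40 + tr, tr)
        y = convolve_regressor(regs["RVT"], gaussian_kernel(1.2, 10.0, 5.0, t_k))
        run = _single_voxel_run(y + 50.0, tr)
        fit = fit_physio_responses(run, regs, mu_step=2.0, sigma_step=2.0)
        assert fit.residual_variance[0] <= 1e-12 * np.var(y)
        assert fit.latency["RVT"][0] == 10.0
        assert fit.width["RVT"][0] == 5.0
        assert fit.amplitude["RVT"][0] == pytest.approx(1.2, rel=1e-6)

    def test_known_response_recovery_high_snr(self, run_and_regressors):
        sim, regs = run_and_regressors
        tr = sim.bold.tr
        t_k = np.arange(0, 40 + tr, tr)
        rng = np.random.default_rng(1)
        y = 50.0 + 0.02 * rng.standard_normal(sim.bold.n_frames)
        true = {"PETCO2": (1.5, 10.0, 5.0), "RVT": (0.8, 7.0, 4.0),
                "CRV": (-1.0, 13.0, 6.0)}
        for s, (a, mu, sg) in true.items():
            y = y + convolve_regressor(regs[s], gaussian_kernel(a, mu, sg, t_k))
        fit = fit_physio_responses(_single_voxel_run(y, tr), regs)
        for s, (a, mu, sg) in true.items():
            assert abs(fit.latency[s][0] - mu) <= 1.0
            assert abs(fit.width[s][0] - sg) <= 1.0
            assert fit.amplitude[s][0] == pytest.approx(a, rel=0.1)

    def test_noise_voxel_r2_below_permutation_null(self, run_and_regressors):
        sim, regs = run_and_regressors
        tr = sim.bold.tr
        rng = np.random.default_rng(5)
        y = rng.standard_normal(sim.bold.n_frames)
        run = _single_voxel_run(y, tr)
        observed = fit_physio_responses(run, regs, mu_step=3.0, sigma_step=3.0
                                        ).r_squared[0]
        # permutation null: phase-randomized regressors destroy any real
        # coupling while preserving the spectra
        null = []
        from physioeval.datatypes import PhysioRegressor
        for p in range(199):
            prng = np.random.default_rng(1000 + p)
            perm = {}
            for s, reg in regs.items():
                spec = np.fft.rfft(reg.values - reg.values.mean())
                phases = np.exp(2j * np.pi * prng.random(spec.size))
                phases[0] = 1.0
                shuffled = np.fft.irfft(spec * phases, n=reg.values.size)
                perm[s] = PhysioRegressor(values=shuffled + reg.values.mean(),
                                          kind=s, frame_times=reg.frame_times)
            null.append(fit_physio_responses(run, perm, mu_step=3.0,
                                             sigma_step=3.0).r_squared[0])
        assert observed <= np.quantile(null, 0.95)

    def test_collinear_regressors_rejected(self, run_and_regressors):
        sim, regs = run_and_regressors
        from physioeval.datatypes import PhysioRegressor
        dup = dict(regs)
        dup["RVT"] = PhysioRegressor(values=regs["PETCO2"].values.copy(),
                                     kind="RVT",
                                     frame_times=regs["PETCO2"].frame_times)
        with pytest.raises(ValueError, match="collinear"):
            fit_physio_responses(sim.bold, dup)


@pytest.fixture(scope="module")
def fitted(run_and_regressors):
    sim, regs = run_and_regressors
    run = BoldRun(data=sim.bold.data, tr=sim.bold.tr,
                  mask=sim.bold.mask, frame_times=sim.bold.frame_times)
    fit = fit_physio_responses(run, regs, mu_step=2.0, sigma_step=2.0,
                               max_cycles=3)
    return run, regs, fit


class TestApplyStrategy:
    def test_base_is_identity(self, fitted):
        run, regs, fit = fitted
        out = apply_strategy(run, regs, fit, "Base")
        assert np.array_equal(out.data, run.data)

    def test_exact_model_removed(self, run_and_regressors):
        sim, regs = run_and_regressors
        tr = sim.bold.tr
        t_k = np.arange(0, 40 + tr, tr)
        y = 10.0
        for s, (a, mu, sg) in {"PETCO2": (1.0, 10, 5), "RVT": (0.5, 8, 4),
                               "CRV": (-0.8, 12, 6)}.items():
            y = y + convolve_regressor(regs[s], gaussian_kernel(a, mu, sg, t_k))
        run = _single_voxel_run(y, tr)
        fit = fit_physio_responses(run, regs)
        out = apply_strategy(run, regs, fit, "All")
        resid = out.data[0, 0, 0]
        assert resid.var() <= 1e-12 * np.var(y)
        assert resid.mean() == pytest.approx(np.mean(y), rel=1e-9)

    def test_residual_orthogonal_to_regressor(self, fitted):
        run, regs, fit = fitted
        out = apply_strategy(run, regs, fit, "PETCO2")
        Y = out.masked_series()
        t_k = np.arange(0, 40 + run.tr, run.tr)
        for v in range(0, Y.shape[1], 197):
            kern = gaussian_kernel(1.0, float(fit.latency["PETCO2"][v]),
                                   float(fit.width["PETCO2"][v]), t_k)
            c = convolve_regressor(regs["PETCO2"], kern)
            r = np.corrcoef(Y[:, v], c)[0, 1]
            assert abs(r) < 1e-10

    def test_variance_non_increasing_and_nested(self, fitted):
        run, regs, fit = fitted
        var0 = run.masked_series().var(axis=0)
        var_all = apply_strategy(run, regs, fit, "All").masked_series().var(axis=0)
        assert (var_all <= var0 + 1e-12).all()
        for single in ("PETCO2", "RVT", "CRV"):
            var_s = apply_strategy(run, regs, fit, single).masked_series().var(axis=0)
            assert (var_s <= var0 + 1e-12).all()
            assert (var_all <= var_s + 1e-10).all()

    def test_missing_response_rejected(self, fitted):
        run, regs, _ = fitted
        with pytest.raises(ValueError):
            apply_strategy(run, regs, None, "PETCO2")


class TestBandpass:
    def _sine_run(self, f, tr=1.0, n=600):
        t = np.arange(n) * tr
        data = np.sin(2 * np.pi * f * t).reshape(1, 1, 1, -1) + 3.0
        return BoldRun(data=data, tr=tr, mask=np.ones((1, 1, 1), bool))

    def test_in_band_gain(self):
        run = self._sine_run(0.05)
        out = bandpass_filter(run, 0.01, 0.1)
        x = out.data[0, 0, 0] - 3.0
        gain = x[100:500].std() / (np.sqrt(0.5))
        assert 0.95 <= gain <= 1.05

    def test_out_of_band_attenuation(self):
        run = self._sine_run(0.3)
        out = bandpass_filter(run, 0.01, 0.1)
        x = out.data[0, 0, 0] - 3.0
        assert x[100:500].std() / np.sqrt(0.5) <= 0.1

    def test_idempotent_within_tolerance(self, sim_run):
        once = bandpass_filter(sim_run.bold, 0.01, 0.1)
        twice = bandpass_filter(once, 0.01, 0.1)
        num = np.sqrt(np.mean((twice.data - once.data) ** 2))
        den = np.sqrt(np.mean((once.data - once.data.mean(axis=3, keepdims=True)) ** 2))
        assert num / den <= 0.02

    def test_invalid_band(self, sim_run):
        with pytest.raises(ValueError):
            bandpass_filter(sim_run.bold, 0.01, 0.4)  # above Nyquist at TR=2


class TestSpatialSmooth:
    def test_zero_fwhm_identity(self, sim_run):
        out = spatial_smooth(sim_run.bold, fwhm=0.0)
        assert np.array_equal(out.data, sim_run.bold.data)

    def test_constant_preserved(self):
        data = np.full((8, 8, 8, 3), 5.0)
        run = BoldRun(data=data, tr=2.0, mask=np.ones((8, 8, 8), bool),
                      voxel_size=(3.0, 3.0, 3.0))
        out = spatial_smooth(run, fwhm=8.0)
        assert np.allclose(out.data, 5.0)

    def test_impulse_matches_gaussian(self):
        shape = (31, 31, 31)
        data = np.zeros(shape + (1,))
        data[15, 15, 15, 0] = 1.0
        run = BoldRun(data=data, tr=2.0, mask=np.ones(shape, bool),
                      voxel_size=(2.0, 2.0, 2.0))
        fwhm = 8.0
        out = spatial_smooth(run, fwhm=fwhm)
        sig_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
        x = np.arange(31) - 15.0
        g = np.exp(-x[:, None, None] ** 2 / (2 * sig_vox ** 2)) * \
            np.exp(-x[None, :, None] ** 2 / (2 * sig_vox ** 2)) * \
            np.exp(-x[None, None, :] ** 2 / (2 * sig_vox ** 2))
        g = g / g.sum()
        core = (slice(10, 21),) * 3
        got = out.data[..., 0][core]
        want = g[core]
        assert np.abs(got - want).max() <= 0.05 * want.max()


class TestDecimate:
    def test_identity_at_target(self, sim_run):
        out = decimate_to_tr(sim_run.bold, target_tr=2.0)
        assert out.n_frames == sim_run.bold.n_frames
        assert np.array_equal(out.data, sim_run.bold.data)
        assert out.condition == "shortTR_downsampled"

    def test_short_run_yields_240_frames(self):
        n = 1486
        data = np.zeros((1, 1, 1, n))
        run = BoldRun(data=data, tr=0.323, mask=np.ones((1, 1, 1), bool),
                      condition="shortTR")
        out = decimate_to_tr(run, target_tr=2.0)
        assert out.n_frames == 240
        assert out.tr == 2.0

    def test_low_frequency_survives(self):
        n = 1486
        t = np.arange(n) * 0.323
        data = np.sin(2 * np.pi * 0.04 * t).reshape(1, 1, 1, -1)
        run = BoldRun(data=data, tr=0.323, mask=np.ones((1, 1, 1), bool))
        out = decimate_to_tr(run, target_tr=2.0)
        x = out.data[0, 0, 0]
        amp = x[20:-20].std() * np.sqrt(2)
        assert abs(amp - 1.0) < 0.05
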