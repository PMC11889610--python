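"""MVAR fitting and spectral connectivity."""

import numpy as np
import pytest

from strokebeta.mvar import (band_window_average, beta_power_timecourse,
                             companion_eigenvalues, derive_rebound_window,
                             fit_mvar, sliding_spectra, spectra,
                             MVARModel, TimeResolvedSpectra)
from strokebeta.preprocess import EpochedSeries
from strokebeta.synthetic import (base_coefficients, make_gain_envelope,
                                  simulate_roi_process)


def model_from(coeffs, cov, fs=250.0):
    return MVARModel(coeffs=coeffs, resid_cov=cov, fs=fs,
                     n_samples_used=1000)


class TestSpectraClosedForms:
    def test_white_noise_identity_structure(self):
        n, sigma2, fs = 4, 2.5, 250.0
        m = model_from(np.zeros((6, n, n)), sigma2 * np.eye(n), fs)
        dec = spectra(m, np.linspace(1, 100, 40))
        np.testing.assert_allclose(
            dec.S, np.broadcast_to(sigma2 * np.eye(n), dec.S.shape),
            atol=1e-12)
        np.testing.assert_allclose(dec.psd, sigma2 / fs)
        off = ~np.eye(n, dtype=bool)
        assert np.all(dec.msc[:, off] == 0.0)
        # PDC is the identity pattern
        np.testing.assert_allclose(dec.pdc[:, off], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.einsum("fii->fi", dec.pdc), 1.0, atol=1e-12)

    def test_unidirectional_two_node_pdc(self):
        a1 = np.array([[0.5, 0.0], [0.4, 0.5]])
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = a1
        m = model_from(coeffs, np.eye(2))
        dec = spectra(m, np.linspace(1, 120, 60))
        # influence 1 -> 2 lives in pdc[:, 1, 0]; no 2 -> 1 influence
        assert (dec.pdc[:, 1, 0] > 0).all()
        np.testing.assert_allclose(dec.pdc[:, 0, 1], 0.0, atol=1e-14)

    def test_invariants_on_fitted_models(self, rng):
        coeffs = base_coefficients(250.0, couplings={(0, 2): 0.02,
                                                     (4, 1): 0.015})
        env = np.ones((6, 3000))
        from strokebeta.synthetic import simulate_continuous

        x = simulate_continuous(coeffs, env, seed=rng.integers(2 ** 31))
        dec = spectra(fit_mvar(x[None], order=6, fs=250.0))
        colnorm = (dec.pdc ** 2).sum(axis=1)
        np.testing.assert_allclose(colnorm, 1.0, atol=1e-10)
        assert (dec.psd >= 0).all()
        assert (dec.msc >= 0).all() and (dec.msc <= 1 + 1e-12).all()
        np.testing.assert_allclose(np.einsum("fii->fi", dec.msc), 1.0)

    def test_frequency_grid_validation(self):
        m = model_from(np.zeros((2, 3, 3)), np.eye(3))
        with pytest.raises(ValueError):
            spectra(m, [0.0, 10.0])
        with pytest.raises(ValueError):
            spectra(m, [130.0])


class TestFitMVAR:
    def test_parameter_recovery(self):
        coeffs = base_coefficients(250.0, n_roi=3, order=4,
                                   couplings={(1, 0): 0.2})
        env = np.ones((3, 300))
        data = simulate_roi_process(coeffs, env, n_epochs=40,
                                    epoch_len_s=1.2, fs=250.0, seed=8,
                                    t0=-0.5)
        m = fit_mvar(data, order=4, fs=250.0)
        rmse = np.sqrt(np.mean((m.coeffs - coeffs) ** 2))
        assert rmse < 0.08
        assert m.stable

    def test_off_diagonal_shrinks_with_sample_size(self):
        # independent channels: cross-coefficients are pure noise and
        # their RMSE should roughly halve when T quadruples
        rng = np.random.default_rng(0)
        errs = []
        off = ~np.eye(3, dtype=bool)
        for n_samples in (400, 1600):
            mse = [np.mean(fit_mvar(rng.standard_normal((20, 3, n_samples)),
                                    order=2, fs=100.0).coeffs[:, off] ** 2)
                   for _ in range(10)]
            errs.append(np.sqrt(np.mean(mse)))
        assert 0.4 < errs[1] / errs[0] < 0.62

    def test_residual_covariance_denominator(self, rng):
        x = rng.standard_normal((5, 2, 100))
        m = fit_mvar(x, order=1, fs=100.0)
        assert m.resid_cov.shape == (2, 2)
        np.testing.assert_allclose(m.resid_cov, m.resid_cov.T, atol=1e-10)

    def test_short_epoch_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mvar(rng.standard_normal((10, 6, 5)), order=6, fs=250.0)

    def test_pooled_sample_precondition(self, rng):
        with pytest.raises(ValueError, match="pooled"):
            fit_mvar(rng.standard_normal((1, 6, 40)), order=6, fs=250.0)


class TestSlidingAndAveraging:
    def _epochs(self, rng, n_epochs=30, n_samples=500):
        coeffs = base_coefficients(250.0)
        env = np.ones((6, n_samples))
        data = simulate_roi_process(coeffs, env, n_epochs, n_samples / 250,
                                    fs=250.0, seed=int(rng.integers(2**31)))
        return EpochedSeries(data=data, fs=250.0, t0=-0.5)

    def test_degenerate_step_equals_whole_epoch_fit(self, rng):
        ep = self._epochs(rng)
        tr = sliding_spectra(ep, step_s=10.0)
        assert tr.centers.size == 1
        whole = spectra(fit_mvar(ep), tr.freqs)
        np.testing.assert_allclose(tr.psd[0], whole.psd)

    def test_stationary_input_no_trend(self, rng):
        ep = self._epochs(rng, n_epochs=60)
        tr = sliding_spectra(ep)
        beta = tr.psd[:, (tr.freqs >= 13) & (tr.freqs <= 30)].mean(
            axis=(1, 2))
        # window-to-window variation stays within sampling error: the
        # slope of a fitted linear trend is small vs. the mean level
        slope = np.polyfit(tr.centers, beta / beta.mean(), 1)[0]
        assert abs(slope) < 0.15

    def test_band_window_average_constant_and_oracle(self, rng):
        n_win, n_f, n = 7, 11, 3
        freqs = np.linspace(5, 45, n_f)
        centers = np.linspace(0, 1.4, n_win)
        const = TimeResolvedSpectra(
            centers=centers, freqs=freqs,
            psd=np.full((n_win, n_f, n), 3.3),
            msc=np.full((n_win, n_f, n, n), 0.25),
            pdc=np.full((n_win, n_f, n, n), 0.5))
        s = band_window_average(const, band=(13, 30), window=(0.2, 1.0))
        np.testing.assert_allclose(s.psd_beta, 3.3)
        np.testing.assert_allclose(s.msc_beta, 0.25)
        # random field: agreement with explicit index enumeration
        tr = TimeResolvedSpectra(
            centers=centers, freqs=freqs,
            psd=rng.random((n_win, n_f, n)),
            msc=rng.random((n_win, n_f, n, n)),
            pdc=rng.random((n_win, n_f, n, n)))
        band, window = (13.0, 30.0), (0.4, 1.2)
        widx = [i for i, c in enumerate(centers)
                if window[0] <= c <= window[1]]
        fidx = [i for i, f in enumerate(freqs) if band[0] <= f <= band[1]]
        expect = np.mean([tr.psd[w, f] for w in widx for f in fidx], axis=0)
        got = band_window_average(tr, band, window)
        np.testing.assert_allclose(got.psd_beta, expect)
        # single-bin band equals that bin
        one = band_window_average(tr, (freqs[3], freqs[3]),
                                  (centers[2], centers[2]))
        np.testing.assert_allclose(one.psd_beta, tr.psd[2, 3])

    def test_empty_selection_errors(self, rng):
        ep = self._epochs(rng, n_epochs=10)
        tr = sliding_spectra(ep)
        with pytest.raises(ValueError):
            band_window_average(tr, band=(100, 110))


class TestBetaTimecourse:
    def test_constant_tone_flat(self):
        fs = 250.0
        t = np.arange(500) / fs - 0.5
        tone = np.sin(2 * np.pi * 20 * t)
        data = np.tile(tone, (5, 2, 1))
        ep = EpochedSeries(data=data, fs=fs, t0=-0.5)
        times, rel = beta_power_timecourse(ep)
        mid = (times > -0.3) & (times < 1.3)
        np.testing.assert_allclose(rel[:, mid], 0.0, atol=0.05)

    def test_suppression_and_rebound_signs(self):
        coeffs = base_coefficients(250.0, n_roi=2, order=2)
        t = np.arange(500) / 250.0 - 0.5
        env = np.tile(make_gain_envelope(t, rebound_gain=1.6), (2, 1))
        data = simulate_roi_process(coeffs, env, n_epochs=80,
                                    epoch_len_s=2.0, fs=250.0, seed=3)
        ep = EpochedSeries(data=data, fs=250.0, t0=-0.5)
        times, rel = beta_power_timecourse(ep)
        sup = rel[:, (times >= 0.25) & (times <= 0.45)].mean()
        reb = rel[:, (times >= 0.7) & (times <= 1.1)].mean()
        assert sup < -0.2
        assert reb > 0.2

    def test_rebound_monotone_in_gain(self):
        coeffs = base_coefficients(250.0, n_roi=2, order=2)
        t = np.arange(500) / 250.0 - 0.5
        rebs = []
        for gain in (0.8, 1.5):
            env = np.tile(make_gain_envelope(t, rebound_gain=gain), (2, 1))
            data = simulate_roi_process(coeffs, env, n_epochs=60,
                                        epoch_len_s=2.0, fs=250.0, seed=5)
            ep = EpochedSeries(data=data, fs=250.0, t0=-0.5)
            times, rel = beta_power_timecourse(ep)
            rebs.append(rel[:, (times >= 0.6) & (times <= 1.2)].mean())
        assert rebs[1] > rebs[0]


class TestReboundWindow:
    def test_all_zero_envelopes_fall_back(self):
        times = np.linspace(-0.5, 1.5, 200)
        with pytest.warns(UserWarning, match="fall"):
            win = derive_rebound_window(np.zeros((8, 200)), times, seed=0)
        assert win == (0.6, 1.2)

    def test_planted_interval_recovered(self):
        times = np.linspace(-0.5, 1.5, 500)
        rng = np.random.default_rng(2)
        base = np.where((times >= 0.6) & (times <= 1.2), 0.5, 0.0)
        tc = base + rng.normal(0, 0.15, size=(10, 500))
        lo, hi = derive_rebound_window(tc, times, seed=1)
        inter = max(0.0, min(hi, 1.2) - max(lo, 0.6))
        union = max(hi, 1.2) - min(lo, 0.6)
        assert inter / union >= 0.5

    def test_minimum_subjects(self):
        with pytest.raises(ValueError):
            derive_rebound_window(np.zeros((3, 50)),
                                  np.linspace(-0.5, 1.5, 50))


def test_companion_eigenvalues_shape():
    coeffs = base_coefficients(250.0)
    eig = companion_eigenvalues(coeffs)
    assert eig.shape == (36,)
    assert np.abs(eig).max() == pytest.approx(0.95, abs=1e-6)
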