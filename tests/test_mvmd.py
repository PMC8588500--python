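import numpy as np
import pytest

import emgflow as ef
from emgflow.mvmd import MvmdSettings


def _vmd_reference(x, K, alpha, tau, n_iter, omega_init):
    """Independent univariate VMD on the full two-sided spectrum.

    Straightforward textbook loop kept deliberately separate from the
    package implementation: mirror extension, full-length FFT with the
    negative-frequency half zeroed, Wiener-filter mode updates, centroid
    frequency updates, and explicit conjugate-symmetric completion for the
    inverse transform.
    """
    T = x.shape[0]
    L = T // 2
    xm = np.concatenate([x[:L][::-1], x, x[L:][::-1]])
    Tm = xm.shape[0]
    H = Tm // 2  # Nyquist index (Tm is even)
    f_plus = np.fft.fft(xm)
    f_plus[H + 1:] = 0  # keep DC..Nyquist only
    freqs = np.arange(Tm) / Tm
    omega = np.array(omega_init, dtype=float)
    u_hat = np.zeros((K, Tm), dtype=complex)
    lam = np.zeros(Tm, dtype=complex)
    sl = slice(0, H + 1)
    for _ in range(n_iter):
        for k in range(K):
            others = u_hat.sum(axis=0) - u_hat[k]
            gain = 1.0 / (1 + 2 * alpha * (freqs[sl] - omega[k]) ** 2)
            u_hat[k, sl] = (f_plus - others + lam / 2)[sl] * gain
            pw = np.abs(u_hat[k, sl]) ** 2
            if pw.sum() > 0:
                omega[k] = (freqs[sl] * pw).sum() / pw.sum()
        lam = lam + tau * (f_plus - u_hat.sum(axis=0))
    modes = np.empty((K, T))
    for k in range(K):
        full = np.zeros(Tm, dtype=complex)
        full[sl] = u_hat[k, sl]
        full[Tm - 1:H:-1] = np.conj(u_hat[k, 1:H])
        m = np.fft.ifft(full).real
        modes[k] = m[L:L + T]
    return modes, omega


class TestToneRecovery:
    def test_single_tone_is_its_own_mode(self):
        t = np.arange(1000) / 100.0
        tone = np.cos(2 * np.pi * 10 * t)
        rec = np.stack([tone, tone], axis=1)
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=1), fs=100.0)
        assert abs(mt.center_freqs[0] - 10.0) < 0.5
        err = np.linalg.norm(mt.modes[0] - rec) / np.linalg.norm(rec)
        assert err < 0.05

    def test_two_tone_mixture_separated(self, two_tone_recording):
        rec, s5, s20 = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        assert abs(mt.center_freqs[0] - 5.0) < 1.0
        assert abs(mt.center_freqs[1] - 20.0) < 1.0
        for k, src in ((0, s5), (1, s20)):
            for c in range(2):
                r = np.corrcoef(mt.modes[k][:, c], src)[0, 1]
                assert r > 0.95

    def test_zero_signal_gives_zero_modes(self):
        mt = ef.mvmd_decompose(np.zeros((100, 3)), MvmdSettings(K=2), fs=100.0)
        assert not mt.modes.any()
        assert not mt.residual.any()

    def test_nonfinite_input_rejected(self):
        x = np.zeros((100, 2))
        x[5, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ef.mvmd_decompose(x, MvmdSettings(K=1), fs=100.0)


class TestReconstruction:
    def test_modes_plus_residual_reproduce_input(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        np.testing.assert_allclose(ef.reconstruct(mt), rec.signal, atol=1e-9)

    def test_mode_sum_close_to_input(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        err = np.linalg.norm(mt.modes.sum(axis=0) - rec.signal) / np.linalg.norm(rec.signal)
        assert err < 0.05

    def test_dual_ascent_tightens_residual(self, two_tone_recording):
        # with tau > 0 the dual variable drives the mode sum toward exact
        # feasibility, shrinking the residual left to absorb
        rec, _, _ = two_tone_recording
        r0 = np.linalg.norm(ef.mvmd_decompose(rec, MvmdSettings(K=2, tau=0.0)).residual)
        r1 = np.linalg.norm(ef.mvmd_decompose(rec, MvmdSettings(K=2, tau=0.5)).residual)
        assert r1 < r0


class TestLowFrequencyMode:
    def test_returns_first_sorted_mode(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        assert (mt.center_freqs == np.sort(mt.center_freqs)).all()
        np.testing.assert_array_equal(ef.low_frequency_mode(mt), mt.modes[0])

    def test_tracks_the_slow_component(self, two_tone_recording):
        rec, s5, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        low = ef.low_frequency_mode(mt)
        assert np.corrcoef(low[:, 0], s5)[0, 1] > 0.95

    def test_single_mode_case(self):
        t = np.arange(200) / 100.0
        x = np.cos(2 * np.pi * 7 * t)[:, None]
        mt = ef.mvmd_decompose(x, MvmdSettings(K=1), fs=100.0)
        np.testing.assert_array_equal(ef.low_frequency_mode(mt), mt.modes[0])


class TestModeSpectrum:
    def test_peak_at_center_frequency(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        freqs, power = ef.mode_spectrum(mt, 1, 0)
        assert abs(freqs[np.argmax(power)] - mt.center_freqs[1]) < 0.5

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((256, 2))
        mt = ef.mvmd_decompose(x, MvmdSettings(K=3, alpha=200.0), fs=100.0)
        _, power = ef.mode_spectrum(mt, 0, 1)
        energy = np.sum(mt.modes[0, :, 1] ** 2)
        assert abs(power.sum() - energy) <= 1e-6 * max(energy, 1e-30)

    def test_index_out_of_range(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        mt = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        with pytest.raises(IndexError):
            ef.mode_spectrum(mt, 5, 0)


class TestAlgorithmInvariants:
    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(400) / 100.0
        x = np.stack([np.cos(2 * np.pi * 8 * t) * (1 + 0.3 * i) +
                      0.5 * np.cos(2 * np.pi * 25 * t + i) +
                      0.05 * rng.standard_normal(400) for i in range(4)], axis=1)
        perm = np.array([2, 0, 3, 1])
        s = MvmdSettings(K=2)
        mt = ef.mvmd_decompose(x, s, fs=100.0)
        mtp = ef.mvmd_decompose(x[:, perm], s, fs=100.0)
        np.testing.assert_allclose(mtp.center_freqs, mt.center_freqs, atol=1e-8)
        np.testing.assert_allclose(mtp.modes, mt.modes[:, :, perm], atol=1e-8)

    def test_amplitude_linearity(self, two_tone_recording):
        rec, _, _ = two_tone_recording
        s = MvmdSettings(K=2)
        mt1 = ef.mvmd_decompose(rec.signal, s, fs=100.0)
        mt3 = ef.mvmd_decompose(3.0 * rec.signal, s, fs=100.0)
        np.testing.assert_allclose(mt3.center_freqs, mt1.center_freqs, atol=1e-6)
        np.testing.assert_allclose(mt3.modes, 3.0 * mt1.modes, atol=1e-6)

    def test_bandwidth_objective_decreases_over_run(self, two_tone_recording):
        # evaluate the variational objective (bandwidth of demodulated
        # analytic modes) at the first iterate and at convergence
        import scipy.signal

        def objective(modes, omegas, fs):
            total = 0.0
            for k in range(modes.shape[0]):
                for c in range(modes.shape[2]):
                    analytic = scipy.signal.hilbert(modes[k, :, c])
                    t = np.arange(modes.shape[1]) / fs
                    demod = analytic * np.exp(-2j * np.pi * omegas[k] * t)
                    total += np.sum(np.abs(np.diff(demod)) ** 2)
            return total

        rec, _, _ = two_tone_recording
        first = ef.mvmd_decompose(rec, MvmdSettings(K=2, max_iter=1))
        final = ef.mvmd_decompose(rec, MvmdSettings(K=2))
        obj_first = objective(first.modes, first.center_freqs, rec.fs)
        obj_final = objective(final.modes, final.center_freqs, rec.fs)
        assert obj_final <= obj_first * (1 + 1e-9)

    def test_single_channel_matches_reference_vmd(self):
        t = np.arange(256) / 100.0
        x = np.cos(2 * np.pi * 6 * t) + 0.8 * np.cos(2 * np.pi * 22 * t)
        K, alpha, tau, n_iter = 2, 2000.0, 0.0, 60
        omega0 = 0.5 * np.arange(K) / K
        ref_modes, ref_omega = _vmd_reference(x, K, alpha, tau, n_iter, omega0)
        mt = ef.mvmd_decompose(x[:, None],
                               MvmdSettings(K=K, alpha=alpha, tau=tau,
                                            max_iter=n_iter, tol=1e-30), fs=100.0)
        order = np.argsort(ref_omega)
        np.testing.assert_allclose(mt.center_freqs, ref_omega[order] * 100.0, atol=1e-6)
        assert np.max(np.abs(mt.modes[:, :, 0] - ref_modes[order])) < 1e-6

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2K"):
            ef.mvmd_decompose(np.zeros((5, 2)), MvmdSettings(K=4), fs=100.0)


class TestTransformer:
    def test_transform_shape_and_sorting(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 64, 2))
        tr = ef.MVMD(K=3, alpha=500.0, fs=100.0, max_iter=50, tol=1e-6)
        modes = tr.transform(X)
        assert modes.shape == (3, 64, 2, 3)
        # stacking matches a per-window decomposition, sorted ascending
        mt0 = tr.decompose(X[0])
        assert (np.diff(mt0.center_freqs) >= 0).all()
        np.testing.assert_allclose(modes[0], np.moveaxis(mt0.modes, 0, -1))

    def test_get_set_params_roundtrip(self):
        tr = ef.MVMD()
        tr.set_params(K=6, alpha=100.0)
        assert tr.get_params()["K"] == 6
        with pytest.raises(ValueError):
            tr.set_params(bogus=1)
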