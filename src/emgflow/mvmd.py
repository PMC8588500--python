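"""Multivariate variational mode decomposition (MVMD).

MVMD extracts K narrow-band multivariate oscillations u_k(t), one set of
channel components per mode with a single shared center frequency ω_k,
such that the modes sum (approximately, exactly when the dual step τ > 0
is driven to feasibility) to the input x(t), while the total bandwidth of
the modes — measured as the H¹-norm of the baseband-demodulated analytic
signals — is minimal.

The problem is solved in the one-sided frequency domain by ADMM with
Gauss–Seidel mode sweeps:

* mode update: a Wiener filter centred on the current ω_k,
  û_k,c ← (x̂_c − Σ_{i<k} û_i,c^{new} − Σ_{i>k} û_i,c^{old} + λ̂_c/2)
           / (1 + 2α(ω − ω_k)²), per channel c;
* center-frequency update: the joint spectral centroid over all channels,
  ω_k ← Σ_c ∫ ω|û_k,c|² dω / Σ_c ∫ |û_k,c|² dω;
* dual ascent: λ̂_c ← λ̂_c + τ(x̂_c − Σ_k û_k,c);

iterated until Σ_k Σ_c ‖û_k^{n+1} − û_k^n‖² / ‖û_k^n‖² < tol.

The signal is mirror-extended by half its length on each side before the
FFT to suppress boundary artifacts; the central portion is returned.
Frequencies are computed on the normalized axis ω ∈ [0, 0.5] and reported
in Hz as ω·fs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MultichannelRecording

__all__ = [
    "MvmdSettings",
    "ModeTensor",
    "mvmd_decompose",
    "reconstruct",
    "low_frequency_mode",
    "mode_spectrum",
    "MVMD",
]


@dataclass
class MvmdSettings:
    """MVMD hyperparameters.

    alpha is the bandwidth penalty (larger → narrower modes); tau the dual
    ascent step (0 gives noise-robust reconstruction, the residual absorbs
    what no mode claims); tol the relative-change stopping threshold.
    """

    K: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("uniform", "octave", "random"):
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class ModeTensor:
    """MVMD output: K × n_samples × n_channels modes sorted by center frequency."""

    modes: np.ndarray            # (K, T, C)
    center_freqs: np.ndarray     # (K,), Hz
    residual: np.ndarray         # (T, C)
    n_iterations: int
    converged: bool
    fs: float


def _init_omegas(settings: MvmdSettings) -> np.ndarray:
    K = settings.K
    if settings.init == "uniform":
        return 0.5 * np.arange(K) / K
    if settings.init == "octave":
        return 0.5 / (2.0 ** np.arange(K, 0, -1))
    rng = np.random.default_rng(settings.seed)
    return np.sort(rng.uniform(0.0, 0.5, K))


def mvmd_decompose(rec: MultichannelRecording | np.ndarray,
                   settings: MvmdSettings | None = None,
                   fs: float | None = None) -> ModeTensor:
    """Decompose a multichannel signal into K joint narrow-band modes.

    Accepts a :class:`MultichannelRecording` or a (T, C) array plus ``fs``.
    """
    settings = settings or MvmdSettings()
    if isinstance(rec, MultichannelRecording):
        x, fs = rec.signal, rec.fs
    else:
        x = np.asarray(rec, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2:
            raise ValueError("expected a (T, C) array")
        if fs is None:
            raise ValueError("fs must be given when decomposing a bare array")
    if not np.isfinite(x).all():
        raise ValueError("input signal contains non-finite values")
    T, C = x.shape
    K, alpha, tau = settings.K, settings.alpha, settings.tau
    if T < 2 * K:
        raise ValueError(f"need at least 2K={2 * K} samples, got {T}")

    # mirror extension by half the length on each side
    L = T // 2
    xm = np.concatenate([x[:L][::-1], x, x[L:][::-1]], axis=0)
    Tm = xm.shape[0]
    F = np.fft.rfft(xm, axis=0)                    # (B, C) one-sided spectrum
    freqs = np.arange(F.shape[0]) / Tm             # normalized, [0, 0.5]

    omega = _init_omegas(settings).astype(float)
    u_hat = np.zeros((K,) + F.shape, dtype=complex)
    lam = np.zeros_like(F)

    n_iter, converged = 0, False
    for n_iter in range(1, settings.max_iter + 1):
        u_prev = u_hat.copy()
        sum_u = u_hat.sum(axis=0)
        for k in range(K):
            sum_others = sum_u - u_hat[k]
            gain = 1.0 / (1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2)
            u_hat[k] = (F - sum_others + lam / 2.0) * gain[:, None]
            sum_u = sum_others + u_hat[k]
            power = np.abs(u_hat[k]) ** 2
            den = power.sum()
            if den > 0:
                omega[k] = float((freqs[:, None] * power).sum() / den)
        if tau > 0:
            lam = lam + tau * (F - sum_u)
        num = np.abs(u_hat - u_prev) ** 2
        den_k = (np.abs(u_prev) ** 2).sum(axis=(1, 2))
        num_k = num.sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(den_k > 0, num_k / den_k, np.where(num_k > 0, np.inf, 0.0))
        if ratios.sum() < settings.tol:
            converged = True
            break

    order = np.argsort(omega)
    modes = np.empty((K, T, C))
    for out_k, k in enumerate(order):
        um = np.fft.irfft(u_hat[k], n=Tm, axis=0)
        modes[out_k] = um[L:L + T]
    residual = x - modes.sum(axis=0)
    return ModeTensor(modes=modes, center_freqs=omega[order] * fs, residual=residual,
                      n_iterations=n_iter, converged=converged, fs=fs)


def reconstruct(mt: ModeTensor) -> np.ndarray:
    """Sum of modes plus residual — recovers the original signal."""
    return mt.modes.sum(axis=0) + mt.residual


def low_frequency_mode(mt: ModeTensor) -> np.ndarray:
    """The mode with the smallest center frequency (the "modified EMG")."""
    return mt.modes[int(np.argmin(mt.center_freqs))]


def mode_spectrum(mt: ModeTensor, k: int, c: int) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of mode k, channel c.

    Normalized so the power sums to the mode's time-domain energy Σ u².
    """
    K, T, C = mt.modes.shape
    if not (0 <= k < K and 0 <= c < C):
        raise IndexError(f"mode {k} / channel {c} out of range ({K} modes, {C} channels)")
    u = mt.modes[k, :, c]
    X = np.fft.rfft(u)
    power = np.abs(X) ** 2 / T
    # double the interior bins of the one-sided spectrum (Parseval)
    power[1:] *= 2.0
    if T % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(T, d=1.0 / mt.fs)
    return freqs, power


class MVMD:
    """Window-batch MVMD transformer (scikit-learn style).

    ``transform`` maps an array of windows (n_windows, T, C) to the stacked
    mode tensor (n_windows, T, C, K), modes sorted by ascending center
    frequency along the last axis — the image stack the fine-stage CNN
    consumes. ``fit`` is stateless and present for pipeline compatibility.
    """

    def __init__(self, K: int = 4, alpha: float = 2000.0, tau: float = 0.0,
                 tol: float = 1e-7, max_iter: int = 500, init: str = "uniform",
                 fs: float = 100.0, random_state: int = 0):
        self.K = K
        self.alpha = alpha
        self.tau = tau
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.fs = fs
        self.random_state = random_state

    def _settings(self) -> MvmdSettings:
        return MvmdSettings(K=self.K, alpha=self.alpha, tau=self.tau, tol=self.tol,
                            max_iter=self.max_iter, init=self.init,
                            seed=self.random_state)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("K", "alpha", "tau", "tol", "max_iter", "init", "fs", "random_state")}

    def set_params(self, **params) -> "MVMD":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MVMD":
        return self

    def decompose(self, x: np.ndarray) -> ModeTensor:
        return mvmd_decompose(np.asarray(x), self._settings(), fs=self.fs)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected windows of shape (n_windows, T, C)")
        n, T, C = X.shape
        out = np.empty((n, T, C, self.K))
        settings = self._settings()
        for i in range(n):
            mt = mvmd_decompose(X[i], settings, fs=self.fs)
            out[i] = np.moveaxis(mt.modes, 0, -1)
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
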