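"""Classical time-domain sEMG features for the coarse (force-level) stage.

Eight per-channel features over a window x₁..x_L:

RMS   √(Σx²/L)                       MAV   Σ|x|/L
WL    Σ|xᵢ−xᵢ₋₁|                     VAR   Σx²/(L−1)  (no mean subtraction)
DASDV √(Σ(xᵢ₊₁−xᵢ)²/(L−1))           ZC    #{i : xᵢxᵢ₊₁<0 ∧ |xᵢ−xᵢ₊₁|>T}
SSC   #{interior i strict local extremum with both neighbor gaps ≥ T}
WA    #{i : |xᵢ−xᵢ₊₁|>T}

VAR is deliberately the uncentered second moment — the printed convention
for this feature family; pass ``centered=True`` to :func:`var_raw` for the
textbook sample variance. The default selection RMS+MAV+DASDV is the
combination that best tracks contraction force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import SegmentWindow

__all__ = [
    "FeatureVector",
    "rms", "mav", "wl", "var_raw", "dasdv", "zc", "ssc", "wa",
    "FEATURE_NAMES", "DEFAULT_FEATURES",
    "extract_features",
    "TimeDomainFeatures",
]

#: Default detection threshold for the count features, on z-scored signals.
DEFAULT_THRESHOLD = 0.01

DEFAULT_FEATURES = ("RMS", "MAV", "DASDV")


def _vec(x, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} samples, got {x.shape[0]}")
    return x


def rms(x) -> float:
    x = _vec(x)
    return float(np.sqrt(np.mean(x ** 2)))


def mav(x) -> float:
    x = _vec(x)
    return float(np.mean(np.abs(x)))


def wl(x) -> float:
    x = _vec(x)
    return float(np.sum(np.abs(np.diff(x))))


def var_raw(x, centered: bool = False) -> float:
    x = _vec(x)
    if centered:
        x = x - x.mean()
    return float(np.sum(x ** 2) / (x.shape[0] - 1))


def dasdv(x) -> float:
    x = _vec(x)
    return float(np.sqrt(np.sum(np.diff(x) ** 2) / (x.shape[0] - 1)))


def zc(x, T: float = DEFAULT_THRESHOLD) -> int:
    x = _vec(x)
    if T < 0:
        raise ValueError("threshold must be >= 0")
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) > T
    return int(np.count_nonzero(sign_change & big_enough))


def ssc(x, T: float = DEFAULT_THRESHOLD) -> int:
    x = _vec(x, min_len=3)
    if T < 0:
        raise ValueError("threshold must be >= 0")
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    extremum = ((cur > prev) & (cur > nxt)) | ((cur < prev) & (cur < nxt))
    gaps = (np.abs(cur - prev) >= T) & (np.abs(cur - nxt) >= T)
    return int(np.count_nonzero(extremum & gaps))


def wa(x, T: float = DEFAULT_THRESHOLD) -> int:
    x = _vec(x)
    if T < 0:
        raise ValueError("threshold must be >= 0")
    return int(np.count_nonzero(np.abs(np.diff(x)) > T))


_SCALAR = {"RMS": rms, "MAV": mav, "WL": wl, "VAR": var_raw, "DASDV": dasdv}
_THRESHOLDED = {"ZC": zc, "SSC": ssc, "WA": wa}
FEATURE_NAMES = tuple(_SCALAR) + tuple(_THRESHOLDED)


@dataclass
class FeatureVector:
    """Per-window feature values, channel-major in declared feature order."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    label: int
    superclass: int
    start_sample: int = -1


def _compute(name: str, x: np.ndarray, T: float) -> float:
    if name in _SCALAR:
        return _SCALAR[name](x)
    return float(_THRESHOLDED[name](x, T))


def extract_features(win: SegmentWindow, selected=DEFAULT_FEATURES,
                     T: float = DEFAULT_THRESHOLD) -> FeatureVector:
    """Compute the selected features per channel, concatenated channel-major.

    Output order: [ch0_feat0, ch0_feat1, ..., ch1_feat0, ...].
    """
    selected = tuple(selected)
    unknown = [s for s in selected if s not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s) {unknown}; known: {FEATURE_NAMES}")
    data = np.asarray(win.data, dtype=float)
    values = np.array([_compute(name, data[:, c], T)
                       for c in range(data.shape[1]) for name in selected])
    return FeatureVector(values=values, feature_names=selected, label=win.label,
                         superclass=win.superclass, start_sample=win.start_sample)


class TimeDomainFeatures:
    """Window-batch feature transformer (scikit-learn style).

    ``transform`` maps windows (n_windows, L, C) to a feature matrix
    (n_windows, C·n_features), channel-major. Stateless.
    """

    def __init__(self, features=DEFAULT_FEATURES, threshold: float = DEFAULT_THRESHOLD):
        self.features = tuple(features)
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"features": self.features, "threshold": self.threshold}

    def set_params(self, **params) -> "TimeDomainFeatures":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, tuple(v) if k == "features" else v)
        return self

    def fit(self, X=None, y=None) -> "TimeDomainFeatures":
        unknown = [s for s in self.features if s not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature name(s) {unknown}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected windows of shape (n_windows, L, C)")
        n, L, C = X.shape
        out = np.empty((n, C * len(self.features)))
        for i in range(n):
            out[i] = [_compute(name, X[i, :, c], self.threshold)
                      for c in range(C) for name in self.features]
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def feature_names_out(self, n_channels: int) -> list[str]:
        return [f"ch{c}_{name}" for c in range(n_channels) for name in self.features]
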