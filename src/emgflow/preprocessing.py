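"""Normalization, Teager-energy activity detection, relabeling, segmentation.

The label stream that ships with cue-driven sEMG recordings lags the actual
muscle activity by the subject's reaction time. The relabeling procedure
locates activity directly in the signal: the discrete Teager–Kaiser energy
ψ[x](n) = x(n)² − x(n−1)·x(n+1) is averaged across channels, smoothed with a
moving window, and thresholded with a duration-hysteresis rule; samples
inside detected intervals keep the majority gesture id of the original
labels, everything else becomes rest.

All intervals are 0-based and half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MultichannelRecording

__all__ = [
    "SegmentWindow",
    "ActivityIntervals",
    "DegenerateInputError",
    "zscore",
    "teager_energy",
    "smoothed_channel_energy",
    "auto_threshold",
    "detect_active",
    "relabel",
    "segment",
    "TeagerRelabeler",
]


class DegenerateInputError(ValueError):
    """Input violates a numerical precondition (constant channel, too short)."""


@dataclass
class SegmentWindow:
    """A fixed-length window cut from a single-label run."""

    data: np.ndarray  # (window_samples, n_channels)
    label: int
    superclass: int
    start_sample: int
    source: str = ""


@dataclass
class ActivityIntervals:
    """Detected activity intervals plus the detector settings that produced them."""

    intervals: list[tuple[int, int]] = field(default_factory=list)
    threshold_used: float = 0.0
    smooth_N: int = 1


def zscore(rec: MultichannelRecording) -> MultichannelRecording:
    """Standardize each channel to zero mean, unit variance."""
    sd = rec.signal.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(f"constant channel(s) {bad.tolist()} cannot be z-scored")
    signal = (rec.signal - rec.signal.mean(axis=0)) / sd
    return MultichannelRecording(signal=signal, fs=rec.fs, labels=rec.labels.copy(),
                                 subject_id=rec.subject_id, exercise_id=rec.exercise_id)


def teager_energy(x: np.ndarray) -> np.ndarray:
    """Discrete Teager–Kaiser energy ψ(n) = x(n)² − x(n−1)·x(n+1).

    Defined on interior samples; the two boundary samples replicate the
    nearest interior value so the output length equals the input length.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] < 3:
        raise DegenerateInputError("teager_energy needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def smoothed_channel_energy(rec: MultichannelRecording, N: int) -> np.ndarray:
    """Channel-averaged Teager energy, moving-averaged over N samples.

    The smoothing window is causal (ends at t) and shortens at the left
    edge, so E(t) is an average of at most N past values.
    """
    if N < 1:
        raise DegenerateInputError("smoothing width N must be >= 1")
    if N > rec.n_samples:
        raise DegenerateInputError(f"N={N} exceeds recording length {rec.n_samples}")
    e = np.stack([teager_energy(rec.signal[:, c]) for c in range(rec.n_channels)], axis=1)
    e_avg = e.mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(e_avg)])
    t = np.arange(e_avg.shape[0])
    lo = np.maximum(0, t - N + 1)
    return (csum[t + 1] - csum[lo]) / (t + 1 - lo)


def auto_threshold(energy: np.ndarray) -> float:
    """Rest-baseline threshold: mean + 3·SD of the lowest-energy half.

    In a cue-paced protocol rest occupies at least half the duty cycle, so
    the lower half of the smoothed-energy distribution is rest-dominated;
    its spread (unlike a bottom decile's) covers the correlated
    fluctuations the moving average induces.
    """
    energy = np.asarray(energy, dtype=float)
    rest = np.sort(energy)[: max(1, energy.shape[0] // 2)]
    thr = float(rest.mean() + 3.0 * rest.std())
    if thr <= 0:
        thr = max(float(energy.max()) * 1e-6, np.finfo(float).tiny)
    return thr


def detect_active(energy: np.ndarray, threshold: float,
                  min_dur: int) -> ActivityIntervals:
    """Threshold the energy trace with duration hysteresis.

    An active interval opens at the first sample of a run of at least
    ``min_dur`` consecutive supra-threshold samples and closes at the first
    sample of a run of at least ``min_dur`` sub-threshold samples; intervals
    shorter than ``min_dur`` are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_dur < 1:
        raise ValueError("min_dur must be >= 1")
    supra = np.asarray(energy, dtype=float) > threshold
    n = supra.shape[0]
    # run-length encode, then walk runs with the hysteresis rule
    change = np.flatnonzero(np.diff(supra.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    intervals: list[tuple[int, int]] = []
    open_at: int | None = None
    for s, e in zip(starts, ends):
        if supra[s]:
            if open_at is None and e - s >= min_dur:
                open_at = s
        else:
            if open_at is not None and e - s >= min_dur:
                intervals.append((open_at, s))
                open_at = None
    if open_at is not None and n - open_at >= min_dur:
        intervals.append((open_at, n))
    intervals = [(s, e) for s, e in intervals if e - s >= min_dur]
    return ActivityIntervals(intervals=intervals, threshold_used=float(threshold),
                             smooth_N=min_dur)


def _majority_nonzero(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels[labels > 0], return_counts=True)
    if vals.size == 0:
        return 0
    return int(vals[np.argmax(counts)])


def relabel(rec: MultichannelRecording, acts: ActivityIntervals) -> MultichannelRecording:
    """Replace the label stream with the detected activity intervals.

    Samples inside each interval take the majority nonzero original label
    overlapping it; samples outside become rest (0). An interval overlapping
    no nonzero label borrows the label of the nearest labeled run (with a
    warning).
    """
    n = rec.n_samples
    new_labels = np.zeros(n, dtype=np.int64)
    nonzero = np.flatnonzero(rec.labels > 0)
    for s, e in acts.intervals:
        if not (0 <= s < e <= n):
            raise ValueError(f"interval ({s},{e}) outside recording bounds [0,{n})")
        gid = _majority_nonzero(rec.labels[s:e])
        if gid == 0:
            if nonzero.size == 0:
                warnings.warn(f"interval ({s},{e}) overlaps no labeled samples and the "
                              "recording has none; left as rest")
                continue
            mid = (s + e) // 2
            nearest = nonzero[np.argmin(np.abs(nonzero - mid))]
            gid = int(rec.labels[nearest])
            warnings.warn(f"interval ({s},{e}) overlaps no labeled samples; "
                          f"borrowing nearest label {gid}")
        new_labels[s:e] = gid
    return MultichannelRecording(signal=rec.signal.copy(), fs=rec.fs, labels=new_labels,
                                 subject_id=rec.subject_id, exercise_id=rec.exercise_id)


def segment(rec: MultichannelRecording, window_ms: float,
            superclass_map: dict[int, int] | None = None) -> list[SegmentWindow]:
    """Cut fixed, non-overlapping windows from runs of identical nonzero label.

    Windowing restarts at every label-run boundary, so no window ever
    straddles two labels; trailing partial windows are dropped.
    """
    ws = int(round(window_ms * rec.fs / 1000.0))
    if ws < 1:
        raise ValueError("window shorter than one sample")
    superclass_map = superclass_map or {}
    labels = rec.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.shape[0]]])
    windows: list[SegmentWindow] = []
    for s, e in zip(starts, ends):
        gid = int(labels[s])
        if gid == 0:
            continue
        for w0 in range(s, e - ws + 1, ws):
            windows.append(SegmentWindow(
                data=rec.signal[w0:w0 + ws],
                label=gid,
                superclass=superclass_map.get(gid, 0),
                start_sample=w0,
                source=rec.subject_id,
            ))
    return windows


class TeagerRelabeler:
    """Recording-level transformer: detect activity and rewrite the labels.

    Parameters mirror the detector: ``smooth_n`` (None → 0.1 s of samples),
    ``threshold`` (None → rest-baseline estimate from the lowest-energy
    decile), ``min_active_ms`` for the duration hysteresis.
    """

    def __init__(self, smooth_n: int | None = None, threshold: float | None = None,
                 min_active_ms: float = 50.0):
        self.smooth_n = smooth_n
        self.threshold = threshold
        self.min_active_ms = min_active_ms

    def get_params(self, deep: bool = True) -> dict:
        return {"smooth_n": self.smooth_n, "threshold": self.threshold,
                "min_active_ms": self.min_active_ms}

    def set_params(self, **params) -> "TeagerRelabeler":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def detect(self, rec: MultichannelRecording) -> ActivityIntervals:
        n = self.smooth_n if self.smooth_n is not None else max(1, int(round(0.1 * rec.fs)))
        energy = smoothed_channel_energy(rec, n)
        thr = self.threshold if self.threshold is not None else auto_threshold(energy)
        min_dur = max(1, int(round(self.min_active_ms * rec.fs / 1000.0)))
        return detect_active(energy, thr, min_dur)

    def transform(self, rec: MultichannelRecording) -> MultichannelRecording:
        self.intervals_ = self.detect(rec)
        return relabel(rec, self.intervals_)
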