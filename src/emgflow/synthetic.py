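"""Surrogate multichannel sEMG generator.

Real surface EMG during a contraction is well approximated, for the purposes
of this framework, by amplitude-modulated band-limited Gaussian noise: an
interference pattern whose envelope follows force. Each gesture archetype
contributes

* a stochastic carrier — white noise band-passed to the archetype's
  passband, modulated by a trapezoidal envelope (ramp up / plateau / ramp
  down), scaled per channel by ``channel_weights`` and globally by
  ``force_scale``; and
* a small deterministic low-frequency component (the envelope itself),
  which is the repeatable across-repetition content that a low-frequency
  oscillatory mode can recover — the analogue of the slow, force-related
  drift present in real recordings.

Superclasses are separable by ``force_scale`` (grasping/functional > wrist
> finger); gestures within a superclass are separable by their channel
topography. Emitted labels are jittered uniformly around the true activity
intervals to emulate the subject's response-time misalignment with the
stimulus cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .io import ConfigError, MultichannelRecording

__all__ = [
    "GestureArchetype",
    "SimulationPlan",
    "simulate_recording",
    "true_intervals",
    "benchmark_plan",
    "benchmark_superclass_map",
]

#: Fraction of the active duration spent ramping up (and down).
RAMP_FRACTION = 0.1

#: Gain of the deterministic envelope-shaped low-frequency component,
#: relative to the unit-variance stochastic carrier.
LF_GAIN = 0.3


@dataclass
class GestureArchetype:
    """One gesture's generative signature."""

    gesture_id: int
    superclass_id: int
    channel_weights: np.ndarray
    force_scale: float
    band: tuple[float, float] = (15.0, 45.0)

    def __post_init__(self) -> None:
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if self.gesture_id <= 0:
            raise ConfigError("gesture_id must be positive")
        if self.force_scale <= 0:
            raise ConfigError("force_scale must be positive")
        if (self.channel_weights < 0).any() or not (self.channel_weights > 0).any():
            raise ConfigError("channel_weights must be nonnegative with at least one positive")
        if not self.band[0] < self.band[1]:
            raise ConfigError("band must satisfy low < high")


@dataclass
class SimulationPlan:
    """Layout and noise model for one simulated recording.

    The recording alternates rest and activity: a leading rest segment, then
    for every repetition each archetype's active segment followed by rest.
    """

    archetypes: list[GestureArchetype] = field(default_factory=list)
    n_repetitions: int = 1
    active_ms: float = 1000.0
    rest_ms: float = 1000.0
    label_jitter_ms: float = 0.0
    noise_sd: float = 0.05
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if self.active_ms <= 0:
            raise ConfigError("active_ms must be positive")
        if self.rest_ms < 0:
            raise ConfigError("rest_ms must be nonnegative")
        if self.label_jitter_ms < 0:
            raise ConfigError("label_jitter_ms must be nonnegative")
        for a in self.archetypes:
            if a.band[1] >= self.fs / 2:
                raise ConfigError(
                    f"gesture {a.gesture_id}: band high {a.band[1]} Hz is at or above "
                    f"Nyquist ({self.fs / 2} Hz)"
                )

    @property
    def n_channels(self) -> int:
        if not self.archetypes:
            return 1
        return int(self.archetypes[0].channel_weights.shape[0])

    def _samples(self, ms: float) -> int:
        return int(round(ms * self.fs / 1000.0))

    @property
    def n_samples(self) -> int:
        rest = self._samples(self.rest_ms)
        active = self._samples(self.active_ms)
        n_runs = self.n_repetitions * len(self.archetypes)
        return max(1, rest + n_runs * (active + rest))


def true_intervals(plan: SimulationPlan) -> list[tuple[int, int, int]]:
    """Ground-truth activity intervals (start, end, gesture_id), pre-jitter.

    Half-open, 0-based, sorted, non-overlapping.
    """
    rest = plan._samples(plan.rest_ms)
    active = plan._samples(plan.active_ms)
    out: list[tuple[int, int, int]] = []
    cursor = rest
    for _ in range(plan.n_repetitions):
        for arch in plan.archetypes:
            out.append((cursor, cursor + active, arch.gesture_id))
            cursor += active + rest
    return out


def _trapezoid(n: int) -> np.ndarray:
    """Trapezoidal envelope of length n with 10% ramps."""
    ramp = max(1, int(round(RAMP_FRACTION * n)))
    env = np.ones(n)
    up = np.linspace(0.0, 1.0, ramp + 1)[1:]
    env[:ramp] = up
    env[n - ramp:] = up[::-1]
    return env


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                       fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    pad = max(32, int(fs))  # absorb filter transients outside the segment
    white = rng.standard_normal(n + 2 * pad)
    x = scipy.signal.sosfiltfilt(sos, white)[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(plan: SimulationPlan) -> MultichannelRecording:
    """Generate a recording from a plan. Same plan + seed → identical output."""
    rng = np.random.default_rng(plan.seed)
    n, c = plan.n_samples, plan.n_channels
    signal = (rng.standard_normal((n, c)) * plan.noise_sd
              if plan.noise_sd > 0 else np.zeros((n, c)))
    labels = np.zeros(n, dtype=np.int64)
    jitter = plan._samples(plan.label_jitter_ms)
    arch_by_id = {a.gesture_id: a for a in plan.archetypes}

    for start, end, gid in true_intervals(plan):
        arch = arch_by_id[gid]
        seg = end - start
        env = _trapezoid(seg)
        for ch in range(c):
            w = arch.channel_weights[ch]
            if w == 0:
                continue
            carrier = _bandlimited_noise(rng, seg, arch.band, plan.fs)
            signal[start:end, ch] += arch.force_scale * w * env * (carrier + LF_GAIN)
        if jitter > 0:
            on = start + rng.integers(-jitter, jitter + 1)
            off = end + rng.integers(-jitter, jitter + 1)
        else:
            on, off = start, end
        on = max(0, on)
        off = min(n, max(off, on + 1))
        labels[on:off] = gid

    return MultichannelRecording(signal=signal, fs=plan.fs, labels=labels,
                                 subject_id="synthetic", exercise_id="sim")


# ---------------------------------------------------------------------------
# The reference benchmark: 3 superclasses × 4 gestures.
# ---------------------------------------------------------------------------

#: Superclass force levels: finger < wrist < functional/grasping.
_FORCE_BY_SUPERCLASS = {1: 1.0, 2: 2.0, 3: 4.0}


def _bump_weights(n_channels: int, center: float, width: float = 1.2,
                  floor: float = 0.15) -> np.ndarray:
    ch = np.arange(n_channels, dtype=float)
    return floor + np.exp(-0.5 * ((ch - center) / width) ** 2)


def benchmark_plan(n_repetitions: int = 40, n_channels: int = 10, fs: float = 100.0,
                   seed: int = 0, label_jitter_ms: float = 200.0) -> SimulationPlan:
    """The package's reference synthetic task: 12 gestures in 3 superclasses.

    Gestures 1–4 are "finger" (force 1), 5–8 "wrist" (force 2), 9–12
    "functional" (force 4). Within a superclass the four gestures share the
    force level and differ only in which channels they activate, so the
    coarse stage must rely on force and the fine stage on topography —
    mirroring the physiological rationale of the two-stage design.
    """
    centers = np.linspace(0.8, n_channels - 1.8, 4)
    archetypes = []
    for sc in (1, 2, 3):
        for j in range(4):
            gid = (sc - 1) * 4 + j + 1
            archetypes.append(GestureArchetype(
                gesture_id=gid,
                superclass_id=sc,
                channel_weights=_bump_weights(n_channels, centers[j]),
                force_scale=_FORCE_BY_SUPERCLASS[sc],
                band=(15.0, 45.0),
            ))
    return SimulationPlan(
        archetypes=archetypes,
        n_repetitions=n_repetitions,
        active_ms=1000.0,
        rest_ms=1000.0,
        label_jitter_ms=label_jitter_ms,
        noise_sd=0.05,
        fs=fs,
        seed=seed,
    )


def benchmark_superclass_map(plan: SimulationPlan) -> dict[int, int]:
    """Gesture id → superclass id map for a plan."""
    return {a.gesture_id: a.superclass_id for a in plan.archetypes}
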