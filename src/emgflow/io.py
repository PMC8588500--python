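"""Reading and writing multichannel sEMG recordings and run configuration.

Recordings travel as :class:`MultichannelRecording`: a samples × channels
signal matrix with a sampling rate and a per-sample integer label stream
(0 = rest, >0 = gesture id). Ninapro-style MAT-files are read with
:func:`read_ninapro_mat`; the internal interchange format is HDF5 for
signals and labels (inspectable, language-neutral) and CSV for feature
tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import scipy.io
import yaml

__all__ = [
    "MultichannelRecording",
    "RunConfig",
    "FormatError",
    "IntegrityError",
    "ConfigError",
    "read_ninapro_mat",
    "write_recording",
    "read_recording",
    "load_config",
]


class FormatError(ValueError):
    """A file does not contain the fields the reader expects."""


class IntegrityError(ValueError):
    """Signal and labels disagree in shape or content."""


class ConfigError(ValueError):
    """A run configuration violates its invariants or has unknown keys."""


@dataclass
class MultichannelRecording:
    """A samples × channels signal with sampling rate and per-sample labels.

    Parameters
    ----------
    signal : ndarray of shape (n_samples, n_channels)
        Signal values (arbitrary units; volts if from hardware).
    fs : float
        Sampling rate in Hz.
    labels : ndarray of shape (n_samples,)
        Integer gesture labels, 0 for rest, >0 for a gesture id.
    subject_id, exercise_id : str
        Opaque provenance identifiers.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    subject_id: str = ""
    exercise_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.signal.ndim != 2:
            raise IntegrityError("signal must be a 2-D samples × channels matrix")
        if self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise IntegrityError("recording needs at least one sample and one channel")
        if self.fs <= 0:
            raise IntegrityError("sampling rate must be positive")
        if self.labels.shape[0] != self.signal.shape[0]:
            raise IntegrityError(
                f"labels length {self.labels.shape[0]} does not match "
                f"n_samples {self.signal.shape[0]}"
            )
        if (self.labels < 0).any():
            raise IntegrityError("labels must be nonnegative (0 = rest)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


#: RunConfig keys that are plain scalars checked positive.
_POSITIVE_FIELDS = ("window_ms", "alpha", "tol")


@dataclass
class RunConfig:
    """End-to-end run configuration with the framework's defaults.

    ``window_ms`` is the fixed non-overlapping segmentation window (400 ms),
    ``n_modes`` the MVMD mode count K (4), ``alpha`` the MVMD bandwidth
    penalty, ``tau`` the dual-ascent step, ``tol`` the MVMD convergence
    threshold, and the ``teager_*`` fields parameterize activity detection.
    ``superclass_map`` maps every gesture id to its coarse superclass.
    """

    window_ms: float = 400.0
    n_modes: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    teager_smooth_N: int | None = None  # None -> 0.1 s worth of samples
    teager_threshold: float | None = None  # None -> rest-baseline estimate
    min_active_ms: float = 50.0
    seed: int = 0
    superclass_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_modes < 1:
            raise ConfigError("n_modes (K) must be >= 1")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if self.min_active_ms <= 0:
            raise ConfigError("min_active_ms must be positive")
        if self.teager_smooth_N is not None and self.teager_smooth_N < 1:
            raise ConfigError("teager_smooth_N must be >= 1")
        self.superclass_map = {int(k): int(v) for k, v in self.superclass_map.items()}


# Ninapro DB1 MAT field names, resolved case-insensitively. "restimulus"
# (the dataset's own movement-aligned relabeling) is preferred when present.
_SIGNAL_KEYS = ("emg",)
_LABEL_KEYS = ("restimulus", "stimulus")


def _find_field(mat: Mapping[str, np.ndarray], names: tuple[str, ...]) -> np.ndarray | None:
    lower = {k.lower(): v for k, v in mat.items() if not k.startswith("__")}
    for name in names:
        if name in lower:
            return lower[name]
    return None


def read_ninapro_mat(
    path: str | Path,
    fs: float = 100.0,
    signal_field: str | None = None,
    label_field: str | None = None,
) -> MultichannelRecording:
    """Read a Ninapro-style MAT-file (v5) into a recording.

    DB1 files carry a 10-channel ``emg`` matrix sampled at 100 Hz and the
    ``stimulus``/``restimulus`` label vectors; field names are matched
    case-insensitively and can be overridden via ``signal_field`` /
    ``label_field``.
    """
    mat = scipy.io.loadmat(str(path))
    sig_names = (signal_field.lower(),) if signal_field else _SIGNAL_KEYS
    lab_names = (label_field.lower(),) if label_field else _LABEL_KEYS
    signal = _find_field(mat, sig_names)
    if signal is None:
        raise FormatError(f"MAT-file {path} lacks a signal field (looked for {sig_names})")
    labels = _find_field(mat, lab_names)
    if labels is None:
        raise FormatError(f"MAT-file {path} lacks a label field (looked for {lab_names})")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    labels = np.asarray(labels).ravel()
    if signal.shape[0] != labels.shape[0]:
        raise IntegrityError(
            f"signal has {signal.shape[0]} samples but labels have {labels.shape[0]}"
        )
    subject = str(_find_field(mat, ("subject",)).ravel()[0]) if _find_field(mat, ("subject",)) is not None else ""
    exercise = str(_find_field(mat, ("exercise",)).ravel()[0]) if _find_field(mat, ("exercise",)) is not None else ""
    return MultichannelRecording(signal=signal, fs=fs, labels=labels,
                                 subject_id=subject, exercise_id=exercise)


def write_recording(rec: MultichannelRecording, path: str | Path) -> None:
    """Write a recording to HDF5 (datasets /signal, /labels; attrs fs, subject)."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("labels", data=rec.labels)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["subject"] = rec.subject_id
        f.attrs["exercise"] = rec.exercise_id


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(str(path), "r") as f:
        if "signal" not in f or "labels" not in f:
            raise FormatError(f"{path} is not an emgflow recording (missing /signal or /labels)")
        return MultichannelRecording(
            signal=f["signal"][()],
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            subject_id=str(f.attrs.get("subject", "")),
            exercise_id=str(f.attrs.get("exercise", "")),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of RunConfig fields")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # wrong value shapes
        raise ConfigError(str(exc)) from exc
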