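"""Two-stage gesture recognition pipeline and its evaluation harness.

Data flow per window: time-domain features → stage-1 superclass decision →
that superclass's CNN on the window's MVMD mode stack → final gesture id.
The stage-1 decision is carried forward even when wrong (no abstention),
so the predicted gesture always belongs to the predicted superclass.

Evaluation is stratified tenfold cross-validation over shuffled windows;
the report aggregates a confusion matrix, per-fold accuracies, and
separate stage-1 and end-to-end accuracies.

The class-consistency analysis quantifies why the low-frequency mode (the
"modified EMG") is the better CNN input: across repetitions of the same
gesture, the lowest-frequency MVMD mode correlates more strongly than the
raw signal, because the repeatable slow force-related content survives the
decomposition while the stochastic interference pattern does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .classifiers import GestureTaxonomy, SeparableCNNClassifier, Stage1Classifier
from .features import DEFAULT_FEATURES, TimeDomainFeatures
from .mvmd import MVMD, MvmdSettings, low_frequency_mode, mvmd_decompose

__all__ = [
    "EvalReport",
    "TwoStageClassifier",
    "confusion_counts",
    "crossvalidate",
    "class_consistency_correlation",
]


@dataclass
class EvalReport:
    """Aggregated cross-validation results."""

    confusion: np.ndarray                 # (n_classes, n_classes) counts
    class_ids: np.ndarray                 # row/column labels
    confusion_normalized: np.ndarray      # row-normalized copy
    per_fold_accuracy: np.ndarray
    stage1_accuracy: float
    end_to_end_accuracy: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_ids": self.class_ids.tolist(),
            "per_fold_accuracy": self.per_fold_accuracy.tolist(),
            "stage1_accuracy": self.stage1_accuracy,
            "end_to_end_accuracy": self.end_to_end_accuracy,
        }


def confusion_counts(y_true, y_pred, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Count matrix (true class i → predicted j) for labels 1..n_classes.

    Returns the integer matrix and its row-normalized copy (zero rows stay
    zero).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        bad = v[(v < 1) | (v > n_classes)]
        if bad.size:
            raise ValueError(f"{name} labels outside [1, {n_classes}]: {np.unique(bad).tolist()}")
    labels = np.arange(1, n_classes + 1)
    mat = _sk_confusion(y_true, y_pred, labels=labels)
    row_sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, mat / row_sums, 0.0)
    return mat, norm


class TwoStageClassifier:
    """Coarse-to-fine gesture classifier over segmented windows.

    ``fit``/``predict`` take raw windows of shape (n, window_samples,
    n_channels) and gesture labels; the MVMD mode stack can be passed
    precomputed (``modes=``, shape (n, T, C, K)) to avoid recomputation
    across cross-validation folds.
    """

    def __init__(self, taxonomy: GestureTaxonomy, fs: float = 100.0,
                 K: int = 4, alpha: float = 2000.0, mvmd_tol: float = 1e-6,
                 mvmd_max_iter: int = 80,
                 features=DEFAULT_FEATURES, feature_threshold: float = 0.01,
                 stage1_method: str = "svm",
                 conv_filters: tuple[int, int, int] = (32, 64, 128),
                 dense_units: int = 128, epochs: int = 100, batch_size: int = 256,
                 lr: float = 1e-3, patience: int = 10,
                 random_state: int | None = None):
        self.taxonomy = taxonomy
        self.fs = fs
        self.K = K
        self.alpha = alpha
        self.mvmd_tol = mvmd_tol
        self.mvmd_max_iter = mvmd_max_iter
        self.features = tuple(features)
        self.feature_threshold = feature_threshold
        self.stage1_method = stage1_method
        self.conv_filters = tuple(conv_filters)
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.random_state = random_state

    _param_names = ("taxonomy", "fs", "K", "alpha", "mvmd_tol", "mvmd_max_iter",
                    "features", "feature_threshold", "stage1_method", "conv_filters",
                    "dense_units", "epochs", "batch_size", "lr", "patience",
                    "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "TwoStageClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _mvmd(self) -> MVMD:
        return MVMD(K=self.K, alpha=self.alpha, tol=self.mvmd_tol,
                    max_iter=self.mvmd_max_iter, fs=self.fs)

    def compute_modes(self, X: np.ndarray) -> np.ndarray:
        """(n, T, C) windows → (n, T, C, K) sorted mode stacks."""
        return self._mvmd().transform(np.asarray(X, dtype=float))

    def _features(self, X: np.ndarray) -> np.ndarray:
        return TimeDomainFeatures(self.features, self.feature_threshold).transform(X)

    def fit(self, X: np.ndarray, y: np.ndarray,
            modes: np.ndarray | None = None) -> "TwoStageClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        sc_map = self.taxonomy.superclass_map
        unknown = set(np.unique(y).tolist()) - set(sc_map)
        if unknown:
            raise ValueError(f"gesture ids {sorted(unknown)} missing from the taxonomy")
        y_sc = np.array([sc_map[g] for g in y.tolist()])

        feats = self._features(X)
        self.stage1_ = Stage1Classifier(method=self.stage1_method,
                                        random_state=self.random_state).fit(feats, y_sc)
        if modes is None:
            modes = self.compute_modes(X)

        self.stage2_: dict[int, SeparableCNNClassifier] = {}
        for sc, _name, members in self.taxonomy.superclasses:
            mask = y_sc == sc
            if not mask.any():
                raise ValueError(f"no training windows for superclass {sc}")
            clf = SeparableCNNClassifier(
                conv_filters=self.conv_filters, dense_units=self.dense_units,
                epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
                patience=self.patience, classes=np.asarray(members),
                random_state=self.random_state)
            clf.fit(modes[mask], y[mask])
            self.stage2_[sc] = clf
        return self

    def predict(self, X: np.ndarray, modes: np.ndarray | None = None,
                return_superclass: bool = False):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "stage1_"):
            raise RuntimeError("model is not fitted")
        feats = self._features(X)
        sc_pred = self.stage1_.predict(feats)
        if modes is None:
            modes = self.compute_modes(X)
        y_pred = np.zeros(X.shape[0], dtype=np.int64)
        for sc in np.unique(sc_pred):
            if sc not in self.stage2_:
                raise RuntimeError(f"no trained stage-2 model for superclass {sc}")
            mask = sc_pred == sc
            y_pred[mask] = self.stage2_[sc].predict(modes[mask])
        if return_superclass:
            return y_pred, sc_pred
        return y_pred

    def score(self, X: np.ndarray, y: np.ndarray,
              modes: np.ndarray | None = None) -> float:
        return float(np.mean(self.predict(X, modes=modes) == np.asarray(y)))


def crossvalidate(X: np.ndarray, y: np.ndarray, model: TwoStageClassifier,
                  folds: int = 10, seed: int = 0,
                  modes: np.ndarray | None = None) -> EvalReport:
    """Stratified k-fold cross-validation of the two-stage pipeline.

    Windows are shuffled with ``seed`` and split into ``folds`` parts,
    stratified by gesture so every class appears in every training set; each
    window is tested exactly once. MVMD mode stacks are computed once and
    shared across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < folds]
    if thin.size:
        raise ValueError(f"class(es) {thin.tolist()} have fewer than {folds} windows; "
                         "cannot stratify")
    if modes is None:
        modes = model.compute_modes(X)
    sc_map = model.taxonomy.superclass_map
    y_sc = np.array([sc_map[g] for g in y.tolist()])
    n_gestures = int(max(sc_map))  # confusion matrix spans gesture ids 1..max
    y_pred_all = np.zeros_like(y)
    sc_pred_all = np.zeros_like(y)
    fold_acc = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(X, y):
        model.fit(X[tr_idx], y[tr_idx], modes=modes[tr_idx])
        yp, scp = model.predict(X[te_idx], modes=modes[te_idx], return_superclass=True)
        y_pred_all[te_idx] = yp
        sc_pred_all[te_idx] = scp
        fold_acc.append(float(np.mean(yp == y[te_idx])))

    mat, norm = confusion_counts(y, y_pred_all, n_gestures)
    return EvalReport(
        confusion=mat,
        class_ids=np.arange(1, n_gestures + 1),
        confusion_normalized=norm,
        per_fold_accuracy=np.array(fold_acc),
        stage1_accuracy=float(np.mean(sc_pred_all == y_sc)),
        end_to_end_accuracy=float(np.mean(y_pred_all == y)),
    )


def windows_by_class(windows, one_per_run: bool = True) -> dict[int, np.ndarray]:
    """Group :class:`~emgflow.preprocessing.SegmentWindow` objects by gesture.

    With ``one_per_run`` only the first window of each labeled run is kept,
    so every array row is one repetition — the unit the class-consistency
    analysis compares.
    """
    grouped: dict[int, list] = {}
    for w in sorted(windows, key=lambda w: w.start_sample):
        grouped.setdefault(w.label, []).append(w)
    out: dict[int, np.ndarray] = {}
    for g, ws in grouped.items():
        if one_per_run:
            # consecutive windows of one run are exactly one window apart;
            # a larger gap marks the next repetition
            length = ws[0].data.shape[0]
            kept, prev = [ws[0]], ws[0]
            for w in ws[1:]:
                if w.start_sample - prev.start_sample > length:
                    kept.append(w)
                prev = w
            ws = kept
        out[g] = np.stack([w.data for w in ws])
    return out


def _pairwise_channel_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over channels of Pearson r between two (T, C) windows."""
    vals = []
    for c in range(a.shape[1]):
        xa, xb = a[:, c], b[:, c]
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            continue
        vals.append(float(np.corrcoef(xa, xb)[0, 1]))
    return float(np.mean(vals)) if vals else 0.0


def class_consistency_correlation(windows_by_class: dict[int, np.ndarray],
                                  use_modified: bool = False,
                                  settings: MvmdSettings | None = None,
                                  fs: float = 100.0) -> dict[int, float]:
    """Mean pairwise across-repetition Pearson correlation per gesture class.

    For each class, every unordered pair of repetition windows contributes
    the channel-averaged Pearson correlation; the class value is the mean
    over pairs. With ``use_modified`` the correlation is computed on each
    window's lowest-center-frequency MVMD mode instead of the raw signal.
    Classes with fewer than 2 repetitions are skipped with a warning.
    """
    settings = settings or MvmdSettings()
    out: dict[int, float] = {}
    for cls, wins in windows_by_class.items():
        wins = np.asarray(wins, dtype=float)
        if wins.shape[0] < 2:
            warnings.warn(f"class {cls} has a single repetition; skipped")
            continue
        if use_modified:
            wins = np.stack([low_frequency_mode(mvmd_decompose(w, settings, fs=fs))
                             for w in wins])
        pair_vals = [_pairwise_channel_corr(wins[i], wins[j])
                     for i, j in combinations(range(wins.shape[0]), 2)]
        out[cls] = float(np.mean(pair_vals))
    return out
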