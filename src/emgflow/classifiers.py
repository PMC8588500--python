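"""Stage-1 (coarse superclass) and stage-2 (fine gesture) classifiers.

Stage 1 maps per-window time-domain feature vectors to a superclass with a
lightweight classical model (SVM with RBF kernel by default, penalty 18,
gamma "scale"). Stage 2 is a compact convolutional network on the
per-window MVMD mode stack, with every convolution implemented as a
depthwise-separable layer. The defining bookkeeping of the architecture —
exact trainable-parameter counts for the separable stack and its standard
counterfactual — is exposed by :func:`build_scnn` and the closed-form
counters:

    standard   k·k·c·N + N
    separable  k·k·c + c·N + N          (no depthwise bias)
    ratio      k²cN / (k²c + cN)        (bias-free standard/separable)

The reference stack (on a 30×10 single-channel input, 12 classes):
Conv(32) → Dropout → Conv(64) → MaxPool → Conv(128) → ZeroPad(width 1) →
MaxPool → Flatten → Dropout → Dense(128) → Softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._nn import (Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2D, Network,
                  ReLU, SeparableConv2D, ZeroPadWidth, cross_entropy)

__all__ = [
    "GestureTaxonomy",
    "ScnnSpec",
    "LayerParamCount",
    "SpecError",
    "count_separable_params",
    "count_standard_params",
    "param_ratio",
    "build_scnn",
    "Stage1Classifier",
    "train_stage1",
    "SeparableCNNClassifier",
    "train_stage2",
]


class SpecError(ValueError):
    """An architecture spec is inconsistent (spatial collapse, class mismatch)."""


@dataclass
class GestureTaxonomy:
    """Partition of gesture ids into coarse superclasses."""

    superclasses: list[tuple[int, str, tuple[int, ...]]]

    def __post_init__(self) -> None:
        if len(self.superclasses) < 2:
            raise ValueError("a taxonomy needs at least 2 superclasses")
        seen: set[int] = set()
        for _, _, members in self.superclasses:
            if not members:
                raise ValueError("every superclass must have members")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"gesture ids {sorted(overlap)} appear in two superclasses")
            seen |= set(members)

    @property
    def k(self) -> int:
        return len(self.superclasses)

    @property
    def superclass_map(self) -> dict[int, int]:
        return {g: sc for sc, _, members in self.superclasses for g in members}

    def members(self, superclass_id: int) -> tuple[int, ...]:
        for sc, _, m in self.superclasses:
            if sc == superclass_id:
                return m
        raise KeyError(f"no superclass {superclass_id}")

    @classmethod
    def from_map(cls, superclass_map: dict[int, int]) -> "GestureTaxonomy":
        groups: dict[int, list[int]] = {}
        for g, sc in sorted(superclass_map.items()):
            groups.setdefault(sc, []).append(g)
        return cls([(sc, f"superclass_{sc}", tuple(m)) for sc, m in sorted(groups.items())])


@dataclass
class ScnnSpec:
    """Architecture of the fine-stage network."""

    input_shape: tuple[int, int, int] = (30, 10, 1)   # (height, width, depth)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    dropout_rate: float = 0.5
    dense_units: int = 128
    n_classes: int = 12
    separable: bool = True
    zero_pad: int = 1

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SpecError("n_classes must be >= 2")
        if min(self.input_shape) < 1:
            raise SpecError("input dimensions must be >= 1")


@dataclass
class LayerParamCount:
    layer_name: str
    params_standard: int
    params_separable: int


def count_standard_params(k: int, c: int, N: int) -> int:
    """Trainable parameters of a standard k×k conv, c in-channels, N filters."""
    return k * k * c * N + N


def count_separable_params(k: int, c: int, N: int) -> int:
    """Depthwise k×k (no bias) + pointwise 1×1 with biases."""
    return k * k * c + c * N + N


def param_ratio(k: int, c: int, N: int) -> float:
    """Bias-free standard/separable parameter ratio k²cN / (k²c + cN)."""
    return (k * k * c * N) / (k * k * c + c * N)


def _trace_shapes(spec: ScnnSpec) -> tuple[int, int, int]:
    """Spatial dimensions after the conv/pool/pad stack; raises on collapse."""
    h, w, _ = spec.input_shape
    h, w = h // 2, w // 2                      # pool after Conv2
    if h < 1 or w < 1:
        raise SpecError(f"spatial collapse after first pool: {h}×{w}")
    w = w + 2 * spec.zero_pad                  # width padding after Conv3
    h, w = h // 2, w // 2                      # final pool
    if h < 1 or w < 1:
        raise SpecError(f"spatial collapse after final pool: {h}×{w}")
    return h, w, spec.conv_filters[2]


def build_scnn(spec: ScnnSpec,
               rng: np.random.Generator | None = None
               ) -> tuple[Network, list[LayerParamCount]]:
    """Assemble the network and account its parameters layer by layer.

    Returns the assembled network (separable or standard convolutions, per
    ``spec.separable``) and per-layer counts for both variants; dense and
    softmax layers are identical between variants.
    """
    rng = rng or np.random.default_rng()
    k = spec.kernel
    f1, f2, f3 = spec.conv_filters
    depth = spec.input_shape[2]
    h, w, c_last = _trace_shapes(spec)
    flat = h * w * c_last

    conv = SeparableConv2D if spec.separable else Conv2D
    layers = [
        conv(depth, f1, k, rng=rng), ReLU(),
        Dropout(spec.dropout_rate, rng=rng),
        conv(f1, f2, k, rng=rng), ReLU(),
        MaxPool2D(),
        conv(f2, f3, k, rng=rng), ReLU(),
        ZeroPadWidth(spec.zero_pad),
        MaxPool2D(),
        Flatten(),
        Dropout(spec.dropout_rate, rng=rng),
        Dense(flat, spec.dense_units, rng=rng), ReLU(),
        Dense(spec.dense_units, spec.n_classes, rng=rng),
    ]
    counts = [
        LayerParamCount("Input", 0, 0),
        LayerParamCount("Convolution1", count_standard_params(k, depth, f1),
                        count_separable_params(k, depth, f1)),
        LayerParamCount("Convolution2", count_standard_params(k, f1, f2),
                        count_separable_params(k, f1, f2)),
        LayerParamCount("Convolution3", count_standard_params(k, f2, f3),
                        count_separable_params(k, f2, f3)),
        LayerParamCount("Dense", flat * spec.dense_units + spec.dense_units,
                        flat * spec.dense_units + spec.dense_units),
        LayerParamCount("Softmax", spec.dense_units * spec.n_classes + spec.n_classes,
                        spec.dense_units * spec.n_classes + spec.n_classes),
    ]
    return Network(layers), counts


class Stage1Classifier:
    """Coarse superclass classifier over time-domain feature vectors.

    ``method`` selects the underlying model: svm (RBF kernel, C=18,
    gamma="scale"), rf, dt, knn, nb, or lda.
    """

    def __init__(self, method: str = "svm", C: float = 18.0,
                 random_state: int | None = None):
        self.method = method
        self.C = C
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "C": self.C, "random_state": self.random_state}

    def set_params(self, **params) -> "Stage1Classifier":
        valid = self.get_params()
        for key, v in params.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, v)
        return self

    def _make(self):
        makers = {
            "svm": lambda: SVC(kernel="rbf", C=self.C, gamma="scale",
                               random_state=self.random_state),
            "rf": lambda: RandomForestClassifier(random_state=self.random_state),
            "dt": lambda: DecisionTreeClassifier(random_state=self.random_state),
            "knn": lambda: KNeighborsClassifier(),
            "nb": lambda: GaussianNB(),
            "lda": lambda: LinearDiscriminantAnalysis(),
        }
        if self.method not in makers:
            raise ValueError(f"unknown method {self.method!r}; choose from {sorted(makers)}")
        return makers[self.method]()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Stage1Classifier":
        X, y = np.asarray(X, dtype=float), np.asarray(y)
        if np.unique(y).shape[0] < 2:
            raise ValueError("stage-1 training needs at least 2 superclasses present")
        self.model_ = self._make().fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=float))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_stage1(X: np.ndarray, y_superclass: np.ndarray, method: str = "svm",
                 random_state: int | None = None) -> Stage1Classifier:
    """Fit a stage-1 model on feature vectors and superclass labels."""
    return Stage1Classifier(method=method, random_state=random_state).fit(X, y_superclass)


class SeparableCNNClassifier:
    """Fine-stage gesture classifier: a depthwise-separable CNN on mode stacks.

    Expects inputs of shape (n, height, width, depth) — window samples ×
    channels × decomposition modes. Training uses Adam (batch 256, up to
    ``epochs`` epochs) with early stopping on a held-out validation split
    (patience epochs without improvement; best weights restored).
    """

    def __init__(self, conv_filters: tuple[int, int, int] = (32, 64, 128),
                 dense_units: int = 128, kernel: int = 3, dropout_rate: float = 0.5,
                 separable: bool = True, batch_size: int = 256, epochs: int = 100,
                 lr: float = 1e-3, patience: int = 10, val_fraction: float = 0.1,
                 classes: np.ndarray | None = None, random_state: int | None = None):
        self.conv_filters = tuple(conv_filters)
        self.dense_units = dense_units
        self.kernel = kernel
        self.dropout_rate = dropout_rate
        self.separable = separable
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr = lr
        self.patience = patience
        self.val_fraction = val_fraction
        self.classes = classes
        self.random_state = random_state

    _param_names = ("conv_filters", "dense_units", "kernel", "dropout_rate",
                    "separable", "batch_size", "epochs", "lr", "patience",
                    "val_fraction", "classes", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SeparableCNNClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SeparableCNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError("expected images of shape (n, H, W, D)")
        if not np.isfinite(X).all():
            raise ValueError("images contain non-finite values")
        observed = np.unique(y)
        if self.classes is not None:
            self.classes_ = np.asarray(self.classes)
            missing = set(observed) - set(self.classes_.tolist())
            if missing:
                raise SpecError(f"labels {sorted(missing)} not in the declared class set")
        else:
            self.classes_ = observed
        if self.classes_.shape[0] < 2:
            raise SpecError("need at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_.tolist())}
        yi = np.array([class_index[v] for v in y.tolist()])

        rng = np.random.default_rng(self.random_state)
        spec = ScnnSpec(input_shape=X.shape[1:], conv_filters=self.conv_filters,
                        kernel=self.kernel, dropout_rate=self.dropout_rate,
                        dense_units=self.dense_units, n_classes=len(self.classes_),
                        separable=self.separable)
        self.spec_ = spec
        self.model_, self.layer_params_ = build_scnn(spec, rng=rng)

        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = int(round(self.val_fraction * n))
        use_val = 0 < n_val < n
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if not use_val:
            tr_idx = perm
        Xtr, ytr = X[tr_idx], yi[tr_idx]
        Xval, yval = (X[val_idx], yi[val_idx]) if use_val else (Xtr, ytr)

        opt = Adam(self.model_.params, lr=self.lr)
        best_loss, best_weights, since_best = np.inf, None, 0
        self.history_ = {"loss": [], "val_loss": [], "accuracy": [], "val_accuracy": []}
        for _epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            losses, n_correct = [], 0
            for b0 in range(0, len(Xtr), self.batch_size):
                idx = order[b0:b0 + self.batch_size]
                loss, nc = self.model_.loss_and_backward(Xtr[idx], ytr[idx])
                losses.append(loss)
                n_correct += nc
                opt.step(self.model_.grads)
            pv = self._proba_batched(Xval)
            val_loss = cross_entropy(pv, yval)
            self.history_["loss"].append(float(np.mean(losses)))
            self.history_["val_loss"].append(val_loss)
            self.history_["accuracy"].append(n_correct / len(Xtr))
            self.history_["val_accuracy"].append(float(np.mean(pv.argmax(1) == yval)))
            if val_loss < best_loss - 1e-6:
                best_loss, best_weights, since_best = val_loss, self.model_.get_weights(), 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_weights is not None:
            self.model_.set_weights(best_weights)
        return self

    def _proba_batched(self, X: np.ndarray) -> np.ndarray:
        out = []
        for b0 in range(0, X.shape[0], self.batch_size):
            out.append(self.model_.predict_proba(X[b0:b0 + self.batch_size]))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._proba_batched(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_stage2(images: np.ndarray, labels: np.ndarray,
                 spec: ScnnSpec | None = None, **train_cfg) -> SeparableCNNClassifier:
    """Fit a fine-stage CNN on mode-stacked window images."""
    kwargs = dict(train_cfg)
    if spec is not None:
        kwargs.setdefault("conv_filters", spec.conv_filters)
        kwargs.setdefault("dense_units", spec.dense_units)
        kwargs.setdefault("kernel", spec.kernel)
        kwargs.setdefault("dropout_rate", spec.dropout_rate)
        kwargs.setdefault("separable", spec.separable)
    return SeparableCNNClassifier(**kwargs).fit(images, labels)
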