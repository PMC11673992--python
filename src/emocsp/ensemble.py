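"""Stacked convolutional-autoencoder ensemble classifier.

Three identical convolutional autoencoders are trained (unsupervised,
reconstruction MSE, Adam, 10 epochs by default) on the same CSP-projected
epochs; the only free variable between branches is the weight
initialisation seed.  Each branch's bottleneck tensor is flattened, the
three feature vectors are concatenated, and a fully-connected softmax head
(128 ReLU units, then 3 outputs) is trained on top with the branches frozen
— a stacking scheme with the dense network as meta-learner.

For a 750 x 19 epoch the encoder trace is
(750,19,16) -> (375,10,16) -> (375,10,8) -> (188,5,8); the bottleneck
flattens to 7520 features and the three branches concatenate to 22560.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .nn import (Adam, Conv2D, Dense, MaxPool2D, Sequential, Upsample2D,
                 mse_loss, softmax, softmax_xent)


# ---------------------------------------------------------------------------
# Split plan

@dataclass
class SplitPlan:
    """Train/validation/test split description.

    ``granularity`` 'window' shuffles individual epochs (reproduces the
    usual protocol but is optimistic when windows overlap); 'block' splits
    each (subject, class) run of consecutive windows into contiguous
    chunks, avoiding train/test leakage through overlap.  Sizes are
    floor(f_train*n) and floor(f_val*n); the test set takes the remainder.
    """

    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    granularity: str = "block"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_train = int(np.floor(self.train * n))
        n_val = int(np.floor(self.val * n))
        return n_train, n_val, n - n_train - n_val

    def split_indices(self, labels: np.ndarray,
                      subject_ids: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = len(labels)
        if self.granularity == "window":
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            n_tr, n_va, _ = self.sizes(n)
            return (perm[:n_tr], perm[n_tr:n_tr + n_va],
                    perm[n_tr + n_va:])
        if self.granularity in ("block", "subject"):
            labels = np.asarray(labels)
            if subject_ids is None or self.granularity == "block":
                subj = (np.zeros(n, dtype=int) if subject_ids is None
                        else np.asarray(subject_ids))
            else:
                subj = np.asarray(subject_ids)
            tr, va, te = [], [], []
            for s in np.unique(subj):
                for c in np.unique(labels):
                    idx = np.where((subj == s) & (labels == c))[0]
                    n_tr, n_va, _ = self.sizes(len(idx))
                    tr.append(idx[:n_tr])
                    va.append(idx[n_tr:n_tr + n_va])
                    te.append(idx[n_tr + n_va:])
            return (np.concatenate(tr), np.concatenate(va),
                    np.concatenate(te))
        raise ValueError(f"unknown granularity {self.granularity!r}")


# ---------------------------------------------------------------------------
# Autoencoder branch

class ConvAutoencoder:
    """One convolutional autoencoder branch (NumPy backend).

    Encoder: conv 3x3x16 -> pool -> conv 2x2x8 -> pool (bottleneck).
    Decoder: conv 2x2x8 -> upsample -> conv 3x3x16 -> upsample ->
    conv 3x3x1 sigmoid.  All convolutions stride-1 'same'; pooling uses
    ceiling division, so any input not smaller than 4 x 4 round-trips to
    its own shape.
    """

    N_ENCODER_LAYERS = 4

    def __init__(self, input_shape: tuple[int, int],
                 activation: str = "relu", seed: int = 0):
        h, w = input_shape
        if h < 4 or w < 4:
            raise ValueError("input must be at least 4 x 4")
        self.input_shape = (h, w)
        self.activation = activation
        self.seed = seed
        rng = np.random.default_rng(seed)
        h2, w2 = -(-h // 2), -(-w // 2)
        h4, w4 = -(-h2 // 2), -(-w2 // 2)
        self.bottleneck_shape = (h4, w4, 8)
        self.flatten_len = h4 * w4 * 8
        self.net = Sequential([
            Conv2D(3, 3, 1, 16, activation, rng),
            MaxPool2D(),
            Conv2D(2, 2, 16, 8, activation, rng),
            MaxPool2D(),
            Conv2D(2, 2, 8, 8, activation, rng),
            Upsample2D((h2, w2)),
            Conv2D(3, 3, 8, 16, activation, rng),
            Upsample2D((h, w)),
            Conv2D(3, 3, 16, 1, "sigmoid", rng),
        ])

    def shape_trace(self) -> list[tuple[int, ...]]:
        """Layer-by-layer output shapes, starting from the input."""
        shape = (*self.input_shape, 1)
        trace = [shape]
        for layer in self.net.layers:
            shape = layer.out_shape(shape)
            trace.append(shape)
        return trace

    def encode(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Bottleneck features, flattened per epoch."""
        x = _as_nhwc(x)
        out = np.empty((len(x), self.flatten_len), dtype=nn.DTYPE)
        for i in range(0, len(x), batch_size):
            z = self.net.forward_until(x[i:i + batch_size],
                                       self.N_ENCODER_LAYERS)
            out[i:i + len(z)] = z.reshape(len(z), -1)
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(_as_nhwc(x), train=False)


def _as_nhwc(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.ndim == 3:
        x = x[..., None]
    return x


def build_autoencoder(input_shape: tuple[int, int],
                      activation: str = "relu",
                      seed: int = 0) -> ConvAutoencoder:
    return ConvAutoencoder(input_shape, activation, seed)


def train_autoencoder(branch: ConvAutoencoder, X: np.ndarray,
                      n_epochs: int = 10, learning_rate: float = 1e-3,
                      batch_size: int = 32, seed: int = 0) -> list[float]:
    """Train one branch on reconstruction MSE; returns per-epoch mean loss.

    Inputs are expected in [0, 1] (sigmoid output layer).  A zero-epoch
    call leaves the initial weights untouched.
    """
    X = _as_nhwc(X)
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = Adam(branch.net.layers, lr=learning_rate)
    history: list[float] = []
    for _ in range(n_epochs):
        order = rng.permutation(len(X))
        losses, weights = [], []
        for i in range(0, len(X), batch_size):
            xb = X[order[i:i + batch_size]]
            y = branch.net.forward(xb, train=True)
            loss, grad = mse_loss(y, xb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf reconstruction loss at epoch {len(history)}; "
                    f"check input scaling and learning rate")
            branch.net.backward(grad)
            opt.step()
            losses.append(loss)
            weights.append(len(xb))
        history.append(float(np.average(losses, weights=weights)))
    return history


def encode_and_concat(branches: list[ConvAutoencoder],
                      X: np.ndarray) -> np.ndarray:
    """Flatten each branch's bottleneck and concatenate in branch order."""
    feats = [b.encode(X) for b in branches]
    lens = {f.shape[1] for f in feats}
    if len(lens) != 1:
        raise ValueError(f"branches disagree on feature length: {lens}")
    return np.concatenate(feats, axis=1)


# ---------------------------------------------------------------------------
# Dense softmax head

class DenseHead:
    """128-unit ReLU layer into a 3-way softmax (meta-learner)."""

    def __init__(self, n_in: int, n_classes: int, n_hidden: int = 128,
                 activation: str = "relu", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = Sequential([
            Dense(n_in, n_hidden, activation, rng),
            Dense(n_hidden, n_classes, "linear", rng),
        ])
        self.n_classes = n_classes

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        logits = self.net.forward(F.astype(nn.DTYPE), train=False)
        return softmax(logits.astype(np.float64))


def train_head(head: DenseHead, F: np.ndarray, y_idx: np.ndarray,
               n_epochs: int = 10, learning_rate: float = 1e-3,
               batch_size: int = 32, seed: int = 0,
               weight_decay: float = 1e-2,
               validation: tuple[np.ndarray, np.ndarray] | None = None
               ) -> dict[str, list[float]]:
    """Cross-entropy training of the head on frozen branch features.

    The stacked feature dimension dwarfs the sample count, so the head is
    L2-regularized (``weight_decay``) to keep it from interpolating the
    training set with near-zero margin.
    """
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training labels contain a single class")
    F = F.astype(nn.DTYPE)
    onehot = np.eye(head.n_classes, dtype=nn.DTYPE)[y_idx]
    rng = np.random.default_rng(seed)
    opt = Adam(head.net.layers, lr=learning_rate,
               weight_decay=weight_decay)
    hist: dict[str, list[float]] = {"loss": [], "acc": [],
                                    "val_loss": [], "val_acc": []}
    for _ in range(n_epochs):
        order = rng.permutation(len(F))
        losses, weights = [], []
        for i in range(0, len(F), batch_size):
            idx = order[i:i + batch_size]
            logits = head.net.forward(F[idx], train=True)
            loss, grad = softmax_xent(logits, onehot[idx])
            head.net.backward(grad)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        hist["loss"].append(float(np.average(losses, weights=weights)))
        pred = head.predict_proba(F).argmax(axis=1)
        hist["acc"].append(float(np.mean(pred == y_idx)))
        if validation is not None:
            Fv, yv = validation
            pv = head.predict_proba(Fv)
            lv = float(-np.mean(np.log(
                pv[np.arange(len(yv)), yv] + 1e-12)))
            hist["val_loss"].append(lv)
            hist["val_acc"].append(float(np.mean(pv.argmax(1) == yv)))
    return hist


# ---------------------------------------------------------------------------
# Estimator

class CAEStackingClassifier(ClassifierMixin, BaseEstimator):
    """Stacking ensemble of three convolutional autoencoders + dense head.

    Parameters
    ----------
    n_branches : number of autoencoder branches (3 in the reference design).
    activation : 'relu', 'leaky_relu' or 'tanh' for the hidden layers.
    n_epochs, head_epochs : Adam epochs for branches and head.
    learning_rate, batch_size : shared optimiser settings.
    scaling : 'global' scales with the min/max of the training tensor
        (learned in :meth:`fit`); 'per_epoch' rescales every epoch to
        [0, 1] independently.
    random_state : master seed; branch seeds are derived from it.

    Attributes
    ----------
    branches_ : trained :class:`ConvAutoencoder` list.
    head_ : trained :class:`DenseHead`.
    branch_history_, head_history_ : loss traces.
    """

    def __init__(self, n_branches: int = 3, activation: str = "relu",
                 n_epochs: int = 10, head_epochs: int = 30,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 head_weight_decay: float = 1e-2,
                 scaling: str = "global", random_state: int = 0):
        self.n_branches = n_branches
        self.activation = activation
        self.n_epochs = n_epochs
        self.head_epochs = head_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.head_weight_decay = head_weight_decay
        self.scaling = scaling
        self.random_state = random_state

    # -- scaling ----------------------------------------------------------
    def _fit_scaler(self, X: np.ndarray) -> None:
        self.scale_min_ = float(X.min())
        self.scale_max_ = float(X.max())
        if self.scale_max_ <= self.scale_min_:
            self.scale_max_ = self.scale_min_ + 1.0

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.scaling == "per_epoch":
            lo = X.min(axis=(1, 2), keepdims=True)
            hi = X.max(axis=(1, 2), keepdims=True)
            rng_ = np.where(hi > lo, hi - lo, 1.0)
            return ((X - lo) / rng_).astype(nn.DTYPE)
        return np.clip((X - self.scale_min_) /
                       (self.scale_max_ - self.scale_min_),
                       0.0, 1.0).astype(nn.DTYPE)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be n x T x C epochs")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self._fit_scaler(X)
        Xs = self._scale(X)
        master = np.random.default_rng(self.random_state)
        seeds = master.integers(0, 2**31 - 1, size=2 * self.n_branches + 2)
        self.branches_ = []
        self.branch_history_ = []
        for b in range(self.n_branches):
            branch = build_autoencoder(X.shape[1:3], self.activation,
                                       seed=int(seeds[2 * b]))
            hist = train_autoencoder(
                branch, Xs, n_epochs=self.n_epochs,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size, seed=int(seeds[2 * b + 1]))
            self.branches_.append(branch)
            self.branch_history_.append(hist)
        F = encode_and_concat(self.branches_, Xs)
        # standardize the stacked features on the training split; the raw
        # bottleneck activations are poorly conditioned for the dense head
        self.feat_mean_ = F.mean(axis=0)
        self.feat_std_ = F.std(axis=0) + nn.DTYPE(1e-8)
        F = (F - self.feat_mean_) / self.feat_std_
        self.head_ = DenseHead(F.shape[1], len(self.classes_),
                               seed=int(seeds[-2]))
        val = None
        if validation_data is not None:
            Xv, yv = validation_data
            Fv = encode_and_concat(self.branches_, self._scale(Xv))
            Fv = (Fv - self.feat_mean_) / self.feat_std_
            yv_idx = np.searchsorted(self.classes_, yv)
            val = (Fv, yv_idx)
        self.head_history_ = train_head(
            self.head_, F, y_idx, n_epochs=self.head_epochs,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            weight_decay=self.head_weight_decay,
            seed=int(seeds[-1]), validation=val)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "head_")
        F = encode_and_concat(self.branches_, self._scale(np.asarray(X)))
        F = (F - self.feat_mean_) / self.feat_std_
        return self.head_.predict_proba(F)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]
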