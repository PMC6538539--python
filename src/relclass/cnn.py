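"""A convolutional text classifier with multi-width filters and max-over-time pooling.

The model embeds a (short) text as an n x k matrix of word vectors, runs
parallel 1-D convolutions whose filters span the full embedding width k and
h = 3, 4, 5 adjacent token rows, producing per-filter feature maps
``A_i = f(w . x_{i:i+h-1} + b)`` for i = 1..n-h+1.  Global max pooling keeps
the single strongest activation of each map, so the pooled vector has fixed
length ``len(filter_widths) * n_maps`` whatever the text length.  The pooled
vector passes through dropout into a fully connected softmax layer trained
with categorical cross-entropy plus an l2 penalty on the softmax weights,
with validation-loss early stopping and best-epoch restoration.

Everything here is plain numpy — forward pass, backpropagation, and the
Adadelta / AdaMax / SGD update rules — wrapped in a scikit-learn estimator
(:class:`CNNTextClassifier`) so it composes with pipelines, cloning, and
model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import train_test_split

from .embeddings import DEFAULT_FIXED_LEN, EmbeddingMatrix, tokenize

__all__ = [
    "CNNTextClassifier",
    "FilterSpec",
    "feature_map",
    "global_max_pool",
    "ACTIVATIONS",
]


# ---------------------------------------------------------------------------
# activations


def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z):
    return (z > 0).astype(z.dtype)


def _leaky_relu(z, alpha=0.01):
    return np.where(z > 0, z, alpha * z)


def _leaky_relu_grad(z, alpha=0.01):
    return np.where(z > 0, 1.0, alpha).astype(z.dtype)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _sigmoid_grad(z):
    s = _sigmoid(z)
    return s * (1.0 - s)


def _tanh_grad(z):
    return 1.0 - np.tanh(z) ** 2


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "leaky_relu": (_leaky_relu, _leaky_relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "tanh": (np.tanh, _tanh_grad),
}


# ---------------------------------------------------------------------------
# convolution primitives


@dataclass
class FilterSpec:
    """One bank of convolution filters of a single region size.

    Parameters
    ----------
    h : filter height in tokens (region size), 1 <= h <= text length.
    weights : array of shape (n_maps, h, k) — one h x k filter per map.
    bias : array of shape (n_maps,).
    activation : name in :data:`ACTIVATIONS`.
    """

    h: int
    weights: np.ndarray
    bias: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 3 or self.weights.shape[0] != self.bias.shape[0]:
            raise ValueError("weights must be (n_maps, h, k) matching bias length")
        if self.weights.shape[1] != self.h or self.h < 1:
            raise ValueError("weight height must equal h >= 1")

    @property
    def n_maps(self) -> int:
        return self.weights.shape[0]


def feature_map(x, spec: FilterSpec) -> np.ndarray:
    """Convolve one embedded text with a filter bank.

    `x` is an n x k matrix (or an object with a ``.matrix``).  Returns the
    feature maps as an array of shape (n_maps, n - h + 1) with
    ``A[m, i] = f(<w_m, x[i:i+h]> + b_m)``.

    Raises a shape error when h exceeds the number of token rows n.
    """
    x = np.asarray(getattr(x, "matrix", x), dtype=np.float64)
    n, k = x.shape
    h = spec.h
    if h > n:
        raise ValueError(f"filter height h={h} exceeds input rows n={n}")
    if spec.weights.shape[2] != k:
        raise ValueError(
            f"filter width {spec.weights.shape[2]} != embedding dim {k}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, (h, k)).reshape(
        n - h + 1, h * k
    )
    z = windows @ spec.weights.reshape(spec.n_maps, h * k).T + spec.bias
    f = ACTIVATIONS[spec.activation][0]
    return f(z).T


def global_max_pool(maps: np.ndarray) -> np.ndarray:
    """Max over positions of each feature map: (n_maps, L) -> (n_maps,)."""
    maps = np.asarray(maps)
    if maps.ndim == 1:
        maps = maps[None, :]
    if maps.shape[-1] == 0:
        raise ValueError("cannot pool an empty feature map")
    return maps.max(axis=-1)


# ---------------------------------------------------------------------------
# optimizers (state per parameter tensor)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params, grads):
        for key, g in grads.items():
            params[key] -= self.lr * g


class _Adadelta:
    """Adadelta with accumulation constant rho=0.95 and eps=1e-6."""

    def __init__(self, lr=1.0, rho=0.95, eps=1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg: dict = {}
        self.ex: dict = {}

    def step(self, params, grads):
        for key, g in grads.items():
            eg = self.eg.setdefault(key, np.zeros_like(g))
            ex = self.ex.setdefault(key, np.zeros_like(g))
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt(ex + self.eps) / np.sqrt(eg + self.eps) * g
            ex *= self.rho
            ex += (1 - self.rho) * dx * dx
            params[key] += self.lr * dx


class _AdaMax:
    def __init__(self, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.u: dict = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for key, g in grads.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            u = self.u.setdefault(key, np.zeros_like(g))
            m *= self.b1
            m += (1 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            params[key] -= (self.lr / (1 - self.b1**self.t)) * m / (u + self.eps)


_OPTIMIZERS = {"sgd": _SGD, "adadelta": _Adadelta, "adamax": _AdaMax}
_DEFAULT_LR = {"sgd": 0.1, "adadelta": 1.0, "adamax": 0.002}


# ---------------------------------------------------------------------------
# the estimator


class CNNTextClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional text classifier over pre-trained word embeddings.

    Parameters
    ----------
    embedding : EmbeddingMatrix
        Vocabulary and vectors used to embed input texts.  Static by
        default; set ``trainable_embeddings=True`` to fine-tune rows.
    filter_widths : tuple of int, default (3, 4, 5)
        Region sizes of the parallel convolution branches.
    n_maps : int, default 300
        Feature maps per region size.
    activation : {"relu", "leaky_relu", "sigmoid", "tanh"}, default "relu"
    dropout : float in [0, 1), default 0.5
        Drop probability on the pooled feature vector during training.
    l2 : float, default 1e-4
        l2 penalty coefficient on the softmax layer weights.
    batch_size : int, default 32
    max_epochs : int, default 500
    optimizer : {"adadelta", "adamax", "sgd"}, default "adadelta"
    learning_rate : float or None
        None selects the optimizer's conventional default
        (adadelta 1.0, adamax 0.002, sgd 0.1).
    patience : int, default 10
        Early stopping: halt after this many epochs without a new best
        validation loss; the best epoch's parameters are restored.
    fixed_len : int, default 64
        Token rows per input; texts are truncated/zero-padded to this.
    validation_fraction : float, default 0.1
        Stratified share of the training data held out for early stopping
        when no explicit validation set is passed to :meth:`fit`.
    seed : int, default 0
        Drives initialization, batch shuffling and dropout; two fits with
        identical parameters and data produce identical histories.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    filters_ : list of fitted :class:`FilterSpec`, one per width.
    softmax_weights_, softmax_bias_ : the fully connected output layer.
    history_ : list of dicts with per-epoch ``train_loss`` / ``val_loss``.
    best_epoch_, best_val_loss_ : the restored early-stopping optimum.
    """

    def __init__(
        self,
        embedding: EmbeddingMatrix | None = None,
        filter_widths: Sequence[int] = (3, 4, 5),
        n_maps: int = 300,
        activation: str = "relu",
        dropout: float = 0.5,
        l2: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 500,
        optimizer: str = "adadelta",
        learning_rate: float | None = None,
        patience: int = 10,
        fixed_len: int = DEFAULT_FIXED_LEN,
        validation_fraction: float = 0.1,
        trainable_embeddings: bool = False,
        seed: int = 0,
    ):
        self.embedding = embedding
        self.filter_widths = filter_widths
        self.n_maps = n_maps
        self.activation = activation
        self.dropout = dropout
        self.l2 = l2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.patience = patience
        self.fixed_len = fixed_len
        self.validation_fraction = validation_fraction
        self.trainable_embeddings = trainable_embeddings
        self.seed = seed

    # -- input handling ----------------------------------------------------

    def _check_params(self):
        if self.embedding is None:
            raise ValueError("an EmbeddingMatrix must be supplied via `embedding`")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        for h in self.filter_widths:
            if not 1 <= h <= self.fixed_len:
                raise ValueError(
                    f"filter width {h} outside 1..fixed_len={self.fixed_len}"
                )

    def _index_texts(self, X) -> np.ndarray:
        """Texts -> (N, fixed_len) rows into the internal embedding table.

        The table is the embedding matrix plus rows appended for OOV tokens
        (per the matrix's policy) and a final all-zero padding row.
        """
        idx = np.full((len(X), self.fixed_len), self._pad_index, dtype=np.int64)
        for r, item in enumerate(X):
            text = getattr(item, "text", item)
            if not isinstance(text, str):
                raise TypeError(f"expected text input, got {type(text).__name__}")
            tokens = tokenize(text)[: self.fixed_len]
            for c, tok in enumerate(tokens):
                idx[r, c] = self._token_index(tok)
        return idx

    def _token_index(self, token: str) -> int:
        emb = self.embedding
        i = emb.vocabulary.get(token)
        if i is not None:
            return i
        if emb.oov_policy == "zero":
            return self._pad_index
        i = self._oov_index.get(token)
        if i is None:
            vec = emb.vector(token)  # seeded, cached on the matrix
            self._extra_rows.append(np.asarray(vec, dtype=np.float64))
            i = self._table_rows
            self._table_rows += 1
            self._oov_index[token] = i
        return i

    # -- forward / backward ------------------------------------------------

    def _forward(self, idx, train_mask=None):
        """Forward pass for a batch of index rows; returns probs + cache."""
        E = self._params["E"]
        X = E[idx]  # (B, n, k)
        B = idx.shape[0]
        f, _ = ACTIVATIONS[self.activation]
        pooled_parts, cache_parts = [], []
        for h in self.filter_widths:
            W = self._params[f"W{h}"]  # (n_maps, h*k)
            b = self._params[f"b{h}"]
            win = self._win_idx[h]  # (P, h)
            # (B, P, h, k) -> (B, P, h*k)
            Xw = X[:, win, :].reshape(B, win.shape[0], -1)
            Z = Xw @ W.T + b  # (B, P, n_maps)
            A = f(Z)
            arg = A.argmax(axis=1)  # (B, n_maps)
            pooled_parts.append(np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :])
            cache_parts.append((h, Xw, Z, arg))
        pooled = np.concatenate(pooled_parts, axis=1)  # (B, F)
        if train_mask is not None:
            dropped = pooled * train_mask
        else:
            dropped = pooled
        logits = dropped @ self._params["Wo"] + self._params["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, (idx, cache_parts, dropped, train_mask)

    def _backward(self, probs, y_onehot, cache):
        idx, cache_parts, dropped, train_mask = cache
        B = probs.shape[0]
        _, fgrad = ACTIVATIONS[self.activation]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot) / B
        grads["Wo"] = dropped.T @ dlogits + 2.0 * self.l2 * self._params["Wo"]
        grads["bo"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self._params["Wo"].T
        if train_mask is not None:
            dpooled = dpooled * train_mask
        dE = None
        if self.trainable_embeddings:
            dE = np.zeros_like(self._params["E"])
        offset = 0
        for h, Xw, Z, arg in cache_parts:
            m = self.n_maps
            dpool_h = dpooled[:, offset : offset + m]  # (B, n_maps)
            offset += m
            Za = np.take_along_axis(Z, arg[:, None, :], axis=1)[:, 0, :]
            g = dpool_h * fgrad(Za)  # (B, n_maps)
            Xa = np.take_along_axis(
                Xw, arg[:, :, None], axis=1
            )  # (B, n_maps, h*k)
            grads[f"W{h}"] = np.einsum("bm,bmj->mj", g, Xa)
            grads[f"b{h}"] = g.sum(axis=0)
            if dE is not None:
                W = self._params[f"W{h}"]
                dXa = g[:, :, None] * W[None, :, :]  # (B, n_maps, h*k)
                win = self._win_idx[h]  # (P, h)
                k = self._k
                dXa = dXa.reshape(B, m, h, k)
                # rows of the table touched by each pooled window
                cols = win[arg]  # (B, n_maps, h) positions in the text
                rows = np.take_along_axis(idx, cols.reshape(B, -1), axis=1)
                np.add.at(dE, rows.reshape(-1), dXa.reshape(-1, k))
        if dE is not None:
            dE[self._pad_index] = 0.0  # padding row stays zero
            grads["E"] = dE
        return grads

    def _loss(self, probs, y_onehot):
        ce = -np.mean(np.log(np.sum(probs * y_onehot, axis=1) + 1e-12))
        return ce + self.l2 * float(np.sum(self._params["Wo"] ** 2))

    def _eval_loss(self, idx, y_codes, chunk=1024):
        total, n = 0.0, idx.shape[0]
        for s in range(0, n, chunk):
            sl = slice(s, min(s + chunk, n))
            probs, _ = self._forward(idx[sl])
            total += -np.sum(
                np.log(probs[np.arange(probs.shape[0]), y_codes[sl]] + 1e-12)
            )
        return total / n + self.l2 * float(np.sum(self._params["Wo"] ** 2))

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on texts `X` with labels `y`.

        When `X_val`/`y_val` are omitted, a stratified
        ``validation_fraction`` split of the training data is held out for
        early stopping.  Raises on a single-class training set.
        """
        self._check_params()
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                "training data contains a single class; need at least 2"
            )
        rng = np.random.default_rng(self.seed)

        if X_val is None:
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)),
                test_size=self.validation_fraction,
                stratify=y_codes,
                random_state=self.seed % (2**32),
            )
            X_tr = [X[i] for i in idx_tr]
            yc_tr = y_codes[idx_tr]
            X_va = [X[i] for i in idx_va]
            yc_va = y_codes[idx_va]
        else:
            X_tr, yc_tr = list(X), y_codes
            X_va = list(X_val)
            yv = np.asarray(y_val)
            lookup = {c: i for i, c in enumerate(self.classes_)}
            try:
                yc_va = np.asarray([lookup[v] for v in yv])
            except KeyError as exc:
                raise ValueError(f"validation label {exc} unseen in training") from exc

        # embedding table: vocabulary rows + OOV rows + one padding row
        emb = self.embedding
        self._k = emb.k
        self._oov_index: dict[str, int] = {}
        self._extra_rows: list[np.ndarray] = []
        self._table_rows = emb.vectors.shape[0]
        self._pad_index = -1  # resolved after OOV collection
        # temporarily route padding to a sentinel; collect indices first
        pad_placeholder = np.iinfo(np.int64).max
        self._pad_index = pad_placeholder
        ids_tr = self._index_texts(X_tr)
        ids_va = self._index_texts(X_va)
        pad_row = self._table_rows
        ids_tr[ids_tr == pad_placeholder] = pad_row
        ids_va[ids_va == pad_placeholder] = pad_row
        self._pad_index = pad_row
        table = np.vstack(
            [np.asarray(emb.vectors, dtype=np.float64)]
            + self._extra_rows
            + [np.zeros((1, self._k))]
        )

        # parameter initialization (Glorot uniform), seeded
        n_classes = len(self.classes_)
        F = len(self.filter_widths) * self.n_maps
        self._params = {"E": table}
        self._win_idx = {}
        for h in self.filter_widths:
            fan_in, fan_out = h * self._k, self.n_maps
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self._params[f"W{h}"] = rng.uniform(
                -limit, limit, (self.n_maps, h * self._k)
            )
            self._params[f"b{h}"] = np.zeros(self.n_maps)
            P = self.fixed_len - h + 1
            self._win_idx[h] = (
                np.arange(P)[:, None] + np.arange(h)[None, :]
            )
        limit = np.sqrt(6.0 / (F + n_classes))
        self._params["Wo"] = rng.uniform(-limit, limit, (F, n_classes))
        self._params["bo"] = np.zeros(n_classes)

        lr = self.learning_rate
        if lr is None:
            lr = _DEFAULT_LR[self.optimizer]
        opt = _OPTIMIZERS[self.optimizer](lr)

        n_tr = ids_tr.shape[0]
        onehot = np.eye(n_classes)
        best_loss = np.inf
        best_params = None
        best_epoch = -1
        since_best = 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, n_tr, self.batch_size):
                batch = order[s : s + self.batch_size]
                ids_b = ids_tr[batch]
                y_b = onehot[yc_tr[batch]]
                if self.dropout > 0:
                    mask = (
                        rng.random((len(batch), F)) >= self.dropout
                    ) / (1.0 - self.dropout)
                else:
                    mask = None
                probs, cache = self._forward(ids_b, train_mask=mask)
                epoch_loss += self._loss(probs, y_b)
                n_batches += 1
                grads = self._backward(probs, y_b, cache)
                if not self.trainable_embeddings:
                    grads.pop("E", None)
                opt.step(self._params, grads)
            val_loss = self._eval_loss(ids_va, yc_va)
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss,
                }
            )
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in self._params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            self._params = best_params
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        self.n_epochs_ = len(self.history_)
        self.filters_ = [
            FilterSpec(
                h=h,
                weights=self._params[f"W{h}"].reshape(self.n_maps, h, self._k),
                bias=self._params[f"b{h}"],
                activation=self.activation,
            )
            for h in self.filter_widths
        ]
        self.softmax_weights_ = self._params["Wo"]
        self.softmax_bias_ = self._params["bo"]
        return self

    def _check_fitted(self):
        if not hasattr(self, "classes_") or not hasattr(self, "_params"):
            raise NotFittedError(
                "this CNNTextClassifier instance is not fitted yet"
            )

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability rows (softmax outputs); dropout inactive."""
        self._check_fitted()
        ids = self._index_texts(X)
        # tokens first seen at prediction time fall back to the zero row
        ids[ids >= self._params["E"].shape[0]] = self._pad_index
        out = []
        for s in range(0, ids.shape[0], 1024):
            probs, _ = self._forward(ids[s : s + 1024])
            out.append(probs)
        return np.vstack(out) if out else np.empty((0, len(self.classes_)))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Save the fitted model to ``<path>`` (numpy .npz + JSON config)."""
        self._check_fitted()
        path = Path(path)
        meta = {
            "classes": [str(c) for c in self.classes_],
            "history": self.history_,
            "best_epoch": self.best_epoch_,
            "best_val_loss": self.best_val_loss_,
        }
        cfg = {
            k: v
            for k, v in self.get_params().items()
            if k != "embedding"
        }
        cfg["filter_widths"] = list(self.filter_widths)
        arrays = {f"param_{k}": v for k, v in self._params.items()}
        arrays["pad_index"] = np.array(self._pad_index)
        np.savez(
            path,
            config=json.dumps(cfg),
            meta=json.dumps(meta),
            oov_tokens=json.dumps(self._oov_index),
            vocabulary=json.dumps(self.embedding.vocabulary),
            **arrays,
        )
        return path

    @classmethod
    def load(
        cls, path: str | Path, embedding: EmbeddingMatrix | None = None
    ) -> "CNNTextClassifier":
        """Load a model saved by :meth:`save`.

        When `embedding` is omitted, the training vocabulary and (fitted)
        vector table stored in the checkpoint are reused, so predictions
        reproduce the training-time token mapping exactly.
        """
        data = np.load(Path(path), allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["filter_widths"] = tuple(cfg["filter_widths"])
        meta = json.loads(str(data["meta"]))
        if embedding is None:
            vocab = json.loads(str(data["vocabulary"]))
            table = data["param_E"]
            embedding = EmbeddingMatrix(
                vocabulary=vocab,
                vectors=table[: len(vocab)],
                oov_policy="zero",
            )
        model = cls(embedding=embedding, **cfg)
        model._params = {
            k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
        }
        model._pad_index = int(data["pad_index"])
        model._oov_index = json.loads(str(data["oov_tokens"]))
        model._table_rows = model._params["E"].shape[0] - 1
        model._k = model.embedding.k
        model._win_idx = {
            h: np.arange(model.fixed_len - h + 1)[:, None] + np.arange(h)[None, :]
            for h in model.filter_widths
        }
        model.classes_ = np.asarray(meta["classes"])
        model.history_ = meta["history"]
        model.best_epoch_ = meta["best_epoch"]
        model.best_val_loss_ = meta["best_val_loss"]
        model.n_epochs_ = len(model.history_)
        model.softmax_weights_ = model._params["Wo"]
        model.softmax_bias_ = model._params["bo"]
        return model


def write_history_csv(model: CNNTextClassifier, path: str | Path) -> Path:
    """Write the per-epoch training curve as CSV (epoch, train_loss, val_loss)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for row in model.history_:
            fh.write(f"{row['epoch']},{row['train_loss']:.10g},{row['val_loss']:.10g}\n")
    return path
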