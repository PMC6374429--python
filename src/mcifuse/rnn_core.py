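"""Recurrent encoder mathematics: cells, losses, and exact BPTT gradients.

Two cell types are provided.  The vanilla recurrent unit

    h_t = tanh(W_h h_{t-1} + W_x x_t)

(no biases — the classical formulation) and the standard gated recurrent
unit (GRU)

    z_t = logistic(W_z x_t + U_z h_{t-1} + b_z)          (update gate)
    r_t = logistic(W_r x_t + U_r h_{t-1} + b_r)          (reset gate)
    c_t = tanh(W_c x_t + U_c (r_t * h_{t-1}) + b_c)      (candidate)
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t

Both start from a zero hidden state, so a length-one sequence is a single
cell step and every hidden entry stays strictly inside (-1, 1).  A linear
read-out ``softmax(W_y h_T)`` turns the final state into class
probabilities, scored by the negative mean log-likelihood (cross-entropy).

Gradients are computed by backpropagation through time, written out
explicitly in numpy (reverse accumulation over the unrolled sequence) and
vectorized over groups of equal-length sequences.  They are exact: tests
check them entrywise against central finite differences.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "RNNParams",
    "GRUParams",
    "tanh_activation",
    "softmax",
    "rnn_step",
    "gru_step",
    "encode_sequence",
    "classify",
    "cross_entropy",
    "one_hot",
    "bptt_gradients",
    "batch_loss",
    "loss_and_gradients",
    "save_params",
    "load_params",
]

_PROB_FLOOR = 1e-12  # clip predicted probabilities away from 0 before log


def tanh_activation(x: np.ndarray) -> np.ndarray:
    """Elementwise hyperbolic tangent, 2/(1+e^{-2x}) - 1, stable for large |x|."""
    return np.tanh(np.asarray(x, dtype=float))


def softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    """Probability vector e^{u_i} / sum_k e^{u_k}, computed with max subtraction."""
    u = np.asarray(u, dtype=float)
    shifted = u - np.max(u, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def _check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class RNNParams:
    """Weights of the vanilla recurrent classifier (recurrent, input, read-out)."""

    W_h: np.ndarray  # (hidden, hidden)
    W_x: np.ndarray  # (hidden, n_features)
    W_y: np.ndarray  # (n_classes, hidden)

    def __post_init__(self) -> None:
        self.W_h = _check_finite("W_h", self.W_h)
        self.W_x = _check_finite("W_x", self.W_x)
        self.W_y = _check_finite("W_y", self.W_y)
        h = self.W_h.shape[0]
        if self.W_h.shape != (h, h):
            raise ValueError("W_h must be square")
        if self.W_x.shape[0] != h or self.W_y.shape[1] != h:
            raise ValueError("inconsistent hidden dimension across W_h/W_x/W_y")

    @property
    def hidden_dim(self) -> int:
        return self.W_h.shape[0]

    @property
    def n_features(self) -> int:
        return self.W_x.shape[1]

    @classmethod
    def init(cls, n_features: int, hidden_dim: int, n_classes: int = 2,
             seed: int = 0) -> "RNNParams":
        """Seeded uniform initialization scaled by 1/sqrt(fan-in)."""
        rng = np.random.default_rng(seed)

        def u(shape, fan_in):
            return rng.uniform(-1.0, 1.0, size=shape) / np.sqrt(fan_in)

        return cls(
            W_h=u((hidden_dim, hidden_dim), hidden_dim),
            W_x=u((hidden_dim, n_features), n_features),
            W_y=u((n_classes, hidden_dim), hidden_dim),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def copy(self) -> "RNNParams":
        return RNNParams(**{k: v.copy() for k, v in self.arrays().items()})

    def zeros_like(self) -> "RNNParams":
        return RNNParams(**{k: np.zeros_like(v) for k, v in self.arrays().items()})


@dataclass
class GRUParams:
    """Gate, candidate, and read-out weights of a GRU classifier.

    ``W_*`` are input-side (hidden, n_features), ``U_*`` recurrent
    (hidden, hidden), ``b_*`` bias vectors (hidden,); ``W_y`` is the
    (n_classes, hidden) read-out.
    """

    W_z: np.ndarray
    U_z: np.ndarray
    b_z: np.ndarray
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W_c: np.ndarray
    U_c: np.ndarray
    b_c: np.ndarray
    W_y: np.ndarray

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            setattr(self, f.name, _check_finite(f.name, getattr(self, f.name)))
        h, nf = self.W_z.shape
        for name in ("W_z", "W_r", "W_c"):
            if getattr(self, name).shape != (h, nf):
                raise ValueError(f"{name} must have shape {(h, nf)}")
        for name in ("U_z", "U_r", "U_c"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_z", "b_r", "b_c"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")
        if self.W_y.ndim != 2 or self.W_y.shape[1] != h:
            raise ValueError("W_y must have shape (n_classes, hidden)")

    @property
    def hidden_dim(self) -> int:
        return self.W_z.shape[0]

    @property
    def n_features(self) -> int:
        return self.W_z.shape[1]

    @classmethod
    def init(cls, n_features: int, hidden_dim: int, n_classes: int = 2,
             seed: int = 0) -> "GRUParams":
        """Seeded uniform 1/sqrt(fan-in) weights, zero biases."""
        rng = np.random.default_rng(seed)

        def u(shape, fan_in):
            return rng.uniform(-1.0, 1.0, size=shape) / np.sqrt(fan_in)

        kw = {}
        for gate in ("z", "r", "c"):
            kw[f"W_{gate}"] = u((hidden_dim, n_features), n_features)
            kw[f"U_{gate}"] = u((hidden_dim, hidden_dim), hidden_dim)
            kw[f"b_{gate}"] = np.zeros(hidden_dim)
        kw["W_y"] = u((n_classes, hidden_dim), hidden_dim)
        return cls(**kw)

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def copy(self) -> "GRUParams":
        return GRUParams(**{k: v.copy() for k, v in self.arrays().items()})

    def zeros_like(self) -> "GRUParams":
        return GRUParams(**{k: np.zeros_like(v) for k, v in self.arrays().items()})


Params = RNNParams | GRUParams


def rnn_step(params: RNNParams, h_prev: np.ndarray, x_t: np.ndarray) -> np.ndarray:
    """One vanilla recurrent update tanh(W_h h_{t-1} + W_x x_t).

    Accepts single vectors (H,), (F,) or batches (N, H), (N, F).
    """
    h_prev = np.asarray(h_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if h_prev.shape[-1] != params.hidden_dim or x_t.shape[-1] != params.n_features:
        raise ValueError(
            f"shape mismatch: h_prev {h_prev.shape}, x {x_t.shape} vs "
            f"hidden {params.hidden_dim}, features {params.n_features}"
        )
    return np.tanh(h_prev @ params.W_h.T + x_t @ params.W_x.T)


def gru_step(params: GRUParams, h_prev: np.ndarray, x_t: np.ndarray) -> np.ndarray:
    """One GRU update; vectorized over a leading batch axis like :func:`rnn_step`."""
    h_prev = np.asarray(h_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if h_prev.shape[-1] != params.hidden_dim or x_t.shape[-1] != params.n_features:
        raise ValueError(
            f"shape mismatch: h_prev {h_prev.shape}, x {x_t.shape} vs "
            f"hidden {params.hidden_dim}, features {params.n_features}"
        )
    z = expit(x_t @ params.W_z.T + h_prev @ params.U_z.T + params.b_z)
    r = expit(x_t @ params.W_r.T + h_prev @ params.U_r.T + params.b_r)
    c = np.tanh(x_t @ params.W_c.T + (r * h_prev) @ params.U_c.T + params.b_c)
    return (1.0 - z) * h_prev + z * c


def _step_fn(params: Params):
    return gru_step if isinstance(params, GRUParams) else rnn_step


def _observation_matrix(sequence) -> np.ndarray:
    obs = getattr(sequence, "observations", sequence)
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        obs = obs[None, :]
    return obs


def encode_sequence(params: Params, sequence) -> np.ndarray:
    """Fold a (T, F) visit matrix (or ModalitySequence) into the final hidden state.

    Starts from the zero state and applies the cell over visits in time
    order; the result is a fixed-size representation regardless of T.
    """
    obs = _observation_matrix(sequence)
    if obs.shape[0] < 1:
        raise ValueError("cannot encode an empty sequence")
    step = _step_fn(params)
    h = np.zeros(params.hidden_dim)
    for x_t in obs:
        h = step(params, h, x_t)
    return h


def classify(h: np.ndarray, W_y: np.ndarray) -> np.ndarray:
    """Class probabilities softmax(W_y h) for a hidden state (or batch of them)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != W_y.shape[1]:
        raise ValueError(f"hidden state length {h.shape[-1]} vs W_y {W_y.shape}")
    return softmax(h @ W_y.T, axis=-1)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Negative mean log-likelihood -(1/N) sum_n sum_c y_nc log(y_hat_nc).

    ``y`` is one-hot (N, C); probabilities are clipped at 1e-12 before the
    log.  Zero exactly when every prediction puts mass one on its true class.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    if y.shape != y_hat.shape:
        raise ValueError(f"label/prediction shape mismatch {y.shape} vs {y_hat.shape}")
    n = y.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    return float(-np.sum(y * np.log(np.clip(y_hat, _PROB_FLOOR, None))) / n)


# ---------------------------------------------------------------------------
# BPTT: forward/backward over a batch of equal-length sequences.

def _forward_rnn(params: RNNParams, X: np.ndarray):
    n, T, _ = X.shape
    hs = np.zeros((T + 1, n, params.hidden_dim))
    for t in range(T):
        hs[t + 1] = np.tanh(hs[t] @ params.W_h.T + X[:, t] @ params.W_x.T)
    return hs


def _backward_rnn(params: RNNParams, X: np.ndarray, hs: np.ndarray,
                  dh: np.ndarray, grads: RNNParams) -> None:
    T = X.shape[1]
    for t in range(T, 0, -1):
        da = dh * (1.0 - hs[t] ** 2)
        grads.W_h += da.T @ hs[t - 1]
        grads.W_x += da.T @ X[:, t - 1]
        dh = da @ params.W_h


def _forward_gru(params: GRUParams, X: np.ndarray):
    n, T, _ = X.shape
    H = params.hidden_dim
    hs = np.zeros((T + 1, n, H))
    zs = np.empty((T, n, H))
    rs = np.empty((T, n, H))
    cs = np.empty((T, n, H))
    for t in range(T):
        x, h = X[:, t], hs[t]
        zs[t] = expit(x @ params.W_z.T + h @ params.U_z.T + params.b_z)
        rs[t] = expit(x @ params.W_r.T + h @ params.U_r.T + params.b_r)
        cs[t] = np.tanh(x @ params.W_c.T + (rs[t] * h) @ params.U_c.T + params.b_c)
        hs[t + 1] = (1.0 - zs[t]) * h + zs[t] * cs[t]
    return hs, zs, rs, cs


def _backward_gru(params: GRUParams, X: np.ndarray, caches, dh: np.ndarray,
                  grads: GRUParams) -> None:
    hs, zs, rs, cs = caches
    T = X.shape[1]
    for t in range(T, 0, -1):
        x, h_prev = X[:, t - 1], hs[t - 1]
        z, r, c = zs[t - 1], rs[t - 1], cs[t - 1]
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)

        da_c = dc * (1.0 - c ** 2)
        grads.W_c += da_c.T @ x
        grads.U_c += da_c.T @ (r * h_prev)
        grads.b_c += da_c.sum(axis=0)
        dUc = da_c @ params.U_c
        dr = dUc * h_prev
        dh_prev += dUc * r

        da_z = dz * z * (1.0 - z)
        grads.W_z += da_z.T @ x
        grads.U_z += da_z.T @ h_prev
        grads.b_z += da_z.sum(axis=0)
        dh_prev += da_z @ params.U_z

        da_r = dr * r * (1.0 - r)
        grads.W_r += da_r.T @ x
        grads.U_r += da_r.T @ h_prev
        grads.b_r += da_r.sum(axis=0)
        dh_prev += da_r @ params.U_r

        dh = dh_prev


def loss_and_gradients(params: Params, sequences, labels) -> tuple[float, Params]:
    """Cross-entropy of the batch and its exact gradient w.r.t. every tensor.

    ``sequences`` is a list of (T_i, F) matrices (or ModalitySequence); the
    loss is the mean over the batch, so gradients are per-sample gradients
    averaged over the batch.  Sequences are grouped by length internally so
    the unrolled recurrences run as batched matrix products.
    """
    mats = [_observation_matrix(s) for s in sequences]
    labels = np.asarray(labels, dtype=int)
    if len(mats) != labels.size or labels.size == 0:
        raise ValueError("need an equal, positive number of sequences and labels")
    n_total = labels.size
    n_classes = params.W_y.shape[0]
    grads = params.zeros_like()
    loss = 0.0

    by_length: dict[int, list[int]] = {}
    for i, m in enumerate(mats):
        by_length.setdefault(m.shape[0], []).append(i)

    is_gru = isinstance(params, GRUParams)
    for T, idx in sorted(by_length.items()):
        X = np.stack([mats[i] for i in idx])          # (n, T, F)
        y = one_hot(labels[idx], n_classes)           # (n, C)
        if is_gru:
            caches = _forward_gru(params, X)
            h_T = caches[0][T]
        else:
            hs = _forward_rnn(params, X)
            h_T = hs[T]
        p = softmax(h_T @ params.W_y.T, axis=-1)
        loss += -np.sum(y * np.log(np.clip(p, _PROB_FLOOR, None)))
        g = (p - y) / n_total                          # d loss / d logits
        grads.W_y += g.T @ h_T
        dh = g @ params.W_y
        if is_gru:
            _backward_gru(params, X, caches, dh, grads)
        else:
            _backward_rnn(params, X, hs, dh, grads)
    return loss / n_total, grads


def bptt_gradients(params: Params, sequences, labels) -> Params:
    """Gradient of :func:`cross_entropy` over the batch, structured like ``params``.

    Exactness contract: agrees with central-difference numerical
    differentiation; realized here by explicit reverse accumulation through
    the unrolled cells.
    """
    return loss_and_gradients(params, sequences, labels)[1]


def batch_loss(params: Params, sequences, labels) -> float:
    """Cross-entropy of final-step predictions over a batch of sequences."""
    return loss_and_gradients(params, sequences, labels)[0]


# ---------------------------------------------------------------------------
# Serialization: flat key -> array JSON documents.

def save_params(params: Params, path: str | Path) -> None:
    doc = {
        "kind": "gru" if isinstance(params, GRUParams) else "rnn",
        "arrays": {k: v.tolist() for k, v in params.arrays().items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_params(path: str | Path) -> Params:
    doc = json.loads(Path(path).read_text())
    cls = GRUParams if doc["kind"] == "gru" else RNNParams
    return cls(**{k: np.asarray(v, dtype=float) for k, v in doc["arrays"].items()})
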