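"""LSTM sequence classifier over hybrid feature vectors.

The recurrence is the standard gated cell: with ``[h_{t-1}, x_t]`` the
concatenation of the previous hidden state and the current input,

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    C~_t = tanh(W_C [h_{t-1}, x_t] + b_C)          (candidate state)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)

A dense softmax readout on the final hidden state produces class
probabilities; training minimises categorical cross-entropy with Adam
through full backpropagation-through-time.  Everything is NumPy and
bit-reproducible for a fixed seed on one thread.

Two input framings are available for a d-dimensional feature vector:

* ``"vector"`` (default): one time step of width d — how a recurrent
  layer is conventionally applied to a single feature vector, and the
  framing under which all feature blocks contribute to the readout;
* ``"scalar"``: the vector is presented as a length-d sequence of
  scalars, so the recurrence traverses the feature vector one
  component at a time.

:func:`cell_step` is a deliberately literal per-gate transcription of
the equations above, kept separate from the vectorised training path
so the two can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import ParameterGrid, train_test_split

from ._nn import Adam, glorot_uniform, orthogonal, sigmoid, softmax


@dataclass
class LSTMCellParams:
    """Per-gate weights over the concatenation [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    @property
    def units(self) -> int:
        return self.b_f.shape[0]


@dataclass
class LSTMState:
    """Cell state C_t and hidden state h_t."""

    C: np.ndarray
    h: np.ndarray


def cell_step(params: LSTMCellParams, state: LSTMState, x_t: np.ndarray) -> LSTMState:
    """One reference step of the gate equations (see module docstring)."""
    hx = np.concatenate([state.h, np.asarray(x_t, dtype=np.float64)])
    if hx.shape[0] != params.W_f.shape[1]:
        raise ValueError(
            f"[h, x] length {hx.shape[0]} does not match weight columns {params.W_f.shape[1]}"
        )
    f_t = sigmoid(params.W_f @ hx + params.b_f)
    i_t = sigmoid(params.W_i @ hx + params.b_i)
    c_tilde = np.tanh(params.W_C @ hx + params.b_C)
    c_t = f_t * state.C + i_t * c_tilde
    o_t = sigmoid(params.W_o @ hx + params.b_o)
    h_t = o_t * np.tanh(c_t)
    return LSTMState(C=c_t, h=h_t)


class LSTMClassifier(ClassifierMixin, BaseEstimator):
    """Seeded NumPy LSTM + softmax classifier (sklearn estimator API).

    Gate order in the packed weight matrices is (f, i, g, o) with g the
    tanh candidate; ``cell_params_for_gates`` unpacks them into the
    per-gate form consumed by :func:`cell_step`.
    """

    def __init__(
        self,
        units: int = 128,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
        framing: str = "vector",
    ):
        self.units = units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.framing = framing

    # -- shaping -------------------------------------------------------

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if self.framing == "scalar":
                return X[:, :, np.newaxis]
            if self.framing == "vector":
                return X[:, np.newaxis, :]
            raise ValueError(f"unknown framing {self.framing!r}")
        if X.ndim == 3:
            return X
        raise ValueError("expected (n, d) features or (n, T, d) sequences")

    # -- forward / backward -------------------------------------------

    def _forward(self, X_seq: np.ndarray, with_cache: bool = False):
        n, T, d = X_seq.shape
        U = self.units
        h = np.zeros((n, U))
        c = np.zeros((n, U))
        zx = X_seq @ self.Wx_  # (n, T, 4U), input contribution per step
        caches = []
        for t in range(T):
            z = zx[:, t] + h @ self.Wh_ + self.b_
            f = sigmoid(z[:, :U])
            i = sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = sigmoid(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            if with_cache:
                caches.append((f, i, g, o, c_prev, c))
        logits = h @ self.Wd_ + self.bd_
        probs = softmax(logits)
        return (probs, h, caches) if with_cache else probs

    def _backward(self, X_seq, y_onehot, probs, h_last, caches):
        n, T, d = X_seq.shape
        U = self.units
        dlogits = (probs - y_onehot) / n
        dWd = h_last.T @ dlogits
        dbd = dlogits.sum(axis=0)
        dh = dlogits @ self.Wd_.T
        dc = np.zeros((n, U))
        dZ = np.empty((n, T, 4 * U))
        # reconstruct h_{t-1} from caches on the fly
        for t in range(T - 1, -1, -1):
            f, i, g, o, c_prev, c = caches[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [df * f * (1 - f), di * i * (1 - i), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dZ[:, t] = dz
            dh = dz @ self.Wh_.T
            dc = dc * f
        dWx = np.tensordot(X_seq, dZ, axes=([0, 1], [0, 1]))
        db = dZ.sum(axis=(0, 1))
        # hidden states feeding each step: h_{-1} = 0, then o*tanh(c)
        H_prev = np.empty((n, T, U))
        H_prev[:, 0] = 0.0
        for t in range(1, T):
            f, i, g, o, c_prev, c = caches[t - 1]
            H_prev[:, t] = o * np.tanh(c)
        dWh = np.tensordot(H_prev, dZ, axes=([0, 1], [0, 1]))
        return [dWx, dWh, db, dWd, dbd]

    # -- estimator API -------------------------------------------------

    def fit(self, X, y) -> "LSTMClassifier":
        X_seq = self._to_sequences(X)
        y = np.asarray(y)
        if X_seq.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training requires at least 2 classes")
        n, T, d = X_seq.shape
        U, K = self.units, self.classes_.size
        rng = np.random.default_rng(self.seed)
        self.Wx_ = glorot_uniform(rng, (d, 4 * U), d, 4 * U)
        self.Wh_ = orthogonal(rng, U, 4 * U)
        self.b_ = np.zeros(4 * U)
        self.b_[:U] = 1.0  # forget-gate bias: remember by default
        self.Wd_ = glorot_uniform(rng, (U, K), U, K)
        self.bd_ = np.zeros(K)
        self.n_features_in_ = X.shape[1] if np.asarray(X).ndim == 2 else d

        params = [self.Wx_, self.Wh_, self.b_, self.Wd_, self.bd_]
        opt = Adam(params, lr=self.learning_rate)
        onehot = np.eye(K)[y_idx]
        self.history_ = {"loss": [], "accuracy": []}
        for _ in range(self.epochs):
            order = rng.permutation(n)
            loss_sum = 0.0
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X_seq[idx], onehot[idx]
                probs, h_last, caches = self._forward(xb, with_cache=True)
                eps = 1e-12
                loss_sum += float(-np.sum(yb * np.log(probs + eps)))
                correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
                grads = self._backward(xb, yb, probs, h_last, caches)
                opt.step(grads)
            self.history_["loss"].append(loss_sum / n)
            self.history_["accuracy"].append(correct / n)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "Wx_"):
            raise ValueError("classifier is not fitted")
        return self._forward(self._to_sequences(X))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def weights_checksum(self) -> float:
        """Sum of all trained weights (a cheap reproducibility fingerprint)."""
        return float(
            sum(np.sum(w) for w in (self.Wx_, self.Wh_, self.b_, self.Wd_, self.bd_))
        )

    def cell_params_for_gates(self) -> LSTMCellParams:
        """Unpack the packed (f, i, g, o) weights into per-gate matrices
        over [h_{t-1}, x_t], as consumed by :func:`cell_step`."""
        U = self.units
        # packed layout: rows are x then h? Wx_ (d,4U), Wh_ (U,4U);
        # cell_step expects W @ [h, x], i.e. columns ordered h then x.
        def gate(j):
            Wx = self.Wx_[:, j * U : (j + 1) * U].T  # (U, d)
            Wh = self.Wh_[:, j * U : (j + 1) * U].T  # (U, U)
            return np.hstack([Wh, Wx]), self.b_[j * U : (j + 1) * U]

        (W_f, b_f), (W_i, b_i), (W_C, b_C), (W_o, b_o) = (gate(j) for j in range(4))
        return LSTMCellParams(W_f, W_i, W_C, W_o, b_f, b_i, b_C, b_o)


def grid_search(
    X,
    y,
    param_grid: Mapping[str, Sequence],
    base_params: Mapping | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out accuracy for every point of a hyperparameter grid.

    The same stratified validation split (fixed by ``seed``) is used
    for all grid points so that rows are comparable.  Returns one row
    per grid point with the varied parameters and the validation
    accuracy in percent.
    """
    param_grid = dict(param_grid)
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("empty hyperparameter grid")
    grid = list(ParameterGrid(param_grid))
    X = np.asarray(X)
    y = np.asarray(y)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=val_fraction, stratify=y, random_state=seed
    )
    rows = []
    for point in grid:
        params = dict(base_params or {})
        params.update(point)
        params.setdefault("seed", seed)
        clf = LSTMClassifier(**params).fit(X_tr, y_tr)
        acc = float((clf.predict(X_val) == y_val).mean() * 100.0)
        rows.append({**point, "accuracy_pct": acc})
    return pd.DataFrame(rows)
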