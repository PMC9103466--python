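"""LSTM sequence classifier with focal loss.

The recurrent cell is nonstandard: every gate reads the concatenation
``[a_{t-1}, x_t, c_{t-1}]`` (the previous hidden state, the current input
and the previous cell state, peephole-style)::

    i_t = sigmoid(W_i [a_{t-1}, x_t, c_{t-1}] + b_i)
    f_t = sigmoid(W_f [a_{t-1}, x_t, c_{t-1}] + b_f)
    o_t = sigmoid(W_o [a_{t-1}, x_t, c_{t-1}] + b_o)
    c_in = tanh(W_c [a_{t-1}, x_t, c_{t-1}] + b_c)
    c_t = f_t * c_{t-1} + i_t * c_in
    a_t = o_t * tanh(c_t)

The last hidden vector is the sequence representation, passed through two
fully connected layers and a softmax.  Training minimizes the focal loss
``-(1 - p_true)^gamma * log(p_true)``, which down-weights easy examples and
helps under the heavy class imbalance of sleep-stage data.  Everything is
plain numpy with hand-derived backpropagation through time and Adam updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class LSTMCellParams:
    """Gate weights over the concatenated ``[a_{t-1}, x_t, c_{t-1}]`` input."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator) -> "LSTMCellParams":
        zdim = 2 * hidden_size + input_size
        sc = 1.0 / np.sqrt(zdim)
        mk = lambda: rng.uniform(-sc, sc, size=(hidden_size, zdim))
        return cls(
            W_i=mk(), W_f=mk(), W_o=mk(), W_c=mk(),
            b_i=np.zeros(hidden_size),
            b_f=np.ones(hidden_size),  # start remembering
            b_o=np.zeros(hidden_size),
            b_c=np.zeros(hidden_size),
        )


def lstm_cell_step(
    x_t: np.ndarray, a_prev: np.ndarray, c_prev: np.ndarray, params: LSTMCellParams
) -> tuple[np.ndarray, np.ndarray]:
    """One forward step of the cell; accepts (D,) vectors or (B, D) batches."""
    single = x_t.ndim == 1
    x_t, a_prev, c_prev = np.atleast_2d(x_t), np.atleast_2d(a_prev), np.atleast_2d(c_prev)
    H = params.hidden_size
    if a_prev.shape[1] != H or c_prev.shape[1] != H:
        raise ValueError("state dimensions do not match hidden size")
    z = np.concatenate([a_prev, x_t, c_prev], axis=1)
    if z.shape[1] != params.W_i.shape[1]:
        raise ValueError("input dimension does not match cell parameters")
    i = _sigmoid(z @ params.W_i.T + params.b_i)
    f = _sigmoid(z @ params.W_f.T + params.b_f)
    o = _sigmoid(z @ params.W_o.T + params.b_o)
    c_in = np.tanh(z @ params.W_c.T + params.b_c)
    c_t = f * c_prev + i * c_in
    a_t = o * np.tanh(c_t)
    if single:
        return a_t[0], c_t[0]
    return a_t, c_t


def focal_loss(y_hat: np.ndarray | float, gamma: float = 2.0) -> float:
    """Focal loss ``-(1 - y_hat)^gamma * log(y_hat)``, averaged over samples.

    ``y_hat`` is the predicted probability of the true class; values <= 0
    are clamped at 1e-12 with a warning.  ``gamma = 0`` recovers plain
    cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    p = np.atleast_1d(np.asarray(y_hat, dtype=float))
    if (p <= 0).any():
        warnings.warn("probabilities <= 0 clamped at 1e-12")
        p = np.maximum(p, 1e-12)
    return float(np.mean(-((1.0 - p) ** gamma) * np.log(p)))


@dataclass
class TrainConfig:
    hidden_size: int = 64
    fc_size: int = 32
    dropout: float = 0.1
    batch_size: int = 128
    gamma: float = 2.0
    epochs: int = 30
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass
class LSTMClassifier:
    cell: LSTMCellParams
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    n_classes: int
    loss_trace: list = field(default_factory=list)

    def parameters(self) -> dict[str, np.ndarray]:
        c = self.cell
        return {
            "W_i": c.W_i, "W_f": c.W_f, "W_o": c.W_o, "W_c": c.W_c,
            "b_i": c.b_i, "b_f": c.b_f, "b_o": c.b_o, "b_c": c.b_c,
            "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
        }


def _forward(model: LSTMClassifier, X: np.ndarray, drop_mask: np.ndarray | None = None):
    """Full forward pass; returns softmax probabilities and a cache for BPTT."""
    B, T, D = X.shape
    H = model.cell.hidden_size
    a = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    p = model.cell
    for t in range(T):
        z = np.concatenate([a, X[:, t, :], c], axis=1)
        i = _sigmoid(z @ p.W_i.T + p.b_i)
        f = _sigmoid(z @ p.W_f.T + p.b_f)
        o = _sigmoid(z @ p.W_o.T + p.b_o)
        g = np.tanh(z @ p.W_c.T + p.b_c)
        c_new = f * c + i * g
        a = o * np.tanh(c_new)
        cache.append((z, i, f, o, g, c, c_new))
        c = c_new
    h1 = a @ model.W1.T + model.b1
    r1 = np.maximum(h1, 0.0)
    if drop_mask is not None:
        r1 = r1 * drop_mask
    logits = r1 @ model.W2.T + model.b2
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    return probs, (cache, a, h1, r1)


def _backward(model, X, y, probs, fwd_cache, gamma, drop_mask):
    B, T, D = X.shape
    H = model.cell.hidden_size
    cache, a_last, h1, r1 = fwd_cache
    p = model.cell
    grads = {k: np.zeros_like(v) for k, v in model.parameters().items()}

    p_y = np.clip(probs[np.arange(B), y], 1e-12, 1.0)
    one_minus = 1.0 - p_y
    # d/dp_y of -(1-p)^g log p
    g_y = gamma * one_minus ** np.maximum(gamma - 1.0, 0.0) * np.log(p_y) - one_minus**gamma / p_y
    g_y = g_y / B
    dlogits = probs * (-(g_y * p_y))[:, None]
    dlogits[np.arange(B), y] += g_y * p_y

    grads["W2"] = dlogits.T @ r1
    grads["b2"] = dlogits.sum(axis=0)
    dr1 = dlogits @ model.W2
    if drop_mask is not None:
        dr1 = dr1 * drop_mask
    dh1 = dr1 * (h1 > 0)
    grads["W1"] = dh1.T @ a_last
    grads["b1"] = dh1.sum(axis=0)
    da = dh1 @ model.W1
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        z, i, f, o, g, c_prev, c_new = cache[t]
        tanh_c = np.tanh(c_new)
        do = da * tanh_c
        dct = dc + da * o * (1.0 - tanh_c**2)
        df = dct * c_prev
        di = dct * g
        dg = dct * i
        dc_prev = dct * f
        dzi = di * i * (1 - i)
        dzf = df * f * (1 - f)
        dzo = do * o * (1 - o)
        dzg = dg * (1 - g**2)
        grads["W_i"] += dzi.T @ z
        grads["W_f"] += dzf.T @ z
        grads["W_o"] += dzo.T @ z
        grads["W_c"] += dzg.T @ z
        grads["b_i"] += dzi.sum(axis=0)
        grads["b_f"] += dzf.sum(axis=0)
        grads["b_o"] += dzo.sum(axis=0)
        grads["b_c"] += dzg.sum(axis=0)
        dz = dzi @ p.W_i + dzf @ p.W_f + dzo @ p.W_o + dzg @ p.W_c
        da = dz[:, :H]
        dc = dc_prev + dz[:, H + D :]
    return grads


def train_lstm(
    sequences: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> LSTMClassifier:
    """Train the sequence classifier with Adam on the focal loss.

    ``sequences`` is (n, T, D) with equal-length sequences; the per-epoch
    mean loss is recorded in ``model.loss_trace``.  Deterministic given
    ``cfg.seed``.  A non-finite loss aborts with diagnostics.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(sequences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 3:
        raise ValueError("sequences must be (n, time, features)")
    n, T, D = X.shape
    C = int(y.max()) + 1
    rng = np.random.default_rng(cfg.seed)
    cell = LSTMCellParams.init(D, cfg.hidden_size, rng)
    sc1 = np.sqrt(2.0 / cfg.hidden_size)
    model = LSTMClassifier(
        cell=cell,
        W1=rng.normal(scale=sc1, size=(cfg.fc_size, cfg.hidden_size)),
        b1=np.zeros(cfg.fc_size),
        W2=rng.normal(scale=np.sqrt(2.0 / cfg.fc_size), size=(C, cfg.fc_size)),
        b2=np.zeros(C),
        n_classes=C,
    )
    params = model.parameters()
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            mask = None
            if cfg.dropout > 0:
                mask = (rng.random((len(idx), cfg.fc_size)) >= cfg.dropout) / (1 - cfg.dropout)
            probs, fc = _forward(model, Xb, mask)
            loss = focal_loss(probs[np.arange(len(idx)), yb], cfg.gamma)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"loss={loss}, max|logit-prob|={np.abs(probs).max()}"
                )
            losses.append(loss)
            grads = _backward(model, Xb, yb, probs, fc, cfg.gamma, mask)
            step += 1
            for k, v in params.items():
                g = grads[k]
                mom[k] = b1m * mom[k] + (1 - b1m) * g
                vel[k] = b2m * vel[k] + (1 - b2m) * g**2
                mh = mom[k] / (1 - b1m**step)
                vh = vel[k] / (1 - b2m**step)
                v -= cfg.lr * mh / (np.sqrt(vh) + eps)
        model.loss_trace.append(float(np.mean(losses)))
    return model


def predict_lstm(model: LSTMClassifier, sequences: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softmax class probabilities and argmax labels; no dropout, repeatable."""
    X = np.asarray(sequences, dtype=float)
    probs, _ = _forward(model, X, None)
    return np.argmax(probs, axis=1), probs


def epochs_to_sequences(X: np.ndarray, n_steps: int) -> np.ndarray:
    """Reshape flat epoch rows into (n, n_steps, features) sequences."""
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if q % n_steps:
        raise ValueError("feature count not divisible by the number of time steps")
    return X.reshape(n, n_steps, q // n_steps)
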