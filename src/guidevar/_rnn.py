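"""A small, deterministic BiLSTM sequence-regression engine in numpy.

Implements exactly what the on-target transfer-learning model needs: a
bidirectional LSTM over one-hot nucleotide sequences whose two final hidden
states form a fixed-length embedding, a linear readout for pretraining, and
full backpropagation-through-time with Adam.  Sequence lengths here are 20
and hidden sizes a few dozen, so plain vectorized numpy is fast and keeps
training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np

from .errors import ConvergenceWarning


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_lstm_params(input_dim: int, hidden: int, rng: np.random.Generator) -> dict:
    """Glorot-scaled LSTM parameters; forget-gate bias initialized to 1."""
    h = hidden
    scale_x = np.sqrt(2.0 / (input_dim + 4 * h))
    scale_h = np.sqrt(2.0 / (h + 4 * h))
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget gate
    return {
        "Wx": rng.normal(0, scale_x, size=(input_dim, 4 * h)),
        "Wh": rng.normal(0, scale_h, size=(h, 4 * h)),
        "b": b,
    }


def lstm_forward(params: dict, X: np.ndarray):
    """Run an LSTM over ``X`` (N, T, D); return final hidden state and cache."""
    N, T, _ = X.shape
    h = params["Wh"].shape[0]
    hs = np.zeros((N, h))
    cs = np.zeros((N, h))
    cache = []
    for t in range(T):
        x_t = X[:, t, :]
        a = x_t @ params["Wx"] + hs @ params["Wh"] + params["b"]
        i = _sigmoid(a[:, :h])
        f = _sigmoid(a[:, h:2 * h])
        g = np.tanh(a[:, 2 * h:3 * h])
        o = _sigmoid(a[:, 3 * h:])
        c_new = f * cs + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((x_t, hs, cs, i, f, g, o, c_new, tanh_c))
        hs, cs = h_new, c_new
    return hs, cache


def lstm_backward(params: dict, cache: list, dh_final: np.ndarray) -> dict:
    """BPTT for a loss attached to the final hidden state only."""
    h = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for t in range(len(cache) - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c = cache[t]
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += x_t.T @ da
        grads["Wh"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dh = da @ params["Wh"].T
        dc = dc * f
    return grads


def bilstm_embed(fwd: dict, bwd: dict, X: np.ndarray, with_cache: bool = False):
    """Concatenated final hidden states of the two directions, (N, 2h)."""
    h_f, cache_f = lstm_forward(fwd, X)
    h_b, cache_b = lstm_forward(bwd, X[:, ::-1, :])
    emb = np.concatenate([h_f, h_b], axis=1)
    if with_cache:
        return emb, cache_f, cache_b
    return emb


class Adam:
    def __init__(self, params: dict, lr: float = 0.01):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_bilstm_regressor(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 32,
    epochs: int = 300,
    lr: float = 0.02,
    patience: int = 10,
    seed: int = 0,
) -> tuple[dict, dict, dict]:
    """Train a BiLSTM + linear head on (X, y) by full-batch Adam / MSE.

    Returns ``(fwd_params, bwd_params, head)`` where ``head`` holds the
    temporary linear readout (discarded by callers that only keep the
    encoder).  Emits :class:`ConvergenceWarning` when training ends without
    a meaningful loss reduction.
    """
    rng = np.random.default_rng(seed)
    N, T, D = X.shape
    fwd = init_lstm_params(D, hidden, rng)
    bwd = init_lstm_params(D, hidden, rng)
    head = {
        "w": rng.normal(0, 1.0 / np.sqrt(2 * hidden), size=(2 * hidden,)),
        "b0": np.zeros(1),
    }
    params = {f"f_{k}": v for k, v in fwd.items()}
    params.update({f"b_{k}": v for k, v in bwd.items()})
    params.update(head)
    opt = Adam(params, lr=lr)

    y = np.asarray(y, dtype=float)
    first_loss = None
    best_loss = np.inf
    stall = 0
    for _ in range(epochs):
        emb, cache_f, cache_b = bilstm_embed(fwd, bwd, X, with_cache=True)
        pred = emb @ head["w"] + head["b0"]
        resid = pred - y
        loss = float(np.mean(resid ** 2))
        if first_loss is None:
            first_loss = loss
        if loss < best_loss - 1e-6:
            best_loss = loss
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
        dpred = 2.0 * resid / len(y)
        demb = np.outer(dpred, head["w"])
        h = hidden
        g_fwd = lstm_backward(fwd, cache_f, demb[:, :h])
        g_bwd = lstm_backward(bwd, cache_b, demb[:, h:])
        grads = {f"f_{k}": v for k, v in g_fwd.items()}
        grads.update({f"b_{k}": v for k, v in g_bwd.items()})
        grads["w"] = emb.T @ dpred
        grads["b0"] = np.array([dpred.sum()])
        opt.step(params, grads)

    if first_loss is not None and best_loss > 0.95 * first_loss:
        warnings.warn(
            "BiLSTM training ended without meaningful loss reduction",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fwd, bwd, head


def params_digest(*param_dicts: dict) -> str:
    """Stable sha256 digest over parameter arrays (order-fixed)."""
    md = hashlib.sha256()
    for params in param_dicts:
        for k in sorted(params):
            md.update(k.encode())
            md.update(np.ascontiguousarray(params[k], dtype=np.float64).tobytes())
    return md.hexdigest()
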