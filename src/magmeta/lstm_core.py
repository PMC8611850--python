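"""Minimal batched LSTM cell with hand-derived backpropagation.

Both the per-coordinate LSTM optimizer and the plain sequence forecaster are
built from this cell.  Parameters are plain NumPy arrays kept in flat dicts
(name -> array), gradients are shape-matched dicts, and every backward pass
is verified against finite differences in the test suite.

Gate layout within the fused projection is [input i, forget f, candidate g,
output o]; the cell follows the standard equations

    c_t = sigmoid(f) * c_{t-1} + sigmoid(i) * tanh(g)
    h_t = sigmoid(o) * tanh(c_t)
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "sigmoid",
    "init_lstm_layer",
    "lstm_step_forward",
    "lstm_step_backward",
    "tree_zeros_like",
    "tree_add",
    "tree_scale",
    "global_norm",
    "clip_by_global_norm",
    "sgd_step",
    "AdamState",
    "adam_step",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_lstm_layer(
    rng: np.random.Generator, input_size: int, hidden_size: int, prefix: str,
    forget_bias: float = 1.0,
) -> dict[str, np.ndarray]:
    """Gaussian fan-in-scaled weights; forget-gate bias offset for retention."""
    h = hidden_size
    b = np.zeros(4 * h)
    b[h : 2 * h] = forget_bias
    return {
        f"{prefix}_wx": rng.normal(0.0, 1.0 / np.sqrt(input_size), (input_size, 4 * h)),
        f"{prefix}_wh": rng.normal(0.0, 1.0 / np.sqrt(h), (h, 4 * h)),
        f"{prefix}_b": b,
    }


class LSTMStepCache(NamedTuple):
    x: np.ndarray
    h_prev: np.ndarray
    c_prev: np.ndarray
    i: np.ndarray
    f: np.ndarray
    g: np.ndarray
    o: np.ndarray
    c: np.ndarray
    tc: np.ndarray


def lstm_step_forward(
    params: dict[str, np.ndarray],
    prefix: str,
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, LSTMStepCache]:
    """One cell step for a batch of rows; returns (h, c, cache)."""
    wx, wh, b = params[f"{prefix}_wx"], params[f"{prefix}_wh"], params[f"{prefix}_b"]
    hsz = wh.shape[0]
    z = x @ wx + h_prev @ wh + b
    i = sigmoid(z[:, :hsz])
    f = sigmoid(z[:, hsz : 2 * hsz])
    g = np.tanh(z[:, 2 * hsz : 3 * hsz])
    o = sigmoid(z[:, 3 * hsz :])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    return h, c, LSTMStepCache(x, h_prev, c_prev, i, f, g, o, c, tc)


def lstm_step_backward(
    params: dict[str, np.ndarray],
    prefix: str,
    cache: LSTMStepCache,
    dh: np.ndarray,
    dc: np.ndarray,
    grads: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward through one step.

    ``dh``/``dc`` are the gradients flowing into this step's outputs;
    weight gradients are accumulated in-place into ``grads``.  Returns
    (dx, dh_prev, dc_prev).
    """
    wx, wh = params[f"{prefix}_wx"], params[f"{prefix}_wh"]
    i, f, g, o, tc = cache.i, cache.f, cache.g, cache.o, cache.tc
    do = dh * tc
    dct = dc + dh * o * (1.0 - tc * tc)
    df = dct * cache.c_prev
    dc_prev = dct * f
    di = dct * g
    dg = dct * i
    dz = np.concatenate(
        [
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ],
        axis=1,
    )
    grads[f"{prefix}_wx"] += cache.x.T @ dz
    grads[f"{prefix}_wh"] += cache.h_prev.T @ dz
    grads[f"{prefix}_b"] += dz.sum(axis=0)
    dx = dz @ wx.T
    dh_prev = dz @ wh.T
    return dx, dh_prev, dc_prev


# ---------------------------------------------------------------------------
# parameter-tree utilities and optimizers

def tree_zeros_like(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


def tree_add(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: a[k] + b[k] for k in a}


def tree_scale(a: dict[str, np.ndarray], s: float) -> dict[str, np.ndarray]:
    return {k: s * v for k, v in a.items()}


def global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(v * v)) for v in grads.values())))


def clip_by_global_norm(
    grads: dict[str, np.ndarray], max_norm: float
) -> dict[str, np.ndarray]:
    norm = global_norm(grads)
    if max_norm > 0 and norm > max_norm:
        return tree_scale(grads, max_norm / norm)
    return grads


def sgd_step(
    params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float
) -> dict[str, np.ndarray]:
    return {k: params[k] - lr * grads[k] for k in params}


class AdamState(NamedTuple):
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState | None,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> tuple[dict[str, np.ndarray], AdamState]:
    if state is None:
        state = AdamState(tree_zeros_like(params), tree_zeros_like(params), 0)
    t = state.t + 1
    m = {k: beta1 * state.m[k] + (1 - beta1) * grads[k] for k in params}
    v = {k: beta2 * state.v[k] + (1 - beta2) * grads[k] ** 2 for k in params}
    new = {
        k: params[k]
        - lr * (m[k] / (1 - beta1**t)) / (np.sqrt(v[k] / (1 - beta2**t)) + eps)
        for k in params
    }
    return new, AdamState(m, v, t)
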