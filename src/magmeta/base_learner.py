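"""The optimization object f_theta: a small fully connected regression network.

The base learner maps a normalized field strength x in [0, 1] to a property
value.  Its parameters live in a single flat vector so that optimizers — a
gradient-descent inner loop or the per-coordinate LSTM optimizer — can treat
every weight uniformly.  The task loss is the summed squared error over the
sampled pairs of one task,

    L_T(f_theta) = sum_j || f_theta(x_j) - y_j ||^2 ,

and gradients are computed analytically by backpropagation.  All arithmetic
is written to be complex-analytic (matrix products, tanh, squared — not
absolute — residuals), which makes exact Hessian-vector products available
through complex-step differentiation of the gradient; second-order MAML
builds on that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterLayout",
    "default_layout",
    "init_theta",
    "forward",
    "mse_loss",
    "grad",
    "loss_and_grad",
    "hvp",
]


@dataclass(frozen=True)
class ParameterLayout:
    """Shapes of a fully connected stack, e.g. sizes (1, 40, 40, 1).

    The flat parameter vector concatenates, layer by layer, the weight
    matrix (row-major, shape in x out) followed by the bias.  ``flatten``
    after ``unflatten`` is the exact identity.
    """

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) < 2:
            raise ValueError("a layout needs at least an input and an output size")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("all layer sizes must be positive")

    @property
    def n_params(self) -> int:
        return sum(
            i * o + o for i, o in zip(self.sizes[:-1], self.sizes[1:])
        )

    def unflatten(self, theta: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        theta = np.asarray(theta)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has shape {theta.shape}, layout needs "
                f"({self.n_params},)"
            )
        out = []
        pos = 0
        for i, o in zip(self.sizes[:-1], self.sizes[1:]):
            w = theta[pos : pos + i * o].reshape(i, o)
            pos += i * o
            b = theta[pos : pos + o]
            pos += o
            out.append((w, b))
        return out

    def flatten(self, layers: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in layers])


#: Conventional few-shot-regression base network: 1 -> 40 -> 40 -> 1.
def default_layout() -> ParameterLayout:
    return ParameterLayout((1, 40, 40, 1))


def init_theta(layout: ParameterLayout, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian weights scaled by 1/sqrt(fan_in); zero biases."""
    parts = []
    for i, o in zip(layout.sizes[:-1], layout.sizes[1:]):
        parts.append(rng.normal(0.0, 1.0 / np.sqrt(i), size=i * o))
        parts.append(np.zeros(o))
    return np.concatenate(parts)


def _as_input(x: np.ndarray, n_in: int) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 1:
        if n_in != 1:
            raise ValueError(f"1-d input given but the network takes {n_in} features")
        return x[:, None]
    if x.ndim == 2 and x.shape[1] == n_in:
        return x
    raise ValueError(f"input of shape {x.shape} does not match {n_in} features")


def _forward_cached(layout, theta, x):
    layers = layout.unflatten(theta)
    a = _as_input(x, layout.sizes[0]).astype(theta.dtype, copy=False)
    pre_acts, acts = [], [a]
    for li, (w, b) in enumerate(layers):
        z = a @ w + b
        pre_acts.append(z)
        a = np.tanh(z) if li < len(layers) - 1 else z  # linear output layer
        acts.append(a)
    return layers, pre_acts, acts


def forward(layout: ParameterLayout, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Predictions, one real value per input row (hidden tanh, linear output)."""
    _, _, acts = _forward_cached(layout, np.asarray(theta), x)
    out = acts[-1]
    return out[:, 0] if out.shape[1] == 1 else out


def mse_loss(
    layout: ParameterLayout, theta: np.ndarray, x: np.ndarray, y: np.ndarray
) -> float | complex:
    """Summed squared error over the batch (the sum — not mean — form)."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("loss of an empty batch is undefined")
    r = forward(layout, np.asarray(theta), x) - y
    loss = np.sum(r * r)
    return loss if np.iscomplexobj(loss) else float(loss)


def loss_and_grad(
    layout: ParameterLayout, theta: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float | complex, np.ndarray]:
    """Task loss and its exact gradient via backpropagation."""
    theta = np.asarray(theta)
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("loss of an empty batch is undefined")
    layers, pre_acts, acts = _forward_cached(layout, theta, x)
    pred = acts[-1][:, 0]
    r = pred - y.astype(theta.dtype, copy=False)
    loss = np.sum(r * r)
    delta = (2.0 * r)[:, None]  # dL/d(output pre-activation); output is linear
    grads = [None] * len(layers)
    for li in range(len(layers) - 1, -1, -1):
        w, _ = layers[li]
        gw = acts[li].T @ delta
        gb = delta.sum(axis=0)
        grads[li] = (gw, gb)
        if li > 0:
            delta = (delta @ w.T) * (1.0 - np.tanh(pre_acts[li - 1]) ** 2)
    g = layout.flatten([(gw, gb) for gw, gb in grads])
    return (loss if np.iscomplexobj(loss) else float(loss)), g


def grad(
    layout: ParameterLayout, theta: np.ndarray, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Exact gradient of :func:`mse_loss` at theta."""
    return loss_and_grad(layout, theta, x, y)[1]


def hvp(
    layout: ParameterLayout,
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    h: float = 1e-20,
) -> np.ndarray:
    """Hessian-vector product H(theta) @ v by complex-step differentiation.

    The loss is a composition of complex-analytic operations, so
    Im(grad(theta + i*h*v)) / h equals the exact directional derivative of
    the gradient to machine precision — there is no subtractive
    cancellation, unlike real finite differences.
    """
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.shape != theta.shape:
        raise ValueError("direction vector must match the parameter vector shape")
    g = grad(layout, theta + 1j * h * v, x, y)
    return np.imag(g) / h
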