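"""The LSTM optimizer: a meta-learner whose cell state *is* the parameters.

Instead of adapting the base learner by a fixed gradient-descent rule, a
two-layer LSTM (applied per coordinate with shared weights) emits, at every
adaptation step, a forget gate f_t and an input gate i_t, and the
base-learner parameters are updated through the cell-state equation

    C_t = f_t ⊙ C_{t-1} + i_t ⊙ C̃_t ,   with  C_{t-1} = θ_{t-1},  C̃_t = -∇L_t .

Gradient descent is the special case f_t ≡ 1, i_t ≡ α:

    θ_t = θ_{t-1} - α ∇L_t ,

so the learned optimizer strictly generalizes the inner loop of MAML — the
forget gate can shrink parameters that produce large losses and the input
gate acts as a learned, state-dependent learning rate.  (The candidate is
taken as the *negative* gradient so that the frozen-gate mode reproduces
the descent direction exactly; see docs/methods.md on the sign convention.)

Meta-training follows the four-step cycle: (1) the LSTM proposes updated
parameters from the support gradient, with its own weights held fixed
within the T-step unroll; (2) the base learner evaluates the query loss at
the proposed parameters; (3) that loss is backpropagated through the unroll
into the LSTM weights (and into the initial cell state θ_0, which is
itself meta-learned); and (4) the LSTM is updated by plain gradient
descent.  By default the cycle's query loss is attached to *every* update
of the unroll (the sum over steps is minimized), which keeps the learning
signal on early steps from being contracted away; a final-θ-only objective
is available.  The gradients and losses *fed to* the LSTM as input
features are treated as constants during backpropagation, but the
dependence of the candidate on θ is differentiated exactly (per-step
Hessian-vector products) when ``second_order`` is on.

Per-coordinate input features are the preprocessed support gradient and
loss (sign / clamped log-magnitude encoding) plus the current parameter
value; the gate read-out additionally sees the previous gate activations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import base_learner as bl
from .base_learner import ParameterLayout
from .episodes import Episode
from .lstm_core import (
    clip_by_global_norm,
    init_lstm_layer,
    lstm_step_backward,
    lstm_step_forward,
    sgd_step,
    adam_step,
    sigmoid,
    tree_add,
    tree_zeros_like,
)

__all__ = [
    "MetaLSTMConfig",
    "OptimizerState",
    "lstm_cell_update",
    "preprocess_scalars",
    "init_metalstm_params",
    "init_state",
    "read_theta",
    "metalearner_step",
    "run_optimizer",
    "train_metalearner",
    "adapt",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class MetaLSTMConfig:
    """Meta-learner hyperparameters.

    Study settings: two stacked LSTM layers of hidden size 256 with dropout
    0.5 (active only during meta-training), 20 meta-epochs, and learning
    rate 0.005 for both loops — ``alpha0`` sets the input-gate bias so the
    untrained optimizer starts out approximating gradient descent at
    0.005, and ``lr`` is the step size of the gradient descent applied to
    the LSTM itself.
    """

    hidden_size: int = 256
    num_layers: int = 2
    dropout: float = 0.5
    alpha0: float = 0.005
    lr: float = 0.005
    unroll_steps: int = 5
    epochs: int = 20
    episodes_per_epoch: int = 4
    preprocess: bool = True
    preprocess_threshold: float = 10.0
    forget_bias_init: float = 7.0
    second_order: bool = True
    loss_at_every_step: bool = True
    grad_clip: float = 100.0
    use_adam: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.alpha0 <= 0 or not 0 < self.alpha0 < 1:
            raise ValueError("alpha0 must lie in (0, 1)")
        if self.lr <= 0 or self.unroll_steps < 1 or self.epochs < 0:
            raise ValueError("invalid lr / unroll_steps / epochs")

    @property
    def n_features(self) -> int:
        # (grad, loss) each contribute 2 preprocessed channels or 1 raw one,
        # plus the current parameter value
        return (2 + 2 + 1) if self.preprocess else (1 + 1 + 1)


@dataclass
class OptimizerState:
    """Per-coordinate optimizer state.

    ``theta`` is the top-level cell state C carrying the base-learner
    parameters; ``h``/``c`` are the hidden and cell states of the stacked
    LSTM layers (one row per base-learner coordinate); ``f_prev``/``i_prev``
    are the previous gate activations fed back into the gate read-out.
    """

    theta: np.ndarray
    h: list[np.ndarray]
    c: list[np.ndarray]
    f_prev: np.ndarray
    i_prev: np.ndarray
    t: int = 0


def read_theta(state: OptimizerState) -> np.ndarray:
    """The current base-learner parameters — verbatim the cell state C."""
    return state.theta


def lstm_cell_update(
    c_prev: np.ndarray, f: np.ndarray, i: np.ndarray, c_tilde: np.ndarray
) -> np.ndarray:
    """Elementwise cell-state update C = f ⊙ C_prev + i ⊙ C̃."""
    c_prev, f, i, c_tilde = map(np.asarray, (c_prev, f, i, c_tilde))
    if not (c_prev.shape == f.shape == i.shape == c_tilde.shape):
        raise ValueError(
            "shape mismatch in cell update: "
            f"{c_prev.shape}, {f.shape}, {i.shape}, {c_tilde.shape}"
        )
    return f * c_prev + i * c_tilde


def preprocess_scalars(v: np.ndarray, p: float = 10.0) -> np.ndarray:
    """Sign / log-magnitude encoding of optimizer inputs.

    Values spanning many orders of magnitude are mapped to two channels:
    (log|v|/p, sign(v)) when |v| >= e^-p, else (-1, e^p * v).  Keeps inputs
    O(1) without losing the sign or the tiny-gradient regime.
    """
    v = np.asarray(v, dtype=float)
    big = np.abs(v) >= np.exp(-p)
    first = np.where(big, np.log(np.maximum(np.abs(v), 1e-300)) / p, -1.0)
    second = np.where(big, np.sign(v), np.exp(p) * v)
    return np.stack([first, second], axis=-1)


def _logit(q: float) -> float:
    return float(np.log(q / (1.0 - q)))


def init_metalstm_params(
    layout: ParameterLayout, config: MetaLSTMConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Meta-parameters: stacked LSTM weights, gate read-out head, and θ0.

    The forget-gate read-out bias starts large-positive (f ≈ 1) and the
    input-gate bias at logit(alpha0) (i ≈ alpha0), so the untrained
    optimizer approximates gradient descent at the study learning rate.
    """
    params: dict[str, np.ndarray] = {}
    in_size = config.n_features
    for layer in range(config.num_layers):
        params.update(
            init_lstm_layer(rng, in_size, config.hidden_size, f"lstm{layer}")
        )
        in_size = config.hidden_size
    head_in = config.hidden_size + 3  # [h_top, theta, f_prev, i_prev]
    params["wf"] = rng.normal(0.0, 1e-3, (head_in, 1))
    params["bf"] = np.array([config.forget_bias_init])
    params["wi"] = rng.normal(0.0, 1e-3, (head_in, 1))
    params["bi"] = np.array([_logit(config.alpha0)])
    params["theta0"] = bl.init_theta(layout, rng)
    return params


def init_state(params: dict[str, np.ndarray], config: MetaLSTMConfig) -> OptimizerState:
    n = params["theta0"].shape[0]
    hsz = config.hidden_size
    return OptimizerState(
        theta=params["theta0"].copy(),
        h=[np.zeros((n, hsz)) for _ in range(config.num_layers)],
        c=[np.zeros((n, hsz)) for _ in range(config.num_layers)],
        f_prev=np.ones(n),
        i_prev=np.full(n, config.alpha0),
        t=0,
    )


def _build_inputs(
    theta: np.ndarray, g: np.ndarray, loss: float, config: MetaLSTMConfig
) -> np.ndarray:
    n = theta.shape[0]
    if config.preprocess:
        pg = preprocess_scalars(g, config.preprocess_threshold)
        pl = np.tile(
            preprocess_scalars(np.array([loss]), config.preprocess_threshold), (n, 1)
        )
        return np.concatenate([pg, pl, theta[:, None]], axis=1)
    return np.concatenate(
        [g[:, None], np.full((n, 1), loss), theta[:, None]], axis=1
    )


def _step(
    params: dict[str, np.ndarray],
    state: OptimizerState,
    g: np.ndarray,
    loss: float,
    config: MetaLSTMConfig,
    dropout_masks: list[np.ndarray] | None,
):
    """Core learned step; returns (new_state, cache)."""
    theta = state.theta
    z = _build_inputs(theta, g, loss, config)
    x = z
    layer_caches = []
    h_new, c_new = [], []
    masks_used = []
    for layer in range(config.num_layers):
        h, c, cache = lstm_step_forward(
            params, f"lstm{layer}", x, state.h[layer], state.c[layer]
        )
        layer_caches.append(cache)
        h_new.append(h)
        c_new.append(c)
        x = h
        if layer < config.num_layers - 1:
            if dropout_masks is not None:
                mask = dropout_masks[layer]
                x = x * mask
                masks_used.append(mask)
            else:
                masks_used.append(None)
    u = np.concatenate(
        [x, theta[:, None], state.f_prev[:, None], state.i_prev[:, None]], axis=1
    )
    f = sigmoid((u @ params["wf"])[:, 0] + params["bf"][0])
    i = sigmoid((u @ params["wi"])[:, 0] + params["bi"][0])
    theta_next = lstm_cell_update(theta, f, i, -g)
    new_state = OptimizerState(
        theta=theta_next, h=h_new, c=c_new, f_prev=f, i_prev=i, t=state.t + 1
    )
    cache = {
        "z": z,
        "layer_caches": layer_caches,
        "masks": masks_used,
        "u": u,
        "f": f,
        "i": i,
        "theta": theta,
        "g": g,
    }
    return new_state, cache


def metalearner_step(
    params: dict[str, np.ndarray],
    state: OptimizerState,
    g: np.ndarray,
    loss: float,
    config: MetaLSTMConfig,
    mode: str = "learned",
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[OptimizerState, np.ndarray]:
    """One optimizer step: consume (gradient, loss), emit updated parameters.

    ``mode='learned'`` runs the stacked LSTM and gate head.
    ``mode='gd_equivalent'`` freezes the gates (f ≡ 1, i ≡ alpha0,
    candidate ≡ -gradient), which must — and does, exactly — reproduce
    vanilla gradient descent.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != state.theta.shape:
        raise ValueError(
            f"gradient shape {g.shape} does not match state with "
            f"{state.theta.shape[0]} coordinates"
        )
    bad = np.flatnonzero(~np.isfinite(g))
    if bad.size:
        raise FloatingPointError(
            f"non-finite gradient entry at coordinate {int(bad[0])}"
        )
    if mode == "gd_equivalent":
        ones = np.ones_like(state.theta)
        alpha = np.full_like(state.theta, config.alpha0)
        theta_next = lstm_cell_update(state.theta, ones, alpha, -g)
        new_state = OptimizerState(
            theta=theta_next,
            h=[a.copy() for a in state.h],
            c=[a.copy() for a in state.c],
            f_prev=ones,
            i_prev=alpha,
            t=state.t + 1,
        )
        return new_state, theta_next
    if mode != "learned":
        raise ValueError(f"unknown mode {mode!r}")
    new_state, _ = _step(params, state, g, float(loss), config, dropout_masks)
    return new_state, new_state.theta


def _backward_unroll(
    params: dict[str, np.ndarray],
    caches: list[dict],
    dthetas: list[np.ndarray | None],
    config: MetaLSTMConfig,
    task=None,
) -> dict[str, np.ndarray]:
    """Backpropagate a query-loss gradient through the whole unroll.

    The parameter value θ_t — which enters the cell-state update, the input
    features and the gate head — is differentiated exactly, and with
    ``config.second_order`` the dependence of the candidate C̃_t = -∇L(θ_t)
    on θ_t is carried as an exact Hessian-vector product per step (``task``
    must expose ``hvp(theta, v)``), mirroring second-order MAML.  Gradients
    and losses *as LSTM input features* are treated as constants, the
    standard learned-optimizer simplification.  Returns gradients for all
    meta-parameters, including the learned initialization θ0.

    ``dthetas[t]`` is the objective's direct gradient with respect to the
    parameters *emitted* by unroll step t (θ_{t+1}); entries may be None.
    With the per-step query objective every entry is populated, with the
    final-θ objective only the last one is.
    """
    if len(dthetas) != len(caches):
        raise ValueError("need one (possibly None) injection per unroll step")
    grads = tree_zeros_like(params)
    hsz = config.hidden_size
    n_layers = config.num_layers
    theta_col = 4 if config.preprocess else 2
    dtheta = np.zeros_like(params["theta0"])
    dh_carry = [None] * n_layers
    dc_carry = [None] * n_layers
    df_carry = None
    di_carry = None
    for t in range(len(caches) - 1, -1, -1):
        cache = caches[t]
        if dthetas[t] is not None:
            dtheta = dtheta + dthetas[t]
        f, i, theta_t, g = cache["f"], cache["i"], cache["theta"], cache["g"]
        u = cache["u"]
        # cell-state update: theta_{t+1} = f*theta_t + i*(-g(theta_t))
        df = dtheta * theta_t
        di = dtheta * (-g)
        dtheta_t = dtheta * f
        if config.second_order and task is not None:
            # exact curvature of the candidate: d/dθ_t [-i ⊙ g(θ_t)]ᵀ dθ_{t+1}
            dtheta_t = dtheta_t - task.hvp(theta_t, i * dtheta)
        if df_carry is not None:
            df = df + df_carry
            di = di + di_carry
        # gate head
        daf = df * f * (1.0 - f)
        dai = di * i * (1.0 - i)
        grads["wf"] += u.T @ daf[:, None]
        grads["bf"] += np.array([daf.sum()])
        grads["wi"] += u.T @ dai[:, None]
        grads["bi"] += np.array([dai.sum()])
        du = daf[:, None] * params["wf"][:, 0][None, :] + dai[:, None] * params["wi"][:, 0][None, :]
        dh_top = du[:, :hsz]
        dtheta_t = dtheta_t + du[:, hsz]
        df_carry = du[:, hsz + 1]
        di_carry = du[:, hsz + 2]
        # stacked LSTM layers, top down
        dh_above = dh_top
        for layer in range(n_layers - 1, -1, -1):
            dh_in = dh_above
            if dh_carry[layer] is not None:
                dh_in = dh_in + dh_carry[layer]
            dc_in = dc_carry[layer] if dc_carry[layer] is not None else np.zeros_like(dh_in)
            dx, dh_prev, dc_prev = lstm_step_backward(
                params, f"lstm{layer}", cache["layer_caches"][layer], dh_in, dc_in, grads
            )
            dh_carry[layer] = dh_prev
            dc_carry[layer] = dc_prev
            if layer > 0:
                mask = cache["masks"][layer - 1]
                dh_above = dx if mask is None else dx * mask
            else:
                dtheta_t = dtheta_t + dx[:, theta_col]
        dtheta = dtheta_t
    grads["theta0"] += dtheta
    return grads


class _SupportTask:
    """Adapter feeding base-learner support losses/gradients to the unroll."""

    def __init__(self, layout: ParameterLayout, x: np.ndarray, y: np.ndarray):
        self.layout, self.x, self.y = layout, x, y

    def loss_and_grad(self, theta: np.ndarray, t: int) -> tuple[float, np.ndarray]:
        loss, g = bl.loss_and_grad(self.layout, theta, self.x, self.y)
        return float(loss), g

    def hvp(self, theta: np.ndarray, v: np.ndarray) -> np.ndarray:
        return bl.hvp(self.layout, theta, self.x, self.y, v)


def _unroll(
    params: dict[str, np.ndarray],
    task,
    config: MetaLSTMConfig,
    train: bool,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, list[dict]]:
    """Run the T-step adaptation unroll from θ0; returns (θ_T, caches)."""
    state = init_state(params, config)
    caches: list[dict] = []
    n = state.theta.shape[0]
    for t in range(config.unroll_steps):
        loss, g = task.loss_and_grad(state.theta, t)
        g = np.asarray(g, dtype=float)
        bad = np.flatnonzero(~np.isfinite(g))
        if bad.size:
            raise FloatingPointError(
                f"non-finite gradient at unroll step {t}, coordinate {int(bad[0])}"
            )
        masks = None
        if train and config.dropout > 0 and config.num_layers > 1 and rng is not None:
            keep = 1.0 - config.dropout
            masks = [
                (rng.random((n, config.hidden_size)) < keep) / keep
                for _ in range(config.num_layers - 1)
            ]
        state, cache = _step(params, state, g, loss, config, masks)
        caches.append(cache)
    return state.theta, caches


def run_optimizer(
    params: dict[str, np.ndarray],
    layout: ParameterLayout,
    support_x: np.ndarray,
    support_y: np.ndarray,
    config: MetaLSTMConfig,
) -> np.ndarray:
    """Adapt the base learner on a support set (deterministic, no dropout)."""
    task = _SupportTask(layout, support_x, support_y)
    theta, _ = _unroll(params, task, config, train=False, rng=None)
    return theta


def adapt(
    params: dict[str, np.ndarray],
    layout: ParameterLayout,
    episode: Episode,
    config: MetaLSTMConfig,
) -> np.ndarray:
    """Adapt on an episode's support set and predict its query inputs."""
    theta = run_optimizer(params, layout, episode.support_x, episode.support_y, config)
    return bl.forward(layout, theta, episode.query_x)


def train_metalearner(
    layout: ParameterLayout,
    config: MetaLSTMConfig,
    episode_sampler: Callable[[int, int], Sequence[Episode]],
    params: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Meta-train the LSTM optimizer (and its initialization θ0).

    Per epoch: sample episodes, unroll the optimizer on each support set
    with the LSTM weights held fixed, evaluate the query loss at the final
    parameters, backpropagate through the unroll, and apply one (clipped)
    gradient-descent step to the meta-parameters.  Returns the trained
    parameters and the per-epoch mean query loss.  Reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(int(config.seed) % (2**31))
    if params is None:
        params = init_metalstm_params(layout, config, rng)
    else:
        params = {k: v.copy() for k, v in params.items()}
    trajectory: list[float] = []
    adam_state = None
    for epoch in range(config.epochs):
        ep_seed = int(rng.integers(0, 2**31 - 1))
        episodes = episode_sampler(epoch, ep_seed)
        if len(episodes) == 0:
            raise ValueError(f"episode sampler returned nothing at epoch {epoch}")
        total = tree_zeros_like(params)
        q_losses = []
        for ep in episodes:
            task = _SupportTask(layout, ep.support_x, ep.support_y)
            theta_T, caches = _unroll(params, task, config, train=True, rng=rng)
            # parameters emitted by step t: theta_{t+1}
            emitted = [c["theta"] for c in caches[1:]] + [theta_T]
            if config.loss_at_every_step:
                # per-step objective sum_t L_q(theta_t): the query loss is
                # attached to every update of the cycle, which keeps the
                # learning signal on early steps (and on theta0) from being
                # contracted away by the unroll
                dthetas, q_sum = [], 0.0
                for th in emitted:
                    ql, dq = bl.loss_and_grad(layout, th, ep.query_x, ep.query_y)
                    q_sum += float(ql)
                    dthetas.append(dq)
                q_loss = q_sum / len(emitted)
            else:
                ql, dq = bl.loss_and_grad(layout, theta_T, ep.query_x, ep.query_y)
                q_loss = float(ql)
                dthetas = [None] * (len(emitted) - 1) + [dq]
            if not np.isfinite(q_loss):
                raise FloatingPointError(
                    f"non-finite query loss at epoch {epoch} (unroll of "
                    f"{config.unroll_steps} steps)"
                )
            grads = _backward_unroll(params, caches, dthetas, config, task=task)
            total = tree_add(total, grads)
            q_losses.append(float(q_loss))
        total = clip_by_global_norm(total, config.grad_clip)
        if config.use_adam:
            params, adam_state = adam_step(params, total, adam_state, config.lr)
        else:
            params = sgd_step(params, total, config.lr)
        trajectory.append(float(np.mean(q_losses)))
    return params, trajectory


# ---------------------------------------------------------------------------
# serialization: array container + JSON sidecar

def save_params(
    params: dict[str, np.ndarray],
    path: str | Path,
    config: MetaLSTMConfig | None = None,
) -> None:
    """Write weights to an .npz container with a JSON sidecar of the config."""
    path = Path(path)
    np.savez(path, **params)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(config), indent=2))


def load_params(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as data:
        return {k: data[k] for k in data.files}
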