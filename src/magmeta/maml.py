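"""Model-agnostic meta-learning (MAML) for few-shot regression.

The inner loop adapts the base learner to one task by gradient descent on
its support set,

    theta_i' = theta - alpha * grad L_i(f_theta) ,

and the outer loop updates the shared initialization with the gradient of
the summed post-adaptation query losses,

    theta <- theta - beta * grad_theta  sum_i L_i(f_{theta_i'}) .

The outer gradient differentiates *through* the inner update by default
(second order): with K inner steps the meta-gradient is obtained by
reverse-propagating the query gradient through the chain
theta_{k+1} = theta_k - alpha * g(theta_k), each step contributing an exact
Hessian-vector product (complex-step, see :mod:`magmeta.base_learner`).
The cheaper first-order variant drops those curvature terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import base_learner as bl
from .base_learner import ParameterLayout
from .episodes import Episode

__all__ = [
    "MetaTrainConfig",
    "inner_update",
    "meta_gradient",
    "outer_update",
    "meta_train",
    "adapt",
]


@dataclass(frozen=True)
class MetaTrainConfig:
    """Hyperparameters of one meta-training run.

    ``alpha`` is the inner (task-adaptation) step size, ``beta`` the outer
    (meta) step size; both default to the study setting 0.005.  Training
    runs for ``epochs`` outer iterations (study setting 20), sampling
    ``tasks_per_iter`` episodes per iteration.
    """

    alpha: float = 0.005
    beta: float = 0.005
    inner_steps: int = 1
    epochs: int = 20
    tasks_per_iter: int = 4
    second_order: bool = True
    grad_clip: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("step sizes alpha and beta must be positive")
        if self.inner_steps < 1:
            raise ValueError("inner_steps must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.tasks_per_iter < 1:
            raise ValueError("tasks_per_iter must be >= 1")


def inner_update(
    layout: ParameterLayout,
    theta: np.ndarray,
    support_x: np.ndarray,
    support_y: np.ndarray,
    alpha: float,
    steps: int = 1,
    return_trajectory: bool = False,
):
    """Task adaptation: ``steps`` gradient-descent steps on the support loss.

    The input vector is never mutated.  With ``return_trajectory`` the full
    list [theta_0, ..., theta_K] is returned (needed by the second-order
    outer update).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    trajectory = [np.array(theta, dtype=float, copy=True)]
    cur = trajectory[0]
    for _ in range(steps):
        cur = cur - alpha * bl.grad(layout, cur, support_x, support_y)
        trajectory.append(cur)
    return trajectory if return_trajectory else cur


def _task_meta_gradient(
    layout: ParameterLayout,
    theta: np.ndarray,
    episode: Episode,
    alpha: float,
    steps: int,
    second_order: bool,
) -> tuple[np.ndarray, float]:
    """Meta-gradient of one task's post-adaptation query loss w.r.t. theta."""
    trajectory = inner_update(
        layout, theta, episode.support_x, episode.support_y, alpha, steps,
        return_trajectory=True,
    )
    adapted = trajectory[-1]
    q_loss, v = bl.loss_and_grad(layout, adapted, episode.query_x, episode.query_y)
    if second_order:
        # reverse through theta_{k+1} = theta_k - alpha * g(theta_k):
        # v <- (I - alpha * H(theta_k)) v at each inner step
        for theta_k in reversed(trajectory[:-1]):
            v = v - alpha * bl.hvp(
                layout, theta_k, episode.support_x, episode.support_y, v
            )
    return v, float(q_loss)


def meta_gradient(
    layout: ParameterLayout,
    theta: np.ndarray,
    episodes: Sequence[Episode],
    alpha: float,
    steps: int = 1,
    second_order: bool = True,
) -> tuple[np.ndarray, float]:
    """Summed meta-gradient over tasks and the mean query loss."""
    if len(episodes) == 0:
        raise ValueError("meta_gradient needs at least one task")
    total = np.zeros_like(np.asarray(theta, dtype=float))
    losses = []
    for ep in episodes:
        g, ql = _task_meta_gradient(layout, theta, ep, alpha, steps, second_order)
        total += g
        losses.append(ql)
    return total, float(np.mean(losses))


def outer_update(
    layout: ParameterLayout,
    theta: np.ndarray,
    episodes: Sequence[Episode],
    alpha: float,
    beta: float,
    steps: int = 1,
    second_order: bool = True,
) -> np.ndarray:
    """One meta-step: theta - beta * grad of the summed query losses."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    g, _ = meta_gradient(layout, theta, episodes, alpha, steps, second_order)
    return np.asarray(theta, dtype=float) - beta * g


def meta_train(
    layout: ParameterLayout,
    config: MetaTrainConfig,
    task_sampler: Callable[[int, int], Sequence[Episode]],
    theta0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Full MAML training loop.

    ``task_sampler(epoch, seed)`` returns the episodes for one outer
    iteration (redrawn every iteration).  Returns the final initialization
    and the per-epoch mean post-adaptation query loss.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(int(config.seed) % (2**31))
    if theta0 is None:
        theta0 = bl.init_theta(layout, rng)
    theta = np.array(theta0, dtype=float, copy=True)
    trajectory: list[float] = []
    for epoch in range(config.epochs):
        ep_seed = int(rng.integers(0, 2**31 - 1))
        episodes = task_sampler(epoch, ep_seed)
        if len(episodes) == 0:
            raise ValueError(f"task sampler returned no episodes at epoch {epoch}")
        g, mean_q_loss = meta_gradient(
            layout, theta, episodes, config.alpha, config.inner_steps,
            config.second_order,
        )
        # meta-gradient norm clipping: the second-order factor (I - alpha H)
        # can amplify an unlucky initialization into divergence
        if config.grad_clip > 0:
            norm = float(np.linalg.norm(g))
            if norm > config.grad_clip:
                g = g * (config.grad_clip / norm)
        theta = theta - config.beta * g
        trajectory.append(mean_q_loss)
    return theta, trajectory


def adapt(
    layout: ParameterLayout,
    theta: np.ndarray,
    episode: Episode,
    alpha: float,
    steps: int = 1,
) -> np.ndarray:
    """Adapt on an episode's support set and predict its query inputs."""
    adapted = inner_update(
        layout, theta, episode.support_x, episode.support_y, alpha, steps
    )
    return bl.forward(layout, adapted, episode.query_x)
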