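"""MAML: inner-loop closed form, second-order meta-gradient, training benefit."""

import numpy as np
import pytest

from magmeta import base_learner as bl
from magmeta import maml
from magmeta.episodes import Episode, sample_episode


def _episode(rng, layout, ns=5, nq=4):
    return Episode(
        rng.random(ns), rng.random(ns), rng.random(nq), rng.random(nq),
        "static", "static",
    )


class TestInnerUpdate:
    def test_single_step_equals_closed_form(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        x, y = rng.random(6), rng.random(6)
        adapted = maml.inner_update(tiny_layout, theta, x, y, alpha=0.01, steps=1)
        closed = theta - 0.01 * bl.grad(tiny_layout, theta, x, y)
        assert np.allclose(adapted, closed, atol=1e-15)

    def test_perfectly_fit_support_is_a_fixed_point(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        x = rng.random(6)
        y = bl.forward(tiny_layout, theta, x)
        adapted = maml.inner_update(tiny_layout, theta, x, y, alpha=0.1, steps=3)
        assert np.allclose(adapted, theta)

    def test_input_vector_not_mutated(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        before = theta.copy()
        maml.inner_update(tiny_layout, theta, rng.random(4), rng.random(4), 0.05, 2)
        assert np.array_equal(theta, before)

    def test_multi_step_composes_single_steps(self, tiny_layout, rng):
        # geometric-contraction check: k steps equal k composed single steps
        theta = bl.init_theta(tiny_layout, rng)
        x, y = rng.random(6), rng.random(6)
        three = maml.inner_update(tiny_layout, theta, x, y, alpha=0.01, steps=3)
        one_by_one = theta
        for _ in range(3):
            one_by_one = maml.inner_update(tiny_layout, one_by_one, x, y, 0.01, 1)
        assert np.allclose(three, one_by_one, atol=1e-15)


class TestMetaGradient:
    def test_zero_beta_leaves_theta_unchanged(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        ep = _episode(rng, tiny_layout)
        out = maml.outer_update(tiny_layout, theta, [ep], alpha=0.05, beta=0.0)
        assert np.allclose(out, theta)

    def test_two_identical_tasks_double_the_gradient(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        ep = _episode(rng, tiny_layout)
        g1, _ = maml.meta_gradient(tiny_layout, theta, [ep], alpha=0.05)
        g2, _ = maml.meta_gradient(tiny_layout, theta, [ep, ep], alpha=0.05)
        assert np.allclose(g2, 2 * g1, rtol=1e-12)

    @pytest.mark.parametrize("steps", [1, 2, 3])
    def test_second_order_matches_finite_differences(self, steps, rng):
        # toy 1-3 parameter regimes: tiny net, FD through the inner loop
        layout = bl.ParameterLayout((1, 2, 1))
        theta = bl.init_theta(layout, rng)
        ep = _episode(rng, layout)
        g, _ = maml.meta_gradient(layout, theta, [ep], alpha=0.05, steps=steps)

        def query_after_adaptation(t):
            adapted = maml.inner_update(layout, t, ep.support_x, ep.support_y, 0.05, steps)
            return bl.mse_loss(layout, adapted, ep.query_x, ep.query_y)

        h = 1e-5
        for i in range(layout.n_params):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (query_after_adaptation(tp) - query_after_adaptation(tm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_first_order_drops_curvature(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng)
        ep = _episode(rng, tiny_layout)
        adapted = maml.inner_update(tiny_layout, theta, ep.support_x, ep.support_y, 0.05)
        fo, _ = maml.meta_gradient(tiny_layout, theta, [ep], 0.05, second_order=False)
        assert np.allclose(fo, bl.grad(tiny_layout, adapted, ep.query_x, ep.query_y))


class TestMetaTrain:
    def test_zero_epochs_is_a_noop(self, tiny_layout):
        config = maml.MetaTrainConfig(epochs=0, seed=1)
        theta, trajectory = maml.meta_train(tiny_layout, config, lambda e, s: [])
        assert trajectory == []

    def test_same_seed_gives_identical_trajectories(self, tiny_layout, sigma_static):
        config = maml.MetaTrainConfig(epochs=4, tasks_per_iter=2, seed=42)
        sampler = lambda e, s: [sample_episode(sigma_static, sigma_static, 10, 5, s)]
        t1, l1 = maml.meta_train(tiny_layout, config, sampler)
        t2, l2 = maml.meta_train(tiny_layout, config, sampler)
        assert np.array_equal(t1, t2)
        assert l1 == l2

    def test_meta_training_beats_random_initialization(self, sigma_static):
        """Control experiment: post-adaptation query MSE (10-shot, 1 inner
        step) after meta-training is below that of the un-meta-trained
        initialization adapted identically, median over 20 seeds."""
        layout = bl.ParameterLayout((1, 8, 1))
        mu = np.mean([m.value for m in sigma_static])
        sdv = np.std([m.value for m in sigma_static])
        from dataclasses import replace as dc_replace

        pool = [dc_replace(m, value=(m.value - mu) / sdv) for m in sigma_static]
        diffs = []
        for seed in range(20):
            config = maml.MetaTrainConfig(epochs=10, tasks_per_iter=2, seed=seed)
            sampler = lambda e, s: [
                sample_episode(pool, pool, 10, 5, s + k, task_id=k) for k in range(2)
            ]
            rng_local = np.random.default_rng(seed)
            theta0 = bl.init_theta(layout, rng_local)
            trained, _ = maml.meta_train(layout, config, sampler, theta0=theta0)
            eval_ep = sample_episode(pool, pool, 10, 5, 10_000 + seed)
            losses = {}
            for name, start in (("random", theta0), ("trained", trained)):
                adapted = maml.inner_update(
                    layout, start, eval_ep.support_x, eval_ep.support_y, 0.005, 1
                )
                losses[name] = bl.mse_loss(layout, adapted, eval_ep.query_x, eval_ep.query_y)
            diffs.append(losses["trained"] - losses["random"])
        assert np.median(diffs) < 0.0

    def test_gradient_clipping_bounds_the_step(self, tiny_layout, rng):
        theta = bl.init_theta(tiny_layout, rng) * 50  # force a huge meta-gradient
        ep = _episode(rng, tiny_layout)
        config = maml.MetaTrainConfig(epochs=1, tasks_per_iter=1, grad_clip=1.0, seed=0)
        out, _ = maml.meta_train(tiny_layout, config, lambda e, s: [ep], theta0=theta)
        assert np.linalg.norm(out - theta) <= config.beta * config.grad_clip + 1e-12
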