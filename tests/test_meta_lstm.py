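"""LSTM optimizer: gradient-descent subsumption, unroll backprop, training."""

from dataclasses import replace

import numpy as np
import pytest

from magmeta import base_learner as bl
from magmeta import meta_lstm as ml
from magmeta.episodes import sample_episode


class _ConstantGradientTask:
    """Injected task whose per-step gradients ignore theta.

    With gradients independent of the parameters, the learned-optimizer
    convention of holding input gradients constant during backprop is exact,
    so finite differences of the unrolled objective must match the hand
    backward pass to machine precision.
    """

    def __init__(self, grads, losses):
        self.grads, self.losses = grads, losses

    def loss_and_grad(self, theta, t):
        return self.losses[t], self.grads[t]

    def hvp(self, theta, v):
        return np.zeros_like(v)


@pytest.fixture()
def small_config():
    return ml.MetaLSTMConfig(hidden_size=6, num_layers=2, dropout=0.0, unroll_steps=3, seed=3)


class TestCellUpdate:
    def test_full_retention(self, rng):
        c = rng.normal(size=5)
        out = ml.lstm_cell_update(c, np.ones(5), np.zeros(5), rng.normal(size=5))
        assert np.array_equal(out, c)

    def test_full_replacement(self, rng):
        cand = rng.normal(size=5)
        out = ml.lstm_cell_update(rng.normal(size=5), np.zeros(5), np.ones(5), cand)
        assert np.array_equal(out, cand)

    def test_frozen_gates_realize_gradient_descent(self, rng):
        theta, g = rng.normal(size=8), rng.normal(size=8)
        alpha = 0.005
        out = ml.lstm_cell_update(theta, np.ones(8), np.full(8, alpha), -g)
        assert np.allclose(out, theta - alpha * g, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ml.lstm_cell_update(np.zeros(3), np.zeros(4), np.zeros(3), np.zeros(3))


class TestGdEquivalentMode:
    def test_twenty_step_trajectory_on_quadratic(self, small_config):
        """Frozen gates reproduce the vanilla-GD trajectory of the isotropic
        quadratic L = ||theta||^2 to 1e-6 per coordinate over 20 steps."""
        rng = np.random.default_rng(0)
        layout = bl.ParameterLayout((1, 2, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        state = ml.init_state(params, small_config)
        theta_gd = params["theta0"].copy()
        for _ in range(20):
            cur = ml.read_theta(state)
            g = 2.0 * cur  # gradient of ||theta||^2
            state, theta = ml.metalearner_step(
                params, state, g, float(np.sum(cur**2)), small_config,
                mode="gd_equivalent",
            )
            theta_gd = theta_gd - small_config.alpha0 * 2.0 * theta_gd
            assert np.max(np.abs(theta - theta_gd)) < 1e-6

    def test_twenty_step_trajectory_on_small_network(self, small_config, rng):
        layout = bl.ParameterLayout((1, 4, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        x, y = rng.random(8), rng.random(8)
        state = ml.init_state(params, small_config)
        theta_gd = params["theta0"].copy()
        for _ in range(20):
            loss, g = bl.loss_and_grad(layout, ml.read_theta(state), x, y)
            state, theta = ml.metalearner_step(
                params, state, g, loss, small_config, mode="gd_equivalent"
            )
            theta_gd = theta_gd - small_config.alpha0 * bl.grad(layout, theta_gd, x, y)
            assert np.max(np.abs(theta - theta_gd)) < 1e-6

    def test_zero_gradient_is_a_fixed_point(self, small_config, rng):
        layout = bl.ParameterLayout((1, 2, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        state = ml.init_state(params, small_config)
        before = ml.read_theta(state).copy()
        state, theta = ml.metalearner_step(
            params, state, np.zeros_like(before), 0.0, small_config, mode="gd_equivalent"
        )
        assert np.array_equal(theta, before)


class TestOptimizerState:
    def test_state_carries_theta_after_every_step(self, small_config, rng):
        layout = bl.ParameterLayout((1, 3, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        state = ml.init_state(params, small_config)
        for mode in ("learned", "gd_equivalent"):
            g = rng.normal(size=layout.n_params)
            state, theta = ml.metalearner_step(params, state, g, 0.4, small_config, mode=mode)
            assert ml.read_theta(state) is state.theta
            assert np.array_equal(ml.read_theta(state), theta)

    def test_initial_cell_state_is_theta0(self, small_config, rng):
        layout = bl.ParameterLayout((1, 3, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        state = ml.init_state(params, small_config)
        assert np.array_equal(ml.read_theta(state), params["theta0"])

    def test_non_finite_gradient_names_the_coordinate(self, small_config, rng):
        layout = bl.ParameterLayout((1, 3, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        state = ml.init_state(params, small_config)
        g = np.zeros(layout.n_params)
        g[4] = np.nan
        with pytest.raises(FloatingPointError, match="coordinate 4"):
            ml.metalearner_step(params, state, g, 0.0, small_config)

    def test_coordinate_permutation_equivariance(self, small_config, rng):
        """Shared per-coordinate weights: permuting the parameter order
        permutes the update and nothing else."""
        layout = bl.ParameterLayout((1, 3, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        g = rng.normal(size=layout.n_params)
        perm = rng.permutation(layout.n_params)

        state = ml.init_state(params, small_config)
        _, theta_plain = ml.metalearner_step(params, state, g, 0.3, small_config)

        params_p = dict(params)
        params_p["theta0"] = params["theta0"][perm]
        state_p = ml.init_state(params_p, small_config)
        _, theta_perm = ml.metalearner_step(params_p, state_p, g[perm], 0.3, small_config)
        assert np.allclose(theta_perm, theta_plain[perm], atol=1e-12)


class TestUnrollBackprop:
    @pytest.mark.parametrize("every_step", [False, True])
    def test_matches_finite_differences_with_injected_task(self, every_step, small_config):
        config = replace(small_config, loss_at_every_step=every_step)
        rng = np.random.default_rng(4)
        layout = bl.ParameterLayout((1, 2, 1))
        params = ml.init_metalstm_params(layout, config, rng)
        # O(1) head weights so every path carries measurable gradient
        params["wf"] = rng.normal(0, 0.5, params["wf"].shape)
        params["wi"] = rng.normal(0, 0.5, params["wi"].shape)
        task = _ConstantGradientTask(
            [rng.normal(size=layout.n_params) * 0.5 for _ in range(3)], [0.7, 0.4, 0.2]
        )
        qx, qy = rng.random(4), rng.random(4)

        def objective(p):
            theta_T, caches = ml._unroll(p, task, config, train=False, rng=None)
            emitted = [c["theta"] for c in caches[1:]] + [theta_T]
            if every_step:
                return sum(bl.mse_loss(layout, th, qx, qy) for th in emitted)
            return bl.mse_loss(layout, emitted[-1], qx, qy)

        theta_T, caches = ml._unroll(params, task, config, train=False, rng=None)
        emitted = [c["theta"] for c in caches[1:]] + [theta_T]
        if every_step:
            dthetas = [bl.loss_and_grad(layout, th, qx, qy)[1] for th in emitted]
        else:
            dthetas = [None] * 2 + [bl.loss_and_grad(layout, emitted[-1], qx, qy)[1]]
        grads = ml._backward_unroll(params, caches, dthetas, config, task=task)

        h = 1e-6
        for key in params:
            fd = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                pp = {k: v.copy() for k, v in params.items()}
                pm = {k: v.copy() for k, v in params.items()}
                pp[key][idx] += h
                pm[key][idx] -= h
                fd[idx] = (objective(pp) - objective(pm)) / (2 * h)
            scale = np.max(np.abs(fd)) + 1e-12
            assert np.max(np.abs(grads[key] - fd)) / scale < 1e-4, key


class TestTraining:
    def test_zero_epochs_is_a_noop(self, small_config):
        layout = bl.ParameterLayout((1, 3, 1))
        config = replace(small_config, epochs=0)
        params, trajectory = ml.train_metalearner(layout, config, lambda e, s: [])
        assert trajectory == []

    def test_same_seed_gives_identical_runs(self, sigma_static):
        layout = bl.ParameterLayout((1, 4, 1))
        config = ml.MetaLSTMConfig(
            hidden_size=8, epochs=3, episodes_per_epoch=1, unroll_steps=2, seed=5
        )
        sampler = lambda e, s: [sample_episode(sigma_static, sigma_static, 10, 5, s)]
        p1, l1 = ml.train_metalearner(layout, config, sampler)
        p2, l2 = ml.train_metalearner(layout, config, sampler)
        assert l1 == l2
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)

    def test_training_reduces_query_loss(self, sigma_static):
        """Final-epoch mean query loss below first-epoch loss, median over
        10 seeds, on standardized study-scale data at reduced size."""
        from dataclasses import replace as dc_replace

        mu = np.mean([m.value for m in sigma_static])
        sdv = np.std([m.value for m in sigma_static])
        pool = [dc_replace(m, value=(m.value - mu) / sdv) for m in sigma_static]
        layout = bl.ParameterLayout((1, 8, 1))
        deltas = []
        for seed in range(10):
            config = ml.MetaLSTMConfig(
                hidden_size=16, epochs=20, episodes_per_epoch=2, seed=seed
            )
            sampler = lambda e, s: [
                sample_episode(pool, pool, 20, 10, s + k, task_id=k) for k in range(2)
            ]
            _, trajectory = ml.train_metalearner(layout, config, sampler)
            assert len(trajectory) == 20
            deltas.append(trajectory[-1] - trajectory[0])
        assert np.median(deltas) < 0.0

    def test_evaluation_is_dropout_free_and_deterministic(self, sigma_static):
        layout = bl.ParameterLayout((1, 4, 1))
        config = ml.MetaLSTMConfig(hidden_size=8, dropout=0.5, epochs=1, seed=2)
        sampler = lambda e, s: [sample_episode(sigma_static, sigma_static, 10, 5, s)]
        params, _ = ml.train_metalearner(layout, config, sampler)
        ep = sample_episode(sigma_static, sigma_static, 10, 5, 77)
        a = ml.adapt(params, layout, ep, config)
        b = ml.adapt(params, layout, ep, config)
        assert np.array_equal(a, b)


class TestSerialization:
    def test_save_load_roundtrip_with_sidecar(self, tmp_path, small_config, rng):
        layout = bl.ParameterLayout((1, 3, 1))
        params = ml.init_metalstm_params(layout, small_config, rng)
        path = tmp_path / "weights.npz"
        ml.save_params(params, path, config=small_config)
        back = ml.load_params(path)
        assert all(np.array_equal(params[k], back[k]) for k in params)
        sidecar = path.with_suffix(".npz.json")
        assert sidecar.exists()
        import json

        meta = json.loads(sidecar.read_text())
        assert meta["hidden_size"] == small_config.hidden_size
        assert meta["seed"] == small_config.seed
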