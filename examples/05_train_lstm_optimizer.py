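"""Train the LSTM optimizer — the model whose cell state carries θ.

First shows the gradient-descent subsumption: with frozen gates (f=1,
i=alpha, candidate=-gradient) the optimizer's cell-state update reproduces
vanilla gradient descent exactly.  Then meta-trains the full learned
optimizer on surface-tension episodes and adapts to a held-out task.
"""

from dataclasses import replace

import numpy as np

from magmeta import base_learner as bl
from magmeta import meta_lstm as ml
from magmeta.episodes import sample_episode, split_train_test
from magmeta.metrics import mape
from magmeta.synthetic import filter_records, generate_study_dataset, study_preset

# --- gradient-descent subsumption -----------------------------------------
layout = bl.ParameterLayout((1, 6, 1))
config = ml.MetaLSTMConfig(hidden_size=16, seed=0)
rng = np.random.default_rng(0)
params = ml.init_metalstm_params(layout, config, rng)
x, y = rng.random(12), rng.random(12)
state = ml.init_state(params, config)
theta_gd = params["theta0"].copy()
worst = 0.0
for _ in range(20):
    loss, g = bl.loss_and_grad(layout, ml.read_theta(state), x, y)
    state, theta = ml.metalearner_step(params, state, g, loss, config, mode="gd_equivalent")
    theta_gd = theta_gd - config.alpha0 * bl.grad(layout, theta_gd, x, y)
    worst = max(worst, float(np.max(np.abs(theta - theta_gd))))
print(f"frozen-gate optimizer vs vanilla GD, 20 steps: max |Δθ| = {worst:.2e}")

# --- meta-training on episodes --------------------------------------------
records = generate_study_dataset(study_preset(seed=0))
sigma = filter_records(records, property="sigma", domain="static")[:100]
train, test = split_train_test(sigma, fraction=0.8, seed=1)
mu = float(np.mean([m.value for m in train]))
sd = float(np.std([m.value for m in train]))
train_z = [replace(m, value=(m.value - mu) / sd) for m in train]
test_z = [replace(m, value=(m.value - mu) / sd) for m in test]

layout = bl.ParameterLayout((1, 16, 16, 1))
config = ml.MetaLSTMConfig(hidden_size=64, epochs=20, seed=0)
sampler = lambda epoch, seed: [
    sample_episode(train_z, train_z, 40, 10, seed + k, task_id=k) for k in range(4)
]
params, trajectory = ml.train_metalearner(layout, config, sampler)
print("mean per-step query loss per epoch:")
print("  " + " ".join(f"{v:6.2f}" for v in trajectory))

episode = sample_episode(test_z, test_z, ns=10, nq=5, seed=99)
pred_z = ml.adapt(params, layout, episode, config)
y_true = episode.query_y * sd + mu
y_pred = pred_z * sd + mu
print(f"held-out episode ({config.unroll_steps}-step unroll): MAPE = {mape(y_true, y_pred):.2f}%")
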