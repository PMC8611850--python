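# magmeta

Few-shot meta-learning for regression of magnetized water-and-fertilizer
physico-chemical properties — MAML, an LSTM *learned optimizer* that
replaces MAML's gradient-descent inner loop, a plain LSTM forecaster
baseline, and a physics-informed synthetic data generator, all runnable end
to end with no external data.

## The problem

Magnetized irrigation water measurably changes a solution's surface tension
σ (N/m), viscosity η (mPa·s), conductivity EC (µS/cm) and pH as the applied
field strength is stepped over a 0–450 mT grid. Collecting such data is
slow and expensive — especially for solution magnetized *while flowing*
(the "dynamic" domain, as in real irrigation), so samples number in the
dozens, far too few for direct deep learning. The package targets exactly
this regime: predict a property's magnetization response from a handful of
measurements by learning across episodes, and adapt from the data-rich
static domain to the scarce, shifted dynamic domain.

## Models

**Base learner.** A small fully connected network f_θ mapping normalized
field strength x = B/450 to a property value, with the summed squared task
loss L_T(f_θ) = Σ_j ‖f_θ(x_j) − y_j‖². Parameters live in one flat vector;
gradients are exact (backpropagation), and Hessian-vector products are
exact too (complex-step differentiation of the gradient).

**MAML** (`magmeta.maml`). Inner loop θ_i′ = θ − α ∇_θ L_i(f_θ) on each
episode's support set; outer loop θ ← θ − β ∇_θ Σ_i L_i(f_{θ_i′}) on the
query sets, differentiated through the inner step (second order) by
default. α = β = 0.005, 20 epochs.

**LSTM optimizer** (`magmeta.meta_lstm`) — the core model. A two-layer LSTM
applied per coordinate with shared weights emits a forget gate f_t and an
input gate i_t each adaptation step, and the base-learner parameters are
updated through the cell-state equation

```
C_t = f_t ⊙ C_{t−1} + i_t ⊙ C̃_t ,   C_{t−1} = θ_{t−1} ,   C̃_t = −∇L_t ,
```

so the cell state *is* the parameter vector and gradient descent is the
frozen-gate special case (f ≡ 1, i ≡ α) — verified to 1e−6 over 20-step
trajectories. The optimizer (including its initial cell state θ_0) is
meta-trained by backpropagating the query loss of every update of a T-step
support unroll into the LSTM weights, which are themselves updated by plain
gradient descent at 0.005.

**LSTM forecaster** (`magmeta.baseline_lstm`). The deep-learning baseline:
a two-layer LSTM (hidden 256, dropout 0.5) trained directly on one domain's
per-level mean series to predict the last 4 field groups (300–450 mT) from
the first 6 (0–250 mT).

**Metrics** (`magmeta.metrics`): MAE = (1/n) Σ|ŷ−y|, MAPE = (100%/n)
Σ|(ŷ−y)/y|, and average accuracy A = fraction of predictions within a
relative tolerance τ (default 0.05), swept against support-set capacity
N_s ∈ {1, 5, 10}.

## Worked example

`examples/06_compare_models.py` runs the full study protocol on one seed —
generate the synthetic dataset, select 100 static surface-tension records,
split 90/10 (forecaster) and 80/20 with 40/10 and 10/5 support/query
episodes (meta-learners), train everything for 20 epochs at learning rate
0.005 — and prints:

```
model       MAE (% of mean)   MAPE (%)   accuracy(tau=0.05)
lstm                 94.172     94.279                0.000
maml                  1.928      1.910                0.960
metalstm              1.781      1.782                0.960
```

The forecaster, trained directly on the raw series for 20 epochs, barely
moves from its initialization (~94% error); both meta-learners adapt to
held-out episodes within ~2% — close to the ~1.1% replicate-noise floor —
with the learned optimizer slightly ahead of MAML. The other examples each
demonstrate one capability: data generation, the instrument forward models,
episode sampling, MAML training, the LSTM optimizer (including its
gradient-descent subsumption), and the single-/cross-domain accuracy sweep.

A thin CLI wraps the same library calls:

```bash
magmeta generate --seed 0 --out data.csv
magmeta compare --seed 1 --outdir out/
magmeta accuracy-sweep --seed 1
```

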