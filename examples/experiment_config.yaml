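# Example experiment configuration for the magmeta CLI
# (magmeta compare --config examples/experiment_config.yaml --seed 1).
# Field names mirror the study's hyperparameter table; omitted keys keep
# their defaults.
property: sigma
domain_mode: single
models: [lstm, maml, metalstm]

# dataset bookkeeping
total_n: 100
lstm_train_fraction: 0.9
meta_train_fraction: 0.8
ns_train: 40
nq_train: 10
ns_test: 10
nq_test: 5

# shared model settings
num_epochs: 20
update_lr: 0.005
dropout: 0.5
hidden_size: 256
num_layers: 2

# evaluation
tau: 0.05
seed: 0
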