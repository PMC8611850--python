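"""Split a dataset into pools and sample a support/query episode.

Reproduces the study's bookkeeping: 100 surface-tension records, an 80/20
train/test split, then a 40-support/10-query episode from the training pool
(support and query are index-disjoint).
"""

from magmeta.episodes import sample_episode, split_train_test
from magmeta.synthetic import filter_records, generate_study_dataset, study_preset

records = generate_study_dataset(study_preset(seed=0))
sigma = filter_records(records, property="sigma", domain="static")[:100]

train, test = split_train_test(sigma, fraction=0.8, seed=1)
print(f"total {len(sigma)} -> train {len(train)} / test {len(test)}")

episode = sample_episode(train, train, ns=40, nq=10, seed=2)
print(f"episode: {episode.n_support} support + {episode.n_query} query pairs")
print(f"  x (normalized field) range: {episode.support_x.min():.2f}-{episode.support_x.max():.2f}")
print(f"  y (sigma, N/m) range:       {episode.support_y.min():.4f}-{episode.support_y.max():.4f}")
print("support adapts the base learner; query measures (and meta-trains) it")
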