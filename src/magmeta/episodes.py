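"""Train/test splitting and episodic support/query sampling.

An *episode* is one regression task instance: a support set used to adapt
the base learner and a disjoint query set used to evaluate (and, during
meta-training, to update) the meta-learner.  Inputs are field strengths
normalized by the top of the measurement grid (450 mT) so that the network
sees values in [0, 1]; targets are the raw property values.

Single-domain episodes draw support and query from the same pool with
disjoint record indices.  Cross-domain episodes draw the support from the
static pool and the query from the (shifted) dynamic pool, emulating
adaptation measured at rest but deployed on flowing solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import FIELD_GRID_MT, PropertyMeasurement

__all__ = [
    "MAX_FIELD_MT",
    "Episode",
    "SplitSpec",
    "normalize_field",
    "denormalize_field",
    "split_train_test",
    "sample_episode",
    "episode_to_frame",
    "forecast_split",
]

#: Normalization constant: the top of the study's field grid.
MAX_FIELD_MT = float(FIELD_GRID_MT[-1])

#: Forecasting protocol: predict the last 4 field groups from the first 6.
FORECAST_WINDOW_LEVELS = FIELD_GRID_MT[:6]   # 0–250 mT
FORECAST_HORIZON_LEVELS = FIELD_GRID_MT[6:]  # 300–450 mT


def normalize_field(field_mT: np.ndarray | float) -> np.ndarray | float:
    """Map field strength (mT) into [0, 1] by dividing by 450."""
    return np.asarray(field_mT, dtype=float) / MAX_FIELD_MT


def denormalize_field(x: np.ndarray | float) -> np.ndarray | float:
    return np.asarray(x, dtype=float) * MAX_FIELD_MT


@dataclass(frozen=True)
class Episode:
    """One sampled task: support pairs for adaptation, query pairs for evaluation."""

    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    support_domain: str
    query_domain: str
    task_id: int = 0

    @property
    def n_support(self) -> int:
        return int(self.support_x.shape[0])

    @property
    def n_query(self) -> int:
        return int(self.query_x.shape[0])


@dataclass(frozen=True)
class SplitSpec:
    """Episode bookkeeping for one experiment (pool fractions and set sizes)."""

    train_fraction: float = 0.8
    ns_train: int = 40
    nq_train: int = 10
    ns_test: int = 10
    nq_test: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        for name in ("ns_train", "nq_train", "ns_test", "nq_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


def split_train_test(
    records: Sequence[PropertyMeasurement], fraction: float, seed: int
) -> tuple[list[PropertyMeasurement], list[PropertyMeasurement]]:
    """Seeded shuffle-split into disjoint train/test pools.

    The train pool receives round(fraction * n) records (round half up);
    together the pools partition the input exactly.
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty record list")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(records)
    n_train = int(math.floor(fraction * n + 0.5))  # round half up
    rng = np.random.default_rng(int(seed) % (2**31))
    perm = rng.permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


def _pairs(records: Sequence[PropertyMeasurement]) -> tuple[np.ndarray, np.ndarray]:
    x = normalize_field(np.array([m.field_mT for m in records], dtype=float))
    y = np.array([m.value for m in records], dtype=float)
    return np.asarray(x), y


def sample_episode(
    support_pool: Sequence[PropertyMeasurement],
    query_pool: Sequence[PropertyMeasurement],
    ns: int,
    nq: int,
    seed: int,
    replace: bool = False,
    task_id: int = 0,
) -> Episode:
    """Draw one episode.

    When support and query come from the same pool the two index sets are
    disjoint.  Without replacement (the default) the pool must be large
    enough; with ``replace=True`` indices may repeat, which permits query
    sets larger than a very small pool.
    """
    if len(support_pool) == 0 or len(query_pool) == 0:
        raise ValueError("episode pools must be non-empty")
    rng = np.random.default_rng(int(seed) % (2**31))
    same_pool = support_pool is query_pool or (
        len(support_pool) == len(query_pool) and all(a is b for a, b in zip(support_pool, query_pool))
    )
    if same_pool:
        if not replace:
            if ns + nq > len(support_pool):
                raise ValueError(
                    f"cannot draw {ns} support + {nq} query records without "
                    f"replacement from a pool of {len(support_pool)}"
                )
            idx = rng.choice(len(support_pool), size=ns + nq, replace=False)
            s_idx, q_idx = idx[:ns], idx[ns:]
        else:
            idx = rng.permutation(len(support_pool))
            if ns + nq <= len(support_pool):
                s_idx, q_idx = idx[:ns], idx[ns : ns + nq]
            else:
                # keep support/query disjoint, fill sizes by resampling inside
                # each half
                half = idx[: len(idx) // 2], idx[len(idx) // 2 :]
                s_idx = rng.choice(half[0], size=ns, replace=True)
                q_idx = rng.choice(half[1], size=nq, replace=True)
        support = [support_pool[i] for i in s_idx]
        query = [query_pool[i] for i in q_idx]
    else:
        if not replace and ns > len(support_pool):
            raise ValueError(
                f"support pool has {len(support_pool)} records, need {ns} "
                "without replacement"
            )
        if not replace and nq > len(query_pool):
            raise ValueError(
                f"query pool has {len(query_pool)} records, need {nq} "
                "without replacement"
            )
        s_idx = rng.choice(len(support_pool), size=ns, replace=replace)
        q_idx = rng.choice(len(query_pool), size=nq, replace=replace)
        support = [support_pool[i] for i in s_idx]
        query = [query_pool[i] for i in q_idx]
    sx, sy = _pairs(support)
    qx, qy = _pairs(query)
    dom = lambda recs: recs[0].domain if len({m.domain for m in recs}) == 1 else "mixed"
    return Episode(sx, sy, qx, qy, dom(support), dom(query), task_id=task_id)


def episode_to_frame(episode: Episode):
    """Serialize an episode to the measurement-CSV schema plus role/task_id.

    Columns: x (normalized field), field_mT, value, domain, role
    (support/query), task_id.
    """
    import pandas as pd

    rows = []
    for role, xs, ys, dom in (
        ("support", episode.support_x, episode.support_y, episode.support_domain),
        ("query", episode.query_x, episode.query_y, episode.query_domain),
    ):
        for x, y in zip(np.atleast_1d(xs), np.atleast_1d(ys)):
            rows.append(
                {
                    "x": float(x),
                    "field_mT": float(denormalize_field(x)),
                    "value": float(y),
                    "domain": dom,
                    "role": role,
                    "task_id": episode.task_id,
                }
            )
    return pd.DataFrame(rows)


def forecast_split(
    records: Sequence[PropertyMeasurement],
) -> tuple[dict[float, np.ndarray], dict[float, np.ndarray]]:
    """Group a series by field level and split into forecasting input/target.

    Input groups cover 0–250 mT (6 levels), target groups 300–450 mT
    (4 levels).  Every grid level must be represented; the error names the
    absent levels.
    """
    by_level: dict[float, list[float]] = {lvl: [] for lvl in FIELD_GRID_MT}
    extra = sorted({m.field_mT for m in records} - set(FIELD_GRID_MT))
    if extra:
        raise ValueError(f"records contain off-grid field levels: {extra}")
    for m in records:
        by_level[m.field_mT].append(m.value)
    missing = [lvl for lvl, vals in by_level.items() if not vals]
    if missing:
        raise ValueError(f"missing field levels: {sorted(missing)}")
    inputs = {lvl: np.array(by_level[lvl]) for lvl in FORECAST_WINDOW_LEVELS}
    targets = {lvl: np.array(by_level[lvl]) for lvl in FORECAST_HORIZON_LEVELS}
    return inputs, targets
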