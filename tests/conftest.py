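"""Shared fixtures: a tiny fixture dataset and the scaled-down benchmark.

The ``benchmark`` fixture runs the full pipeline once per session
(>=1000 regions per scenario, CNN training) and is shared by the
end-to-end acceptance tests plus a few qualitative checks; everything
else uses the fast ``small_fixtures`` set or synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from introscan.config import make_fixtures
from introscan.encode import encode_simulation
from introscan.model import (
    ModelConfig,
    TrainingConfig,
    build_model,
    predict,
    split_train_val,
    train,
)
from introscan.simulate import get_model, post_filter_af, simulate_scenario

BENCH_N = 1000  # regions per scenario in the scaled-down benchmark
BENCH_Q = 20.0
BENCH_M = 64
BENCH_K = 5
BENCH_S_RANGE = (0.01, 0.1)
BENCH_AF_CUTOFF = 0.25


@pytest.fixture(scope="session")
def small_fixtures():
    return make_fixtures(seed=123, n_per_scenario=12)


@dataclass
class Benchmark:
    results: list
    X: np.ndarray
    y: np.ndarray
    scenarios: np.ndarray
    params: list
    classifier: object
    train_set: tuple = None
    val_set: tuple = None
    val_probs: np.ndarray = None

    @property
    def val_X(self):
        return self.val_set[0]

    @property
    def val_y(self):
        return self.val_set[1]

    @property
    def val_scenarios(self):
        return self.val_set[2]


@pytest.fixture(scope="session")
def benchmark():
    """Scaled-down end-to-end run: simulate, encode, train (Model A1)."""
    model = get_model("A1")
    results = []
    for scen, seed in (("neutral", 101), ("sweep", 202), ("ai", 303)):
        batch = simulate_scenario(
            model, scen, BENCH_N, Q=BENCH_Q, seed=seed, s_range=BENCH_S_RANGE
        )
        if scen == "ai":
            batch = post_filter_af(batch, BENCH_AF_CUTOFF)
        results.extend(batch)
    X = np.stack(
        [encode_simulation(r, m=BENCH_M, phased=True).matrix for r in results]
    )
    y = np.asarray([1 if r.params.scenario == "ai" else 0 for r in results])
    scen = np.asarray([r.params.scenario for r in results])
    params = [r.params for r in results]
    train_set, val_set = split_train_val((X, y, scen, params), 0.9, seed=5)
    clf = build_model(ModelConfig(m=BENCH_M, k=BENCH_K), X.shape[1:3], seed=7)
    train(clf, train_set[:2], TrainingConfig(), seed=7)
    val_probs = predict(clf, val_set[0])
    return Benchmark(
        results=results,
        X=X,
        y=y,
        scenarios=scen,
        params=params,
        classifier=clf,
        train_set=train_set,
        val_set=val_set,
        val_probs=val_probs,
    )
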