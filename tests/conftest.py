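"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nipthmm.hmm import HmmModel
from nipthmm.simulate import CONDITIONS, SimulationConfig, simulate_cohort


def brute_force_viterbi(obs: np.ndarray, model: HmmModel) -> tuple[np.ndarray, float]:
    """Exhaustive-enumeration maximum-probability path (tiny instances only).

    Scores every possible state path in lexicographic order and keeps the
    first strict maximum.  Independent of the dynamic-programming decoder.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    t = obs.shape[0]
    s = model.space.n_states
    assert t <= 10 and s <= 4, "brute force is for tiny instances"

    loglik = np.empty((t, s))
    for si in range(s):
        ll = np.zeros(t)
        for di in range(obs.shape[1]):
            mu, var = model.means[si, di], model.variances[si, di]
            ll -= 0.5 * (np.log(2 * np.pi * var) + (obs[:, di] - mu) ** 2 / var)
        loglik[:, si] = ll

    log_start = np.log(model.startprob)
    log_trans = np.log(model.transmat)
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(s), repeat=t):
        score = log_start[path[0]] + loglik[0, path[0]]
        for step in range(1, t):
            score += log_trans[path[step - 1], path[step]] + loglik[step, path[step]]
        if score > best_score:
            best_path, best_score = path, score
    return np.asarray(best_path), best_score


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_viterbi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture(scope="session")
def trisomy_cohort():
    """100 maternal-trisomy samples at RD 1000, FF 10% (shared, read-only)."""
    cfg = SimulationConfig(
        read_depth=1000, fetal_fraction=0.10, condition="maternal_trisomy"
    )
    return simulate_cohort(cfg, 100, np.random.default_rng(7))


@pytest.fixture(scope="session")
def training_cohorts():
    """One 100-sample training cohort per condition at RD 1000, FF 10%."""
    out = []
    for i, cond in enumerate(CONDITIONS):
        cfg = SimulationConfig(read_depth=1000, fetal_fraction=0.10, condition=cond)
        out.append(simulate_cohort(cfg, 100, np.random.default_rng([11, i])))
    return out
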