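import numpy as np
import pandas as pd
import pytest

from twostep import CohortSpec, HybridParams, TaskConfig, generate_cohort
from twostep.agents import simulate_subject
from twostep.task import generate_reward_walks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort (4 per group) reused across read-only tests."""
    spec = CohortSpec(group_sizes={"HC": 4, "SIB": 4, "OCD": 4})
    return spec, generate_cohort(spec, np.random.default_rng(42))


def simulate_agents(params: HybridParams, n_subjects: int, model: str,
                    seed: int, n_trials: int = 200):
    """Simulate a homogeneous batch of agents; returns per-subject tables."""
    from twostep.io import trials_to_dataframe

    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials)
    out = {}
    for i in range(n_subjects):
        walk = generate_reward_walks(cfg, rng)
        recs = simulate_subject(params, cfg, walk, rng, model)
        out[f"a{i:03d}"] = trials_to_dataframe(recs, f"a{i:03d}")
    return out
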