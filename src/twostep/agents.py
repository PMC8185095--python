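"""Generative decision models for the two-step task.

Three agents are supported, all special cases of one seven-parameter hybrid:

* ``hybrid`` — SARSA(lambda) model-free learner mixed with a model-based
  planner at the first stage, mixture weight ``omega`` (7 free parameters);
* ``mf`` — pure model-free: ``omega`` frozen at 0 (6 free parameters);
* ``mb`` — pure model-based: ``omega`` frozen at 1, ``lam`` dropped
  (5 free parameters).

The model-based planner uses the true, fixed transition probabilities
(participants are instructed about them). The mixture and the perseveration
bonus apply at the first stage only; the second stage is a plain softmax over
learned state-action values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .task import (
    COMMON,
    RewardWalk,
    TaskConfig,
    TrialRecord,
    emit_outcome,
    step_transition,
)

__all__ = [
    "PARAM_NAMES",
    "MODEL_NAMES",
    "HybridParams",
    "AgentState",
    "mb_values",
    "choice_probs_stage1",
    "choice_probs_stage2",
    "update_state",
    "simulate_subject",
]

PARAM_NAMES = ("alpha1", "alpha2", "lam", "beta1", "beta2", "pi_persev", "omega")
MODEL_NAMES = ("hybrid", "mf", "mb")

#: parameters fixed (not free) per model variant
MODEL_FIXED = {
    "hybrid": {},
    "mf": {"omega": 0.0},
    "mb": {"omega": 1.0, "lam": 0.0},
}


@dataclass(frozen=True)
class HybridParams:
    """The seven parameters of the hybrid model.

    alpha1, alpha2 : stage-1 / stage-2 learning rates in [0, 1]
    lam            : eligibility trace in [0, 1]
    beta1, beta2   : stage-1 / stage-2 inverse temperatures >= 0
    pi_persev      : perseveration weight (any real)
    omega          : model-based weight in [0, 1] (1 = pure MB)
    """

    alpha1: float
    alpha2: float
    lam: float
    beta1: float
    beta2: float
    pi_persev: float
    omega: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "HybridParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def with_model(self, model_name: str) -> "HybridParams":
        """Return a copy with the model variant's frozen parameters imposed."""
        fixed = MODEL_FIXED[model_name]
        return replace(self, **fixed) if fixed else self


@dataclass
class AgentState:
    """Learned values carried across trials.

    ``q_mb_stage1`` is derived (recomputed from ``q_stage2`` and ``p_common``
    after every update); ``last_choice1`` is -1 before the first trial.
    """

    q_mf_stage1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q_stage2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    q_mb_stage1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    last_choice1: int = -1
    p_common: float = 0.70


def mb_values(q_stage2: np.ndarray, p_common: float) -> np.ndarray:
    """Model-based first-stage values from second-stage values.

    Q_MB(a) = p_common * max_a' Q2(S_a, a') + (1 - p_common) * max_a' Q2(S_other, a'),
    with S_a the majority destination of action a.
    """
    best = np.max(q_stage2, axis=1)
    return np.array(
        [
            p_common * best[0] + (1.0 - p_common) * best[1],
            p_common * best[1] + (1.0 - p_common) * best[0],
        ]
    )


def _softmax2(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def choice_probs_stage1(state: AgentState, params: HybridParams) -> np.ndarray:
    """Softmax over the omega-weighted MB/MF mixture plus perseveration."""
    net = params.omega * state.q_mb_stage1 + (1.0 - params.omega) * state.q_mf_stage1
    x = params.beta1 * net
    if state.last_choice1 in (0, 1):
        x = x.copy()
        x[state.last_choice1] += params.pi_persev
    return _softmax2(x)


def choice_probs_stage2(state: AgentState, state2: int, params: HybridParams) -> np.ndarray:
    """Softmax over second-stage action values in the visited state."""
    return _softmax2(params.beta2 * state.q_stage2[state2])


def update_state(state: AgentState, trial: TrialRecord, params: HybridParams) -> AgentState:
    """SARSA(lambda) update after one trial (in place; the state is returned).

    delta1 = Q2(s2, a2) - Q_MF(a1);  Q_MF(a1) += alpha1 * delta1
    delta2 = r - Q2(s2, a2);         Q2(s2, a2) += alpha2 * delta2
    Q_MF(a1) += alpha1 * lam * delta2
    """
    a1, s2, a2, r = trial.choice1, trial.state2, trial.choice2, trial.reward
    delta1 = state.q_stage2[s2, a2] - state.q_mf_stage1[a1]
    state.q_mf_stage1[a1] += params.alpha1 * delta1
    delta2 = r - state.q_stage2[s2, a2]
    state.q_stage2[s2, a2] += params.alpha2 * delta2
    state.q_mf_stage1[a1] += params.alpha1 * params.lam * delta2
    state.last_choice1 = a1
    state.q_mb_stage1 = mb_values(state.q_stage2, state.p_common)
    return state


def simulate_subject(
    params: HybridParams,
    config: TaskConfig,
    walk: RewardWalk,
    rng: np.random.Generator,
    model_name: str = "hybrid",
) -> list[TrialRecord]:
    """Simulate one session: choose, transition, choose, collect, learn.

    Reaction times are not generated here (they are injected by the cohort
    generator); the RT fields of the returned records are missing sentinels.
    """
    params = params.with_model(model_name)
    state = AgentState(p_common=config.p_common)
    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        p1 = choice_probs_stage1(state, params)
        a1 = int(rng.random() < p1[1])
        s2, label = step_transition(a1, config, rng)
        p2 = choice_probs_stage2(state, s2, params)
        a2 = int(rng.random() < p2[1])
        r = emit_outcome(s2, a2, t, walk, rng)
        trial = TrialRecord(t, a1, s2, label, a2, r)
        update_state(state, trial, params)
        records.append(trial)
    return records
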