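"""Generative environment of the two-step task.

The task has a binary first-stage choice leading probabilistically to one of
two second-stage states (a *common* transition with probability ``p_common``,
a *rare* one otherwise), a binary second-stage choice, and a binary reward
whose probability drifts over trials as an independent bounded Gaussian
random walk per second-stage stimulus.

State/stimulus indexing convention (fixed throughout the package):

* first-stage actions are 0 and 1; action ``a`` leads *commonly* to
  second-stage state ``a`` (state A = 0, state B = 1);
* the four second-stage stimuli are indexed ``2 * state + choice2``
  (state A: 0, 1; state B: 2, 3), matching the reward-walk columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "generate_reward_walks",
    "step_transition",
    "emit_outcome",
    "stimulus_index",
    "transition_label",
]

STATE_A = 0
STATE_B = 1
COMMON = "common"
RARE = "rare"

#: sentinel for a missing reaction time
RT_MISSING = float("nan")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step task environment.

    Defaults follow the canonical version of the task: 200 trials, 70/30
    transition structure, reward-probability random walks with Gaussian
    steps of s.d. 0.025 reflected at [0.25, 0.75].
    """

    n_trials: int = 200
    p_common: float = 0.70
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    n_walks: int = 4
    reward_value: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if not (0.5 < self.p_common < 1.0):
            raise ValueError(f"p_common must lie in (0.5, 1), got {self.p_common}")
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 <= lo < hi <= 1, got {self.walk_bounds}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be >= 0")


@dataclass
class RewardWalk:
    """Drifting win probabilities, one column per second-stage stimulus."""

    probs: np.ndarray  # (n_trials, n_walks)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-d array (n_trials x n_walks)")


@dataclass
class TrialRecord:
    """One two-stage trial."""

    trial_index: int
    choice1: int
    state2: int
    transition: str
    choice2: int
    reward: int
    rt1_ms: float = RT_MISSING
    rt2_ms: float = RT_MISSING


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def generate_reward_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalk:
    """Simulate independent bounded Gaussian random walks of win probability.

    Each of the ``config.n_walks`` trajectories starts uniformly inside
    ``walk_bounds`` and takes a Gaussian step of s.d. ``walk_sd`` per trial,
    reflected at the bounds. Deterministic given the generator state.
    """
    lo, hi = config.walk_bounds
    start = rng.uniform(lo, hi, size=config.n_walks)
    steps = rng.normal(0.0, config.walk_sd, size=(config.n_trials - 1, config.n_walks)) \
        if config.n_trials > 1 else np.empty((0, config.n_walks))
    raw = np.vstack([start, start + np.cumsum(steps, axis=0)]) if config.n_trials > 1 \
        else start[None, :]
    return RewardWalk(_reflect(raw, lo, hi))


def transition_label(choice1: int, state2: int) -> str:
    """Label a transition: common iff state2 is the majority destination of choice1."""
    return COMMON if state2 == choice1 else RARE


def step_transition(choice1: int, config: TaskConfig, rng: np.random.Generator) -> tuple[int, str]:
    """Draw the second-stage state reached after a first-stage choice."""
    if choice1 not in (0, 1):
        raise ValueError(f"choice1 must be 0 or 1, got {choice1}")
    if rng.random() < config.p_common:
        state2 = choice1
    else:
        state2 = 1 - choice1
    return state2, transition_label(choice1, state2)


def stimulus_index(state2: int, choice2: int) -> int:
    """Column of the reward walk addressed by a second-stage state/choice pair."""
    return 2 * state2 + choice2


def emit_outcome(
    state2: int,
    choice2: int,
    trial_index: int,
    walk: RewardWalk,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward draw from the walk's current win probability."""
    n_trials = walk.probs.shape[0]
    if not (0 <= trial_index < n_trials):
        raise IndexError(f"trial_index {trial_index} out of range [0, {n_trials})")
    p = walk.probs[trial_index, stimulus_index(state2, choice2)]
    return int(rng.random() < p)
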