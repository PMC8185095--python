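"""Per-subject likelihood and MAP estimation under a Gaussian population prior.

Parameters are estimated in an unconstrained *transformed* space — logistic
for unit-interval parameters (alpha1, alpha2, lam, omega), log for positive
ones (beta1, beta2), identity for the perseveration weight — where the
population prior is an independent (diagonal) Gaussian per dimension.

The trial-replay likelihood kernel is numba-compiled; it reproduces exactly
the value dynamics of :mod:`twostep.agents` (a property test pins the two
code paths together).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

from .agents import MODEL_FIXED, PARAM_NAMES, HybridParams
from .task import TrialRecord

__all__ = [
    "MODEL_FREE_PARAMS",
    "GroupPrior",
    "SubjectFit",
    "transform_to_natural",
    "transform_to_unconstrained",
    "z_to_params",
    "params_to_z",
    "trials_to_arrays",
    "negative_log_likelihood",
    "fit_subject_map",
    "numerical_hessian",
]

#: free (estimated) parameters per model variant, in canonical order
MODEL_FREE_PARAMS = {
    "hybrid": list(PARAM_NAMES),
    "mf": [n for n in PARAM_NAMES if n != "omega"],
    "mb": [n for n in PARAM_NAMES if n not in ("lam", "omega")],
}

_UNIT = {"alpha1", "alpha2", "lam", "omega"}
_POSITIVE = {"beta1", "beta2"}

_ZCAP = 30.0  # keeps exp/expit finite; far outside any plausible optimum


def transform_to_natural(name: str, z: float) -> float:
    """Map one unconstrained coordinate back to its natural scale."""
    z = float(np.clip(z, -_ZCAP, _ZCAP))
    if name in _UNIT:
        return 1.0 / (1.0 + math.exp(-z))
    if name in _POSITIVE:
        return math.exp(z)
    return z


def transform_to_unconstrained(name: str, value: float) -> float:
    """Inverse of :func:`transform_to_natural` (logit / log / identity)."""
    if name in _UNIT:
        v = min(max(value, 1e-12), 1.0 - 1e-12)
        return math.log(v / (1.0 - v))
    if name in _POSITIVE:
        return math.log(max(value, 1e-12))
    return float(value)


def z_to_params(z: Sequence[float], model_name: str = "hybrid") -> HybridParams:
    """Assemble full natural-scale parameters from a free-parameter z vector."""
    free = MODEL_FREE_PARAMS[model_name]
    values = dict(MODEL_FIXED[model_name])
    for name, zk in zip(free, z):
        values[name] = transform_to_natural(name, zk)
    return HybridParams(**values)


def params_to_z(params: HybridParams, model_name: str = "hybrid") -> np.ndarray:
    free = MODEL_FREE_PARAMS[model_name]
    return np.array([transform_to_unconstrained(n, getattr(params, n)) for n in free])


@dataclass
class GroupPrior:
    """Diagonal Gaussian population prior over transformed parameters."""

    mu: np.ndarray
    sigma2: np.ndarray
    param_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same shape")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        self.param_names = tuple(self.param_names)
        if len(self.param_names) != self.mu.size:
            raise ValueError("param_names length must match prior dimension")

    @classmethod
    def vague(cls, model_name: str, sigma2: float = 100.0) -> "GroupPrior":
        names = MODEL_FREE_PARAMS[model_name]
        return cls(np.zeros(len(names)), np.full(len(names), sigma2), tuple(names))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.normal(self.mu, np.sqrt(self.sigma2), size=(n, self.mu.size))


@dataclass
class SubjectFit:
    """MAP estimate for one subject, with local curvature."""

    z_map: np.ndarray
    params_map: HybridParams
    neg_log_lik: float
    log_posterior: float
    hessian: np.ndarray
    converged: bool
    posterior_var: Optional[np.ndarray] = None
    log_marginal: Optional[float] = None


# ---------------------------------------------------------------------------
# fast likelihood kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _nll_kernel(a1r, a2r, lam, b1, b2, pi, om, c1, s2, c2, rew, p_common):  # pragma: no cover
    q_mf = np.zeros(2)
    q2 = np.zeros((2, 2))
    total = 0.0
    last = -1
    for t in range(c1.shape[0]):
        best0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        best1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * best0 + (1.0 - p_common) * best1
        qmb1 = p_common * best1 + (1.0 - p_common) * best0
        x0 = b1 * (om * qmb0 + (1.0 - om) * q_mf[0])
        x1 = b1 * (om * qmb1 + (1.0 - om) * q_mf[1])
        if last == 0:
            x0 += pi
        elif last == 1:
            x1 += pi
        m = x0 if x0 > x1 else x1
        logz = m + math.log(math.exp(x0 - m) + math.exp(x1 - m))
        total -= (x0 if c1[t] == 0 else x1) - logz
        s = s2[t]
        y0 = b2 * q2[s, 0]
        y1 = b2 * q2[s, 1]
        m2 = y0 if y0 > y1 else y1
        logz2 = m2 + math.log(math.exp(y0 - m2) + math.exp(y1 - m2))
        total -= (y0 if c2[t] == 0 else y1) - logz2
        a1 = c1[t]
        a2 = c2[t]
        d1 = q2[s, a2] - q_mf[a1]
        q_mf[a1] += a1r * d1
        d2 = rew[t] - q2[s, a2]
        q2[s, a2] += a2r * d2
        q_mf[a1] += a1r * lam * d2
        last = a1
    return total


def trials_to_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (choice1, state2, choice2, reward) int arrays from trial data.

    Accepts a list of :class:`~twostep.task.TrialRecord`, a DataFrame with
    the trial CSV schema, or a tuple of arrays (passed through).
    """
    if isinstance(trials, tuple) and len(trials) == 4:
        return trials
    if isinstance(trials, pd.DataFrame):
        return (
            trials["choice1"].to_numpy(np.int64),
            trials["state2"].to_numpy(np.int64),
            trials["choice2"].to_numpy(np.int64),
            trials["reward"].to_numpy(np.int64),
        )
    c1 = np.array([t.choice1 for t in trials], dtype=np.int64)
    s2 = np.array([t.state2 for t in trials], dtype=np.int64)
    c2 = np.array([t.choice2 for t in trials], dtype=np.int64)
    r = np.array([t.reward for t in trials], dtype=np.int64)
    return c1, s2, c2, r


def negative_log_likelihood(
    params: HybridParams,
    trials,
    model_name: str = "hybrid",
    p_common: float = 0.70,
) -> float:
    """Negative log likelihood (nats) of both choices on every trial.

    The trial sequence is replayed through the agent's value dynamics; the
    model variant imposes its frozen parameters (omega=0 for ``mf``;
    omega=1, lam=0 for ``mb``) before evaluation.
    """
    params = params.with_model(model_name)
    c1, s2, c2, r = trials_to_arrays(trials)
    if c1.size == 0:
        return 0.0
    return float(
        _nll_kernel(
            params.alpha1, params.alpha2, params.lam, params.beta1,
            params.beta2, params.pi_persev, params.omega,
            c1, s2, c2, r.astype(np.float64), p_common,
        )
    )


def _map_objective(z, arrays, prior, model_name, p_common):
    params = z_to_params(z, model_name)
    nll = _nll_kernel(
        params.alpha1, params.alpha2, params.lam, params.beta1,
        params.beta2, params.pi_persev, params.omega,
        arrays[0], arrays[1], arrays[2], arrays[3], p_common,
    )
    dz = z - prior.mu
    return nll + 0.5 * float(np.sum(dz * dz / prior.sigma2))


def numerical_hessian(f, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    d = x.size
    h = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            if i == j:
                h[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
            else:
                h[i, j] = h[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * step**2)
    return h


def fit_subject_map(
    trials,
    prior: GroupPrior,
    model_name: str = "hybrid",
    n_starts: int = 10,
    rng: Optional[np.random.Generator] = None,
    start_points: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    p_common: float = 0.70,
) -> SubjectFit:
    """Multi-start MAP estimate of one subject's transformed parameters.

    Minimises ``nll(z) + sum_k (z_k - mu_k)^2 / (2 sigma2_k)``. The first
    start is the prior mean; the rest are prior draws (or the supplied
    ``start_points``, e.g. warm starts from a previous EM iteration).
    Non-convergence from every start is flagged, not raised.
    """
    free = MODEL_FREE_PARAMS[model_name]
    if prior.mu.size != len(free):
        raise ValueError(
            f"prior dimension {prior.mu.size} does not match model "
            f"'{model_name}' ({len(free)} free parameters)"
        )
    arrays = trials_to_arrays(trials)
    arrays = (arrays[0], arrays[1], arrays[2], arrays[3].astype(np.float64))
    rng = rng if rng is not None else np.random.default_rng()

    starts = [prior.mu.copy()]
    if start_points is not None:
        starts.extend(np.atleast_2d(start_points))
    while len(starts) < max(n_starts, 1):
        starts.append(prior.sample(rng)[0])

    obj = lambda z: _map_objective(z, arrays, prior, model_name, p_common)
    best = None
    any_converged = False
    for z0 in starts[: max(n_starts, 1)]:
        res = minimize(obj, z0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    z_map = np.clip(best.x, -_ZCAP, _ZCAP)
    params = z_to_params(z_map, model_name)
    nll = negative_log_likelihood(params, arrays, model_name, p_common)
    hess = numerical_hessian(obj, z_map)
    return SubjectFit(
        z_map=z_map,
        params_map=params,
        neg_log_lik=nll,
        log_posterior=-float(best.fun),
        hessian=hess,
        converged=any_converged,
    )
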