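"""Hierarchical empirical-Bayes EM across subjects, and iBIC model comparison.

The E-step computes each subject's MAP estimate and a Laplace approximation
to the posterior covariance under the current Gaussian population prior; the
M-step re-estimates the prior moments from those summaries:

    mu_k     <- mean_i z_map,ik
    sigma2_k <- mean_i (z_map,ik^2 + var_ik) - mu_k^2

Model comparison uses the integrated BIC: minus twice the summed Laplace
log marginal likelihoods, penalised by the number of population-level
hyperparameters times log of the total observation count (two observed
choices per trial by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .likelihood import (
    MODEL_FREE_PARAMS,
    GroupPrior,
    SubjectFit,
    fit_subject_map,
    trials_to_arrays,
)

__all__ = ["EMSettings", "ModelFitResult", "em_fit", "integrated_bic", "laplace_log_marginal"]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EMSettings:
    """Knobs of the EM scheme (defaults follow standard practice)."""

    max_iter: int = 100
    tol: float = 1e-3            # on max |d mu| and max |d sigma2|
    n_starts_first: int = 10     # random starts, first E-step
    n_starts_later: int = 2      # warm starts thereafter
    opt_tol: float = 1e-6
    sigma2_floor: float = 1e-6
    hess_ridge: float = 1e-6
    init_sigma2: float = 2.25    # vague-ish starting prior variance
    obs_per_trial: int = 2       # two observed choices per trial
    seed: int = 0
    p_common: float = 0.70


@dataclass
class ModelFitResult:
    """Cohort-level fit of one model variant."""

    model_name: str
    subject_fits: Dict[str, SubjectFit]
    prior: GroupPrior
    total_log_marginal: float
    ibic: float
    n_free_params: int
    n_iter: int = 0
    converged: bool = False
    total_observations: int = 0


def _regularize_spd(h: np.ndarray, ridge: float) -> np.ndarray:
    """Return an SPD version of ``h``, adding escalating ridge if needed."""
    d = h.shape[0]
    bump = ridge
    hh = 0.5 * (h + h.T)
    for _ in range(40):
        try:
            np.linalg.cholesky(hh)
            return hh
        except np.linalg.LinAlgError:
            hh = hh + bump * np.eye(d)
            bump *= 10.0
    raise np.linalg.LinAlgError("could not regularize Hessian to SPD")


def laplace_log_marginal(fit: SubjectFit, prior: GroupPrior, ridge: float = 1e-6) -> float:
    """Laplace approximation to log p(data | prior) at the subject's MAP.

    log p ~ log p(data|z*) + log p(z*|prior) + (d/2) log 2pi - 0.5 log det H
    """
    d = fit.z_map.size
    h = _regularize_spd(fit.hessian, ridge)
    sign, logdet = np.linalg.slogdet(h)
    dz = fit.z_map - prior.mu
    log_prior = -0.5 * float(np.sum(dz * dz / prior.sigma2 + np.log(2.0 * np.pi * prior.sigma2)))
    return -fit.neg_log_lik + log_prior + 0.5 * d * _LOG2PI - 0.5 * logdet


def integrated_bic(result: ModelFitResult, total_observations: Optional[int] = None) -> float:
    """iBIC = -2 * sum_i log p(data_i | prior) + n_hyper * log(N). Lower is better."""
    n_obs = total_observations if total_observations is not None else result.total_observations
    n_hyper = 2 * result.n_free_params  # a mean and a variance per dimension
    return -2.0 * result.total_log_marginal + n_hyper * float(np.log(n_obs))


def em_fit(
    all_subject_trials: Dict[str, object],
    model_name: str = "hybrid",
    settings: Optional[EMSettings] = None,
    init_mu: Optional[np.ndarray] = None,
) -> ModelFitResult:
    """Fit one model variant to a cohort by empirical-Bayes EM.

    ``all_subject_trials`` maps subject id to that subject's trial data
    (DataFrame, TrialRecord list, or array tuple). Deterministic given
    ``settings.seed``.
    """
    if len(all_subject_trials) < 2:
        raise ValueError("EM requires at least 2 subjects")
    settings = settings or EMSettings()
    free = MODEL_FREE_PARAMS[model_name]
    d = len(free)
    rng = np.random.default_rng(settings.seed)

    if init_mu is None:
        # start learning rates / omega near 0.5, betas near e, pi near 0
        init_mu = np.array([1.0 if n.startswith("beta") else 0.0 for n in free])
    prior = GroupPrior(np.asarray(init_mu, float), np.full(d, settings.init_sigma2), tuple(free))

    subjects = list(all_subject_trials)
    arrays = {s: trials_to_arrays(all_subject_trials[s]) for s in subjects}
    n_obs = settings.obs_per_trial * sum(a[0].size for a in arrays.values())

    fits: Dict[str, SubjectFit] = {}
    warm: Dict[str, np.ndarray] = {}
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        n_starts = settings.n_starts_first if it == 1 else settings.n_starts_later
        z = np.empty((len(subjects), d))
        var = np.empty((len(subjects), d))
        for i, s in enumerate(subjects):
            fit = fit_subject_map(
                arrays[s],
                prior,
                model_name,
                n_starts=n_starts,
                rng=rng,
                start_points=warm.get(s),
                tol=settings.opt_tol,
                p_common=settings.p_common,
            )
            h = _regularize_spd(fit.hessian, settings.hess_ridge)
            fit.posterior_var = np.diag(np.linalg.inv(h))
            fits[s] = fit
            warm[s] = fit.z_map[None, :]
            z[i] = fit.z_map
            var[i] = fit.posterior_var

        mu_new = z.mean(axis=0)
        sigma2_new = np.mean(z**2 + var, axis=0) - mu_new**2
        if np.any(sigma2_new < settings.sigma2_floor):
            logger.info("EM iter %d: prior variance floored for %s", it,
                        [free[k] for k in np.where(sigma2_new < settings.sigma2_floor)[0]])
        sigma2_new = np.maximum(sigma2_new, settings.sigma2_floor)

        d_mu = float(np.max(np.abs(mu_new - prior.mu)))
        d_s2 = float(np.max(np.abs(sigma2_new - prior.sigma2)))
        prior = GroupPrior(mu_new, sigma2_new, tuple(free))
        if d_mu < settings.tol and d_s2 < settings.tol:
            converged = True
            break

    total_lm = 0.0
    for s in subjects:
        lm = laplace_log_marginal(fits[s], prior, settings.hess_ridge)
        fits[s].log_marginal = lm
        total_lm += lm

    result = ModelFitResult(
        model_name=model_name,
        subject_fits=fits,
        prior=prior,
        total_log_marginal=total_lm,
        ibic=0.0,
        n_free_params=d,
        n_iter=it,
        converged=converged,
        total_observations=n_obs,
    )
    result.ibic = integrated_bic(result)
    return result
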