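"""Statsmodels-style front end: a model object built from trial data whose
``fit()`` returns a results object with estimates, uncertainties and a
``summary()`` table."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .agents import PARAM_NAMES, HybridParams, simulate_subject
from .em import EMSettings, ModelFitResult, em_fit
from .likelihood import (
    MODEL_FREE_PARAMS,
    GroupPrior,
    fit_subject_map,
    negative_log_likelihood,
    transform_to_natural,
)
from .task import TaskConfig, generate_reward_walks

__all__ = ["TwoStepModel", "TwoStepResults"]


class TwoStepModel:
    """Hybrid / pure-MF / pure-MB choice model for a cohort of sessions.

    Parameters
    ----------
    trials_by_subject
        Mapping of subject id to that subject's trials (DataFrame with the
        trial schema, or a list of TrialRecord).
    model
        One of ``"hybrid"`` (7 free parameters), ``"mf"`` (omega frozen at 0)
        or ``"mb"`` (omega frozen at 1, lambda dropped).
    p_common
        The task's common-transition probability used by the model-based
        planner.
    """

    def __init__(self, trials_by_subject: Dict[str, object], model: str = "hybrid",
                 p_common: float = 0.70):
        if model not in MODEL_FREE_PARAMS:
            raise ValueError(f"unknown model '{model}'")
        self.trials_by_subject = dict(trials_by_subject)
        self.model = model
        self.p_common = p_common

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "hybrid",
                       p_common: float = 0.70) -> "TwoStepModel":
        """Build from a long trial table with a ``subject_id`` column."""
        groups = {sid: g.sort_values("trial").reset_index(drop=True)
                  for sid, g in df.groupby("subject_id", sort=True)}
        return cls(groups, model=model, p_common=p_common)

    def loglike(self, params: HybridParams, subject: str) -> float:
        """Log likelihood of one subject's choices under given parameters."""
        return -negative_log_likelihood(
            params, self.trials_by_subject[subject], self.model, self.p_common
        )

    def fit_subject(self, subject: str, prior: Optional[GroupPrior] = None,
                    **kwargs):
        """MAP fit of a single subject (vague prior unless one is given)."""
        prior = prior or GroupPrior.vague(self.model)
        return fit_subject_map(self.trials_by_subject[subject], prior,
                               self.model, p_common=self.p_common, **kwargs)

    def fit(self, settings: Optional[EMSettings] = None, **kwargs) -> "TwoStepResults":
        """Hierarchical empirical-Bayes EM fit of the whole cohort.

        Keyword arguments override :class:`~twostep.em.EMSettings` fields.
        """
        if settings is None:
            settings = EMSettings(**kwargs)
        elif kwargs:
            raise TypeError("pass either settings or keyword overrides, not both")
        settings.p_common = self.p_common
        raw = em_fit(self.trials_by_subject, self.model, settings)
        return TwoStepResults(self, raw)


class TwoStepResults:
    """Cohort fit: per-subject MAP estimates, population prior, iBIC."""

    def __init__(self, model: TwoStepModel, raw: ModelFitResult):
        self.model = model
        self.raw = raw
        self.model_name = raw.model_name
        self.prior = raw.prior
        self.ibic = raw.ibic
        self.total_log_marginal = raw.total_log_marginal
        self.n_free_params = raw.n_free_params
        self.subject_fits = raw.subject_fits

    @property
    def params(self) -> pd.DataFrame:
        """Per-subject natural-scale estimates (one row per subject)."""
        rows = []
        for sid, fit in self.subject_fits.items():
            row = {"subject_id": sid, "model": self.model_name}
            row.update({n: getattr(fit.params_map, n) for n in PARAM_NAMES})
            row["nll"] = fit.neg_log_lik
            row["converged"] = fit.converged
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def prior_table(self) -> pd.DataFrame:
        """Population prior per transformed dimension, with the natural-scale
        value implied by the prior mean."""
        return pd.DataFrame({
            "param": self.prior.param_names,
            "mu": self.prior.mu,
            "sigma": np.sqrt(self.prior.sigma2),
            "natural_at_mu": [transform_to_natural(n, m)
                              for n, m in zip(self.prior.param_names, self.prior.mu)],
        })

    def omega(self) -> pd.Series:
        """Per-subject MAP omega (model-based weight), indexed by subject."""
        return pd.Series({sid: f.params_map.omega for sid, f in self.subject_fits.items()},
                         name="omega_hat")

    def summary(self) -> str:
        pt = self.prior_table
        lines = [
            f"Two-step {self.model_name} model — hierarchical EM fit",
            f"  subjects: {len(self.subject_fits)}   free parameters: {self.n_free_params}",
            f"  EM iterations: {self.raw.n_iter} (converged: {self.raw.converged})",
            f"  total log marginal: {self.total_log_marginal:.1f} nats",
            f"  iBIC: {self.ibic:.1f} (N = {self.raw.total_observations} observations)",
            "",
            "  population prior (transformed scale)",
            "  param        mu     sigma   natural(mu)",
        ]
        for _, r in pt.iterrows():
            lines.append(f"  {r['param']:<10}{r['mu']:>8.3f}{r['sigma']:>9.3f}"
                         f"{r['natural_at_mu']:>12.3f}")
        return "\n".join(lines)

    def simulate(self, config: Optional[TaskConfig] = None,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
        """Simulate one session per subject from the fitted MAP parameters."""
        from .io import trials_to_dataframe

        config = config or TaskConfig(p_common=self.model.p_common)
        rng = rng if rng is not None else np.random.default_rng()
        frames = []
        for sid, fit in self.subject_fits.items():
            walk = generate_reward_walks(config, rng)
            records = simulate_subject(fit.params_map, config, walk, rng, self.model_name)
            frames.append(trials_to_dataframe(records, subject_id=sid))
        return pd.concat(frames, ignore_index=True)

    def plot_prior(self, ax=None):
        """Bar plot of the fitted population prior (transformed scale)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pt = self.prior_table
        ax.bar(pt["param"], pt["mu"], yerr=np.sqrt(self.prior.sigma2), capsize=3)
        ax.set_ylabel("prior mean (transformed scale)")
        ax.set_title(f"{self.model_name} population prior")
        return ax
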