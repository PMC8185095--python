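"""Synthetic study cohorts with the statistical structure the analyses assume.

Generates, per subject: hybrid-model parameters drawn from a group-specific
population prior (group mean model-based weight ordered OCD < SIB < HC), a
simulated 200-trial session, second-stage reaction times with a group-specific
rare-transition penalty (ordered OCD < HC < SIB), demographic/cognitive
covariates, and ICV-normalized subcortical volumes coupled to the subject's
RT effect with group-specific sign (negative in OCD/SIB, positive in HC).

Reaction times are generated independently of the agent's internal state —
an additive transition penalty plus noise — because the RT effect is treated
as a separate model-based signature. The optional ``omega_coupled`` mode
scales each subject's penalty with their generative omega to emulate the
positive correlation between the RT effect and the model-based weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .agents import PARAM_NAMES, simulate_subject
from .likelihood import transform_to_unconstrained, z_to_params
from .task import RARE, TaskConfig, generate_reward_walks

__all__ = ["RTModel", "RoiModel", "CovariateModel", "CohortSpec", "CohortData",
           "generate_cohort", "null_cohort"]

logger = logging.getLogger(__name__)

GROUPS = ("HC", "SIB", "OCD")


@dataclass(frozen=True)
class RTModel:
    """Additive second-stage RT model: base + rare penalty + noise (ms)."""

    base_mean_ms: float = 830.0
    base_sd_ms: float = 150.0
    rare_penalty_ms: Dict[str, float] = field(
        default_factory=lambda: {"HC": 71.0, "SIB": 106.0, "OCD": 46.0})
    noise_sd_ms: float = 300.0
    floor_ms: float = 100.0
    lognormal: bool = False
    omega_coupled: bool = False


@dataclass(frozen=True)
class RoiModel:
    """ICV and normalized-volume distributions with RT-effect coupling.

    Couplings act on the *normalized* (volume/ICV) ratios through a Gaussian
    copula on the within-group ranks of the RT effect; raw volumes are the
    ratio times the subject's ICV.
    """

    icv_mean_mm3: float = 1.5e6
    icv_sd_mm3: float = 1.5e5
    ratio_mean: Dict[str, float] = field(default_factory=lambda: {
        "putamen_l": 5000 / 1.5e6, "putamen_r": 5000 / 1.5e6,
        "caudate_l": 3500 / 1.5e6, "caudate_r": 3500 / 1.5e6})
    ratio_sd: Dict[str, float] = field(default_factory=lambda: {
        "putamen_l": 3.3e-4, "putamen_r": 3.3e-4,
        "caudate_l": 2.4e-4, "caudate_r": 2.4e-4})
    coupling: Dict[str, float] = field(
        default_factory=lambda: {"HC": 0.35, "SIB": -0.55, "OCD": -0.45})


@dataclass(frozen=True)
class CovariateModel:
    """Demographics and cognitive scores (group means follow the cohort table)."""

    age_mean: Dict[str, float] = field(
        default_factory=lambda: {"HC": 32.0, "SIB": 33.5, "OCD": 32.2})
    age_sd: float = 10.0
    p_female: float = 0.55
    dsst_mean: Dict[str, float] = field(
        default_factory=lambda: {"HC": 57.7, "SIB": 50.2, "OCD": 42.1})
    dsst_sd: float = 16.0
    ds_mean: Dict[str, float] = field(
        default_factory=lambda: {"HC": 6.7, "SIB": 5.3, "OCD": 5.6})
    ds_sd: float = 2.3
    #: optional dependence of the transformed omega mean on the DSST z-score
    dsst_omega_slope: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic study dataset."""

    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {"HC": 31, "SIB": 27, "OCD": 32})
    #: natural-scale group means of the model-based weight (ordered OCD<SIB<HC)
    omega_mean: Dict[str, float] = field(
        default_factory=lambda: {"HC": 0.55, "SIB": 0.45, "OCD": 0.35})
    #: natural-scale population means of the remaining parameters
    param_means: Dict[str, float] = field(default_factory=lambda: {
        "alpha1": 0.5, "alpha2": 0.5, "lam": 0.5,
        "beta1": 4.0, "beta2": 4.0, "pi_persev": 0.2})
    #: between-subject s.d. on the transformed scale, shared across dimensions
    prior_sigma_z: float = 0.5
    rt_model: RTModel = field(default_factory=RTModel)
    roi_model: RoiModel = field(default_factory=RoiModel)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.rt_model.noise_sd_ms < 0:
            raise ValueError("noise sd must be >= 0")
        for g, c in self.roi_model.coupling.items():
            if abs(c) > 1:
                raise ValueError(f"coupling for {g} must satisfy |c| <= 1")
            if abs(c) > 0.999:
                raise ValueError(f"coupling for {g} is degenerate (|c| ~ 1)")

    def prior_mu_z(self, group: str) -> np.ndarray:
        """Transformed-scale prior mean for one group."""
        values = dict(self.param_means)
        values["omega"] = self.omega_mean[group]
        return np.array([transform_to_unconstrained(n, values[n]) for n in PARAM_NAMES])


@dataclass
class CohortData:
    """One generated dataset plus its ground truth."""

    trials: pd.DataFrame
    covariates: pd.DataFrame
    roi: pd.DataFrame
    truth: pd.DataFrame


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores (Gaussian copula margin)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.5) / x.size)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> CohortData:
    """Draw a complete synthetic cohort; fully reproducible from (spec, rng)."""
    from .io import trials_to_dataframe

    cov_m = spec.covariate_model
    rt_m = spec.rt_model
    sigma_z = spec.prior_sigma_z

    trial_frames = []
    cov_rows = []
    truth_rows = []
    rt_effects: Dict[str, float] = {}
    subject_groups: Dict[str, str] = {}

    sid_counter = 0
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        mu_z = spec.prior_mu_z(group)
        omega_idx = PARAM_NAMES.index("omega")
        for _ in range(n):
            sid = f"s{sid_counter:03d}"
            sid_counter += 1
            subject_groups[sid] = group

            age = float(np.clip(rng.normal(cov_m.age_mean[group], cov_m.age_sd), 18, 65))
            gender = int(rng.random() < cov_m.p_female)  # 1 = female
            dsst = float(rng.normal(cov_m.dsst_mean[group], cov_m.dsst_sd))
            ds = float(rng.normal(cov_m.ds_mean[group], cov_m.ds_sd))

            mu = mu_z.copy()
            if cov_m.dsst_omega_slope != 0.0:
                grand = np.mean(list(cov_m.dsst_mean.values()))
                mu[omega_idx] += cov_m.dsst_omega_slope * (dsst - grand) / cov_m.dsst_sd
            z = rng.normal(mu, sigma_z)
            params = z_to_params(z, "hybrid")

            walk = generate_reward_walks(spec.task, rng)
            records = simulate_subject(params, spec.task, walk, rng)

            base = rng.normal(rt_m.base_mean_ms, rt_m.base_sd_ms)
            penalty = rt_m.rare_penalty_ms[group]
            if rt_m.omega_coupled:
                penalty = penalty * params.omega / max(spec.omega_mean[group], 1e-9)
            n_t = len(records)
            noise1 = rng.normal(0.0, rt_m.noise_sd_ms, n_t)
            noise2 = rng.normal(0.0, rt_m.noise_sd_ms, n_t)
            for t, rec in enumerate(records):
                rare = rec.transition == RARE
                rt2 = base + (penalty if rare else 0.0) + noise2[t]
                rt1 = base + noise1[t]
                if rt_m.lognormal:
                    rt1 = base * float(np.exp(noise1[t] / rt_m.base_mean_ms))
                    rt2 = (base + (penalty if rare else 0.0)) * float(
                        np.exp(noise2[t] / rt_m.base_mean_ms))
                rec.rt1_ms = max(rt1, rt_m.floor_ms)
                rec.rt2_ms = max(rt2, rt_m.floor_ms)
            frame = trials_to_dataframe(records, subject_id=sid)
            trial_frames.append(frame)

            rt2 = frame["rt2_ms"].to_numpy()
            rare_mask = (frame["transition"] == RARE).to_numpy()
            if rare_mask.any() and (~rare_mask).any():
                rt_effects[sid] = float(rt2[rare_mask].mean() - rt2[~rare_mask].mean())
            else:  # degenerate short session: no observable transition contrast
                rt_effects[sid] = 0.0

            cov_rows.append({"subject_id": sid, "group": group, "age": age,
                             "gender": gender, "dsst": dsst, "ds_backwards": ds})
            truth_rows.append({"subject_id": sid, "group": group,
                               **{p: getattr(params, p) for p in PARAM_NAMES},
                               "rare_penalty_ms": penalty, "base_ms": base})

    roi_m = spec.roi_model
    roi_rows = {sid: {"subject_id": sid} for sid in subject_groups}
    sids = np.array(list(subject_groups))
    groups_arr = np.array([subject_groups[s] for s in sids])
    icv = rng.normal(roi_m.icv_mean_mm3, roi_m.icv_sd_mm3, sids.size)
    icv = np.clip(icv, 0.5 * roi_m.icv_mean_mm3, None)
    for i, sid in enumerate(sids):
        roi_rows[sid]["icv_mm3"] = float(icv[i])
    for roi, mean in roi_m.ratio_mean.items():
        sd = roi_m.ratio_sd[roi]
        ratio = np.empty(sids.size)
        for group in GROUPS:
            mask = groups_arr == group
            if not mask.any():
                continue
            c = roi_m.coupling[group]
            z_rt = _normal_scores(np.array([rt_effects[s] for s in sids[mask]]))
            eps = rng.normal(0.0, 1.0, int(mask.sum()))
            ratio[mask] = mean + sd * (c * z_rt + np.sqrt(1.0 - c * c) * eps)
        ratio = np.clip(ratio, 0.2 * mean, None)
        for i, sid in enumerate(sids):
            roi_rows[sid][f"{roi}_mm3"] = float(ratio[i] * icv[i])

    return CohortData(
        trials=pd.concat(trial_frames, ignore_index=True),
        covariates=pd.DataFrame(cov_rows),
        roi=pd.DataFrame(list(roi_rows.values())),
        truth=pd.DataFrame(truth_rows),
    )


def null_cohort(spec: CohortSpec, rng: np.random.Generator) -> CohortData:
    """Same generator with every group-level difference and coupling zeroed.

    All groups share the average omega mean, RT penalty and covariate means;
    ROI couplings are 0. Used for type-I-error calibration.
    """
    mean_of = lambda d: float(np.mean(list(d.values())))
    flat = lambda d: {g: mean_of(d) for g in GROUPS}
    null_spec = replace(
        spec,
        omega_mean=flat(spec.omega_mean),
        rt_model=replace(spec.rt_model,
                         rare_penalty_ms=flat(spec.rt_model.rare_penalty_ms)),
        roi_model=replace(spec.roi_model, coupling={g: 0.0 for g in GROUPS}),
        covariate_model=replace(spec.covariate_model,
                                age_mean=flat(spec.covariate_model.age_mean),
                                dsst_mean=flat(spec.covariate_model.dsst_mean),
                                ds_mean=flat(spec.covariate_model.ds_mean),
                                dsst_omega_slope=0.0),
    )
    return generate_cohort(null_spec, rng)
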