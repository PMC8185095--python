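"""Readers/writers for the tabular schemas, run configuration, and the
pipeline orchestrator.

All schemas are plain CSV with a header row; missing values are empty
fields; reaction times are milliseconds, volumes mm^3. The trial schema is
``subject_id, trial, choice1, state2, transition, choice2, reward, rt1_ms,
rt2_ms`` with ``state2`` written as the letters A/B (stored internally as
0/1) and ``transition`` as common/rare.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .task import COMMON, RARE, TrialRecord, transition_label

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_dataframe",
    "dataframe_to_records",
    "write_trials",
    "read_trials",
    "read_covariates",
    "read_roi",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("subject_id", "trial", "choice1", "state2", "transition",
                 "choice2", "reward", "rt1_ms", "rt2_ms")

_STATE_LETTERS = {0: "A", 1: "B"}
_STATE_CODES = {"A": 0, "B": 1, "0": 0, "1": 1}


def trials_to_dataframe(records: Sequence[TrialRecord], subject_id: str = "s0") -> pd.DataFrame:
    """In-memory trial table (state2 as int codes) for one subject."""
    return pd.DataFrame({
        "subject_id": subject_id,
        "trial": [r.trial_index for r in records],
        "choice1": [r.choice1 for r in records],
        "state2": [r.state2 for r in records],
        "transition": [r.transition for r in records],
        "choice2": [r.choice2 for r in records],
        "reward": [r.reward for r in records],
        "rt1_ms": [r.rt1_ms for r in records],
        "rt2_ms": [r.rt2_ms for r in records],
    })


def dataframe_to_records(df: pd.DataFrame) -> List[TrialRecord]:
    return [TrialRecord(int(r.trial), int(r.choice1), int(r.state2), str(r.transition),
                        int(r.choice2), int(r.reward), float(r.rt1_ms), float(r.rt2_ms))
            for r in df.itertuples()]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the long trial table, with state2 as A/B letters."""
    out = df.loc[:, list(TRIAL_COLUMNS)].copy()
    out["state2"] = out["state2"].map(_STATE_LETTERS)
    out.to_csv(path, index=False)


def read_trials(path) -> Dict[str, pd.DataFrame]:
    """Read and validate a trial CSV; returns per-subject tables ordered by
    trial. Raises on schema violations, naming the offending row/column."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df.empty:
        logger.warning("trial file %s is empty", path)
        return {}
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    df["state2"] = df["state2"].astype(str).map(_STATE_CODES)
    if df["state2"].isna().any():
        row = int(df.index[df["state2"].isna()][0])
        raise ValueError(f"row {row}: state2 must be A/B")
    for col in ("choice1", "choice2", "reward"):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            raise ValueError(f"row {int(df.index[bad][0])}: column {col} must be 0/1")
    bad_label = ~df["transition"].isin((COMMON, RARE))
    if bad_label.any():
        raise ValueError(f"row {int(df.index[bad_label][0])}: bad transition label")
    expect = [transition_label(c1, s2) for c1, s2 in zip(df["choice1"], df["state2"])]
    mismatch = df["transition"].to_numpy() != np.array(expect)
    if mismatch.any():
        row = int(df.index[mismatch][0])
        raise ValueError(
            f"row {row}: transition label inconsistent with choice1/state2 mapping")
    for col in ("rt1_ms", "rt2_ms"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ValueError(f"column {col} has negative reaction times")
    out = {}
    for sid, g in df.groupby("subject_id", sort=True):
        out[sid] = g.sort_values("trial").reset_index(drop=True)
    return out


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("covariate file needs a subject_id column")
    return df


def read_roi(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    need = {"subject_id", "icv_mm3"}
    if not need <= set(df.columns):
        raise ValueError(f"ROI file missing columns: {sorted(need - set(df.columns))}")
    vol_cols = [c for c in df.columns if c.endswith("_mm3")]
    if (df[vol_cols] <= 0).any().any():
        raise ValueError("ROI volumes and ICV must be positive")
    return df


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either the three input paths or ``synthesize=True`` (defaults of the
    synthetic cohort generator) must be provided.
    """

    trials_path: Optional[str] = None
    covariates_path: Optional[str] = None
    roi_path: Optional[str] = None
    synthesize: bool = False
    cohort_spec: Optional[object] = None  # CohortSpec; defaults when None
    models: Sequence[str] = ("hybrid", "mf", "mb")
    em: Dict = field(default_factory=dict)       # EMSettings overrides
    n_perm: int = 10_000
    ordering: Sequence[str] = ("OCD", "SIB", "HC")
    seed: int = 0
    output_dir: str = "twostep_out"

    def __post_init__(self) -> None:
        if not self.synthesize and self.trials_path is None:
            raise ValueError("provide input paths or set synthesize=True")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Dict:
    """Execute fit -> behavioral stats -> group inference -> ROI correlations.

    Writes every report as CSV under ``config.output_dir`` plus a JSON
    manifest recording (config hash, seed, package version, stage status,
    and the analysis defaults in force). A stage failure is logged and the
    remaining stages still run on whatever inputs exist.
    """
    from . import __version__
    from .behavior import (compute_subject_metrics, correlation_matrix,
                           fit_rt_model, fit_stay_model, build_stay_records)
    from .cohort import CohortSpec, generate_cohort
    from .em import EMSettings
    from .inference import omega_group_pipeline
    from .model import TwoStepModel
    from .neuro import normalize_volumes, roi_behavior_correlations

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "defaults": {
            "walk": "Gaussian steps sd 0.025 reflected at [0.25, 0.75] (assumed)",
            "stay_model": "two-stage summary-statistics estimator",
            "rt_model": "MixedLM random intercept + transition slope",
            "ibic_observations": "two choices per trial",
            "permutations": "unstratified label permutation, add-one p",
        },
    }
    rng = np.random.default_rng(config.seed)

    if config.synthesize:
        data = generate_cohort(config.cohort_spec or CohortSpec(), rng)
        trials_by_subject = {s: g.reset_index(drop=True)
                             for s, g in data.trials.groupby("subject_id")}
        covariates, roi = data.covariates, data.roi
        write_trials(data.trials, out / "trials.csv")
        covariates.to_csv(out / "covariates.csv", index=False)
        roi.to_csv(out / "roi.csv", index=False)
        data.truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        trials_by_subject = read_trials(config.trials_path)
        covariates = (read_covariates(config.covariates_path)
                      if config.covariates_path else None)
        roi = read_roi(config.roi_path) if config.roi_path else None

    results = {}
    omega = None
    comparison_rows = []
    try:
        settings_kwargs = dict(config.em)
        for model_name in config.models:
            settings = EMSettings(seed=config.seed, **settings_kwargs)
            res = TwoStepModel(trials_by_subject, model=model_name).fit(settings)
            res.params.to_csv(out / f"params_{model_name}.csv", index=False)
            comparison_rows.append({"model": model_name, "ibic": res.ibic,
                                    "n_params": res.n_free_params})
            results[model_name] = res
            if model_name == "hybrid":
                omega = res.omega()
        pd.DataFrame(comparison_rows).to_csv(out / "model_comparison.csv", index=False)
        manifest["stages"]["fit"] = "ok"
    except Exception as exc:
        logger.exception("fit stage failed")
        manifest["stages"]["fit"] = f"failed: {exc}"

    metrics = None
    try:
        metrics = compute_subject_metrics(trials_by_subject, omega, covariates)
        metrics.to_csv(out / "subject_metrics.csv", index=False)
        group_map = (covariates.set_index("subject_id")["group"]
                     if covariates is not None and "group" in covariates else None)
        rec = pd.concat(
            [build_stay_records(t, sid,
                                None if group_map is None else group_map.get(sid))
             for sid, t in trials_by_subject.items()], ignore_index=True)
        fit_stay_model(rec).to_csv(out / "stay_model.csv", index=False)
        long = pd.concat(
            [t.assign(subject_id=sid,
                      group=None if group_map is None else group_map.get(sid))
             for sid, t in trials_by_subject.items()], ignore_index=True)
        fit_rt_model(long).to_csv(out / "rt_model.csv", index=False)
        if omega is not None:
            correlation_matrix(metrics).to_csv(out / "correlation_matrix.csv",
                                               index=False)
        manifest["stages"]["behavior"] = "ok"
    except Exception as exc:
        logger.exception("behavior stage failed")
        manifest["stages"]["behavior"] = f"failed: {exc}"

    try:
        if metrics is not None and omega is not None and "group" in metrics:
            report = omega_group_pipeline(metrics, n_perm=config.n_perm,
                                          ordering=tuple(config.ordering),
                                          seed=config.seed)
            report.to_csv(out / "group_inference.csv", index=False)
            manifest["stages"]["inference"] = "ok"
        else:
            manifest["stages"]["inference"] = "skipped (no omega or group labels)"
    except Exception as exc:
        logger.exception("inference stage failed")
        manifest["stages"]["inference"] = f"failed: {exc}"

    try:
        if roi is not None and metrics is not None:
            norm = normalize_volumes(roi)
            norm.to_csv(out / "roi_normalized.csv", index=False)
            m = metrics.set_index("subject_id")
            corr = roi_behavior_correlations(
                m["rt_effect_ms"], norm,
                groups=m["group"] if "group" in m else None)
            corr.to_csv(out / "roi_correlations.csv", index=False)
            manifest["stages"]["neuro"] = "ok"
        else:
            manifest["stages"]["neuro"] = "skipped (no ROI table)"
            logger.info("neuro stage skipped: no ROI table")
    except Exception as exc:
        logger.exception("neuro stage failed")
        manifest["stages"]["neuro"] = f"failed: {exc}"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"manifest": manifest, "results": results, "metrics": metrics,
            "output_dir": str(out)}
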