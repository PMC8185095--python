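"""Choice and reaction-time statistics of the two-step task.

Covers the stay/switch analysis (does the previous trial's outcome and
transition type predict repeating the first-stage choice?), the second-stage
RT analysis (are responses slower after rare transitions?), per-subject
derived metrics, and the Spearman correlation matrix among the model-based /
model-free measures.

Effect coding convention: previous outcome +1 = reward, -1 = no reward;
previous transition +1 = common, -1 = rare. With this coding a pure
model-free learner shows a positive *outcome* main effect on staying and a
pure model-based learner a positive *outcome x transition* interaction.

For the RT model the transition regressor is an indicator for *common*
(1 = common, 0 = rare), so its coefficient is the common-minus-rare RT
difference — negative when rare transitions slow responding.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import COMMON

__all__ = [
    "build_stay_records",
    "subject_stay_coefs",
    "fit_stay_model",
    "rt_effect",
    "fit_rt_model",
    "repetition_probabilities",
    "correlation_matrix",
    "compute_subject_metrics",
]

logger = logging.getLogger(__name__)

STAY_TERMS = ("intercept", "outcome", "transition", "outcome:transition")

GROUPS = ("HC", "SIB", "OCD")


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .io import trials_to_dataframe

    return trials_to_dataframe(trials)


def build_stay_records(trials, subject_id: str = "s0",
                       group: Optional[str] = None) -> pd.DataFrame:
    """Stay/switch records for trials 2..n of one session.

    ``stay`` is 1 iff the first-stage choice repeats the previous trial's;
    ``prev_outcome`` / ``prev_transition`` are the previous trial's reward
    and transition type, effect-coded as documented above.
    """
    df = _as_frame(trials)
    if len(df) < 2:
        return pd.DataFrame(
            columns=["subject_id", "stay", "prev_outcome", "prev_transition", "group"]
        )
    c1 = df["choice1"].to_numpy()
    rew = df["reward"].to_numpy()
    trans = df["transition"].to_numpy()
    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "stay": (c1[1:] == c1[:-1]).astype(int),
            "prev_outcome": np.where(rew[:-1] == 1, 1, -1),
            "prev_transition": np.where(trans[:-1] == COMMON, 1, -1),
            "group": group,
        }
    )
    return out


def _penalized_logistic(X: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """Ridge-penalised logistic regression coefficients (guards separation)."""

    def nll(b):
        eta = X @ b
        # log(1 + exp(-eta*ysign)) computed stably
        ysign = 2.0 * y - 1.0
        val = np.logaddexp(0.0, -ysign * eta).sum()
        return val + 0.5 * penalty * b @ b

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        return X.T @ (p - y) + penalty * b

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    return res.x


def subject_stay_coefs(records: pd.DataFrame, penalty: float = 1e-3) -> Dict[str, float]:
    """Per-subject logistic coefficients of stay on outcome, transition and
    their interaction (ridge penalty guards against complete separation)."""
    o = records["prev_outcome"].to_numpy(float)
    t = records["prev_transition"].to_numpy(float)
    X = np.column_stack([np.ones_like(o), o, t, o * t])
    b = _penalized_logistic(X, records["stay"].to_numpy(float), penalty)
    return dict(zip(STAY_TERMS, b))


def _group_level_table(coefs: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Grand-mean and between-group contrasts of per-subject coefficients.

    One-sample t across all subjects for each term; OLS on group dummies
    (HC reference) for the group contrasts, plus an OCD-SIB recode pass.
    """
    import statsmodels.api as sm

    rows = []
    has_groups = coefs["group"].notna().all() and coefs["group"].nunique() > 1
    for term in terms:
        v = coefs[term].to_numpy(float)
        n = v.size
        m, se = v.mean(), v.std(ddof=1) / np.sqrt(n)
        tstat = m / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tstat), n - 1) if se > 0 else np.nan
        ci = stats.t.ppf(0.975, n - 1) * se
        rows.append({"term": term, "estimate": m, "se": se,
                     "ci_lo": m - ci, "ci_hi": m + ci, "p": p})
        if has_groups:
            for ref, others in (("HC", ("SIB", "OCD")), ("SIB", ("OCD",))):
                sub = coefs[coefs["group"].isin((ref,) + others)]
                dummies = pd.get_dummies(
                    pd.Categorical(sub["group"], categories=[ref] + list(others)),
                    drop_first=True, dtype=float)
                Xg = sm.add_constant(dummies.to_numpy())
                fit = sm.OLS(sub[term].to_numpy(float), Xg).fit()
                for j, other in enumerate(others, start=1):
                    if ref == "SIB" and other == "OCD":
                        label = f"{term}:group[OCD-SIB]"
                    elif ref != "HC":
                        continue
                    else:
                        label = f"{term}:group[{other}-HC]"
                    lo, hi = fit.conf_int()[j]
                    rows.append({"term": label, "estimate": fit.params[j],
                                 "se": fit.bse[j], "ci_lo": lo, "ci_hi": hi,
                                 "p": fit.pvalues[j]})
    return pd.DataFrame(rows)


def fit_stay_model(records: pd.DataFrame, penalty: float = 1e-3) -> pd.DataFrame:
    """Stay/switch regression: outcome x transition x group coefficient table.

    Two-stage summary-statistics estimator: ridge-penalised logistic fit per
    subject, then group-level inference on the per-subject coefficients
    (grand-mean t-tests; OLS group contrasts with HC as reference plus an
    OCD-SIB recode pass). The returned terms and their signs — not a
    particular mixed-model estimator — are the analysis contract.
    """
    if records["subject_id"].nunique() < 2:
        raise ValueError("stay model requires at least 2 subjects")
    per_subject = []
    for sid, g in records.groupby("subject_id", sort=True):
        row = subject_stay_coefs(g, penalty)
        row["subject_id"] = sid
        row["group"] = g["group"].iloc[0] if "group" in g else None
        per_subject.append(row)
    coefs = pd.DataFrame(per_subject)
    return _group_level_table(coefs, STAY_TERMS)


def rt_effect(trials) -> float:
    """Second-stage RT effect: mean RT on rare minus common transitions (ms).

    Positive values index knowledge of the transition structure (model-based
    slowing after rare transitions). NaN when either class has no valid RT.
    """
    df = _as_frame(trials)
    rt = pd.to_numeric(df["rt2_ms"], errors="coerce")
    valid = rt.notna() & (rt > 0)
    common = rt[valid & (df["transition"] == COMMON)]
    rare = rt[valid & (df["transition"] != COMMON)]
    if len(common) == 0 or len(rare) == 0:
        logger.warning("rt_effect undefined: a transition class has no valid RT")
        return float("nan")
    return float(rare.mean() - common.mean())


def fit_rt_model(trials: pd.DataFrame, method: str = "mixed") -> pd.DataFrame:
    """Second-stage RT regression on transition and group.

    Primary estimator: linear mixed model (random intercept and transition
    slope per subject) via statsmodels MixedLM. ``method="two-stage"`` — or
    a degenerate mixed fit — falls back to per-subject common-minus-rare
    differences analysed at the group level.

    The ``transition`` coefficient is the common-minus-rare RT difference
    (negative when rare transitions slow responding); ``transition:group[X-Y]``
    rows are between-group differences in that coefficient.
    """
    df = trials.copy()
    df["rt2_ms"] = pd.to_numeric(df["rt2_ms"], errors="coerce")
    df = df[df["rt2_ms"].notna() & (df["rt2_ms"] > 0)]
    df["trans_common"] = (df["transition"] == COMMON).astype(float)
    if df["subject_id"].nunique() < 2:
        raise ValueError("rt model requires at least 2 subjects")

    if method == "mixed":
        try:
            return _rt_mixed(df)
        except Exception as exc:  # singular fit, convergence failure
            logger.warning("MixedLM failed (%s); falling back to two-stage", exc)
    return _rt_two_stage(df)


def _rt_mixed(df: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.formula.api as smf

    has_groups = df["group"].notna().all() and df["group"].nunique() > 1
    rows = []

    def collect(fit, wanted: Dict[str, str]):
        ci = fit.conf_int()
        for name, label in wanted.items():
            if name not in fit.params.index:
                continue
            rows.append({"term": label, "estimate": fit.params[name],
                         "se": fit.bse[name], "ci_lo": ci.loc[name, 0],
                         "ci_hi": ci.loc[name, 1], "p": fit.pvalues[name]})

    if has_groups:
        df = df.copy()
        df["group"] = pd.Categorical(df["group"], categories=list(GROUPS))
        fit = smf.mixedlm("rt2_ms ~ trans_common * group", df,
                          groups=df["subject_id"], re_formula="~trans_common").fit()
        collect(fit, {
            "Intercept": "intercept",
            "trans_common": "transition",
            "trans_common:group[T.SIB]": "transition:group[SIB-HC]",
            "trans_common:group[T.OCD]": "transition:group[OCD-HC]",
        })
        df2 = df.copy()
        df2["group"] = pd.Categorical(df2["group"], categories=["SIB", "OCD", "HC"])
        fit2 = smf.mixedlm("rt2_ms ~ trans_common * group", df2,
                           groups=df2["subject_id"], re_formula="~trans_common").fit()
        collect(fit2, {"trans_common:group[T.OCD]": "transition:group[OCD-SIB]"})
    else:
        fit = smf.mixedlm("rt2_ms ~ trans_common", df, groups=df["subject_id"],
                          re_formula="~trans_common").fit()
        collect(fit, {"Intercept": "intercept", "trans_common": "transition"})
    return pd.DataFrame(rows)


def _rt_two_stage(df: pd.DataFrame) -> pd.DataFrame:
    per = []
    for sid, g in df.groupby("subject_id", sort=True):
        eff = rt_effect(g)
        per.append({"subject_id": sid, "transition": -eff,  # common - rare
                    "group": g["group"].iloc[0] if "group" in g else None})
    coefs = pd.DataFrame(per).dropna(subset=["transition"])
    return _group_level_table(coefs, ["transition"])


def repetition_probabilities(trials, subject_id: str = "s0") -> pd.DataFrame:
    """Empirical P(stay) per previous-outcome x previous-transition cell.

    Rows: reward / no_reward; columns: common / rare. Empty cells are NaN.
    """
    rec = build_stay_records(trials, subject_id)
    table = pd.DataFrame(index=["reward", "no_reward"], columns=["common", "rare"],
                         dtype=float)
    for o_label, o in (("reward", 1), ("no_reward", -1)):
        for t_label, t in (("common", 1), ("rare", -1)):
            cell = rec[(rec["prev_outcome"] == o) & (rec["prev_transition"] == t)]
            table.loc[o_label, t_label] = cell["stay"].mean() if len(cell) else np.nan
    return table


DEFAULT_METRICS = ("omega_hat", "rt_effect_ms", "interaction_coef", "outcome_coef")


def correlation_matrix(metrics: pd.DataFrame,
                       columns: Sequence[str] = DEFAULT_METRICS) -> pd.DataFrame:
    """Pairwise Spearman correlations among subject-level task measures.

    Returns a long table (var1, var2, rho, p, n); pairs with a constant
    column get NaN and a log entry.
    """
    clean = metrics[list(columns)].dropna()
    if len(clean) < 4:
        raise ValueError("correlation matrix requires >= 4 complete subjects")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            x, y = clean[a].to_numpy(float), clean[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s~%s undefined (constant column)", a, b)
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"var1": a, "var2": b, "rho": rho, "p": p, "n": len(clean)})
    return pd.DataFrame(rows)


def compute_subject_metrics(trials_by_subject: Dict[str, pd.DataFrame],
                            omega_hat: Optional[pd.Series] = None,
                            covariates: Optional[pd.DataFrame] = None,
                            penalty: float = 1e-3) -> pd.DataFrame:
    """Assemble the per-subject metrics table used by downstream inference.

    Columns: omega_hat (if provided), rt_effect_ms, outcome_coef,
    interaction_coef, plus any covariate columns (merged on subject_id).
    """
    rows = []
    for sid, trials in trials_by_subject.items():
        rec = build_stay_records(trials, sid)
        coefs = subject_stay_coefs(rec, penalty)
        rows.append({
            "subject_id": sid,
            "rt_effect_ms": rt_effect(trials),
            "outcome_coef": coefs["outcome"],
            "interaction_coef": coefs["outcome:transition"],
        })
    out = pd.DataFrame(rows)
    if omega_hat is not None:
        om = omega_hat.rename("omega_hat").rename_axis("subject_id").reset_index()
        out = out.merge(om, on="subject_id", how="left")
    if covariates is not None:
        out = out.merge(covariates, on="subject_id", how="left")
    return out
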