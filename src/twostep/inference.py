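"""Ordered-group and pairwise inference, residualization, partial correlation.

The ordered-alternative test is the Jonckheere–Terpstra statistic evaluated
by label permutation (Monte Carlo by default; exhaustive enumeration for tiny
groups). Robustness arms repeat the group tests after residualizing the
tested values on nuisance covariates.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JTResult",
    "PartialCorrResult",
    "jonckheere_terpstra",
    "wilcoxon_ranksum",
    "residualize",
    "partial_correlation",
    "omega_group_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class JTResult:
    j_stat: float
    p_value: float
    n_perm: int
    ordering: tuple[str, ...]
    direction: str
    j_max: float = 0.0
    method: str = "montecarlo"


@dataclass
class PartialCorrResult:
    r: float
    p_value: float
    covariates: tuple[str, ...]
    n: int
    method: str = "pearson"


def _jt_stat_batch(pool: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """J statistic for each row of ``pool`` (rows are permuted value vectors).

    J = sum over ordered group pairs (i before j) of
        #(x_i < x_j) + 0.5 * #(x_i == x_j).
    """
    bounds = np.cumsum([0] + list(sizes))
    blocks = [pool[:, bounds[k]:bounds[k + 1]] for k in range(len(sizes))]
    j = np.zeros(pool.shape[0])
    for a in range(len(sizes)):
        for b in range(a + 1, len(sizes)):
            lo = blocks[a][:, :, None]
            hi = blocks[b][:, None, :]
            j += (lo < hi).sum(axis=(1, 2)) + 0.5 * (lo == hi).sum(axis=(1, 2))
    return j


def jonckheere_terpstra(
    values_by_group: Dict[str, np.ndarray],
    ordering: Sequence[str],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    method: str = "montecarlo",
    direction: str = "increasing",
) -> JTResult:
    """Jonckheere–Terpstra permutation test for an ordered alternative.

    ``ordering`` lists the groups from smallest to largest expected location
    under the alternative (``direction="increasing"``); ``"decreasing"``
    reverses it. The permutation p-value is one-sided for that ordering,
    with the add-one convention p = (1 + #{J* >= J}) / (1 + n_perm); the
    exact method enumerates every distinct label assignment instead.
    """
    for g in ordering:
        if g not in values_by_group:
            raise ValueError(f"group '{g}' in ordering but not in data")
    order = list(ordering) if direction == "increasing" else list(ordering)[::-1]
    groups = [np.asarray(values_by_group[g], float) for g in order]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    sizes = [g.size for g in groups]
    pool = np.concatenate(groups)
    j_obs = float(_jt_stat_batch(pool[None, :], sizes)[0])
    j_max = float(sum(sizes[a] * sizes[b]
                      for a in range(len(sizes)) for b in range(a + 1, len(sizes))))

    if method == "exact":
        count = total = 0
        idx = np.arange(pool.size)
        perms = []
        for assign in _enumerate_assignments(idx, sizes):
            perms.append(pool[assign])
        js = _jt_stat_batch(np.array(perms), sizes)
        total = js.size
        count = int(np.sum(js >= j_obs - 1e-12))
        p = count / total
        return JTResult(j_obs, p, total, tuple(ordering), direction, j_max, "exact")

    rng = rng if rng is not None else np.random.default_rng()
    count = 0
    batch = 2000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = rng.permuted(np.tile(pool, (b, 1)), axis=1)
        js = _jt_stat_batch(perms, sizes)
        count += int(np.sum(js >= j_obs - 1e-12))
        done += b
    p = (1 + count) / (1 + n_perm)
    return JTResult(j_obs, p, n_perm, tuple(ordering), direction, j_max, "montecarlo")


def _enumerate_assignments(idx: np.ndarray, sizes: Sequence[int]):
    """All distinct splits of ``idx`` into consecutive groups of given sizes."""
    if len(sizes) == 1:
        yield list(idx)
        return
    for head in itertools.combinations(range(idx.size), sizes[0]):
        mask = np.zeros(idx.size, bool)
        mask[list(head)] = True
        for rest in _enumerate_assignments(idx[~mask], sizes[1:]):
            yield list(idx[mask]) + rest


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise. Returns (U statistic, p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= 8 and not ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if small else "asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def residualize(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus the covariate columns.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution (residuals stay orthogonal to every covariate); the deficiency
    is logged.
    """
    y = np.asarray(values, float)
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any() or np.isnan(y).any():
        raise ValueError("covariates and values must be complete (no NaN)")
    X = np.column_stack([np.ones(len(y)), C])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("residualize: design rank %d < %d columns (collinearity)",
                       rank, X.shape[1])
    return y - X @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame,
    method: str = "pearson",
) -> PartialCorrResult:
    """Correlation between x and y after removing the covariates from both.

    ``spearman`` ranks all variables first. The p-value uses the t
    distribution with n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = pd.DataFrame(covariates)
    n, k = x.size, C.shape[1]
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        C = C.apply(lambda c: stats.rankdata(c))
    rx = residualize(x, C)
    ry = residualize(y, C)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("partial correlation undefined: constant residuals")
        return PartialCorrResult(float("nan"), float("nan"),
                                 tuple(map(str, C.columns)), n, method)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrResult(r, float(p), tuple(map(str, C.columns)), n, method)


DEFAULT_ORDERING = ("OCD", "SIB", "HC")  # expected increasing in omega


def omega_group_pipeline(
    metrics: pd.DataFrame,
    value_col: str = "omega_hat",
    ordering: Sequence[str] = DEFAULT_ORDERING,
    n_perm: int = 10_000,
    seed: int = 0,
    covariate_arms: Optional[Dict[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Ordered and pairwise group tests on a subject metric, raw and after
    covariate residualization.

    Default arms mirror the robustness sequence for the model-based weight:
    raw values, values residualized on age, and values residualized on the
    cognitive scores (DSST, digit-span backwards). Arms whose covariates are
    missing from ``metrics`` are skipped with a log entry.
    """
    if covariate_arms is None:
        covariate_arms = {"raw": (), "minus_age": ("age",),
                          "minus_cognition": ("dsst", "ds_backwards")}
    rng = np.random.default_rng(seed)
    df = metrics.dropna(subset=[value_col, "group"])
    rows = []
    for arm, covs in covariate_arms.items():
        missing = [c for c in covs if c not in df.columns or df[c].isna().any()]
        if missing:
            logger.warning("pipeline arm '%s' skipped (missing covariates %s)",
                           arm, missing)
            continue
        vals = df[value_col].to_numpy(float)
        if covs:
            vals = residualize(vals, df[list(covs)])
        by_group = {g: vals[(df["group"] == g).to_numpy()] for g in ordering}
        jt = jonckheere_terpstra(by_group, ordering, n_perm=n_perm, rng=rng)
        rows.append({"analysis": "jonckheere_terpstra", "arm": arm,
                     "groups": "<".join(ordering), "statistic": jt.j_stat,
                     "p": jt.p_value, "n_perm": jt.n_perm,
                     "covariates_removed": "+".join(covs), "seed": seed})
        for ga, gb in itertools.combinations(ordering[::-1], 2):
            u, p = wilcoxon_ranksum(by_group[ga], by_group[gb])
            rows.append({"analysis": f"wilcoxon[{ga}-{gb}]", "arm": arm,
                         "groups": f"{ga},{gb}", "statistic": u, "p": p,
                         "n_perm": 0, "covariates_removed": "+".join(covs),
                         "seed": seed})
    return pd.DataFrame(rows)
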