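"""ROI-level brain–behavior analysis.

Consumes a plain table of subcortical volumes (mm^3) with intracranial
volume (ICV), normalizes by head size, and correlates the normalized volumes
with behavioral metrics overall and within each group. Extraction of the
volumes from imaging is upstream of this package; units are mm^3 throughout.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import partial_correlation

__all__ = ["ROI_COLUMNS", "normalize_volumes", "roi_behavior_correlations"]

logger = logging.getLogger(__name__)

ROI_COLUMNS = ("putamen_l_mm3", "putamen_r_mm3", "caudate_l_mm3", "caudate_r_mm3")

#: normalized ratios are conventionally displayed multiplied by 10,000
DISPLAY_SCALE = 10_000.0


def normalize_volumes(table: pd.DataFrame,
                      roi_columns: Sequence[str] = ROI_COLUMNS) -> pd.DataFrame:
    """Divide each ROI volume by the subject's intracranial volume.

    Adds ``<roi>_norm`` (ratio) and ``<roi>_norm_x1e4`` (display scale)
    columns. Rows with nonpositive ICV are rejected.
    """
    df = table.copy()
    bad = df["icv_mm3"] <= 0
    if bad.any():
        logger.warning("normalize_volumes: dropping %d rows with nonpositive ICV",
                       int(bad.sum()))
        df = df[~bad]
    for col in roi_columns:
        base = col.removesuffix("_mm3")
        df[f"{base}_norm"] = df[col] / df["icv_mm3"]
        df[f"{base}_norm_x1e4"] = df[f"{base}_norm"] * DISPLAY_SCALE
    return df


def roi_behavior_correlations(
    metric: pd.Series,
    normalized: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    roi_columns: Sequence[str] = ROI_COLUMNS,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Spearman correlations between a behavioral metric and normalized ROI
    volumes, overall and within each group.

    ``metric`` and ``groups`` are indexed by subject_id, as is ``normalized``
    (via its ``subject_id`` column). When ``covariates`` is given (indexed the
    same way), covariate-adjusted Spearman partial correlations are reported
    instead of plain ones.
    """
    df = normalized.set_index("subject_id")
    rows = []
    scopes = [("overall", df.index)]
    if groups is not None:
        for g in pd.unique(groups):
            scopes.append((str(g), groups.index[groups == g]))
    for col in roi_columns:
        base = col.removesuffix("_mm3")
        vol = df[f"{base}_norm"]
        for scope, idx in scopes:
            ids = [i for i in idx if i in vol.index and i in metric.index
                   and np.isfinite(metric[i]) and np.isfinite(vol[i])]
            n = len(ids)
            if n < 4:
                logger.warning("scope %s for %s has n=%d < 4; skipped", scope, base, n)
                continue
            x = metric.loc[ids].to_numpy(float)
            y = vol.loc[ids].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = np.nan, np.nan
                logger.warning("constant vector in scope %s for %s", scope, base)
            elif covariates is not None:
                res = partial_correlation(x, y, covariates.loc[ids], method="spearman")
                rho, p = res.r, res.p_value
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"roi": base, "scope": scope, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(rows)
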