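"""Phenotype quality control: outlier masking, AUC traits, trait correlations.

Outliers are defined as single measurements deviating from the trait mean by
more than ``k`` standard deviations (default 4) and are masked per trait, not
removed as whole animals.  The rule runs in a single pass: mean and SD are
computed once on all non-missing values, including any outliers, and values
are flagged against that estimate.  Re-running on the cleaned table may flag
further values (the estimate shifts once extremes are masked); the removal
log makes the pass reproducible.

Trait-pair correlations are gated by per-trait normality: Pearson if both
traits pass a Shapiro-Wilk test, Spearman otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import trait_columns

logger = logging.getLogger(__name__)


def remove_outliers(
    table: pd.DataFrame, k: float = 4.0, traits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask per-trait values more than ``k`` SD from the trait mean.

    Returns the cleaned table (flagged values set to NaN) and a removal log
    with columns ``id, trait, value, z``.  Traits with fewer than 3
    non-missing values, or zero SD, are skipped with a warning.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    traits = list(traits) if traits is not None else trait_columns(table)
    out = table.copy()
    log_rows = []
    for t in traits:
        vals = table[t].dropna()
        if len(vals) < 3:
            logger.warning("trait %r has < 3 non-missing values; outlier rule skipped", t)
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        z = (vals - vals.mean()) / sd
        flagged = z[z.abs() > k]
        for ind, zval in flagged.items():
            log_rows.append({"id": ind, "trait": t, "value": table.at[ind, t], "z": zval})
            out.at[ind, t] = np.nan
    log = pd.DataFrame(log_rows, columns=["id", "trait", "value", "z"])
    return out, log


def compute_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a tolerance-test curve (e.g. mg/dl x min).

    ``times`` must be strictly increasing with at least two points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two time points")
    if len(t) != len(y):
        raise ValueError("times and values must have equal length")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


@dataclass(frozen=True)
class CorrelationReport:
    trait1: str
    trait2: str
    method: str  # "pearson" or "spearman"
    r: float
    p: float
    n: int


def correlation_matrix(
    table: pd.DataFrame,
    traits: Sequence[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Normality-gated pairwise trait correlations.

    Each trait is tested once for normality (Shapiro-Wilk on its non-missing
    values); a pair is correlated with Pearson iff both traits pass at
    ``normality_alpha``, with Spearman otherwise, using pairwise-complete
    observations.  Constant traits yield NaN coefficients.

    Returns a long-form frame ``trait1 trait2 method r p n`` covering each
    unordered pair once.
    """
    traits = list(traits) if traits is not None else trait_columns(table)
    normal: dict[str, bool] = {}
    for t in traits:
        vals = table[t].dropna()
        if len(vals) < 3 or vals.nunique() < 2:
            normal[t] = False
            continue
        normal[t] = stats.shapiro(vals).pvalue >= normality_alpha

    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            sub = table[[t1, t2]].dropna()
            n = len(sub)
            method = "pearson" if (normal[t1] and normal[t2]) else "spearman"
            if n < 3 or sub[t1].nunique() < 2 or sub[t2].nunique() < 2:
                rows.append(
                    {"trait1": t1, "trait2": t2, "method": method, "r": np.nan, "p": np.nan, "n": n}
                )
                continue
            if method == "pearson":
                res = stats.pearsonr(sub[t1], sub[t2])
            else:
                res = stats.spearmanr(sub[t1], sub[t2])
            rows.append(
                {
                    "trait1": t1,
                    "trait2": t2,
                    "method": method,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["trait1", "trait2", "method", "r", "p", "n"])


def correlation_square(report: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """Render a long-form correlation report as a symmetric matrix with unit diagonal."""
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in report.iterrows():
        mat.at[row["trait1"], row["trait2"]] = row["r"]
        mat.at[row["trait2"], row["trait1"]] = row["r"]
    return mat
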