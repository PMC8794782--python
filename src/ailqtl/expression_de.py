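"""Microarray-style expression analysis: normalization, DE tests, line clustering.

Intensities are log2-transformed and quantile normalized within tissue, then
each probe is tested for a between-line difference with a Welch two-sample
t-test; p-values are Benjamini-Hochberg adjusted across probes within
tissue.  Fold change is reported as the difference of group means on the
log2 scale (S1 - S2), matching the small FC magnitudes typical of
quantile-normalized arrays.

``cluster_by_line`` reproduces the heatmap-dendrogram logic used to decide
which tissue carries the line signal: average-linkage hierarchical
clustering on 1 - sample correlation, cut into two clusters, checked against
the line labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)


def _quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: columns share the mean sorted profile.

    Ties within a column get the mean of their tied ranks' reference values
    (average ranks interpolated into the sorted-reference profile).
    """
    n, m = mat.shape
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat, dtype=float)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = stats.rankdata(mat[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return out


def normalize(x: ExpressionMatrix, epsilon: float = 1e-6) -> ExpressionMatrix:
    """Log2 transform then quantile-normalize samples within each tissue.

    Raw intensities must be non-negative; zeros are offset by ``epsilon``
    before the log.  A tissue with a single sample is only log-transformed
    (warned) since quantile normalization needs at least two columns.
    """
    vals = x.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensities cannot be log-transformed")
    log2 = np.log2(vals + epsilon * (vals == 0))
    out = np.array(log2)
    for tissue in x.tissues:
        cols = np.flatnonzero((x.samples["tissue"] == tissue).to_numpy())
        if len(cols) < 2:
            logger.warning("tissue %r has a single sample; quantile step skipped", tissue)
            continue
        out[:, cols] = _quantile_normalize(log2[:, cols])
    values = pd.DataFrame(out, index=x.values.index, columns=x.values.columns)
    return ExpressionMatrix(values, x.samples.copy(), x.probe_genes.copy())


def differential_expression(
    x: ExpressionMatrix,
    group_col: str = "line",
    groups: tuple[str, str] = ("S1", "S2"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch t-tests between two lines, BH-adjusted within tissue.

    Expects normalized (log2-scale) values.  Returns a long frame
    ``probe gene tissue fc p p_adj significant`` where ``fc`` is the
    log2-scale difference of group means (first group minus second).
    Probes with zero variance in both groups and equal means get p = 1.
    """
    rows = []
    for tissue in x.tissues:
        sub = x.tissue_subset(tissue)
        g1 = sub.samples.index[sub.samples[group_col] == groups[0]]
        g2 = sub.samples.index[sub.samples[group_col] == groups[1]]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 2 samples per group")
        a = sub.values[g1].to_numpy(dtype=float)
        b = sub.values[g2].to_numpy(dtype=float)
        fc = a.mean(axis=1) - b.mean(axis=1)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = np.isnan(p)
        p[degenerate & (np.abs(fc) < 1e-12)] = 1.0
        p[degenerate & (np.abs(fc) >= 1e-12)] = 0.0
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        frame = pd.DataFrame(
            {
                "probe": sub.values.index,
                "gene": sub.probe_genes.to_numpy(),
                "tissue": tissue,
                "fc": fc,
                "p": p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def de_genes_any_tissue(de: pd.DataFrame) -> set[str]:
    """Genes significant (BH-adjusted p < alpha flag) in at least one tissue."""
    return set(de.loc[de["significant"], "gene"].dropna().unique())


@dataclass(frozen=True)
class CohesionReport:
    perfect_separation: bool
    cohesion: float
    n_samples: int


def cluster_by_line(x: ExpressionMatrix, group_col: str = "line") -> CohesionReport:
    """Do samples of the same line cluster together?

    Average-linkage hierarchical clustering of 1 - Pearson correlation
    between samples, cut into two clusters.  ``perfect_separation`` is true
    iff the two clusters coincide with the two line labels; ``cohesion`` is
    mean within-line minus mean between-line sample correlation.
    """
    if x.values.shape[1] < 4:
        raise ValueError("need at least 4 samples to assess clustering")
    corr = np.corrcoef(x.values.to_numpy(dtype=float).T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard tiny asymmetries
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=2, criterion="maxclust")
    labels = x.samples[group_col].to_numpy()
    lines = pd.unique(labels)
    perfect = False
    if len(lines) == 2 and len(np.unique(assignment)) == 2:
        mask = labels == lines[0]
        perfect = (
            len(np.unique(assignment[mask])) == 1
            and len(np.unique(assignment[~mask])) == 1
            and assignment[mask][0] != assignment[~mask][0]
        )
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    cohesion = float(corr[same & off_diag].mean() - corr[~same].mean())
    return CohesionReport(perfect_separation=bool(perfect), cohesion=cohesion, n_samples=len(labels))
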