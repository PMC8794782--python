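"""Pairwise causal modeling of a QTL shared by two traits.

When one locus is associated with two traits, three generative structures
can explain the joint data: the QTL drives both traits directly
(*independent*), it drives T1 which in turn drives T2 (*causal*), or the
mirror image (*reactive*).  Each structure factorizes the joint likelihood
of (T1, T2) given the genotype Q into two Gaussian linear components:

    independent:  [T1 | Q]  +  [T2 | Q]
    causal:       [T1 | Q]  +  [T2 | T1]
    reactive:     [T2 | Q]  +  [T1 | T2]

with the genotype entering as an unordered 3-level factor.  Models are
compared by the small-sample-corrected Akaike criterion (AICc; the three
structures are non-nested, so a likelihood-ratio test does not apply).  The
best structure is accepted only if it beats the runner-up by at least a
configurable AICc gap (default 2.0); otherwise, or when the winning model's
residuals fail a goodness-of-fit screen, causality is left *undetermined*.

A winning *causal* verdict labels the QTL's effect on T1 direct and on T2
indirect (mediated through T1); *independent* labels both direct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VERDICTS = ("independent", "causal_T1_to_T2", "reactive_T2_to_T1", "undetermined")


@dataclass(frozen=True)
class ModelFit:
    name: str
    loglik: float
    n_params: int
    aicc: float


@dataclass
class CausalVerdict:
    marker: str
    trait1: str
    trait2: str
    fits: dict[str, ModelFit]
    verdict: str
    margin: float
    gof_pass: bool


def _gauss_component_ll(y: np.ndarray, X: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Max log-likelihood, parameter count (incl. sigma), residuals of y ~ X."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(float(y @ y), 1.0):
        return np.inf, X.shape[1] + 1, resid  # degenerate: exact fit
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return float(ll), X.shape[1] + 1, resid


def _factor_design(q: np.ndarray) -> np.ndarray:
    levels = np.unique(q)
    cols = [np.ones(len(q))] + [(q == lvl).astype(float) for lvl in levels[1:]]
    return np.column_stack(cols)


def _slope_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(x)), x])


def _aicc(ll: float, k: int, n: int) -> float:
    if not np.isfinite(ll):
        return -np.inf
    penalty = 2 * k + (2 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return -2 * ll + penalty


def fit_causal_models(
    q: Sequence[float],
    t1: Sequence[float],
    t2: Sequence[float],
    gap: float = 2.0,
    marker: str = "",
    trait1: str = "T1",
    trait2: str = "T2",
    gof_alpha: float = 0.01,
) -> CausalVerdict:
    """Classify the effect structure of one QTL over a trait pair.

    Complete cases only; requires at least 30 of them and at least two
    genotype classes.  Returns the per-model fits, the winning verdict, and
    the AICc margin to the runner-up (``undetermined`` when the margin is
    below ``gap`` or the winner's residuals fail Shapiro-Wilk at
    ``gof_alpha``).
    """
    q = np.asarray(q, dtype=float)
    t1v = np.asarray(t1, dtype=float)
    t2v = np.asarray(t2, dtype=float)
    ok = ~(np.isnan(q) | np.isnan(t1v) | np.isnan(t2v))
    q, t1v, t2v = q[ok], t1v[ok], t2v[ok]
    n = len(q)
    if n < 30:
        raise ValueError(f"need >= 30 complete cases, got {n}")
    if len(np.unique(q)) < 2:
        raise ValueError("genotype must have >= 2 classes")
    if np.std(t1v) == 0 or np.std(t2v) == 0:
        raise ValueError("constant trait")

    Xq = _factor_design(q)
    components = {
        "independent": [(t1v, Xq), (t2v, Xq)],
        "causal_T1_to_T2": [(t1v, Xq), (t2v, _slope_design(t1v))],
        "reactive_T2_to_T1": [(t2v, Xq), (t1v, _slope_design(t2v))],
    }
    fits: dict[str, ModelFit] = {}
    residuals: dict[str, list[np.ndarray]] = {}
    for name, comps in components.items():
        ll_total, k_total, res = 0.0, 0, []
        for y, X in comps:
            ll, k, r = _gauss_component_ll(y, X)
            ll_total += ll
            k_total += k
            res.append(r)
        fits[name] = ModelFit(name, float(ll_total), k_total, _aicc(ll_total, k_total, n))
        residuals[name] = res

    ranked = sorted(fits.values(), key=lambda f: f.aicc)
    best, runner = ranked[0], ranked[1]
    if not np.isfinite(best.aicc) and not np.isfinite(runner.aicc):
        margin = 0.0  # two degenerate exact fits are indistinguishable
    else:
        margin = float(runner.aicc - best.aicc)

    gof_pass = True
    for r in residuals[best.name]:
        if not np.all(np.isfinite(r)) or np.std(r) == 0:
            gof_pass = False
            break
        if len(r) >= 3 and stats.shapiro(r).pvalue < gof_alpha:
            gof_pass = False
            break

    if margin < gap or not gof_pass:
        verdict = "undetermined"
    else:
        verdict = best.name
    return CausalVerdict(
        marker=marker,
        trait1=trait1,
        trait2=trait2,
        fits=fits,
        verdict=verdict,
        margin=margin,
        gof_pass=gof_pass,
    )


def classify_qtl_effects(
    verdicts: Sequence[CausalVerdict],
) -> tuple[dict[str, str], list[str]]:
    """Roll pairwise verdicts up to per-trait direct/indirect labels.

    ``independent`` labels both traits direct; ``causal_T1_to_T2`` labels T1
    direct and T2 indirect (and symmetrically for reactive); undetermined
    pairs label nothing.  Traits given conflicting labels across pairs are
    reported in the conflict list and left unlabeled.
    """
    markers = {v.marker for v in verdicts}
    if len(markers) > 1:
        raise ValueError(f"verdicts span multiple QTL markers: {sorted(markers)}")
    proposed: dict[str, set[str]] = {}

    def add(trait: str, label: str) -> None:
        proposed.setdefault(trait, set()).add(label)

    for v in verdicts:
        if v.verdict == "independent":
            add(v.trait1, "direct")
            add(v.trait2, "direct")
        elif v.verdict == "causal_T1_to_T2":
            add(v.trait1, "direct")
            add(v.trait2, "indirect")
        elif v.verdict == "reactive_T2_to_T1":
            add(v.trait2, "direct")
            add(v.trait1, "indirect")

    labels: dict[str, str] = {}
    conflicts: list[str] = []
    for trait, lab in proposed.items():
        if len(lab) == 1:
            labels[trait] = next(iter(lab))
        else:
            conflicts.append(trait)
    return labels, conflicts


def verdicts_to_frame(verdicts: Sequence[CausalVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {
            "marker": v.marker,
            "trait1": v.trait1,
            "trait2": v.trait2,
            "verdict": v.verdict,
            "margin": v.margin,
            "gof_pass": v.gof_pass,
        }
        for name, fit in v.fits.items():
            row[f"aicc_{name}"] = fit.aicc
            row[f"loglik_{name}"] = fit.loglik
        rows.append(row)
    return pd.DataFrame(rows)
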