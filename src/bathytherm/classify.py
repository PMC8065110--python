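"""Occupancy classification: ROC analysis, Index-of-Union cut-point, and
habitat envelopes.

The fitted model yields continuous presence probabilities; conservation
summaries need a binary occupied/unoccupied call. The cut-point c is chosen
by minimising the Index of Union,

    IU(c) = |Se(c) - AUC| + |Sp(c) - AUC|,

over the observed unique scores, where Se/Sp are sensitivity/specificity of
the rule "predict presence iff score >= c" and AUC is the trapezoidal area
under the ROC curve. Cells with probability at or above c form the core
habitat; the top-quartile rule flags cells at or above the 75th percentile
of unmasked probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .habitat import HabitatFit, predict_probability

__all__ = [
    "RocCurve",
    "CutpointResult",
    "HabitatEnvelope",
    "roc_curve",
    "iu_cutpoint",
    "classify_occupancy",
    "core_habitat_envelope",
    "top_quartile_habitat",
]


@dataclass
class RocCurve:
    """ROC summary over the unique observed scores (ascending).

    se[k]/sp[k] are the sensitivity/specificity of "positive iff score >=
    thresholds[k]"; se is non-increasing and sp non-decreasing in k.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float


@dataclass
class CutpointResult:
    c: float
    iu_value: float
    se_at_c: float
    sp_at_c: float


def roc_curve(scores, labels) -> RocCurve:
    """Exact ROC curve with candidate thresholds at the unique scores.

    AUC is the trapezoidal area over the full curve (including the
    (0,0)/(1,1) endpoints), which equals the Mann-Whitney rank statistic
    with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)
    # counts of pos/neg scores >= each threshold, via cumulative sums
    pos_counts = np.bincount(np.searchsorted(thresholds, scores[pos]), minlength=len(thresholds))
    neg_counts = np.bincount(np.searchsorted(thresholds, scores[neg]), minlength=len(thresholds))
    pos_ge = np.cumsum(pos_counts[::-1])[::-1]
    neg_ge = np.cumsum(neg_counts[::-1])[::-1]
    se = pos_ge / n_pos
    sp = (n_neg - neg_ge) / n_neg
    # trapezoid over (FPR, TPR), thresholds descending, endpoints included
    fpr = np.concatenate([[0.0], (neg_ge / n_neg)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], se[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, se=se, sp=sp, auc=auc)


def iu_cutpoint(roc: RocCurve) -> CutpointResult:
    """Minimise IU(c) = |Se - AUC| + |Sp - AUC| over the candidate
    thresholds; ties broken by smaller |Se - Sp|, then smaller c."""
    iu = np.abs(roc.se - roc.auc) + np.abs(roc.sp - roc.auc)
    m = iu.min()
    tied = np.flatnonzero(iu <= m + 1e-12)
    balance = np.abs(roc.se[tied] - roc.sp[tied])
    b = balance.min()
    tied = tied[balance <= b + 1e-12]
    k = int(tied[np.argmin(roc.thresholds[tied])])
    return CutpointResult(
        c=float(roc.thresholds[k]),
        iu_value=float(iu[k]),
        se_at_c=float(roc.se[k]),
        sp_at_c=float(roc.sp[k]),
    )


def classify_occupancy(prob_field, c: float) -> np.ndarray:
    """Binary occupancy: 1 where probability >= c, 0 below, NaN preserved
    for masked cells."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("cut-point must be in [0, 1]")
    p = np.asarray(prob_field, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    out = np.where(p >= c, 1.0, 0.0)
    out[~finite] = np.nan
    return out


@dataclass
class HabitatEnvelope:
    """Covariate-space region with predicted probability >= c."""

    sst_interval: tuple[float, float] | None
    depth_interval: tuple[float, float] | None
    sst_grid: np.ndarray
    depth_grid: np.ndarray
    region: np.ndarray  # bool, shape (len(depth_grid), len(sst_grid))
    empty: bool


def core_habitat_envelope(
    fit: HabitatFit,
    c: float,
    sst_range: tuple[float, float] = (0.0, 35.0),
    depth_range: tuple[float, float] = (0.0, 250.0),
    n_sst: int = 701,
    n_depth: int = 501,
) -> HabitatEnvelope:
    """Bounding SST and depth intervals of the region with p >= c.

    Evaluated on a fine covariate grid; for the concave quadratic surface
    the region is an ellipse-like sub-level set, so the bounding interval
    in each covariate is attained at the other covariate's optimum.
    """
    sst = np.linspace(*sst_range, n_sst)
    depth = np.linspace(*depth_range, n_depth)
    ss, dd = np.meshgrid(sst, depth)
    p = predict_probability(fit, ss, dd)
    region = p >= c
    if not region.any():
        return HabitatEnvelope(None, None, sst, depth, region, True)
    s_any = region.any(axis=0)
    d_any = region.any(axis=1)
    return HabitatEnvelope(
        sst_interval=(float(sst[s_any].min()), float(sst[s_any].max())),
        depth_interval=(float(depth[d_any].min()), float(depth[d_any].max())),
        sst_grid=sst,
        depth_grid=depth,
        region=region,
        empty=False,
    )


def top_quartile_habitat(prob_field) -> np.ndarray:
    """Flag cells at or above the 75th percentile (inclusive linear-
    interpolation quantile) of the unmasked probabilities."""
    p = np.asarray(prob_field, dtype=float)
    vals = p[np.isfinite(p)]
    if len(vals) < 4:
        raise ValueError("need at least 4 unmasked cells")
    q75 = float(np.quantile(vals, 0.75))
    if np.ptp(vals) == 0:
        warnings.warn("constant probability field: all unmasked cells flagged")
    out = np.where(p >= q75, 1.0, 0.0)
    out[~np.isfinite(p)] = np.nan
    return out
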