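"""Pairwise diagnostic (ROC) evaluation of IVIM parameters between grades.

For each grade pair the less-differentiated group is the positive class
(PD over MD over WD): perfusion fraction f rises with dedifferentiation
(greater-is-positive), diffusion D falls (lesser-is-positive). The AUC is
the Mann-Whitney pair-ordering probability (ties counted 1/2), equal to the
area under the empirical ROC curve; the operating cutoff maximizes the
Youden index (sensitivity + specificity - 1) over all threshold midpoints.

A closed-form binormal AUC, Phi(delta_mu / sqrt(sd1^2 + sd2^2)), is provided
as an analytic cross-check for normally distributed parameter values.

AUC interpretation bands: [0.5, 0.7) low, [0.7, 0.9] moderate, (0.9, 1] high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .simulate import Cohort

__all__ = [
    "ROCResult",
    "mann_whitney_auc",
    "youden_cutoff",
    "binormal_auc",
    "classify_auc",
    "pairwise_roc_table",
    "table2_frame",
]

#: Ranking from least to most differentiated; the earlier grade of a pair
#: is the positive class.
_POSITIVITY_RANK = {"PD": 0, "MD": 1, "WD": 2}


@dataclass(frozen=True)
class ROCResult:
    """One parameter's diagnostic performance for one grade pair."""

    positive_group: str
    negative_group: str
    parameter: str
    model_tag: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "greater-is-positive" | "lesser-is-positive"
    band: str  # "low" | "moderate" | "high"

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc <= 1.0:
            raise ValidationError("oriented AUC must lie in [0.5, 1]")
        for v in (self.sensitivity, self.specificity):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("sensitivity/specificity must lie in [0, 1]")


def mann_whitney_auc(positives, negatives) -> tuple[float, str]:
    """Empirical AUC as the Mann-Whitney pair-ordering probability.

    Returns ``(auc, direction)`` with the orientation flipped so auc >= 0.5;
    direction records whether larger values indicate the positive class.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    if auc >= 0.5:
        return auc, "greater-is-positive"
    return 1.0 - auc, "lesser-is-positive"


def youden_cutoff(positives, negatives, direction: str) -> tuple[float, float, float]:
    """Youden-optimal threshold scan over midpoints of adjacent sorted values.

    Returns ``(cutoff, sensitivity, specificity)``. A case is called positive
    when its value exceeds the cutoff (direction ``greater-is-positive``) or
    falls below it (``lesser-is-positive``). Ties in the Youden index break
    toward higher specificity, then lower cutoff.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both groups must be non-empty")
    allv = np.unique(np.concatenate([pos, neg]))
    if allv.size == 1:
        cands = np.array([allv[0]])
    else:
        cands = (allv[:-1] + allv[1:]) / 2.0
    best = None
    for c in cands:
        if direction == "greater-is-positive":
            sens = float(np.mean(pos > c))
            spec = float(np.mean(neg <= c))
        else:
            sens = float(np.mean(pos < c))
            spec = float(np.mean(neg >= c))
        j = sens + spec - 1.0
        key = (j, spec, -c)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    return best[1], best[2], best[3]


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two normal distributions, oriented >= 0.5."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValidationError("standard deviations must be positive")
    z = (mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)
    return float(stats.norm.cdf(abs(z)))


def classify_auc(auc: float) -> str:
    """Interpretation band: [0.5, 0.7) low, [0.7, 0.9] moderate, (0.9, 1] high."""
    if not 0.5 <= auc <= 1.0:
        raise ValidationError(f"AUC {auc} outside [0.5, 1]")
    if auc < 0.7:
        return "low"
    if auc <= 0.9:
        return "moderate"
    return "high"


def roc_for_pair(
    cohort: Cohort, grade_a: str, grade_b: str, parameter: str, model_tag: str
) -> ROCResult:
    """ROCResult for one parameter and one grade pair; positive class is the
    less-differentiated grade."""
    a, b = sorted((grade_a, grade_b), key=_POSITIVITY_RANK.__getitem__)
    pos = cohort.parameter_values(parameter, model_tag, a)
    neg = cohort.parameter_values(parameter, model_tag, b)
    auc, direction = mann_whitney_auc(pos, neg)
    cutoff, sens, spec = youden_cutoff(pos, neg, direction)
    return ROCResult(
        positive_group=a,
        negative_group=b,
        parameter=parameter,
        model_tag=model_tag,
        auc=auc,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        band=classify_auc(auc),
    )


def pairwise_roc_table(
    cohort: Cohort,
    comparisons,
    parameters=("D", "D_star", "f"),
    model_tags=("mono", "bi"),
) -> list[ROCResult]:
    """ROC rows for every grade pair x parameter that survived the group
    comparison.

    A (pair, parameter) row is emitted when that parameter's omnibus test was
    significant and, on the ANOVA path, the pair's LSD p-value is also below
    alpha — reproducing the convention that ROC analysis is only reported for
    discriminating parameters.
    """
    from .group_stats import ALPHA, GRADE_PAIRS

    by_key = {(c.parameter, c.model_tag): c for c in comparisons}
    results = []
    for pair in GRADE_PAIRS:
        for tag in model_tags:
            for param in parameters:
                comp = by_key.get((param, tag))
                if comp is None or not comp.significant:
                    continue
                if comp.pairwise_p is not None and comp.pairwise_p[pair] >= ALPHA:
                    continue
                results.append(roc_for_pair(cohort, *pair, param, tag))
    return results


def table2_frame(results: list[ROCResult]) -> pd.DataFrame:
    from .group_stats import DISPLAY_SCALE

    return pd.DataFrame(
        [
            {
                "comparison": f"{r.positive_group} vs {r.negative_group}",
                "variable": f"{r.parameter}_{r.model_tag}",
                "cutoff": r.cutoff * DISPLAY_SCALE[r.parameter],
                "auc": r.auc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "band": r.band,
            }
            for r in results
        ]
    )
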