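"""Three-group comparison statistics for IVIM parameters.

The analysis pipeline mirrors standard radiology practice for comparing a
quantitative parameter across three diagnostic groups:

1. Shapiro-Wilk normality per group (gate at alpha = 0.05);
2. if all three groups pass: one-way ANOVA, followed by Fisher's least
   significant difference (LSD) post hoc — unadjusted pairwise t tests that
   reuse the ANOVA's pooled within-group mean square error and its error
   degrees of freedom;
3. otherwise: Kruskal-Wallis, with no post hoc;
4. Spearman rank correlation of each parameter with an ordinal grade coding
   (default PD=1 < MD=2 < WD=3, so diffusion D correlates positively with
   differentiation and perfusion fraction f negatively).

Tests are two-tailed; no multiplicity correction is applied across
parameters by default (LSD is by definition unadjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .simulate import GRADE_ORDER, Cohort

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "DEFAULT_GRADE_CODING",
    "shapiro_normality",
    "one_way_anova",
    "lsd_posthoc",
    "kruskal_wallis",
    "compare_parameter",
    "spearman_grade",
    "table1_frame",
    "correlations_frame",
]

ALPHA = 0.05

#: Ordinal coding of differentiation grade: higher = better differentiated.
DEFAULT_GRADE_CODING: dict[str, int] = {"PD": 1, "MD": 2, "WD": 3}

#: The three grade pairs in the conventional reporting order.
GRADE_PAIRS: tuple[tuple[str, str], ...] = (("PD", "WD"), ("PD", "MD"), ("MD", "WD"))


@dataclass(frozen=True)
class GroupComparison:
    """One parameter's group-comparison row (means, omnibus, post hoc)."""

    parameter: str
    model_tag: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    normality_p: dict[str, float]
    omnibus_test: str  # "anova" | "kruskal-wallis"
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float] | None  # None unless ANOVA path

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    model_tag: str
    rho: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [-1, 1]")


def shapiro_normality(values) -> float:
    """Shapiro-Wilk p-value; 0.0 (gate fail) for degenerate constant input."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        return 0.0
    return float(stats.shapiro(values).pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across the given groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    F = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(F):
        return 0.0, 1.0
    return F, p


def _pooled_mse(groups) -> tuple[float, int]:
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = sum(g.size for g in groups) - len(groups)
    return sse / df, df


def lsd_posthoc(*groups) -> list[float]:
    """Fisher's LSD pairwise p-values for all group pairs, in index order.

    Each pair's t statistic uses the pooled within-group MSE of the full
    omnibus ANOVA and its error degrees of freedom; no multiplicity
    adjustment (that is what LSD means).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    mse, df = _pooled_mse(groups)
    pvals = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if mse == 0:
                pvals.append(1.0 if a.mean() == b.mean() else 0.0)
                continue
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t = (a.mean() - b.mean()) / se
            pvals.append(float(2.0 * stats.t.sf(abs(t), df)))
    return pvals


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def compare_parameter(
    cohort: Cohort, parameter: str, model_tag: str, alpha: float = ALPHA
) -> GroupComparison:
    """Full gated comparison of one fitted parameter across the three grades.

    All three groups must pass Shapiro-Wilk at ``alpha`` to take the
    ANOVA + LSD path; otherwise Kruskal-Wallis is used and no pairwise
    p-values are reported (mirroring the NA cells of a non-significant or
    nonparametric row).
    """
    groups = {g: cohort.parameter_values(parameter, model_tag, g) for g in GRADE_ORDER}
    if any(v.size == 0 for v in groups.values()):
        raise ValidationError("cohort is missing a grade group")
    normality = {g: shapiro_normality(v) for g, v in groups.items()}
    glist = [groups[g] for g in GRADE_ORDER]
    if all(p > alpha for p in normality.values()):
        stat, p = one_way_anova(*glist)
        test = "anova"
        raw = lsd_posthoc(*glist)
        # index order over GRADE_ORDER = (WD, MD, PD): (WD,MD), (WD,PD), (MD,PD)
        pairwise = {
            ("PD", "WD"): raw[1],
            ("PD", "MD"): raw[2],
            ("MD", "WD"): raw[0],
        }
    else:
        stat, p = kruskal_wallis(*glist)
        test = "kruskal-wallis"
        pairwise = None
    return GroupComparison(
        parameter=parameter,
        model_tag=model_tag,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
        normality_p=normality,
        omnibus_test=test,
        omnibus_stat=stat,
        omnibus_p=p,
        pairwise_p=pairwise,
    )


def spearman_grade(
    cohort: Cohort,
    parameter: str,
    model_tag: str,
    coding: dict[str, int] | None = None,
) -> CorrelationResult:
    """Spearman rank correlation of a fitted parameter with coded grade."""
    coding = coding or DEFAULT_GRADE_CODING
    if len(set(coding.values())) != 3:
        raise ValidationError("coding must assign distinct integers to the grades")
    vals, codes = [], []
    for g in GRADE_ORDER:
        v = cohort.parameter_values(parameter, model_tag, g)
        vals.append(v)
        codes.append(np.full(v.size, coding[g]))
    x = np.concatenate(vals)
    y = np.concatenate(codes)
    if np.ptp(x) == 0:
        raise ValidationError("parameter values are constant; rho undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(parameter, model_tag, float(rho), float(p))


# display scale factors: D in 1e-3 mm^2/s, D* in 1e-2 mm^2/s, f dimensionless
DISPLAY_SCALE = {"D": 1e3, "D_star": 1e2, "f": 1.0}


def table1_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Assemble comparison rows into the conventional per-group summary table."""
    rows = []
    for c in comparisons:
        k = DISPLAY_SCALE[c.parameter]
        row = {
            "parameter": f"{c.parameter}_{c.model_tag}",
            **{
                f"{g}_mean": c.group_means[g] * k for g in GRADE_ORDER
            },
            **{f"{g}_sd": c.group_sds[g] * k for g in GRADE_ORDER},
            "test": c.omnibus_test,
            "omnibus_p": c.omnibus_p,
        }
        for pair in GRADE_PAIRS:
            key = f"p_{pair[0]}_vs_{pair[1]}"
            if c.pairwise_p is not None and c.significant:
                row[key] = c.pairwise_p[pair]
            else:
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def correlations_frame(correlations: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": f"{c.parameter}_{c.model_tag}",
                "rho": c.rho,
                "p": c.p_value,
            }
            for c in correlations
        ]
    )
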