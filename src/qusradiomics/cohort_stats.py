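"""Group-difference screening between complete and partial responders.

Each feature is compared between the two response groups with a normality
gate: if both groups pass a Shapiro-Wilk test (alpha = 0.05) the two-sided
Welch t-test is used, otherwise the two-sided Mann-Whitney U test.  Means
and SDs are reported either way, mirroring the study's group-statistics
table.  No multiple-testing correction is applied by default (significance
is declared per feature at p < 0.05); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import SubjectRecord

__all__ = ["GroupComparison", "choose_and_compare", "summarize_cohort"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_cr: float
    mean_pr: float
    sd_cr: float
    sd_pr: float
    n_cr: int
    n_pr: int
    test: str  # "t" | "mann_whitney"
    p_value: float
    significant: bool


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0:  # constant sample: Shapiro is undefined; treat as non-normal
        return False
    return stats.shapiro(values).pvalue >= alpha


def choose_and_compare(
    cr_values: np.ndarray,
    pr_values: np.ndarray,
    feature: str = "",
    alpha_normality: float = SIGNIFICANCE_LEVEL,
) -> GroupComparison:
    """Normality-gated two-sample comparison of one feature.

    Welch's t-test when both groups pass Shapiro-Wilk at ``alpha_normality``,
    Mann-Whitney U otherwise.  Two identical constant groups carry no
    evidence of a difference and report p = 1 by convention.
    """
    cr = np.asarray(cr_values, dtype=float)
    pr = np.asarray(pr_values, dtype=float)
    cr = cr[np.isfinite(cr)]
    pr = pr[np.isfinite(pr)]
    if len(cr) < 3 or len(pr) < 3:
        raise ValueError("need >= 3 finite values per group")
    stats_common = dict(
        feature=feature,
        mean_cr=float(cr.mean()),
        mean_pr=float(pr.mean()),
        sd_cr=float(cr.std(ddof=1)),
        sd_pr=float(pr.std(ddof=1)),
        n_cr=len(cr),
        n_pr=len(pr),
    )
    if np.ptp(cr) == 0 and np.ptp(pr) == 0 and cr[0] == pr[0]:
        return GroupComparison(**stats_common, test="t", p_value=1.0, significant=False)
    if _is_normal(cr, alpha_normality) and _is_normal(pr, alpha_normality):
        test = "t"
        p = float(stats.ttest_ind(cr, pr, equal_var=False).pvalue)
    else:
        test = "mann_whitney"
        p = float(stats.mannwhitneyu(cr, pr, alternative="two-sided").pvalue)
    return GroupComparison(
        **stats_common, test=test, p_value=p, significant=p < SIGNIFICANCE_LEVEL
    )


def summarize_cohort(
    records: list[SubjectRecord],
    feature_names: list[str] | None = None,
    bh_correction: bool = False,
) -> list[GroupComparison]:
    """Per-feature group comparisons, ordered by ascending p-value.

    Missing values are excluded pairwise (per feature).  With
    ``bh_correction`` the significance flags use Benjamini-Hochberg adjusted
    thresholds instead of the raw per-feature 0.05.
    """
    labels = {r.label for r in records}
    if labels != {"CR", "PR"}:
        raise ValueError("cohort must contain both CR and PR subjects")
    if feature_names is None:
        feature_names = list(records[0].features.keys())
    comparisons = []
    for name in feature_names:
        cr = np.array([r.features[name] for r in records if r.label == "CR"], dtype=float)
        pr = np.array([r.features[name] for r in records if r.label == "PR"], dtype=float)
        n_cr = int(np.isfinite(cr).sum())
        n_pr = int(np.isfinite(pr).sum())
        if n_cr < 3 or n_pr < 3:
            # features missing for most subjects (e.g. undefined scatterer
            # spacing in diffuse media) carry no comparison
            comparisons.append(
                GroupComparison(
                    feature=name,
                    mean_cr=float(np.nanmean(cr)) if n_cr else float("nan"),
                    mean_pr=float(np.nanmean(pr)) if n_pr else float("nan"),
                    sd_cr=float("nan"),
                    sd_pr=float("nan"),
                    n_cr=n_cr,
                    n_pr=n_pr,
                    test="insufficient",
                    p_value=float("nan"),
                    significant=False,
                )
            )
            continue
        comparisons.append(choose_and_compare(cr, pr, feature=name))
    comparisons.sort(key=lambda c: (np.isnan(c.p_value), c.p_value))
    if bh_correction:
        m = len(comparisons)
        adjusted = []
        threshold_rank = 0
        for k, comp in enumerate(comparisons, start=1):
            if comp.p_value <= k / m * SIGNIFICANCE_LEVEL:
                threshold_rank = k
        for k, comp in enumerate(comparisons, start=1):
            adjusted.append(
                GroupComparison(
                    **{
                        **comp.__dict__,
                        "significant": k <= threshold_rank,
                    }
                )
            )
        comparisons = adjusted
    return comparisons
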