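"""Group-level inference on decoding scores.

Covers the simple (non-mixed-model) inference layer: one-sided one-sample
t-tests of per-subject balanced accuracies against the 1/6 chance baseline,
one-sided exceedance p-values against permutation null distributions
(add-one estimator), Bonferroni-Holm correction across ROIs, and paired
within-subject condition contrasts. Full factorial linear mixed models
(intervention x age x ROI x order with random intercept and intervention
slope) are deliberately left to downstream statistics software; the
pipeline emits a tidy long-format table as their input (see
``pipeline.tidy_table``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .decode import CHANCE_LEVEL


@dataclasses.dataclass
class GroupTestResult:
    """Outcome of one group-level test."""

    statistic: float
    df: float
    p_one_sided: float
    method: str  # "t-test" | "permutation" | "paired-t"
    p_adjusted: float | None = None
    note: str = ""


def t_test_vs_chance(scores, chance: float = CHANCE_LEVEL) -> GroupTestResult:
    """One-sided one-sample t-test that scores exceed the chance baseline."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least two subjects")
    if np.std(scores, ddof=1) == 0:
        # degenerate: direction of the constant offset decides
        mean = scores.mean()
        if mean > chance:
            stat, p = float("inf"), 0.0
        elif mean < chance:
            stat, p = float("-inf"), 1.0
        else:
            stat, p = 0.0, 0.5
        return GroupTestResult(stat, n - 1, p, "t-test", note="zero variance")
    res = scipy.stats.ttest_1samp(scores, chance, alternative="greater")
    return GroupTestResult(float(res.statistic), n - 1, float(res.pvalue), "t-test")


def permutation_p(observed_group_mean: float, group_null) -> float:
    """One-sided exceedance p-value with the add-one rule.

    p = (1 + #{null >= observed}) / (1 + n_iterations); never exactly zero.
    """
    null = np.asarray(group_null, dtype=float)
    if len(null) == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null >= observed_group_mean)) / (1 + len(null)))


def holm_correct(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def paired_contrast(scores_a, scores_b, alternative: str = "two-sided") -> GroupTestResult:
    """Paired t-test of condition A vs condition B, matched by subject."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired contrast needs equal-length, matched scores")
    if len(a) < 2:
        raise ValueError("need at least two subjects")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        mean = diff.mean()
        if mean == 0:
            stat, p = 0.0, 1.0
        else:
            stat = float("inf") if mean > 0 else float("-inf")
            p = 0.0
        return GroupTestResult(stat, len(a) - 1, p, "paired-t", note="zero variance")
    res = scipy.stats.ttest_rel(a, b, alternative=alternative)
    return GroupTestResult(
        float(res.statistic), len(a) - 1, float(res.pvalue), "paired-t"
    )
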