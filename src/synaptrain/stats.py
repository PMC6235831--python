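"""Group-comparison statistics with a normality-gated test choice.

Two-sample comparisons first test each group for normality with the
D'Agostino-Pearson omnibus test; if both groups pass, a two-sided two-sample
t-test is used, otherwise a two-sided Mann-Whitney rank test.  Curve-level
genotype comparisons treat the curves as a split-plot two-way design (group
between units, stimulus index within units) and report the group main
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = ["ComparisonResult", "compare_two_groups", "compare_curves"]

_MIN_N_NORMALITY = 8


@dataclass
class ComparisonResult:
    """Outcome of a group comparison.

    ``test_name`` records which path the decision rule took
    (``"t-test"``, ``"rank-sum"`` or ``"two-way ANOVA"``).
    """

    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple[float, ...]
    n_per_group: tuple[int, ...]


def compare_two_groups(
    a, b, alpha: float = 0.05
) -> ComparisonResult:
    """Normality-gated two-sample comparison (two-sided).

    Groups smaller than 8 observations cannot be normality-tested; the
    comparison then falls back to the rank test with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if min(a.size, b.size) < _MIN_N_NORMALITY:
        warnings.warn(
            "group too small for the normality test; using rank-sum"
        )
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(
            "rank-sum", float(stat), float(p), (), (a.size, b.size)
        )
    norm_p = tuple(float(sps.normaltest(g).pvalue) for g in (a, b))
    if all(p > alpha for p in norm_p):
        stat, p = sps.ttest_ind(a, b)
        name = "t-test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "rank-sum"
    return ComparisonResult(
        name, float(stat), float(p), norm_p, (a.size, b.size)
    )


def compare_curves(curves_a, curves_b) -> ComparisonResult:
    """Two-way (group x stimulus index) comparison of per-unit curves.

    ``curves_a`` and ``curves_b`` are (units x stimuli) matrices of per-unit
    normalized amplitudes (one row per neuron).  The design is a split plot:
    group is a between-unit factor and stimulus index a within-unit factor,
    so the group main effect must be tested against unit-to-unit variation,
    not against the pooled cell residual (which would be anticonservative
    because a unit's points are correlated across stimuli).  The reported F
    and p are that between-unit test, equivalent to a one-way ANOVA on
    per-unit curve means.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need >= 2 units per group")
    if a.shape[1] != b.shape[1]:
        raise ValidationError("ragged curves: stimulus counts differ")
    stat, p = sps.f_oneway(a.mean(axis=1), b.mean(axis=1))
    return ComparisonResult(
        "two-way ANOVA",
        float(stat),
        float(p),
        (),
        (a.shape[0], b.shape[0]),
    )
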