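"""Annotation-burden analysis.

Detection performance grows roughly logarithmically with the number of
manually labeled training exams, so performance observed at a handful of
annotation budgets is interpolated *linearly in log(budget)* to obtain a
continuous performance curve.  The annotation burden reduction factor is
the ratio of manual labels needed by supervised training to the manual
labels needed by semisupervised training to reach the same performance:

    factor = N_supervised / N_semisupervised

Budget bookkeeping: under k-fold cross-validation a "budget" of B labeled
exams trains each model on B * (k-1)/k exams; :func:`per_fold_training_size`
makes that conversion explicit so the two conventions are never mixed
silently.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .exceptions import InputError, NotAchievableError

__all__ = [
    "PerformanceCurve",
    "ReductionResult",
    "interpolate_performance",
    "matched_budget",
    "annotation_reduction_factor",
    "per_fold_training_size",
    "reduction_from_curves",
]


@dataclasses.dataclass(frozen=True)
class PerformanceCurve:
    """Metric values observed at strictly increasing annotation budgets."""

    budgets: tuple[int, ...]
    metric_values: tuple[float, ...]
    metric_name: str = "auc"

    def __post_init__(self) -> None:
        budgets = tuple(int(b) for b in self.budgets)
        values = tuple(float(v) for v in self.metric_values)
        if len(budgets) != len(values) or len(budgets) < 2:
            raise InputError("need >= 2 (budget, value) knots of equal length")
        if any(b <= 0 for b in budgets):
            raise InputError("budgets must be positive")
        if any(b2 <= b1 for b1, b2 in zip(budgets, budgets[1:])):
            raise InputError("budgets must be strictly increasing")
        object.__setattr__(self, "budgets", budgets)
        object.__setattr__(self, "metric_values", values)

    def is_monotone_non_decreasing(self) -> bool:
        return all(v2 >= v1 for v1, v2 in zip(self.metric_values, self.metric_values[1:]))


def interpolate_performance(curve: PerformanceCurve, n: float) -> float:
    """Piecewise logarithmic interpolation of the curve at budget ``n``.

    Linear in ln(budget) within the bracketing segment; exact at knots; no
    extrapolation outside [min(budgets), max(budgets)].
    """
    n = float(n)
    b = curve.budgets
    if not b[0] <= n <= b[-1]:
        raise InputError(f"n={n} outside the budget range [{b[0]}, {b[-1]}]")
    i = int(np.searchsorted(b, n, side="right")) - 1
    if i == len(b) - 1:  # n == max budget
        return curve.metric_values[-1]
    b0, b1 = b[i], b[i + 1]
    v0, v1 = curve.metric_values[i], curve.metric_values[i + 1]
    t = (math.log(n) - math.log(b0)) / (math.log(b1) - math.log(b0))
    return v0 + t * (v1 - v0)


def matched_budget(ssl_curve: PerformanceCurve, target: float) -> float:
    """Smallest budget at which the interpolated curve reaches ``target``.

    The curve must be monotone non-decreasing; the budget is solved in
    closed form within the first segment whose upper knot reaches the
    target.
    """
    if not ssl_curve.is_monotone_non_decreasing():
        raise InputError("matched_budget requires a monotone non-decreasing curve")
    target = float(target)
    values = ssl_curve.metric_values
    if target > values[-1]:
        raise NotAchievableError(
            f"target {target} exceeds the curve maximum {values[-1]}"
        )
    if target <= values[0]:
        return float(ssl_curve.budgets[0])
    for i in range(len(values) - 1):
        if values[i + 1] >= target:
            b0, b1 = ssl_curve.budgets[i], ssl_curve.budgets[i + 1]
            v0, v1 = values[i], values[i + 1]
            if v1 == v0:  # flat segment at exactly the target level
                return float(b0)
            t = (target - v0) / (v1 - v0)
            return math.exp(math.log(b0) + t * (math.log(b1) - math.log(b0)))
    raise NotAchievableError(f"target {target} not reached")  # pragma: no cover


@dataclasses.dataclass(frozen=True)
class ReductionResult:
    """Annotation burden reduction: factor = N_supervised / N_semisupervised."""

    n_supervised: int
    n_semisupervised: int
    factor: float

    @property
    def rounded(self) -> int:
        return round(self.factor)


def annotation_reduction_factor(n_supervised: float, n_semisupervised: float) -> ReductionResult:
    """How many times fewer manual annotations semisupervised training needs."""
    if n_supervised <= 0 or n_semisupervised <= 0:
        raise InputError("annotation counts must be positive")
    return ReductionResult(
        n_supervised=int(round(n_supervised)),
        n_semisupervised=int(round(n_semisupervised)),
        factor=float(n_supervised) / float(n_semisupervised),
    )


def per_fold_training_size(budget: int, n_folds: int = 5) -> int:
    """Exams each model trains on when ``budget`` exams are split into
    ``n_folds`` cross-validation folds (e.g. 3050 -> 2440 at 5 folds)."""
    if budget <= 0 or n_folds < 2:
        raise InputError("budget must be positive and n_folds >= 2")
    return round(budget * (n_folds - 1) / n_folds)


def reduction_from_curves(
    supervised: PerformanceCurve,
    semisupervised: PerformanceCurve,
    target_budget: int | None = None,
) -> ReductionResult:
    """Reduction factor implied by two performance curves.

    The target is the supervised performance at ``target_budget`` (default:
    its maximum budget); the semisupervised curve is interpolated to find
    the matched budget.
    """
    if target_budget is None:
        target_budget = supervised.budgets[-1]
    target = interpolate_performance(supervised, target_budget)
    matched = matched_budget(semisupervised, target)
    return annotation_reduction_factor(target_budget, matched)
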