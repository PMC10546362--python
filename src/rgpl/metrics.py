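"""Evaluation stack: lesion matching, FROC, ROC, Dice, permutation tests,
and bootstrap confidence intervals.

Lesion-level detection is scored by free-response ROC (FROC) analysis:
candidates are greedily matched one-to-one to ground-truth lesions in order
of descending confidence (hit when intersection-over-union >= 0.10 by
default), and the curve of lesion sensitivity against false positives per
examination is summarized by the partial area under the curve between 0 and
1 FP/exam (raw area, maximum 1.0).  Exam-level diagnosis reduces each exam
to its maximum candidate confidence and is scored by ROC AUC.

Groups of independently trained runs are compared with a two-sided
permutation test on the difference of group means (Monte Carlo with a fixed
seed, or exhaustive for small groups).  Confidence intervals are estimated
by n-of-n patient bootstrap in which resamples containing a single class
are rejected and redrawn.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .candidates import CONNECTIVITY_26, DetectionMap
from .exceptions import ConfigurationError, InputError
from .volume import Volume3D

__all__ = [
    "CaseEvaluation",
    "FrocCurve",
    "RocCurve",
    "PermutationTestResult",
    "match_candidates",
    "froc",
    "roc_auc",
    "dice",
    "permutation_test",
    "bootstrap_ci",
]


@dataclasses.dataclass(frozen=True)
class CaseEvaluation:
    """Per-exam result of matching candidates against ground truth.

    ``tp_confidences`` holds one confidence per matched ground-truth lesion;
    unmatched candidates contribute ``fp_confidences``.  ``case_score`` is
    the exam-level diagnosis score: the maximum candidate confidence (0 when
    there are no candidates).  ``matches`` records (candidate label, ground
    truth lesion label, IoU, Dice) per hit.
    """

    exam_id: str
    tp_confidences: tuple[float, ...]
    fp_confidences: tuple[float, ...]
    n_gt_lesions: int
    case_score: float
    case_label: int
    matches: tuple[tuple[int, int, float, float], ...] = ()


def match_candidates(
    detection: DetectionMap,
    gt: Volume3D,
    iou_threshold: float = 0.10,
    criterion: str = "iou",
    exam_id: str = "",
    case_label: int | None = None,
) -> CaseEvaluation:
    """Greedy one-to-one matching of candidates to ground-truth lesions.

    Ground truth is decomposed into 26-connected lesions.  Candidates are
    processed in descending confidence; each is a hit for the unmatched
    lesion with the largest overlap, provided IoU >= ``iou_threshold``
    (``criterion="iou"``) or its peak lies inside the lesion
    (``criterion="peak"``).  Each lesion matches at most one candidate.
    """
    if criterion not in ("iou", "peak"):
        raise ConfigurationError(f"unknown match criterion {criterion!r}")
    gt_values = np.asarray(gt.values)
    if gt_values.shape != detection.labels.shape:
        raise InputError(
            f"shape mismatch: detection {detection.labels.shape} vs gt {gt_values.shape}"
        )
    gt_labels, n_gt = ndimage.label(gt_values > 0.5, structure=CONNECTIVITY_26)
    gt_sizes = np.bincount(gt_labels.ravel(), minlength=n_gt + 1)

    matched_gt: set[int] = set()
    tp: list[float] = []
    fp: list[float] = []
    matches: list[tuple[int, int, float, float]] = []
    for cand in detection.candidates:  # already sorted by descending confidence
        region = detection.labels == cand.label_id
        overlap = np.bincount(gt_labels[region], minlength=n_gt + 1)
        size_c = int(region.sum())
        best_gt, best_iou = 0, 0.0
        for g in range(1, n_gt + 1):
            if g in matched_gt or overlap[g] == 0:
                continue
            inter = int(overlap[g])
            iou = inter / (size_c + int(gt_sizes[g]) - inter)
            if iou > best_iou:
                best_gt, best_iou = g, iou
        if criterion == "peak":
            hit = gt_labels[cand.peak] != 0 and gt_labels[cand.peak] not in matched_gt
            if hit:
                best_gt = int(gt_labels[cand.peak])
                inter = int(overlap[best_gt])
                best_iou = inter / (size_c + int(gt_sizes[best_gt]) - inter)
        else:
            hit = best_iou >= iou_threshold
        if hit:
            matched_gt.add(best_gt)
            tp.append(cand.confidence)
            inter = int(overlap[best_gt])
            dsc = 2.0 * inter / (size_c + int(gt_sizes[best_gt]))
            matches.append((cand.label_id, best_gt, best_iou, dsc))
        else:
            fp.append(cand.confidence)

    case_score = max((c.confidence for c in detection.candidates), default=0.0)
    return CaseEvaluation(
        exam_id=exam_id,
        tp_confidences=tuple(tp),
        fp_confidences=tuple(fp),
        n_gt_lesions=int(n_gt),
        case_score=float(case_score),
        case_label=int(case_label) if case_label is not None else int(n_gt > 0),
        matches=tuple(matches),
    )


@dataclasses.dataclass(frozen=True)
class FrocCurve:
    """FROC operating points (one per distinct confidence threshold,
    descending) and the partial AUC on [0, 1] FP/exam."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fp_per_exam: np.ndarray
    pauc_0_1: float
    n_lesions: int = 0
    n_cases: int = 0


def _step_pauc(fp_per_exam: np.ndarray, sensitivity: np.ndarray, fp_max: float = 1.0) -> float:
    """Area under the step curve sensitivity(fp) on [0, fp_max].

    Points must be sorted by non-decreasing fp (non-decreasing sensitivity);
    the curve is zero-extended below the first point and held constant
    beyond the last.
    """
    area, prev_fp, prev_sens = 0.0, 0.0, 0.0
    for f, s in zip(fp_per_exam, sensitivity):
        f = min(float(f), fp_max)
        area += (f - prev_fp) * prev_sens
        prev_fp, prev_sens = f, float(s)
    area += (fp_max - prev_fp) * prev_sens
    return area


def froc(cases: Sequence[CaseEvaluation]) -> FrocCurve:
    """Free-response ROC over a set of evaluated cases.

    At each distinct candidate confidence t (descending): sensitivity is the
    fraction of all ground-truth lesions matched with TP confidence >= t,
    and fp_per_exam the number of FPs with confidence >= t divided by the
    number of cases.
    """
    if len(cases) == 0:
        raise InputError("froc requires at least one case")
    n_lesions = sum(c.n_gt_lesions for c in cases)
    if n_lesions == 0:
        raise InputError("froc requires at least one ground-truth lesion")
    n_cases = len(cases)
    tps = np.sort(np.concatenate([np.asarray(c.tp_confidences) for c in cases] or [[]]))
    fps = np.sort(np.concatenate([np.asarray(c.fp_confidences) for c in cases] or [[]]))
    thresholds = np.unique(np.concatenate([tps, fps]))[::-1]
    if thresholds.size == 0:
        return FrocCurve(
            thresholds=thresholds,
            sensitivity=np.array([]),
            fp_per_exam=np.array([]),
            pauc_0_1=0.0,
            n_lesions=n_lesions,
            n_cases=n_cases,
        )
    # counts of values >= t via searchsorted on the ascending sorted arrays
    sens = (tps.size - np.searchsorted(tps, thresholds, side="left")) / n_lesions
    fppe = (fps.size - np.searchsorted(fps, thresholds, side="left")) / n_cases
    pauc = _step_pauc(fppe, sens)
    return FrocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        fp_per_exam=fppe,
        pauc_0_1=float(pauc),
        n_lesions=n_lesions,
        n_cases=n_cases,
    )


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """ROC operating points and trapezoidal AUC (ties counted half)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(case_scores: Sequence[float], case_labels: Sequence[int]) -> RocCurve:
    """Exam-level ROC of diagnosis scores against binary labels."""
    scores = np.asarray(case_scores, dtype=np.float64)
    labels = np.asarray(case_labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputError("case_scores and case_labels must be equal-length 1D sequences")
    if len(np.unique(labels)) < 2:
        raise InputError("roc_auc requires both classes to be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def dice(a: Volume3D, b: Volume3D) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 if both empty."""
    av = np.asarray(a.values) > 0.5
    bv = np.asarray(b.values) > 0.5
    if av.shape != bv.shape:
        raise InputError(f"shape mismatch: {av.shape} vs {bv.shape}")
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(av, bv).sum()) / denom


@dataclasses.dataclass(frozen=True)
class PermutationTestResult:
    observed_diff: float
    p_value: float
    n_iterations: int
    seed: int
    method: str  # "exact" | "montecarlo"


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_iterations: int = 1_000_000,
    seed: int = 0,
    method: str = "auto",
    exact_limit: int = 12,
) -> PermutationTestResult:
    """Two-sided permutation test on the difference of group means.

    ``method="auto"`` enumerates all assignments exactly when the combined
    sample size is at most ``exact_limit`` and falls back to Monte Carlo
    otherwise.  Monte Carlo p-values use the add-one correction
    p = (1 + #{|perm diff| >= |observed|}) / (n_iterations + 1), so the
    smallest attainable p is 1/(n_iterations + 1).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise InputError("each group must be a 1D sequence with at least 2 values")
    if method not in ("auto", "exact", "montecarlo"):
        raise ConfigurationError(f"unknown method {method!r}")
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    n, n_a, n_b = pool.size, a.size, b.size
    tol = 1e-12 * max(1.0, abs(observed))

    if method == "exact" or (method == "auto" and n <= exact_limit):
        total = math.comb(n, n_a)
        count = 0
        csum = pool.sum()
        for idx in itertools.combinations(range(n), n_a):
            sa = pool[list(idx)].sum()
            d = sa / n_a - (csum - sa) / n_b
            if abs(d) >= abs(observed) - tol:
                count += 1
        return PermutationTestResult(
            observed_diff=observed,
            p_value=count / total,
            n_iterations=total,
            seed=int(seed),
            method="exact",
        )

    rng = np.random.default_rng(seed)
    count = 0
    remaining = int(n_iterations)
    csum = pool.sum()
    scale_a, scale_b = 1.0 / n_a, 1.0 / n_b
    while remaining > 0:
        chunk = min(remaining, max(1, 4_000_000 // n))
        mat = np.tile(pool, (chunk, 1))
        rng.permuted(mat, axis=1, out=mat)
        sa = mat[:, :n_a].sum(axis=1)
        d = sa * (scale_a + scale_b) - csum * scale_b
        count += int((np.abs(d) >= abs(observed) - tol).sum())
        remaining -= chunk
    p = (1 + count) / (n_iterations + 1)
    return PermutationTestResult(
        observed_diff=observed,
        p_value=p,
        n_iterations=int(n_iterations),
        seed=int(seed),
        method="montecarlo",
    )


def _auc_rows(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC per row (ties counted half) for 2D label/score arrays."""
    ranks = stats.rankdata(scores, method="average", axis=1)
    n_pos = labels.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    rank_sum_pos = (ranks * labels).sum(axis=1)
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_ci(
    case_labels: Sequence[int],
    case_scores: Sequence[float],
    metric: str = "auc",
    n_iterations: int = 1_000_000,
    seed: int = 0,
    threshold: float = 0.5,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI with single-class resamples rejected.

    Each iteration draws n-of-n patients with replacement and recomputes the
    metric; iterations whose resample contains only one class are rejected
    and redrawn.  ``metric`` is one of ``auc``, ``sensitivity`` (fraction of
    positives with score >= ``threshold``), ``specificity`` (fraction of
    negatives with score < ``threshold``).
    """
    labels = np.asarray(case_labels, dtype=np.int64)
    scores = np.asarray(case_scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise InputError("case_labels and case_scores must be equal-length 1D sequences")
    if len(np.unique(labels)) < 2:
        raise InputError("bootstrap_ci requires both classes to be present")
    if metric not in ("auc", "sensitivity", "specificity"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    if not 0 < ci < 1:
        raise ConfigurationError(f"ci must be in (0, 1), got {ci}")

    rng = np.random.default_rng(seed)
    n = labels.size
    values: list[np.ndarray] = []
    accepted = 0
    while accepted < n_iterations:
        chunk = min(n_iterations - accepted + 64, max(64, 2_000_000 // n))
        idx = rng.integers(0, n, size=(chunk, n))
        lab = labels[idx]
        pos = lab.sum(axis=1)
        ok = (pos > 0) & (pos < n)
        if not ok.any():
            continue
        lab, sc = lab[ok], scores[idx[ok]]
        if metric == "auc":
            vals = _auc_rows(lab, sc)
        elif metric == "sensitivity":
            vals = ((sc >= threshold) & (lab == 1)).sum(axis=1) / lab.sum(axis=1)
        else:
            vals = ((sc < threshold) & (lab == 0)).sum(axis=1) / (lab == 0).sum(axis=1)
        take = min(vals.size, n_iterations - accepted)
        values.append(vals[:take])
        accepted += take
    allvals = np.concatenate(values)
    alpha = (1.0 - ci) / 2.0
    lower, upper = np.quantile(allvals, [alpha, 1.0 - alpha])
    return float(lower), float(upper)
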