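"""Lesion matching, FROC/ROC, Dice, permutation test, bootstrap CI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgpl import (
    CaseEvaluation,
    InputError,
    Volume3D,
    bootstrap_ci,
    dice,
    extract_lesion_candidates,
    froc,
    match_candidates,
    permutation_test,
    roc_auc,
)
from tests_oracles import (
    froc_oracle,
    permutation_enumeration_oracle,
    roc_auc_pair_oracle,
)


def _det_from_blobs(blob_map_factory, blobs, **kwargs):
    vol = blob_map_factory((8, 48, 16), blobs)
    return extract_lesion_candidates(vol, min_volume_mm3=0, **kwargs)


def _mask_like(det, label_ids):
    return Volume3D((np.isin(det.labels, label_ids)).astype(np.uint8), det.spacing)


class TestMatchCandidates:
    def test_identical_candidate_is_tp(self, blob_map_factory):
        det = _det_from_blobs(blob_map_factory, [((4, 8, 8), (1.5, 3, 3), 0.9)])
        gt = _mask_like(det, [1])
        ev = match_candidates(det, gt)
        assert len(ev.tp_confidences) == 1 and len(ev.fp_confidences) == 0
        assert ev.matches[0][2] == pytest.approx(1.0)  # IoU
        assert ev.matches[0][3] == pytest.approx(1.0)  # Dice

    def test_disjoint_candidate_is_fp(self, blob_map_factory):
        det = _det_from_blobs(blob_map_factory, [((4, 8, 8), (1.5, 3, 3), 0.9)])
        gt = np.zeros(det.labels.shape, dtype=np.uint8)
        gt[6, 40, 8] = 1
        ev = match_candidates(det, Volume3D(gt, det.spacing))
        assert len(ev.tp_confidences) == 0 and len(ev.fp_confidences) == 1
        assert ev.n_gt_lesions == 1

    def test_one_to_one_higher_confidence_wins(self, blob_map_factory):
        # two overlapping candidates vs one ground-truth lesion: the more
        # confident candidate is the TP, the other an FP
        det = _det_from_blobs(
            blob_map_factory,
            [((4, 8, 8), (1.5, 3, 3), 0.9), ((4, 28, 8), (1.5, 3, 3), 0.6)],
        )
        assert len(det) == 2
        gt = _mask_like(det, [1, 2])
        # bridge the two regions so the ground truth is a single lesion
        gv = np.array(gt.values)
        gv[4, 8:29, 8] = 1
        ev = match_candidates(det, Volume3D(gv, det.spacing))
        assert ev.n_gt_lesions == 1
        assert list(ev.tp_confidences) == [pytest.approx(0.9)]
        assert list(ev.fp_confidences) == [pytest.approx(0.6)]

    def test_case_score_is_max_confidence(self, blob_map_factory):
        det = _det_from_blobs(
            blob_map_factory,
            [((4, 8, 8), (1.5, 3, 3), 0.7), ((4, 30, 8), (1.5, 3, 3), 0.4)],
        )
        ev = match_candidates(det, Volume3D(np.zeros(det.labels.shape), det.spacing), case_label=0)
        assert ev.case_score == pytest.approx(0.7)
        assert ev.case_label == 0

    def test_shape_mismatch(self, blob_map_factory):
        det = _det_from_blobs(blob_map_factory, [((4, 8, 8), (1.5, 3, 3), 0.9)])
        with pytest.raises(InputError):
            match_candidates(det, Volume3D(np.zeros((2, 2, 2))))


def _case(tps, fps, n_gt, label=None):
    return CaseEvaluation(
        exam_id="",
        tp_confidences=tuple(tps),
        fp_confidences=tuple(fps),
        n_gt_lesions=n_gt,
        case_score=max(list(tps) + list(fps) + [0.0]),
        case_label=label if label is not None else int(n_gt > 0),
    )


class TestFroc:
    def test_perfect_detector(self):
        cases = [_case([1.0], [], 1) for _ in range(4)]
        curve = froc(cases)
        assert curve.pauc_0_1 == pytest.approx(1.0)
        assert curve.sensitivity[0] == 1.0 and curve.fp_per_exam[0] == 0.0

    def test_no_candidates(self):
        curve = froc([_case([], [], 2), _case([], [], 1)])
        assert curve.pauc_0_1 == 0.0

    def test_requires_ground_truth_lesions(self):
        with pytest.raises(InputError):
            froc([_case([], [0.5], 0)])

    def test_matches_brute_force_recount_on_toy_set(self):
        cases = [
            _case([0.9, 0.4], [0.2], 2),
            _case([], [0.7, 0.3], 0, label=0),
            _case([0.6], [], 2),
            _case([], [], 1),
        ]
        curve = froc(cases)
        points, pauc = froc_oracle(
            [c.tp_confidences for c in cases],
            [c.fp_confidences for c in cases],
            [c.n_gt_lesions for c in cases],
        )
        got = list(zip(curve.fp_per_exam, curve.sensitivity))
        assert got == pytest.approx(points)
        assert curve.pauc_0_1 == pytest.approx(pauc, abs=1e-3)

    def test_randomized_toy_sets_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n_cases = int(rng.integers(1, 6))
            cases = []
            for _ in range(n_cases):
                n_gt = int(rng.integers(0, 3))
                n_tp = int(rng.integers(0, n_gt + 1))
                n_fp = int(rng.integers(0, 3))
                tps = np.round(rng.uniform(0.05, 1, n_tp), 2)
                fps = np.round(rng.uniform(0.05, 1, n_fp), 2)
                cases.append(_case(tps, fps, n_gt))
            if sum(c.n_gt_lesions for c in cases) == 0:
                continue
            curve = froc(cases)
            _, pauc = froc_oracle(
                [c.tp_confidences for c in cases],
                [c.fp_confidences for c in cases],
                [c.n_gt_lesions for c in cases],
            )
            assert curve.pauc_0_1 == pytest.approx(pauc, abs=1e-3)

    def test_pauc_monotone_under_tp_and_fp_edits(self):
        base = [_case([0.8], [0.5], 2), _case([0.6], [], 1)]
        with_extra_tp = [_case([0.8, 0.7], [0.5], 2), _case([0.6], [], 1)]
        with_extra_fp = [_case([0.8], [0.5, 0.7], 2), _case([0.6], [], 1)]
        assert froc(with_extra_tp).pauc_0_1 >= froc(base).pauc_0_1
        assert froc(with_extra_fp).pauc_0_1 <= froc(base).pauc_0_1


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid -> ties
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_pair_oracle(scores, labels)
            )


class TestDice:
    def _vol(self, arr):
        return Volume3D(np.asarray(arr, dtype=np.uint8).reshape(1, 1, -1))

    def test_basic_values(self):
        a = self._vol([1, 1, 0, 0])
        assert dice(a, a) == 1.0
        assert dice(a, self._vol([0, 0, 1, 1])) == 0.0
        assert dice(self._vol([1] * 4), self._vol([1, 1, 0, 0])) == pytest.approx(2 * 2 / 6)
        assert dice(self._vol([0, 0, 0, 0]), self._vol([0, 0, 0, 0])) == 1.0

    @given(st.lists(st.booleans(), min_size=1, max_size=24), st.data())
    def test_symmetric_and_identity(self, bits, data):
        other = data.draw(st.lists(st.booleans(), min_size=len(bits), max_size=len(bits)))
        a, b = self._vol(bits), self._vol(other)
        assert dice(a, b) == dice(b, a)
        if any(bits):
            assert (dice(a, b) == 1.0) == (bits == other)


class TestPermutation:
    def test_identical_groups_give_p_one(self):
        res = permutation_test([0.8, 0.9, 0.7], [0.7, 0.9, 0.8])
        assert res.p_value == 1.0

    def test_exact_mode_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 13 - n_a))
            a = np.round(rng.normal(size=n_a), 2)
            b = np.round(rng.normal(size=n_b), 2)
            res = permutation_test(a, b, method="exact")
            assert res.p_value == pytest.approx(permutation_enumeration_oracle(a, b))

    def test_extreme_separation_exact(self):
        res = permutation_test([0, 0, 0], [1, 1, 1], method="exact")
        assert res.p_value == pytest.approx(2 / 20)  # only the two extreme splits

    def test_monte_carlo_floor_and_seed_determinism(self):
        a = list(range(10))
        b = [x + 100 for x in range(10)]
        r1 = permutation_test(a, b, n_iterations=999, seed=3, method="montecarlo")
        r2 = permutation_test(a, b, n_iterations=999, seed=3, method="montecarlo")
        assert r1.p_value == r2.p_value == 1 / 1000

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            permutation_test([1.0], [1.0, 2.0])


class TestBootstrap:
    def test_perfect_separation_degenerate_ci(self):
        labels = [0] * 5 + [1] * 5
        scores = [0.1] * 5 + [0.9] * 5
        assert bootstrap_ci(labels, scores, "auc", n_iterations=500, seed=0) == (1.0, 1.0)

    def test_single_class_input_rejected(self):
        with pytest.raises(InputError):
            bootstrap_ci([1, 1, 1], [0.5, 0.6, 0.7])

    def test_rejection_rule_keeps_lone_positive(self):
        # 1 positive of 50 with a perfectly separating score: every accepted
        # resample must contain the positive, so sensitivity is always 1
        labels = [0] * 49 + [1]
        scores = [0.0] * 49 + [1.0]
        lo, hi = bootstrap_ci(labels, scores, "sensitivity", n_iterations=2000, seed=4)
        assert (lo, hi) == (1.0, 1.0)

    def test_auc_ci_covers_known_value(self):
        # scores ~ N(label, 1) at n=200: theoretical AUC = Phi(1/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(12)
        hits = 0
        reps = 60
        for _ in range(reps):
            labels = rng.integers(0, 2, 200)
            scores = rng.normal(labels.astype(float), 1.0)
            lo, hi = bootstrap_ci(labels, scores, "auc", n_iterations=400, seed=int(rng.integers(2**31)))
            hits += lo <= true_auc <= hi
        # 95% nominal coverage; allow a generous binomial band at 60 reps
        assert hits / reps >= 0.85

    def test_specificity_matches_direct_computation(self):
        labels = np.array([0, 0, 0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.6, 0.7, 0.8, 0.9])
        lo, hi = bootstrap_ci(labels, scores, "specificity", n_iterations=300, seed=9)
        assert 0.0 <= lo <= hi <= 1.0
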