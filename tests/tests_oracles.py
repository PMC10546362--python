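"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: per-threshold
recount loops, O(n^2) pair counting, exhaustive bitmask enumeration, dense
grid search, and per-blob connected-component labeling on hand-built maps.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from rgpl import Volume3D

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def random_separated_blob_map(rng, min_confidence=0.10, relative_threshold=0.40):
    """A confidence map whose 1-3 compact blobs sit in disjoint slabs
    separated by all-zero planes, plus the per-blob ground truth.

    Returns (Volume3D, blobs) with blobs = list of (peak_value, slab_slice).
    """
    n_blobs = int(rng.integers(1, 4))
    slab = 16
    shape = (10, slab * n_blobs, 14)
    values = np.zeros(shape)
    # distinct peaks so ranking is unambiguous
    peaks = sorted(rng.uniform(min_confidence + 0.1, 1.0, size=n_blobs), reverse=True)
    peaks = [round(p, 3) for p in peaks]
    while len(set(peaks)) < n_blobs:  # pragma: no cover - vanishingly rare
        peaks = [round(p + i * 1e-3, 4) for i, p in enumerate(peaks)]
    blobs = []
    order = rng.permutation(n_blobs)
    for i, peak in zip(order, peaks):
        y0 = i * slab
        # integer centers put each nominal peak exactly on the voxel grid
        cz = int(rng.integers(4, 7))
        cy = y0 + int(rng.integers(6, 10))
        cx = int(rng.integers(5, 10))
        sz, sy, sx = rng.uniform(1.0, 1.8), rng.uniform(1.5, 2.8), rng.uniform(1.5, 2.8)
        zz, yy, xx = np.indices(shape)
        g = np.exp(
            -0.5 * (((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
        )
        g[g < relative_threshold + 0.05] = 0.0  # compact support above the threshold
        # keep the blob inside its slab; the surrounding zero plane separates it
        g[:, : y0 + 1, :] = 0.0
        g[:, y0 + slab - 1 :, :] = 0.0
        values = np.maximum(values, peak * g)
        blobs.append((peak, np.s_[:, y0 : y0 + slab, :]))
    blobs.sort(key=lambda b: -b[0])
    return Volume3D(values), blobs


def per_blob_oracle(vol, blobs, relative_threshold=0.40):
    """Simple thresholding + connected-component labeling, one blob at a time."""
    out = []
    for peak, slab in blobs:
        sub = np.zeros(vol.shape, dtype=bool)
        sub[slab] = vol.values[slab] >= relative_threshold * peak
        lab, n = ndimage.label(sub, structure=_STRUCT26)
        assert n == 1, "oracle precondition: one component per blob"
        out.append((peak, lab == 1))
    return out


def froc_oracle(case_tps, case_fps, n_lesions_per_case):
    """Per-threshold recount of sensitivity and FP/exam, plus a dense-grid
    numerical integral of the step curve on [0, 1] FP/exam."""
    all_conf = sorted({c for tps in case_tps for c in tps} | {c for fps in case_fps for c in fps}, reverse=True)
    n_cases = len(case_tps)
    n_lesions = sum(n_lesions_per_case)
    points = []
    for t in all_conf:
        tp = sum(1 for tps in case_tps for c in tps if c >= t)
        fp = sum(1 for fps in case_fps for c in fps if c >= t)
        points.append((fp / n_cases, tp / n_lesions))
    grid = np.linspace(0, 1, 20001)
    sens_at = np.zeros_like(grid)
    for f, s in points:  # step curve: best sensitivity at fp-rate <= grid value
        sens_at[grid >= f - 1e-12] = np.maximum(sens_at[grid >= f - 1e-12], s)
    pauc = float(np.trapezoid(sens_at, grid))
    return points, pauc


def roc_auc_pair_oracle(scores, labels):
    """Mann-Whitney by explicit pair counting; ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def permutation_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating every binary group assignment."""
    pool = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n, n_a = pool.size, len(a)
    observed = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != n_a:
            continue
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        d = abs(pool[sel].mean() - pool[~sel].mean())
        total += 1
        if d >= observed - 1e-12:
            count += 1
    return count / total


def matched_budget_grid_oracle(budgets, values, target, step=1e-3):
    """Dense grid search in ln(n) for the smallest budget reaching target."""
    ln = np.arange(np.log(budgets[0]), np.log(budgets[-1]) + step, step)
    ns = np.exp(ln)
    interp = np.interp(np.log(ns), np.log(budgets), values)
    ok = np.nonzero(interp >= target - 1e-12)[0]
    return float(ns[ok[0]]) if ok.size else None
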