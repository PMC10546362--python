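# Methods

## Problem setting

Semisupervised detection of clinically significant prostate cancer (and
countable-lesion detection generally) can leverage unlabeled examinations
when each exam carries a diagnostic report. The report's contribution is a
single integer per exam: `n_sig`, the number of findings the radiologist
scored PI-RADS ≥ 4. A teacher model's voxel-level confidence map proposes
*where* lesions are; the report says *how many* to trust. This package
implements everything around that idea except the deep-learning training
itself: it consumes confidence maps and produces filtered voxel labels plus
the evaluation stack.

## Report parsing

Report style is site-specific, so pattern matching is isolated in
*dialects*: an ordered list of regular expressions with a named `score`
capture, optional overall-impression fallbacks, and an optional addendum
delimiter. Decisions made where reporting practice is genuinely ambiguous:

- an addendum score for lesion index *k* **replaces** the body score for
  the same index (addenda are corrections, the later reading wins);
- split scores ("PI-RADS 4/5") count **once with the higher value**
  (conservative single-lesion reading);
- duplicate scores for distinct lesions are all kept;
- a report with **zero** recognizable scores is `unparseable` and its exam
  is excluded from pseudo-labeling rather than treated as negative —
  negative exams are recognized by explicit low scores (e.g. an overall
  PI-RADS ≤ 3 impression), not by the absence of matches.

`n_sig` is the count of extracted scores at or above the significance
threshold (default 4; PI-RADS 4 and 5 mean "likely"/"very likely"
clinically significant cancer).

## Candidate extraction

`extract_lesion_candidates` uses iterative dynamic thresholding. Per
iteration: global maximum `p_max` (ties broken toward the lexicographically
lowest (z, y, x)); stop when `p_max < min_confidence`; candidate region =
26-connected component containing the peak among voxels
≥ `relative_threshold · p_max`; candidate confidence = `p_max`; region
zeroed; regions below `min_volume_mm3` discarded but still zeroed so they
cannot re-seed. Defaults, all surfaced in `CandidateExtractionParams`:

| parameter | default | rationale |
|---|---|---|
| `min_confidence` | 0.10 | floor below which peaks are ensemble noise |
| `relative_threshold` | 0.40 | region grows to 40% of its own peak, adapting to weak lesions where a fixed global threshold fails |
| `min_volume_mm3` | 50 | sub-0.05-cm³ specks are not plausible reported lesions |
| `max_candidates` | 10 | safety bound, far above clinical lesion counts |

The *relative* threshold is the essential choice: a single global
binarization either merges confident lesions or loses faint ones, whereas
peak-relative growth yields distinct, ranked candidates — the property the
n_sig mask needs. Confidence is the region's **peak** (not mean) because
candidates are ranked as "most likely lesion".

Ensembling (`ensemble_confidence`) is the plain voxel-wise mean of member
softmax maps; it sharpens candidate regions and recovers lesions single
members miss.

## Pseudo labels

Keep the `n_sig` most confident candidates (extraction order breaks
confidence ties); the label is the binary union of their regions.
`n_sig = 0` yields a *labeled* negative exam with an empty mask — negative
exams are where automatic annotation is essentially free. Exams with fewer
candidates than `n_sig` are excluded: they are guaranteed to miss a
reported lesion, so removing them raises the lesion-level sensitivity of
the surviving labels. Soft labels from other pipelines can be binarized at
0.5 (`binarize_soft_label`, boundary inclusive) for comparison.

## Evaluation

- **Matching**: candidates greedily matched to 26-connected ground-truth
  lesions in descending confidence; hit when IoU ≥ 0.10 (configurable; a
  peak-inside-lesion criterion is also provided); one-to-one.
- **FROC**: thresholds swept over all distinct candidate confidences;
  sensitivity = matched lesions / all lesions, FP/exam = unmatched
  candidates / exams. The partial AUC integrates the step curve over
  FP/exam ∈ [0, 1] (raw area, max 1.0), zero-extended below the first
  operating point and held constant beyond the last.
- **ROC**: exam score = maximum candidate confidence (0 if none); AUC by
  trapezoid, equivalent to the tie-corrected Mann–Whitney statistic.
- **Permutation test**: two-sided, statistic = difference of group means;
  exhaustive enumeration when the pooled sample is ≤ 12, otherwise Monte
  Carlo with add-one correction `p = (1 + k)/(B + 1)` — validity is exact,
  and the smallest attainable p is `1/(B+1)`.
- **Bootstrap CIs**: n-of-n patient resampling, percentile interval;
  resamples containing a single class are rejected and redrawn (the metric
  is undefined on them).
- **Dice**: `2|A∩B|/(|A|+|B|)`, defined as 1 when both masks are empty.

## Annotation burden

Performance-vs-budget observations are interpolated **linearly in
ln(budget)** (performance grows roughly logarithmically with training-set
size; base of the logarithm is immaterial). `matched_budget` inverts a
monotone curve in closed form within the first qualifying segment; no
extrapolation beyond observed budgets is offered — extrapolated log trends
are not trustworthy. The reduction factor is
`N_supervised / N_semisupervised`. Because a budget of B exams under
k-fold cross-validation trains each model on `B·(k−1)/k` exams, both
conventions appear in practice; `per_fold_training_size` makes the
conversion explicit (3050 → 2440 at 5 folds) instead of guessing.

## Synthetic cohorts

The generator emulates the *statistical structure* the pipeline consumes,
not MRI physics. Per exam: Poisson(`lesion_rate`) lesion blobs and
Poisson(`distractor_rate`) distractor blobs, each an axis-aligned
anisotropic Gaussian merged by voxel-wise maximum; an ensemble of noisy
copies; a ground-truth region per lesion (voxels ≥ half that blob's peak);
a templated report with one PI-RADS ≥ 4 line per lesion. Everything is a
pure function of `(seed, case_index)`.

Two shape choices matter:

- **Support truncation.** Blob profiles are zeroed below 0.45 of their
  peak. Trained segmentation networks produce steep, saturated softmax
  boundaries; smooth Gaussian tails would instead be shredded by the
  iterative extractor into shell-shaped spurious candidates that dominate
  the false-positive count. With truncation, a candidate region covers the
  whole blob support, and false positives are the planted distractors.
- **Lesion peak range (0.05, 0.95).** The lower tail dips below the
  extractor's confidence floor, so ~2% of lesions are genuine teacher
  misses. This exercises the insufficient-candidate exclusion rule and
  produces realistic sensitivity below 1.

Default study conditions (chosen once, with their reasoning):

| parameter | default | models |
|---|---|---|
| `n_exams` | 200 | desk-scale cohort, minutes on one CPU |
| `volume_shape`, `spacing_mm` | (16, 48, 48) @ (3, 1, 1) mm | prostate-like field of view, anisotropic slices |
| `lesion_rate` | 0.5 | Poisson P(0) ≈ 0.61 ≈ the ~60% negative-exam fraction typical of detection cohorts |
| `distractor_rate` | 0.4 | the ≈0.4 false-positive candidates/exam a high-sensitivity teacher produces |
| `distractor_peak_range` | (0.20, 0.45) | teacher FPs are less confident than most true lesions, so suppression by ranking is verifiable |
| `noise_sd`, `ensemble_size` | 0.05, 15 | inter-model disagreement; 15 = 3 restarts × 5 folds |
| report noise | flip 0.007, unparseable 0.02 | per-mille extraction errors and ~2% unparseable reports seen in clinical text |

What the generator does **not** model: anatomy and zonal priors, imaging
artifacts, spatially correlated model errors, report ambiguity beyond
score flips (multifocality, size-only descriptions), and any coupling
between lesion difficulty and report quality. Passing tests therefore
demonstrate the correctness and the qualitative behavior of the
*labeling and evaluation machinery* — FP suppression, exclusion effects,
calibration of the statistics — not clinical performance.

## Numerical choices and edge cases

- Peak ties: lowest (z, y, x) wins (C-order argmax) — determinism.
- Candidate confidence ties at the n_sig boundary: extraction order wins.
- FROC with zero candidates: empty curve, pAUC 0. Zero ground-truth
  lesions: rejected (`sensitivity` undefined).
- Permutation p-values compare `|diff| ≥ |observed| − 1e-12` to absorb
  float noise in mean differences.
- `binarize_soft_label` and ground-truth binarization use ≥ (boundary
  inclusive).
- Volumes are (z, y, x) with spacing in mm; SimpleITK's (x, y, z) header
  spacing is reversed on I/O.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the pipeline at 200 exams
(16×48×48 voxels, 15-member ensembles), 100-map oracle-equivalence sweeps,
1000 × 2000-iteration permutation calibration, and reduced-iteration
bootstrap checks — sizes at which every result is exact or
seed-deterministic while the whole suite completes in seconds on one CPU.
The statistical defaults (10⁶ iterations) remain available for production
use.

## Known limitations

- The dialect grammar ships with a templated-English and a loose pattern
  set; unstructured clinical prose in other languages needs a new dialect
  (or a learned extractor, which is out of scope).
- The FROC hit criterion (IoU ≥ 0.10, greedy) and the exam-score reduction
  (max confidence) are field-standard but not canonical; both are
  config-exposed so alternatives can be evaluated.
- Pseudo labels are binary: per-lesion PI-RADS categories are not
  propagated into the mask.
- No resampling/registration: input volumes are assumed co-registered on a
  shared grid.
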