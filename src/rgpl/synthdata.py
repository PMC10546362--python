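"""Synthetic cohorts: confidence-map ensembles, masks, and report texts.

The generator emulates the statistical structure the pseudo-labeling
pipeline consumes, not MRI physics.  Each exam gets:

* a base confidence map built from axis-aligned anisotropic Gaussian blobs
  — *lesions* (high peaks, each backed by a ground-truth region) and
  *distractors* (lower peaks with no ground truth, standing in for teacher
  false positives, the quantity the n_sig mask must suppress);
  overlapping blobs merge by voxel-wise maximum;
* an ensemble of noisy copies (clipped(base + Gaussian noise, 0, 1)),
  mimicking independently trained teacher models;
* a ground-truth mask: per lesion blob, the voxels at or above half its
  peak;
* a templated English radiology report with one PI-RADS >= 4 entry per
  planted lesion, optionally degraded by score flips or replaced by an
  unparseable text.

Lesion and distractor counts follow Poisson models.  Everything is fully
determined by (spec.seed, case_index).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator

import numpy as np

from .exceptions import ConfigurationError
from .volume import Volume3D, write_volume

__all__ = ["ReportNoise", "CohortSpec", "SyntheticCase", "generate_case", "iter_cases", "generate_cohort"]

_UNPARSEABLE_TEXT = (
    "Report unavailable. Examination performed for follow-up of known benign "
    "prostatic hyperplasia; see prior study for details.\n"
)


@dataclasses.dataclass(frozen=True)
class ReportNoise:
    """Degradation model for template reports.

    score_flip_prob
        Per lesion entry, probability that the written score is replaced by
        a uniformly random different score in 1..5 (emulates typing
        mistakes and addendum updates).
    unparseable_prob
        Per exam, probability the report is replaced with text containing
        no recognizable PI-RADS score.
    """

    score_flip_prob: float = 0.007
    unparseable_prob: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.score_flip_prob, self.unparseable_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probabilities must be in [0, 1], got {p}")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults model a prostate-MRI-like setting at desk scale: roughly 60%
    of exams negative (Poisson lesion rate 0.5), teacher false-positive
    blobs at 0.4 per exam, a 15-member teacher ensemble, and report noise
    at the per-mille level.  The lesion peak range reaches below the
    extractor's confidence floor so a small fraction of lesions (~2%) is
    genuinely missed by the teacher, exercising the insufficient-candidate
    exclusion rule.
    """

    n_exams: int = 200
    volume_shape: tuple[int, int, int] = (16, 48, 48)
    spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    lesion_rate: float = 0.5
    lesion_peak_range: tuple[float, float] = (0.05, 0.95)
    distractor_rate: float = 0.4
    distractor_peak_range: tuple[float, float] = (0.2, 0.45)
    noise_sd: float = 0.05
    ensemble_size: int = 15
    report_noise: ReportNoise = dataclasses.field(default_factory=ReportNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 1 or self.ensemble_size < 1:
            raise ConfigurationError("n_exams and ensemble_size must be >= 1")
        if any(s < 4 for s in self.volume_shape):
            raise ConfigurationError("volume_shape axes must be >= 4")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing must be strictly positive")
        for lo, hi in (self.lesion_peak_range, self.distractor_peak_range):
            if not (0.0 < lo <= hi <= 1.0):
                raise ConfigurationError("peak ranges must satisfy 0 < low <= high <= 1")
        if self.lesion_rate < 0 or self.distractor_rate < 0 or self.noise_sd < 0:
            raise ConfigurationError("rates and noise_sd must be non-negative")


@dataclasses.dataclass(frozen=True)
class SyntheticCase:
    exam_id: str
    confidence_ensemble: tuple[Volume3D, ...]
    gt_mask: Volume3D
    report_text: str
    true_counts: dict
    lesion_centers: tuple[tuple[float, float, float], ...]
    planted_scores: tuple[int, ...]
    written_scores: tuple[int, ...]


#: Blob support cutoff, relative to the blob's peak.  Softmax confidence
#: maps of trained segmentation models are steep near lesion boundaries
#: (saturated inside, near zero outside); a hard cutoff on the Gaussian
#: profile emulates that.  It is set above the extractor's default relative
#: threshold (0.40) so a candidate region covers the whole blob support and
#: smooth tails are not shredded into shell-shaped spurious candidates.
SUPPORT_RELATIVE = 0.45


def _blob(shape, center, sigma_vox, peak) -> np.ndarray:
    """Separable anisotropic Gaussian with hard support cutoff."""
    axes = [
        np.exp(-0.5 * ((np.arange(n) - c) / s) ** 2)
        for n, c, s in zip(shape, center, sigma_vox)
    ]
    g = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    g[g < SUPPORT_RELATIVE] = 0.0
    return peak * g


def _sample_blob(rng, spec: CohortSpec, peak_range, sigma_mm_ranges):
    sigma_mm = np.array([rng.uniform(lo, hi) for lo, hi in sigma_mm_ranges])
    sigma_vox = np.maximum(sigma_mm / np.asarray(spec.spacing_mm), 0.5)
    margin = np.minimum(2.0 * sigma_vox + 1.0, np.asarray(spec.volume_shape) / 2.0 - 0.5)
    center = np.array(
        [rng.uniform(m, n - 1 - m) for n, m in zip(spec.volume_shape, margin)]
    )
    peak = float(rng.uniform(*peak_range))
    return center, sigma_vox, peak


# Physical blob sizes in mm (z, y, x): lesions ~0.3 cm^3 at half peak,
# distractors somewhat smaller but still above the 50 mm^3 size filter.
_LESION_SIGMA_MM = ((3.0, 4.5), (2.5, 4.5), (2.5, 4.5))
_DISTRACTOR_SIGMA_MM = ((3.0, 3.6), (2.0, 3.0), (2.0, 3.0))


def generate_case(spec: CohortSpec, case_index: int) -> SyntheticCase:
    """Generate one exam; bit-identical for identical (spec.seed, case_index)."""
    rng = np.random.default_rng([int(spec.seed) % (2**31), int(case_index)])
    shape = spec.volume_shape

    n_lesions = int(rng.poisson(spec.lesion_rate))
    base = np.zeros(shape, dtype=np.float64)
    gt = np.zeros(shape, dtype=np.uint8)
    centers = []
    for _ in range(n_lesions):
        center, sigma_vox, peak = _sample_blob(rng, spec, spec.lesion_peak_range, _LESION_SIGMA_MM)
        field = _blob(shape, center, sigma_vox, peak)
        np.maximum(base, field, out=base)
        gt[field >= 0.5 * peak] = 1
        centers.append(tuple(float(c) for c in center))

    n_distractors = int(rng.poisson(spec.distractor_rate))
    for _ in range(n_distractors):
        center, sigma_vox, peak = _sample_blob(
            rng, spec, spec.distractor_peak_range, _DISTRACTOR_SIGMA_MM
        )
        np.maximum(base, _blob(shape, center, sigma_vox, peak), out=base)

    ensemble = []
    for _ in range(spec.ensemble_size):
        member = base + rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else base
        ensemble.append(
            Volume3D(np.clip(member, 0.0, 1.0).astype(np.float32), spec.spacing_mm)
        )

    planted = tuple(int(s) for s in rng.integers(4, 6, size=n_lesions))
    written = []
    for s in planted:
        if rng.random() < spec.report_noise.score_flip_prob:
            others = [x for x in range(1, 6) if x != s]
            s = int(others[rng.integers(0, len(others))])
        written.append(s)
    unparseable = bool(rng.random() < spec.report_noise.unparseable_prob)

    if unparseable:
        report = _UNPARSEABLE_TEXT
    else:
        lines = ["Prostate MRI, biparametric protocol."]
        for i, s in enumerate(written, start=1):
            d = int(rng.integers(8, 22))
            lines.append(f"Lesion {i}: peripheral zone, {d} mm, PI-RADS {s}.")
        if not written:
            lines.append("No suspicious focal lesions. Overall PI-RADS category: 2.")
        report = "\n".join(lines) + "\n"

    return SyntheticCase(
        exam_id=f"case_{case_index:04d}",
        confidence_ensemble=tuple(ensemble),
        gt_mask=Volume3D(gt, spec.spacing_mm),
        report_text=report,
        true_counts={
            "n_lesions": n_lesions,
            "n_sig": n_lesions,
            "n_distractors": n_distractors,
            "unparseable": unparseable,
        },
        lesion_centers=tuple(centers),
        planted_scores=planted,
        written_scores=tuple(written),
    )


def iter_cases(spec: CohortSpec) -> Iterator[SyntheticCase]:
    """Stream the cohort one exam at a time (volumes can be large)."""
    for i in range(spec.n_exams):
        yield generate_case(spec, i)


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> list[dict]:
    """Generate the whole cohort; optionally write it to disk.

    Returns the manifest: per exam, the true lesion count and n_sig, the
    planted blob centers, and (when writing) relative file paths.  On disk
    each exam gets a directory with ``member_XX.mha`` ensemble maps,
    ``gt.mha``, and ``report.txt``; the manifest is ``manifest.json``.
    """
    manifest: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for case in iter_cases(spec):
        entry = {
            "exam_id": case.exam_id,
            "true_n_lesions": case.true_counts["n_lesions"],
            "true_n_sig": case.true_counts["n_sig"],
            "n_distractors": case.true_counts["n_distractors"],
            "lesion_centers": [list(c) for c in case.lesion_centers],
            "written_scores": list(case.written_scores),
        }
        if out_path is not None:
            exam_dir = out_path / case.exam_id
            exam_dir.mkdir(exist_ok=True)
            members = []
            for j, vol in enumerate(case.confidence_ensemble):
                name = f"member_{j:02d}.mha"
                write_volume(vol, exam_dir / name)
                members.append(f"{case.exam_id}/{name}")
            write_volume(case.gt_mask, exam_dir / "gt.mha")
            (exam_dir / "report.txt").write_text(case.report_text, encoding="utf-8")
            entry.update(
                confidence_paths=members,
                gt_path=f"{case.exam_id}/gt.mha",
                report_path=f"{case.exam_id}/report.txt",
            )
        manifest.append(entry)
    if out_path is not None:
        (out_path / "manifest.json").write_text(
            json.dumps({"spec": dataclasses.asdict(spec), "exams": manifest}, indent=1),
            encoding="utf-8",
        )
    return manifest
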