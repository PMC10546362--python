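"""Report-guided pseudo labels.

Given a detection map (ranked lesion candidates from a teacher model) and
the number of clinically significant findings stated in the exam's report
(``n_sig``), the pseudo label keeps the ``n_sig`` most confident candidates
and discards the rest.  Two exclusion rules apply:

* exams whose report yielded no PI-RADS score are excluded
  (``excluded_unparseable_report``) rather than treated as negative;
* exams with fewer candidates than ``n_sig`` are excluded
  (``excluded_insufficient_candidates``) — for these we are certain at
  least one reported lesion was missed, so dropping them raises the
  lesion-level sensitivity of the remaining pseudo labels.

``n_sig = 0`` produces a labeled negative exam with an all-zero mask:
negative exams can be annotated automatically almost perfectly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .candidates import DetectionMap
from .exceptions import ConfigurationError, InputError
from .reports import PARSED, ReportFindings
from .volume import Volume3D, write_volume

__all__ = [
    "PseudoLabelResult",
    "CohortSummary",
    "LABELED",
    "EXCLUDED_INSUFFICIENT",
    "EXCLUDED_UNPARSEABLE",
    "generate_pseudo_label",
    "binarize_soft_label",
    "build_pseudo_labeled_cohort",
]

LABELED = "labeled"
EXCLUDED_INSUFFICIENT = "excluded_insufficient_candidates"
EXCLUDED_UNPARSEABLE = "excluded_unparseable_report"


@dataclasses.dataclass(frozen=True)
class PseudoLabelResult:
    """Binary voxel label for one exam, or the reason it was excluded.

    When ``status`` is ``labeled``, ``mask`` is exactly the union of the
    ``kept_candidates`` regions (all zero for a negative exam with
    ``n_sig`` = 0); otherwise ``mask`` is ``None``.
    """

    exam_id: str
    status: str
    n_sig: int
    kept_candidates: tuple[int, ...] = ()
    mask: Volume3D | None = None


def generate_pseudo_label(
    detection: DetectionMap,
    findings: ReportFindings,
) -> PseudoLabelResult:
    """Mask a detection map down to the n_sig most confident candidates.

    Candidates are already sorted by non-increasing confidence with ties
    resolved by extraction order, so "keep the first n_sig" is exact.
    """
    if findings.status != PARSED:
        return PseudoLabelResult(
            exam_id=findings.exam_id, status=EXCLUDED_UNPARSEABLE, n_sig=findings.n_sig
        )
    n_sig = findings.n_sig
    if len(detection.candidates) < n_sig:
        return PseudoLabelResult(
            exam_id=findings.exam_id, status=EXCLUDED_INSUFFICIENT, n_sig=n_sig
        )
    kept = tuple(c.label_id for c in detection.candidates[:n_sig])
    return PseudoLabelResult(
        exam_id=findings.exam_id,
        status=LABELED,
        n_sig=n_sig,
        kept_candidates=kept,
        mask=detection.mask_for(kept),
    )


def binarize_soft_label(soft: Volume3D, threshold: float = 0.5) -> Volume3D:
    """Binarize a soft (probabilistic) label; a voxel is 1 iff value >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    soft.validate_confidence()
    return Volume3D(
        values=(np.asarray(soft.values) >= threshold).astype(np.uint8),
        spacing=soft.spacing,
    )


@dataclasses.dataclass
class CohortSummary:
    """Bookkeeping of a pseudo-labeling pass over a cohort."""

    results: dict[str, PseudoLabelResult]
    n_labeled: int
    n_excluded_by_reason: dict[str, int]
    missing: list[str]

    def to_dict(self) -> dict:
        return {
            "n_exams": len(self.results),
            "n_labeled": self.n_labeled,
            "n_excluded_by_reason": dict(self.n_excluded_by_reason),
            "missing": list(self.missing),
            "status_by_exam": {k: r.status for k, r in sorted(self.results.items())},
        }


def build_pseudo_labeled_cohort(
    detections: Mapping[str, DetectionMap],
    findings: Mapping[str, ReportFindings],
    out_dir: str | Path | None = None,
    mask_format: str = ".mha",
) -> CohortSummary:
    """Generate pseudo labels for every exam present in both inputs.

    Exams present in only one input are skipped and reported in
    ``missing``.  When ``out_dir`` is given, labeled masks are written as
    ``<exam_id>_pseudo<mask_format>`` plus a ``manifest.json``.
    """
    shared = sorted(set(detections) & set(findings))
    if not shared:
        raise InputError("detections and findings share no exam ids")
    missing = sorted(set(detections) ^ set(findings))

    results: dict[str, PseudoLabelResult] = {}
    n_excluded: dict[str, int] = {EXCLUDED_INSUFFICIENT: 0, EXCLUDED_UNPARSEABLE: 0}
    for exam_id in shared:
        res = generate_pseudo_label(detections[exam_id], findings[exam_id])
        results[exam_id] = res
        if res.status != LABELED:
            n_excluded[res.status] += 1
    n_labeled = sum(1 for r in results.values() if r.status == LABELED)
    summary = CohortSummary(
        results=results, n_labeled=n_labeled, n_excluded_by_reason=n_excluded, missing=missing
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for exam_id, res in results.items():
            entry = {"exam_id": exam_id, "status": res.status, "n_sig": res.n_sig}
            if res.status == LABELED and res.mask is not None:
                path = out_dir / f"{exam_id}_pseudo{mask_format}"
                write_volume(res.mask, path)
                entry["pseudo_label_path"] = path.name
                entry["kept_candidates"] = list(res.kept_candidates)
            manifest.append(entry)
        (out_dir / "manifest.json").write_text(
            json.dumps({"exams": manifest, "summary": summary.to_dict()}, indent=1),
            encoding="utf-8",
        )
    return summary
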