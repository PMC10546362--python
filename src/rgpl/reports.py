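"""Rule-based extraction of PI-RADS scores from radiology report text.

The quantity of interest is ``n_sig``: the number of lesions the radiologist
deemed (very) likely to harbor clinically significant prostate cancer, i.e.
the number of reported PI-RADS >= 4 findings.  Report style varies between
sites, so the pattern matching is factored into *dialects*: an ordered list
of regular expressions with a named capture for the score digit, optional
fallback patterns for overall-impression lines, and an optional addendum
delimiter.  Two dialects ship with the package:

``structured_en``
    Templated English reports with per-lesion lines ("Lesion 1: ...
    PI-RADS 4.") and an overall impression used as fallback for negative
    exams.  An addendum section ("Addendum: Lesion 1: PI-RADS 5.") overrides
    the body score for the same lesion index.
``loose``
    Any occurrence of a PI-RADS score anywhere in the text.

A report from which no score can be extracted gets status ``unparseable``;
such exams are excluded from pseudo-labeling rather than silently treated
as negative.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "ReportFindings",
    "Dialect",
    "ExtractionConfusion",
    "available_dialects",
    "get_dialect",
    "extract_scores",
    "count_significant",
    "evaluate_extraction",
    "read_reports",
    "write_findings_jsonl",
]

PARSED = "parsed"
UNPARSEABLE = "unparseable"

#: PI-RADS scores at or above this value count as clinically significant.
DEFAULT_SIGNIFICANCE_THRESHOLD = 4


@dataclasses.dataclass(frozen=True)
class ReportFindings:
    """PI-RADS scores extracted from one report.

    ``scores`` are in reading order; duplicate values for distinct lesions
    are all kept.  ``matched_spans`` gives, per score, the (start, end)
    character offsets of the text the dialect matched.
    """

    exam_id: str
    scores: tuple[int, ...]
    n_sig: int
    status: str  # "parsed" | "unparseable"
    matched_spans: tuple[tuple[int, int], ...] = ()

    def to_dict(self) -> dict:
        return {
            "exam_id": self.exam_id,
            "scores": list(self.scores),
            "n_sig": self.n_sig,
            "status": self.status,
            "matched_spans": [list(s) for s in self.matched_spans],
        }


@dataclasses.dataclass(frozen=True)
class Dialect:
    """A report-style grammar: ordered score patterns plus section handling.

    ``lesion_patterns`` are tried in order over the report body; each must
    expose a named group ``score`` (and may expose ``lesion`` for the lesion
    index and ``score2`` for split forms like "PI-RADS 4/5", which count once
    with the higher value).  ``fallback_patterns`` are consulted only when no
    lesion pattern matched anywhere (overall-impression lines).  Text after
    ``addendum_delimiter`` is parsed separately; an addendum score for lesion
    index k replaces the body score for the same index.
    """

    name: str
    lesion_patterns: tuple[re.Pattern, ...]
    fallback_patterns: tuple[re.Pattern, ...] = ()
    addendum_delimiter: re.Pattern | None = None


_PIRADS = r"PI\s*-?\s*RADS\s*(?:category\s*)?:?\s*"

_STRUCTURED_EN = Dialect(
    name="structured_en",
    lesion_patterns=(
        re.compile(
            r"(?:lesion|laesie)\s*(?P<lesion>\d+)\b[^\n]*?"
            + _PIRADS
            + r"(?P<score>[1-5])(?:\s*/\s*(?P<score2>[1-5]))?",
            re.IGNORECASE,
        ),
    ),
    fallback_patterns=(
        re.compile(
            r"(?:overall|impression|conclusion)\b[^\n]*?"
            + _PIRADS
            + r"(?P<score>[1-5])\b",
            re.IGNORECASE,
        ),
    ),
    addendum_delimiter=re.compile(r"\baddendum\b\s*:?", re.IGNORECASE),
)

_LOOSE = Dialect(
    name="loose",
    lesion_patterns=(
        re.compile(
            _PIRADS + r"(?P<score>[1-5])(?:\s*/\s*(?P<score2>[1-5]))?",
            re.IGNORECASE,
        ),
    ),
)

_DIALECTS: dict[str, Dialect] = {d.name: d for d in (_STRUCTURED_EN, _LOOSE)}


def available_dialects() -> tuple[str, ...]:
    return tuple(sorted(_DIALECTS))


def get_dialect(name: str | Dialect) -> Dialect:
    if isinstance(name, Dialect):
        return name
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {name!r}; available: {available_dialects()}"
        ) from None


def count_significant(
    scores: Iterable[int], threshold: int = DEFAULT_SIGNIFICANCE_THRESHOLD
) -> int:
    """Number of scores at or above the significance threshold (n_sig)."""
    threshold = int(threshold)
    if not 1 <= threshold <= 5:
        raise InputError(f"threshold must be in 1..5, got {threshold}")
    n = 0
    for s in scores:
        s = int(s)
        if not 1 <= s <= 5:
            raise InputError(f"PI-RADS scores must be in 1..5, got {s}")
        if s >= threshold:
            n += 1
    return n


@dataclasses.dataclass
class _Match:
    score: int
    span: tuple[int, int]
    lesion_index: int | None


def _scan(dialect: Dialect, text: str, offset: int = 0) -> list[_Match]:
    """Collect lesion-pattern matches in reading order; overlapping matches
    from lower-priority patterns are dropped."""
    found: list[tuple[int, int, _Match]] = []
    taken: list[tuple[int, int]] = []
    for pat in dialect.lesion_patterns:
        for m in pat.finditer(text):
            span = m.span()
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            taken.append(span)
            score = int(m.group("score"))
            g = m.groupdict()
            if g.get("score2"):
                score = max(score, int(g["score2"]))
            lesion = int(g["lesion"]) if g.get("lesion") else None
            found.append(
                (span[0], span[1], _Match(score, (span[0] + offset, span[1] + offset), lesion))
            )
    found.sort(key=lambda t: (t[0], t[1]))
    return [m for _, _, m in found]


def extract_scores(
    report_text: str,
    dialect: str | Dialect = "structured_en",
    significance_threshold: int = DEFAULT_SIGNIFICANCE_THRESHOLD,
    exam_id: str = "",
) -> ReportFindings:
    """Extract every PI-RADS score the dialect recognizes, in reading order.

    Addendum scores override body scores for the same lesion index; split
    scores such as "PI-RADS 4/5" count once with the higher value; when no
    lesion pattern matches, overall-impression fallback patterns are tried.
    Zero recognized scores yields status ``unparseable``.
    """
    if not isinstance(report_text, str):
        raise InputError(f"report_text must be str, got {type(report_text).__name__}")
    d = get_dialect(dialect)

    body, addendum, add_offset = report_text, "", 0
    if d.addendum_delimiter is not None:
        m = d.addendum_delimiter.search(report_text)
        if m:
            body = report_text[: m.start()]
            addendum = report_text[m.end() :]
            add_offset = m.end()

    matches = _scan(d, body)
    for am in _scan(d, addendum, offset=add_offset):
        if am.lesion_index is not None:
            existing = [x for x in matches if x.lesion_index == am.lesion_index]
            if existing:
                for x in existing:
                    x.score, x.span = am.score, am.span
                continue
        matches.append(am)

    if not matches:
        for pat in d.fallback_patterns:
            fm = pat.search(report_text)
            if fm:
                matches = [_Match(int(fm.group("score")), fm.span(), None)]
                break

    scores = tuple(m.score for m in matches)
    spans = tuple(m.span for m in matches)
    status = PARSED if scores else UNPARSEABLE
    return ReportFindings(
        exam_id=exam_id,
        scores=scores,
        n_sig=count_significant(scores, significance_threshold),
        status=status,
        matched_spans=spans,
    )


@dataclasses.dataclass(frozen=True)
class ExtractionConfusion:
    """Confusion matrix of reported-count extraction, true x predicted.

    Counts above ``top_bin`` are clipped into the top bin for display
    (bins "0", "1", "2", ">=3" by default).  ``accuracy`` is the exact-match
    fraction on the raw (unclipped) counts; ``negative_accuracy`` is the same
    restricted to exams whose reference count is zero (negative exams).
    """

    matrix: np.ndarray
    accuracy: float
    negative_accuracy: float
    top_bin: int = 3
    n_reports: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        labels = [str(i) for i in range(self.top_bin)] + [f">={self.top_bin}"]
        return pd.DataFrame(self.matrix, index=labels, columns=labels).rename_axis(
            index="true", columns="predicted"
        )


def evaluate_extraction(
    predicted: Mapping[str, int],
    reference: Mapping[str, int],
    top_bin: int = 3,
) -> ExtractionConfusion:
    """Compare predicted n_sig against reference counts over shared exam ids."""
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise InputError("predicted and reference share no exam ids")
    pred = np.array([int(predicted[k]) for k in shared])
    ref = np.array([int(reference[k]) for k in shared])
    if (pred < 0).any() or (ref < 0).any():
        raise InputError("counts must be non-negative")

    k = top_bin + 1
    matrix = np.zeros((k, k), dtype=np.int64)
    np.add.at(matrix, (np.minimum(ref, top_bin), np.minimum(pred, top_bin)), 1)
    accuracy = float((pred == ref).mean())
    neg = ref == 0
    negative_accuracy = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    return ExtractionConfusion(
        matrix=matrix,
        accuracy=accuracy,
        negative_accuracy=negative_accuracy,
        top_bin=top_bin,
        n_reports=len(shared),
    )


def read_reports(path: str | Path) -> dict[str, str]:
    """Read reports from a JSONL file ({"exam_id", "report"} per line) or a
    directory of ``<exam_id>.txt`` files."""
    path = Path(path)
    reports: dict[str, str] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            reports[f.stem] = f.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                reports[str(rec["exam_id"])] = rec["report"]
    if not reports:
        raise InputError(f"no reports found at {path}")
    return reports


def write_findings_jsonl(findings: Iterable[ReportFindings], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in findings:
            fh.write(json.dumps(f.to_dict()) + "\n")
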