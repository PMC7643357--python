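"""Matching selected detections against ground truth and scoring.

A predicted rectangle is correct when it has more than 80% overlap
(IoU) with a native contact of the same type; matching is greedy by
descending overlap with each prediction and each truth used at most
once.  Precision, recall and F-measure are reported per contact type
and overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .selection import iou
from .types import CONTACT_TYPES, Detection, SSEContact


@dataclass
class TypeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class EvalReport:
    """Per-type and overall counts/metrics plus the matched pair list."""

    per_type: dict[str, TypeCounts] = field(
        default_factory=lambda: {t: TypeCounts() for t in CONTACT_TYPES}
    )
    matches: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def overall(self) -> TypeCounts:
        return TypeCounts(
            tp=sum(c.tp for c in self.per_type.values()),
            fp=sum(c.fp for c in self.per_type.values()),
            fn=sum(c.fn for c in self.per_type.values()),
        )

    def merge(self, other: "EvalReport") -> "EvalReport":
        """Pool counts with another report (matches are not carried over)."""
        out = EvalReport()
        for t in CONTACT_TYPES:
            a, b = self.per_type[t], other.per_type[t]
            out.per_type[t] = TypeCounts(a.tp + b.tp, a.fp + b.fp, a.fn + b.fn)
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for name, c in [*self.per_type.items(), ("overall", self.overall)]:
            rows.append(
                {
                    "type": name,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "precision": round(c.precision, 4),
                    "recall": round(c.recall, 4),
                    "f_measure": round(c.f_measure, 4),
                }
            )
        return rows

    def to_tsv(self) -> str:
        rows = self.to_rows()
        header = "\t".join(rows[0].keys())
        body = "\n".join("\t".join(str(v) for v in row.values()) for row in rows)
        return header + "\n" + body + "\n"

    def to_json(self) -> str:
        return json.dumps({row["type"]: row for row in self.to_rows()}, indent=2)


def match_detections(
    selected: list[Detection],
    truth: list[SSEContact | Detection],
    overlap_threshold: float = 0.8,
) -> EvalReport:
    """Match predictions to ground truth and count TP/FP/FN per type.

    Candidate pairs are same-type (prediction, truth) pairs with IoU
    strictly above ``overlap_threshold``; they are committed greedily in
    descending IoU order, each side used at most once.
    """
    report = EvalReport()
    candidates: list[tuple[float, int, int]] = []
    for pi, pred in enumerate(selected):
        for ti, tru in enumerate(truth):
            if pred.type != tru.type:
                continue
            ov = iou(pred.region, tru.region)
            if ov > overlap_threshold:
                candidates.append((ov, pi, ti))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_pred: set[int] = set()
    used_truth: set[int] = set()
    for ov, pi, ti in candidates:
        if pi in used_pred or ti in used_truth:
            continue
        used_pred.add(pi)
        used_truth.add(ti)
        report.matches.append((pi, ti, ov))
        report.per_type[selected[pi].type].tp += 1
    for pi, pred in enumerate(selected):
        if pi not in used_pred:
            report.per_type[pred.type].fp += 1
    for ti, tru in enumerate(truth):
        if ti not in used_truth:
            report.per_type[tru.type].fn += 1
    return report
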