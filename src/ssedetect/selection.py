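"""Greedy selection of non-overlapping high-confidence detections.

Candidate rectangles are first filtered: anything overlapping the
diagonal band is discarded (contacting SSEs never straddle the
diagonal), as is anything scoring below the confidence threshold
(T = 0.70 by default).  The remainder is sorted by decreasing score
and consumed greedily: keep the top rectangle, drop everything that
shares a cell with it, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import Detection, RectRegion


@dataclass
class SelectionConfig:
    """T: confidence threshold; diag_halfwidth: diagonal band half-width."""

    T: float = 0.70
    diag_halfwidth: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.T <= 1.0):
            raise ValueError("threshold T must lie in [0, 1]")
        if self.diag_halfwidth < 0:
            raise ValueError("diag_halfwidth must be >= 0")


def overlaps_diagonal(region: RectRegion, diag_halfwidth: int = 5) -> bool:
    """True iff the region contains a cell (i, j) with |i - j| <= halfwidth."""
    # equivalent to the row interval intersecting [j0 - w, j1 + w)
    return region.i0 < region.j1 + diag_halfwidth and region.j0 - diag_halfwidth < region.i1


def rect_overlap_area(r1: RectRegion, r2: RectRegion) -> int:
    """Number of cells shared by two rectangles."""
    dh = min(r1.i1, r2.i1) - max(r1.i0, r2.i0)
    dw = min(r1.j1, r2.j1) - max(r1.j0, r2.j0)
    return max(dh, 0) * max(dw, 0)


def iou(r1: RectRegion, r2: RectRegion) -> float:
    """Intersection-over-union of two rectangles."""
    inter = rect_overlap_area(r1, r2)
    union = r1.area + r2.area - inter
    return inter / union if union else 0.0


def filter_candidates(
    detections: list[Detection],
    config: SelectionConfig | None = None,
    L: int | None = None,
) -> list[Detection]:
    """Drop detections below threshold T or overlapping the diagonal band."""
    config = config or SelectionConfig()
    return [
        d
        for d in detections
        if d.score >= config.T and not overlaps_diagonal(d.region, config.diag_halfwidth)
    ]


def _priority(d: Detection) -> tuple:
    # descending score, then larger area, then lexicographic corner,
    # then type name: a total order, so selection ignores input order
    return (-d.score, -d.region.area, d.region.i0, d.region.j0,
            d.region.i1, d.region.j1, d.type)


def greedy_select(detections: list[Detection]) -> list[Detection]:
    """Select a maximal set of pairwise non-overlapping detections.

    Detections are processed in decreasing score order (ties: larger
    area first, then top-left corner), keeping each one unless it shares
    a cell with an already-kept detection.  The total order makes the
    result independent of input order.
    """
    selected: list[Detection] = []
    for det in sorted(detections, key=_priority):
        if all(rect_overlap_area(det.region, s.region) == 0 for s in selected):
            selected.append(det)
    return selected


def select_detections(
    detections: list[Detection],
    config: SelectionConfig | None = None,
) -> list[Detection]:
    """Convenience composition: filter then greedily select."""
    config = config or SelectionConfig()
    return greedy_select(filter_candidates(detections, config))
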