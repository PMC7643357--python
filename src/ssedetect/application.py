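"""Downstream use of selected inter-SSE detections.

Two applications: (1) re-weighting a residue-contact training loss so
that residue pairs inside predicted contacting-SSE rectangles carry
weight 1 + S_t, where S_t is the detection's confidence score; and
(2) the standard range-stratified top-L/k evaluation of predicted
contact maps (short [6, 11], medium [12, 23], long [24, inf)
sequence-separation bands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selection import rect_overlap_area
from .types import Detection

_CLAMP = 1e-7
#: minimum sequence separation considered anywhere (below it: trivial neighbours)
MIN_SEPARATION = 6

RANGE_BANDS: dict[str, tuple[int, float]] = {
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, np.inf),
}


@dataclass
class WeightMap:
    """Symmetric L x L multiplier matrix: 1 + S_t inside selected regions."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("weight map must be square")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight map must be symmetric")
        if self.W.min(initial=1.0) < 1.0:
            raise ValueError("weights must be >= 1")

    @property
    def L(self) -> int:
        return self.W.shape[0]


def weight_map_from_detections(selected: list[Detection], L: int) -> WeightMap:
    """Build the 1 + S_t multiplier matrix from non-overlapping detections."""
    for a in range(len(selected)):
        for b in range(a + 1, len(selected)):
            if rect_overlap_area(selected[a].region, selected[b].region) > 0:
                raise ValueError(
                    "selected detections must be pairwise non-overlapping"
                )
    W = np.ones((L, L))
    for det in selected:
        r = det.region
        if r.i1 > L or r.j1 > L:
            raise ValueError(f"detection region {r} outside an L={L} map")
        W[r.i0:r.i1, r.j0:r.j1] = 1.0 + det.score
        W[r.j0:r.j1, r.i0:r.i1] = 1.0 + det.score
    return WeightMap(W=W)


def reweighted_cross_entropy(
    pred: np.ndarray,
    truth: np.ndarray,
    weights: WeightMap | np.ndarray | None = None,
    min_separation: int = MIN_SEPARATION,
) -> float:
    """Weighted cross-entropy over upper-triangle non-local residue pairs.

    Sum over pairs (i, j) with j - i >= ``min_separation`` of
    ``W[i,j] * [-y log p - (1 - y) log(1 - p)]``, probabilities clamped
    to [1e-7, 1 - 1e-7].  With all weights 1 this is the plain loss.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    W = np.ones_like(pred) if weights is None else (
        weights.W if isinstance(weights, WeightMap) else np.asarray(weights, dtype=float)
    )
    if not (pred.shape == truth.shape == W.shape) or pred.ndim != 2:
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}, W {W.shape}"
        )
    L = pred.shape[0]
    iu, ju = np.triu_indices(L, k=min_separation)
    p = np.clip(pred[iu, ju], _CLAMP, 1.0 - _CLAMP)
    y = truth[iu, ju]
    ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.sum(W[iu, ju] * ce))


def range_of(i: int, j: int) -> str:
    """Sequence-separation band of a residue pair.

    short for |i-j| in [6, 11], medium for [12, 23], long for
    [24, inf); separations below 6 fall in no band ('none').
    """
    if i == j:
        raise ValueError("range undefined for i == j")
    sep = abs(i - j)
    for name, (lo, hi) in RANGE_BANDS.items():
        if lo <= sep <= hi:
            return name
    return "none"


def topk_accuracy(
    pred: np.ndarray,
    truth: np.ndarray,
    band: str,
    divisor: int,
) -> float | None:
    """Accuracy of the top L/divisor predicted contacts in one band.

    Upper-triangle pairs whose separation falls in ``band`` are ranked
    by predicted probability (descending, ties broken by coordinates);
    the returned value is the fraction of true contacts among the top
    k = floor(L / divisor).  Returns None when the band holds no pairs
    for this L or when k < 1.
    """
    if band not in RANGE_BANDS:
        raise ValueError(f"unknown band {band!r}")
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 2:
        raise ValueError("pred and truth must be equal-shape square matrices")
    L = pred.shape[0]
    k = L // divisor
    if k < 1:
        return None
    lo, hi = RANGE_BANDS[band]
    iu, ju = np.triu_indices(L, k=1)
    sep = ju - iu
    keep = (sep >= lo) & (sep <= hi)
    if not keep.any():
        return None
    iu, ju = iu[keep], ju[keep]
    order = np.lexsort((ju, iu, -pred[iu, ju]))[:k]
    hits = truth[iu[order], ju[order]] > 0
    return float(hits.sum()) / k


def topk_table(pred: np.ndarray, truth: np.ndarray) -> dict[str, dict[str, float | None]]:
    """Top L/10, L/5, L/2 and L accuracies for every separation band."""
    return {
        band: {
            f"L/{d}" if d > 1 else "L": topk_accuracy(pred, truth, band, d)
            for d in (10, 5, 2, 1)
        }
        for band in RANGE_BANDS
    }
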