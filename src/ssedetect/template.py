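"""Matched-filter detection of contact-map rectangle patterns.

A non-learned detector used as an independent reference for the trained
model.  Square templates of the three characteristic patterns (diagonal
line, anti-diagonal line, dashed anti-diagonal line) are slid over the
upper triangle at a range of sizes; every window whose score clears a
floor is then *calibrated*: the pattern line through the window is
walked outwards to its maximal run of signal cells, and the run's
bounding square becomes the candidate rectangle, rescored in place.
The calibration step is what turns many overlapping window hits along
one line into a single full-extent candidate.

Scores combine two factors in [0, 1]:

* the normalised cross-correlation between the patch and the zero-mean
  template (shape evidence, scale-invariant), and
* a saturating signal-strength term — the mean intensity over the
  template's "on" cells divided by a reference level (default 0.5),
  clipped to 1 — which keeps dim background flecks that happen to align
  from masquerading as contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ContactMap, Detection, RectRegion


@dataclass
class TemplateConfig:
    """Matched-filter parameters.

    sizes : template side lengths scanned for seeds.
    dash_period : dash repeat of the helix-helix pattern.
    signal_ref : reference intensity of the strength term; also the
        threshold a cell must reach to extend a pattern run.
    score_floor : minimum score for a window to seed a candidate and
        for a calibrated candidate to be emitted.
    min_size : smallest calibrated rectangle side emitted.
    """

    sizes: tuple[int, ...] = tuple(range(3, 17))
    dash_period: int = 4
    signal_ref: float = 0.5
    score_floor: float = 0.5
    min_size: int = 3


def pattern_template(ctype: str, size: int, dash_period: int = 4) -> np.ndarray:
    """Binary template of a characteristic pattern in a size x size box."""
    t = np.zeros((size, size))
    if ctype == "EE_PAR":
        np.fill_diagonal(t, 1.0)
    elif ctype == "EE_ANTI":
        np.fill_diagonal(np.fliplr(t), 1.0)
    elif ctype == "HH":
        for k in range(size):
            if k % dash_period in (0, 1):
                t[k, size - 1 - k] = 1.0
    else:
        raise ValueError(f"unknown contact type {ctype!r}")
    return t


def _score_patch(patch: np.ndarray, t: np.ndarray, signal_ref: float) -> float:
    """NCC x saturating strength of one patch against one template."""
    n_on = t.sum()
    if n_on < 2:
        return 0.0
    t0 = t - t.mean()
    t0 /= np.linalg.norm(t0)
    pm = patch.mean()
    denom = float(np.sqrt(max(((patch - pm) ** 2).sum(), 0.0)))
    if denom < 1e-9:
        return 0.0
    corr = float((patch * t0).sum()) / denom
    strength = min(float((patch * t).sum()) / n_on / signal_ref, 1.0)
    # round so float round-off cannot defeat the larger-area tie-break
    return round(min(max(corr, 0.0), 1.0) * max(strength, 0.0), 6)


def _walk_run(
    upper: np.ndarray,
    seed: tuple[int, int],
    step: tuple[int, int],
    thresh: float,
    gap_tol: int,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Maximal run of >= thresh cells through ``seed`` along ``step``,
    tolerating up to ``gap_tol`` consecutive sub-threshold cells."""
    L = upper.shape[0]
    ends = []
    for sign in (1, -1):
        di, dj = sign * step[0], sign * step[1]
        i, j = seed
        last = seed
        gap = 0
        while True:
            i, j = i + di, j + dj
            if not (0 <= i < L and 0 <= j < L and i < j):
                break
            if upper[i, j] >= thresh:
                last = (i, j)
                gap = 0
            else:
                gap += 1
                if gap > gap_tol:
                    break
        ends.append(last)
    return ends[1], ends[0]  # (backward end, forward end)


def _calibrate(
    upper: np.ndarray,
    ctype: str,
    seed: tuple[int, int],
    config: TemplateConfig,
) -> RectRegion | None:
    """Bounding square of the maximal pattern run through a seed cell."""
    if ctype == "EE_PAR":
        step, gap_tol = (1, 1), 0
    elif ctype == "EE_ANTI":
        step, gap_tol = (1, -1), 0
    else:  # HH: planted dashes leave period-2 holes along the anti-diagonal
        step, gap_tol = (1, -1), config.dash_period - 2
    (ai, aj), (bi, bj) = _walk_run(upper, seed, step, config.signal_ref, gap_tol)
    size = abs(bi - ai) + 1
    if size < config.min_size:
        return None
    i0, i1 = min(ai, bi), max(ai, bi) + 1
    j0, j1 = min(aj, bj), max(aj, bj) + 1
    if i1 <= i0 or j1 <= j0:
        return None
    return RectRegion(i0, i1, j0, j1)


def template_detect(
    cmap: ContactMap | np.ndarray,
    config: TemplateConfig | None = None,
) -> list[Detection]:
    """Slide pattern templates over the upper triangle and calibrate hits.

    Deterministic; no trained parameters.  Emits one Detection per
    calibrated (rectangle, type) with score >= the floor; downstream
    selection resolves overlaps and applies the confidence threshold.
    """
    config = config or TemplateConfig()
    P = cmap.P if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    L = P.shape[0]
    upper = np.triu(P, k=1)
    upper_sq = upper * upper
    map_id = getattr(cmap, "id", "")
    best: dict[tuple, Detection] = {}

    for size in config.sizes:
        if size < 2 or size > L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(upper, (size, size))
        win_sq = np.lib.stride_tricks.sliding_window_view(upper_sq, (size, size))
        n2 = size * size
        sums = np.einsum("ijkl->ij", win)
        means = sums / n2
        denom = np.sqrt(np.maximum(np.einsum("ijkl->ij", win_sq) - n2 * means * means, 0.0))

        for ctype in ("EE_PAR", "EE_ANTI", "HH"):
            t = pattern_template(ctype, size, config.dash_period)
            n_on = t.sum()
            if n_on < 2:
                continue
            t0 = t - t.mean()
            t0 /= np.linalg.norm(t0)
            num = np.einsum("ijkl,kl->ij", win, t0)
            corr = np.where(denom > 1e-9, num / np.maximum(denom, 1e-12), 0.0)
            on_mean = np.einsum("ijkl,kl->ij", win, t) / n_on
            strength = np.clip(on_mean / config.signal_ref, 0.0, 1.0)
            score = np.clip(corr, 0.0, 1.0) * strength

            for i, j in zip(*np.nonzero(score >= config.score_floor)):
                # seed: the brightest cell on the window's template line
                ti, tj = np.nonzero(t)
                vals = upper[i + ti, j + tj]
                k = int(np.argmax(vals))
                if vals[k] < config.signal_ref:
                    continue
                seed = (int(i + ti[k]), int(j + tj[k]))
                region = _calibrate(upper, ctype, seed, config)
                if region is None:
                    continue
                key = (region.as_tuple(), ctype)
                if key in best:
                    continue
                m = region.height
                patch = upper[region.i0:region.i1, region.j0:region.j1]
                tm = pattern_template(ctype, m, config.dash_period)
                final = _score_patch(patch, tm, config.signal_ref)
                if final >= config.score_floor:
                    best[key] = Detection(
                        region=region, type=ctype, score=final, id=map_id
                    )
    return sorted(best.values(), key=lambda d: (-d.score, d.region.as_tuple(), d.type))
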