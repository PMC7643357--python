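"""Synthetic contact maps with planted inter-SSE contact patterns.

Generates, at desk scale, the three characteristic rectangle patterns a
contact map shows for contacting secondary-structure elements: a
diagonal line for parallel strand pairs, an anti-diagonal line for
anti-parallel strand pairs, and a dashed (anti-diagonal) line for
helix pairs.  Every sample carries its ground truth, so detector
training and the evaluation protocol run end-to-end with no external
data.

Design notes
------------
* The two segments of a planted contact share one sampled length, so
  the planted line spans the full truth rectangle and the rectangle is
  recoverable from the pattern alone.  Real strand pairs of unequal
  length leave part of their rectangle patternless; see the methods
  documentation for what this simplification implies.
* Contacting pairs are placed with a sequence gap of at least 7
  residues so planted rectangles clear the diagonal exclusion band used
  during candidate selection.
* All randomness flows from ``SyntheticSpec.seed`` through per-sample
  spawned generators; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import (
    ContactMap,
    GenerationError,
    RectRegion,
    SecondaryStructure,
    SSEContact,
    SSESegment,
)

#: minimum coil gap between consecutive segments
_MIN_GAP = 2
#: minimum sequence gap between the two segments of a planted contact,
#: keeping the rectangle outside the default diagonal band (half-width 5)
_MIN_CONTACT_GAP = 7
_MAX_ATTEMPTS = 1000


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic contact-map distribution.

    L : map size (residues).
    n_sse : inclusive range for the total number of segments.
    len_h, len_e : inclusive helix / strand length ranges.
    n_contacts : inclusive range for the number of planted contacts.
    type_mix : probabilities over contact types; default 2:1:2
        (HH : EE_PAR : EE_ANTI), the composition of a mixed
        globular-protein test set.
    p_fg : (mean, sd) of the clipped-normal foreground signal.
    p_bg_rate : probability that a background cell is nonzero.
    p_bg_mag : (low, high) of the uniform background magnitude.
    dash_period : dash repeat of the helix-helix pattern; cells at
        offsets t = 0, 1 (mod period) along the anti-diagonal are kept.
    blur_sigma : Gaussian smoothing width (0 disables).
    seed : master seed; everything derives from it.
    """

    L: int = 96
    n_sse: tuple[int, int] = (5, 8)
    len_h: tuple[int, int] = (5, 12)
    len_e: tuple[int, int] = (4, 9)
    n_contacts: tuple[int, int] = (2, 4)
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"HH": 0.4, "EE_PAR": 0.2, "EE_ANTI": 0.4}
    )
    p_fg: tuple[float, float] = (0.8, 0.1)
    p_bg_rate: float = 0.05
    p_bg_mag: tuple[float, float] = (0.0, 0.4)
    dash_period: int = 4
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 16:
            raise ValueError("map size L must be at least 16")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix probabilities must sum to 1")
        if set(self.type_mix) - {"HH", "EE_PAR", "EE_ANTI"}:
            raise ValueError("type_mix keys must be contact types")
        if self.dash_period < 2:
            raise ValueError("dash_period must be >= 2")
        for name in ("n_sse", "len_h", "len_e", "n_contacts"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}")
        max_len = max(self.len_h[1], self.len_e[1])
        if max_len * max_len > self.L * self.L / 4:
            raise ValueError("segment lengths allow regions above the 1/4-map cap")


@dataclass
class SyntheticSample:
    """A contact map paired with its secondary structure and ground truth."""

    map: ContactMap
    ss: SecondaryStructure
    truth: list[SSEContact]


def _kind_of(ctype: str) -> str:
    return "H" if ctype == "HH" else "E"


def _draw_int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _collinear_patterns(c1: SSEContact, c2: SSEContact, dash_period: int) -> bool:
    """True when two planted lines lie on the same (anti)diagonal with a
    small gap.  Such configurations are inherently ambiguous: the union
    of the two lines is itself a valid longer pattern (two in-phase
    dashed helix lines two residues apart merge into one perfect dashed
    line), so no detector could recover the individual rectangles."""
    anti1 = c1.type in ("HH", "EE_ANTI")
    anti2 = c2.type in ("HH", "EE_ANTI")
    if anti1 != anti2:
        return False
    r1, r2 = c1.region, c2.region
    if anti1:  # anti-diagonal index i + j is constant along the line
        if r1.i0 + r1.j1 != r2.i0 + r2.j1:
            return False
    else:  # diagonal index j - i is constant
        if r1.j0 - r1.i0 != r2.j0 - r2.i0:
            return False
    gap = max(r2.i0 - r1.i1, r1.i0 - r2.i1)
    return gap <= dash_period


def sample_architecture(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[SecondaryStructure, list[SSESegment], list[SSEContact]]:
    """Draw a segment layout and planted-contact list (cells not yet planted).

    Segments are non-overlapping and separated by at least two coil
    residues; contact types follow ``spec.type_mix``; each contact pairs
    two dedicated equal-length segments, so planted rectangles are
    pairwise disjoint and lie strictly above the diagonal.
    """
    types = list(spec.type_mix)
    probs = np.array([spec.type_mix[t] for t in types])

    # Contact count and types are drawn once, before the placement loop:
    # rejection sampling then only retries the layout, so the type
    # marginal stays exactly the configured multinomial (feasibility is
    # correlated with segment lengths and would otherwise skew it).
    k = _draw_int(rng, spec.n_contacts)
    contact_types = [types[i] for i in rng.choice(len(types), size=k, p=probs)]

    for _ in range(_MAX_ATTEMPTS):
        n_total = max(_draw_int(rng, spec.n_sse), 2 * k)

        # Each contact owns two equal-length segments; extras are decoys.
        # Helix-contact lengths come in whole dash periods (m mod period in
        # {1, 2}) so the dashed pattern spans the full rectangle; otherwise
        # the rectangle would not be identifiable from the map at all.
        hh_lengths = [
            m
            for m in range(spec.len_h[0], spec.len_h[1] + 1)
            if m % spec.dash_period in (1, 2)
        ]
        entries: list[tuple[str, int, int | None]] = []  # (kind, length, contact idx)
        for c, ctype in enumerate(contact_types):
            kind = _kind_of(ctype)
            if ctype == "HH":
                if not hh_lengths:
                    raise GenerationError(
                        "len_h range contains no dash-aligned helix length"
                    )
                length = int(rng.choice(hh_lengths))
            else:
                length = _draw_int(rng, spec.len_e)
            entries.append((kind, length, c))
            entries.append((kind, length, c))
        for _ in range(n_total - 2 * k):
            kind = "H" if rng.random() < 0.5 else "E"
            length = _draw_int(rng, spec.len_h if kind == "H" else spec.len_e)
            entries.append((kind, length, None))

        order = rng.permutation(len(entries))
        entries = [entries[i] for i in order]

        total_len = sum(e[1] for e in entries)
        slack = spec.L - total_len - _MIN_GAP * (len(entries) - 1)
        if slack < 0:
            continue
        # distribute the slack as random extra gaps (including the ends)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(entries)))
        extra = np.diff(np.concatenate(([0], cuts)))

        segments: list[SSESegment] = []
        placed: list[tuple[int, int, str, int | None]] = []
        pos = 0
        for idx, ((kind, length, cidx), add) in enumerate(zip(entries, extra)):
            pos += int(add) + (_MIN_GAP if idx > 0 else 0)
            start, end = pos, pos + length
            placed.append((start, end, kind, cidx))
            pos = end
        if pos > spec.L:
            continue

        segments = [
            SSESegment(kind=kind, start=start, end=end, index=i)
            for i, (start, end, kind, _) in enumerate(placed)
        ]

        # pair up contact segments; enforce the diagonal clearance gap
        by_contact: dict[int, list[SSESegment]] = {}
        for seg, (_, _, _, cidx) in zip(segments, placed):
            if cidx is not None:
                by_contact.setdefault(cidx, []).append(seg)
        ok = True
        truth: list[SSEContact] = []
        for c, ctype in enumerate(contact_types):
            a, b = sorted(by_contact[c], key=lambda s: s.start)
            if b.start - a.end < _MIN_CONTACT_GAP:
                ok = False
                break
            region = RectRegion(a.start, a.end, b.start, b.end)
            if region.area > spec.L * spec.L / 4:
                ok = False
                break
            truth.append(SSEContact(a=a, b=b, type=ctype, region=region))
        if ok:
            for x in range(len(truth)):
                for y in range(x + 1, len(truth)):
                    if _collinear_patterns(truth[x], truth[y], spec.dash_period):
                        ok = False
                        break
                if not ok:
                    break
        if not ok:
            continue

        ss_chars = ["C"] * spec.L
        for seg in segments:
            ss_chars[seg.start:seg.end] = seg.kind * seg.length
        ss = SecondaryStructure(id="synthetic", ss="".join(ss_chars))
        return ss, segments, truth

    raise GenerationError(
        f"could not place {spec.n_sse} segments in L={spec.L} "
        f"after {_MAX_ATTEMPTS} attempts"
    )


def plant_cells(contact: SSEContact, dash_period: int = 4) -> frozenset[tuple[int, int]]:
    """Cells of the characteristic pattern for one contact.

    EE_PAR: diagonal line from the rectangle's top-left corner.
    EE_ANTI: anti-diagonal line from the top-right corner.
    HH: anti-diagonal line dashed with the given period (offsets
    t = 0, 1 mod period kept).
    """
    r = contact.region
    if r.height < 2 or r.width < 2:
        raise ValueError(f"region {r} too small to carry a pattern")
    m = min(r.height, r.width)
    if contact.type == "EE_PAR":
        cells = {(r.i0 + t, r.j0 + t) for t in range(m)}
    elif contact.type == "EE_ANTI":
        cells = {(r.i0 + t, r.j1 - 1 - t) for t in range(m)}
    else:  # HH: dashed anti-diagonal
        cells = {
            (r.i0 + t, r.j1 - 1 - t)
            for t in range(m)
            if t % dash_period in (0, 1)
        }
    return frozenset(cells)


def render_map(
    ss: SecondaryStructure,
    truth: list[SSEContact],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    map_id: str = "synthetic",
) -> ContactMap:
    """Render a noisy contact map from planted truth cells.

    Foreground cells draw from a clipped normal; background cells are
    independently nonzero at ``p_bg_rate`` with uniform magnitude;
    optional Gaussian blur is renormalised back into [0, 1].  The upper
    triangle is mirrored to produce a symmetric map.
    """
    L = spec.L
    if len(ss) != L:
        raise ValueError("secondary structure length must equal spec.L")
    upper = np.zeros((L, L))
    iu, ju = np.triu_indices(L, k=1)

    bg_on = rng.random(len(iu)) < spec.p_bg_rate
    upper[iu[bg_on], ju[bg_on]] = rng.uniform(
        spec.p_bg_mag[0], spec.p_bg_mag[1], size=int(bg_on.sum())
    )

    for contact in truth:
        for (i, j) in sorted(contact.cells):
            upper[i, j] = np.clip(rng.normal(spec.p_fg[0], spec.p_fg[1]), 0.0, 1.0)

    if spec.blur_sigma > 0:
        upper = ndimage.gaussian_filter(upper, sigma=spec.blur_sigma)
        hi = upper.max()
        if hi > 0:
            upper = upper / hi

    P = np.triu(upper, k=1)
    P = P + P.T
    return ContactMap(id=map_id, P=P)


def make_sample(spec: SyntheticSpec, rng: np.random.Generator, map_id: str) -> SyntheticSample:
    ss, _, truth = sample_architecture(spec, rng)
    truth = [replace(c, cells=plant_cells(c, spec.dash_period)) for c in truth]
    cmap = render_map(ss, truth, spec, rng, map_id=map_id)
    return SyntheticSample(map=cmap, ss=ss, truth=truth)


def make_dataset(n: int, spec: SyntheticSpec) -> list[SyntheticSample]:
    """Generate ``n`` independent samples, deterministic given ``spec.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n)
    return [
        make_sample(spec, np.random.default_rng(child), map_id=f"syn{i:05d}")
        for i, child in enumerate(children)
    ]
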