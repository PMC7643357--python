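"""Core domain types for inter-SSE contact detection.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open intervals.  A rectangle
region ``(i0, i1, j0, j1)`` covers residue pairs ``(i, j)`` with
``i0 <= i < i1`` and ``j0 <= j < j1``.  Selected detections and ground
truth live in the upper triangle (``i1 <= j0``).  On-disk formats use
1-based inclusive coordinates, the common bioinformatics convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three inter-SSE contact types: helix-helix, parallel strand pair,
#: anti-parallel strand pair.
CONTACT_TYPES = ("HH", "EE_PAR", "EE_ANTI")

SYMMETRY_TOL = 1e-6


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad tokens, unknown labels)."""


class ConfigError(ValueError):
    """Invalid configuration (violated invariant, infeasible setting)."""


class GenerationError(RuntimeError):
    """Synthetic-architecture rejection sampling exhausted its attempts."""


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangle of residue pairs, 0-based half-open."""

    i0: int
    i1: int
    j0: int
    j1: int

    def __post_init__(self) -> None:
        if not (0 <= self.i0 < self.i1 and 0 <= self.j0 < self.j1):
            raise ValueError(f"degenerate region {self!r}")

    @property
    def height(self) -> int:
        return self.i1 - self.i0

    @property
    def width(self) -> int:
        return self.j1 - self.j0

    @property
    def area(self) -> int:
        return self.height * self.width

    def transpose(self) -> "RectRegion":
        return RectRegion(self.j0, self.j1, self.i0, self.i1)

    def is_upper(self) -> bool:
        """True when the region lies strictly above the diagonal (i1 <= j0)."""
        return self.i1 <= self.j0

    def contains(self, i: int, j: int) -> bool:
        return self.i0 <= i < self.i1 and self.j0 <= j < self.j1

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.i0, self.i1, self.j0, self.j1)


@dataclass
class ContactMap:
    """Symmetric L x L matrix of inter-residue contact probabilities.

    The diagonal carries no information and is ignored by every consumer.
    """

    id: str
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError(f"contact map must be square, got {self.P.shape}")
        if not np.allclose(self.P, self.P.T, atol=SYMMETRY_TOL):
            raise ValueError("contact map must be symmetric")
        if self.P.size and (self.P.min() < -SYMMETRY_TOL or self.P.max() > 1 + SYMMETRY_TOL):
            raise ValueError("contact probabilities must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.P.shape[0]


@dataclass
class SecondaryStructure:
    """3-state secondary-structure string over {H, E, C}."""

    id: str
    ss: str

    def __post_init__(self) -> None:
        bad = set(self.ss) - set("HEC")
        if bad:
            raise ValueError(f"invalid 3-state characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ss)


@dataclass
class Detection:
    """A candidate or selected rectangle region with type, score, mask."""

    region: RectRegion
    type: str
    score: float
    mask: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type {self.type!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            expect = (self.region.height, self.region.width)
            if self.mask.shape != expect:
                raise ValueError(
                    f"mask shape {self.mask.shape} != region shape {expect}"
                )


@dataclass(frozen=True)
class SSESegment:
    """A helix (H) or strand (E) run of residues, 0-based half-open."""

    kind: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.kind not in ("H", "E"):
            raise ValueError(f"segment kind must be H or E, got {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("segment interval must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SSEContact:
    """A typed contact between two SSEs with its rectangle and cells.

    ``a`` precedes ``b`` in sequence; ``region`` is the full rectangle
    spanned by the two segments; ``cells`` are the contacting residue
    pairs inside it.
    """

    a: SSESegment
    b: SSESegment
    type: str
    region: RectRegion
    cells: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type {self.type!r}")
        kinds = (self.a.kind, self.b.kind)
        if self.type == "HH" and kinds != ("H", "H"):
            raise ValueError("HH contact requires two helices")
        if self.type.startswith("EE") and kinds != ("E", "E"):
            raise ValueError(f"{self.type} contact requires two strands")
        expect = RectRegion(self.a.start, self.a.end, self.b.start, self.b.end)
        if self.region != expect:
            raise ValueError("region must equal the segment-pair rectangle")
        for (i, j) in self.cells:
            if not self.region.contains(i, j):
                raise ValueError(f"cell {(i, j)} outside region {self.region}")

    def as_detection(self, score: float = 1.0) -> Detection:
        """View this ground-truth contact as a score-`score` Detection."""
        mask = np.zeros((self.region.height, self.region.width), dtype=np.uint8)
        for (i, j) in self.cells:
            mask[i - self.region.i0, j - self.region.j0] = 1
        return Detection(region=self.region, type=self.type, score=score, mask=mask)
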