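"""SSE definition and geometric ground-truth annotation.

Segments a 3-state secondary-structure string into helix/strand
elements and annotates true inter-SSE contacts from a Cb-Cb distance
matrix: a same-kind segment pair is in contact when enough residue
pairs fall under the distance cutoff, and strand pairs are classified
as parallel or anti-parallel from the geometry of their contacting
cells.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass

import numpy as np

from .types import RectRegion, SecondaryStructure, SSEContact, SSESegment


@dataclass
class AnnotationParams:
    """Contact-definition parameters.

    d_contact : Cb-Cb distance cutoff in Angstrom below which a residue
        pair counts as contacting (Ca for glycine).
    n_min_hh / n_min_ee : minimum number of contacting residue pairs for
        a helix-helix / strand-strand contact to be declared.
    min_len_h / min_len_e : minimum helix / strand segment length in
        residues.
    """

    d_contact: float = 8.0
    n_min_hh: int = 2
    n_min_ee: int = 2
    min_len_h: int = 4
    min_len_e: int = 3

    def __post_init__(self) -> None:
        vals = (self.d_contact, self.n_min_hh, self.n_min_ee,
                self.min_len_h, self.min_len_e)
        if any(v <= 0 for v in vals):
            raise ValueError("all annotation parameters must be positive")

    def min_len(self, kind: str) -> int:
        return self.min_len_h if kind == "H" else self.min_len_e

    def n_min(self, kind: str) -> int:
        return self.n_min_hh if kind == "H" else self.n_min_ee


def segment_sse(
    ss: SecondaryStructure | str, params: AnnotationParams | None = None
) -> list[SSESegment]:
    """Extract maximal H and E runs meeting the minimum-length cutoffs.

    Runs separated by even a single coil residue are distinct segments.
    """
    params = params or AnnotationParams()
    s = ss.ss if isinstance(ss, SecondaryStructure) else ss
    segments: list[SSESegment] = []
    for kind, group in itertools.groupby(enumerate(s), key=lambda t: t[1]):
        if kind not in ("H", "E"):
            continue
        positions = [i for i, _ in group]
        start, end = positions[0], positions[-1] + 1
        if end - start >= params.min_len(kind):
            segments.append(SSESegment(kind=kind, start=start, end=end,
                                       index=len(segments)))
    return segments


def orientation_of(
    cells: set[tuple[int, int]] | frozenset[tuple[int, int]],
    region: RectRegion | None = None,
) -> str:
    """Classify a strand-pair cell set as parallel or anti-parallel.

    Parallel strands trace a diagonal line (row and column indices
    increase together), anti-parallel strands an anti-diagonal line.
    The sign of the sample correlation between row and column indices
    decides: positive -> EE_PAR, negative -> EE_ANTI.  A degenerate
    (zero/undefined) correlation is broken to EE_ANTI with a warning,
    anti-parallel pairing being the more frequent class.
    """
    if len(cells) < 2:
        raise ValueError("orientation needs at least 2 cells")
    arr = np.asarray(sorted(cells), dtype=float)
    rows, cols = arr[:, 0], arr[:, 1]
    sr, sc = rows.std(), cols.std()
    corr = 0.0
    if sr > 0 and sc > 0:
        corr = float(np.corrcoef(rows, cols)[0, 1])
    if corr > 0:
        return "EE_PAR"
    if corr < 0:
        return "EE_ANTI"
    warnings.warn(
        "degenerate cell geometry: orientation tie broken to EE_ANTI",
        stacklevel=2,
    )
    return "EE_ANTI"


def annotate_contacts(
    segments: list[SSESegment],
    cb_dist: np.ndarray,
    params: AnnotationParams | None = None,
) -> list[SSEContact]:
    """Annotate true inter-SSE contacts from a Cb-Cb distance matrix.

    For every same-kind segment pair (a before b), the contacting cells
    are the residue pairs closer than ``d_contact``; a contact is
    declared when at least ``n_min`` cells exist.  Strand pairs are
    oriented via :func:`orientation_of`.  Mixed helix-strand pairs are
    not annotated.
    """
    params = params or AnnotationParams()
    cb_dist = np.asarray(cb_dist, dtype=float)
    if cb_dist.ndim != 2 or cb_dist.shape[0] != cb_dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {cb_dist.shape}")
    L = cb_dist.shape[0]
    if segments and max(seg.end for seg in segments) > L:
        raise ValueError(
            "distance matrix dimension does not cover the segmented sequence"
        )

    ordered = sorted(segments, key=lambda s: s.start)
    contacts: list[SSEContact] = []
    for a, b in itertools.combinations(ordered, 2):
        if a.kind != b.kind:
            continue
        sub = cb_dist[a.start:a.end, b.start:b.end]
        ii, jj = np.nonzero(sub < params.d_contact)
        if len(ii) < params.n_min(a.kind):
            continue
        cells = frozenset(
            (int(i) + a.start, int(j) + b.start) for i, j in zip(ii, jj)
        )
        region = RectRegion(a.start, a.end, b.start, b.end)
        if a.kind == "H":
            ctype = "HH"
        else:
            ctype = orientation_of(set(cells), region)
        contacts.append(SSEContact(a=a, b=b, type=ctype, region=region, cells=cells))
    return contacts


def cb_distances_from_pdb(
    path: str | os.PathLike, chain: str
) -> tuple[SecondaryStructure | None, np.ndarray]:
    """Cb-Cb distance matrix (and, when DSSP is runnable, the SS string).

    Cb is replaced by Ca for glycine and for residues missing a Cb;
    residues with no usable coordinate get +inf rows/columns so they can
    never form a contact cell.  Secondary structure is computed through
    DSSP when the executable is available, otherwise ``None`` is
    returned in its place.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise KeyError(f"chain {chain!r} not present in {path}")
    residues = [r for r in model[chain] if r.id[0] == " "]
    L = len(residues)
    coords = np.full((L, 3), np.nan)
    for k, res in enumerate(residues):
        atom = None
        if res.get_resname() != "GLY" and "CB" in res:
            atom = res["CB"]
        elif "CA" in res:
            atom = res["CA"]
        if atom is not None:
            coords[k] = atom.coord
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    missing = np.isnan(coords).any(axis=1)
    dist[missing, :] = np.inf
    dist[:, missing] = np.inf
    np.fill_diagonal(dist, 0.0)

    ss = None
    try:
        from Bio.PDB.DSSP import DSSP

        dssp = DSSP(model, str(path))
        codes = "".join(dssp[key][2] for key in dssp.keys())
        from .io import parse_ss

        ss = parse_ss(codes, dialect="dssp8")
    except Exception:
        ss = None  # DSSP executable unavailable or failed; distances still valid
    return ss, dist
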