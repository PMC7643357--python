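"""Readers and writers for the standard formats the pipeline touches.

Supported formats: CCMpred-style whitespace-separated L x L score
matrices, CASP RR contact records, detections TSV (1-based inclusive
coordinates on disk), and secondary-structure strings in plain 3-state
or DSSP 8-state alphabets.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .types import ContactMap, Detection, FormatError, RectRegion, SecondaryStructure

# DSSP 8-state -> 3-state reduction: helices (H/G/I) -> H, strands and
# bridges (E/B) -> E, everything else (turn/bend/coil/blank) -> C.
_DSSP8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", ".": "C",
}


def _symmetrize_and_scale(M: np.ndarray) -> np.ndarray:
    """Average with the transpose, then bring values into [0, 1].

    Scores already in [0, 1] are only clamped against round-off; raw
    coupling scores outside that range (e.g. unnormalised CCMpred
    output) are min-max rescaled, since downstream stages expect
    probabilities.
    """
    M = (M + M.T) / 2.0
    lo, hi = float(M.min(initial=0.0)), float(M.max(initial=0.0))
    if lo < 0.0 or hi > 1.0:
        span = hi - lo
        M = (M - lo) / span if span > 0 else np.zeros_like(M)
    return np.clip(M, 0.0, 1.0)


def read_ccmpred_matrix(path: str | os.PathLike) -> ContactMap:
    """Read a whitespace-separated L x L score matrix (CCMpred layout).

    The matrix is symmetrized by averaging with its transpose and
    clamped/rescaled into [0, 1].
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token ({exc})") from exc
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"{path}:{lineno}: ragged row (got {len(row)} values, "
                    f"expected {len(rows[0])})"
                )
            rows.append(row)
    M = np.asarray(rows, dtype=float)
    if M.size == 0:
        raise FormatError(f"{path}: empty matrix")
    if M.shape[0] != M.shape[1]:
        raise FormatError(f"{path}: matrix is {M.shape[0]}x{M.shape[1]}, not square")
    return ContactMap(id=path.stem, P=_symmetrize_and_scale(M))


def write_ccmpred_matrix(cmap: ContactMap | np.ndarray, path: str | os.PathLike) -> None:
    """Write a matrix in CCMpred layout (one whitespace-separated row per line)."""
    M = cmap.P if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    np.savetxt(path, M, fmt="%.6f")


def read_casp_rr(path: str | os.PathLike, L: int) -> ContactMap:
    """Read sparse CASP RR contact records into a dense symmetric map.

    RR body lines are ``i j d1 d2 p`` with 1-based residue indices.
    Header/sequence/keyword lines are skipped.  Unlisted pairs get
    probability 0.
    """
    path = Path(path)
    if L <= 0:
        raise ValueError("L must be positive")
    P = np.zeros((L, L), dtype=float)
    keywords = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(keywords):
                continue
            toks = line.split()
            if len(toks) < 5:
                # sequence continuation line in some RR dialects
                if all(c.isalpha() for tok in toks for c in tok):
                    continue
                raise FormatError(f"{path}:{lineno}: expected 'i j d1 d2 p'")
            try:
                i, j = int(toks[0]), int(toks[1])
                p = float(toks[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad record ({exc})") from exc
            if not (1 <= i <= L and 1 <= j <= L):
                raise FormatError(
                    f"{path}:{lineno}: residue index outside [1, {L}]"
                )
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{path}:{lineno}: probability {p} outside [0, 1]")
            P[i - 1, j - 1] = p
            P[j - 1, i - 1] = p
    return ContactMap(id=path.stem, P=P)


def _rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a binary mask as 'HxW:n0,n1,...' (runs start at 0)."""
    h, w = mask.shape
    flat = np.asarray(mask, dtype=np.uint8).ravel()
    runs: list[int] = []
    cur, count = 0, 0
    for v in flat:
        if v == cur:
            count += 1
        else:
            runs.append(count)
            cur, count = v, 1
    runs.append(count)
    return f"{h}x{w}:" + ",".join(map(str, runs))


def _rle_decode(text: str) -> np.ndarray:
    shape_part, runs_part = text.split(":")
    h, w = (int(t) for t in shape_part.split("x"))
    runs = [int(t) for t in runs_part.split(",")] if runs_part else []
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, val = 0, 0
    for run in runs:
        if val:
            flat[pos:pos + run] = 1
        pos += run
        val ^= 1
    if pos != h * w:
        raise FormatError(f"run-length mask covers {pos} cells, expected {h * w}")
    return flat.reshape(h, w)


_TSV_HEADER = "id\ttype\ti_start\ti_end\tj_start\tj_end\tscore\tmask"


def write_detections_tsv(detections: list[Detection], path: str | os.PathLike) -> None:
    """Write detections as TSV with 1-based inclusive coordinates."""
    with Path(path).open("w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for det in detections:
            r = det.region
            mask = _rle_encode(det.mask) if det.mask is not None else "."
            fh.write(
                f"{det.id or '.'}\t{det.type}\t{r.i0 + 1}\t{r.i1}\t"
                f"{r.j0 + 1}\t{r.j1}\t{det.score:.4f}\t{mask}\n"
            )


def read_detections_tsv(path: str | os.PathLike) -> list[Detection]:
    """Read detections TSV written by :func:`write_detections_tsv`."""
    path = Path(path)
    out: list[Detection] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("id\t") or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 7:
                raise FormatError(f"{path}:{lineno}: expected >= 7 columns")
            ident, typ = toks[0], toks[1]
            if typ not in ("HH", "EE_PAR", "EE_ANTI"):
                raise FormatError(f"{path}:{lineno}: unknown contact type {typ!r}")
            try:
                i_start, i_end, j_start, j_end = (int(t) for t in toks[2:6])
                score = float(toks[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad record ({exc})") from exc
            mask = None
            if len(toks) > 7 and toks[7] not in (".", ""):
                mask = _rle_decode(toks[7])
            region = RectRegion(i_start - 1, i_end, j_start - 1, j_end)
            out.append(
                Detection(
                    region=region,
                    type=typ,
                    score=score,
                    mask=mask,
                    id="" if ident == "." else ident,
                )
            )
    return out


def parse_ss(path_or_string: str | os.PathLike, dialect: str = "plain3") -> SecondaryStructure:
    """Parse a secondary-structure string.

    Parameters
    ----------
    path_or_string:
        Either a path to a single-record FASTA-like file or the raw
        string itself.
    dialect:
        ``plain3`` for {H, E, C} strings; ``dssp8`` for DSSP 8-state
        codes, reduced as H/G/I -> H, E/B -> E, else -> C.
    """
    if dialect not in ("plain3", "dssp8"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = str(path_or_string)
    ident = "ss"
    looks_like_path = ("\n" not in text) and (
        os.path.exists(text) or text.endswith((".fasta", ".fa", ".ss", ".txt"))
    )
    if looks_like_path:
        raw_lines = Path(text).read_text().splitlines()
        body: list[str] = []
        for line in raw_lines:
            if line.startswith(">"):
                ident = line[1:].strip() or ident
                continue
            body.append(line.strip())
        seq = "".join(body)
    else:
        seq = "".join(text.split())

    if dialect == "plain3":
        bad = set(seq) - set("HEC")
        if bad:
            raise FormatError(f"invalid 3-state characters: {sorted(bad)}")
        return SecondaryStructure(id=ident, ss=seq)

    try:
        reduced = "".join(_DSSP8_TO_3[c] for c in seq)
    except KeyError as exc:
        raise FormatError(f"invalid DSSP 8-state character {exc.args[0]!r}") from exc
    return SecondaryStructure(id=ident, ss=reduced)
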