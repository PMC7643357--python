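"""SSE segmentation and geometric contact annotation."""

import numpy as np
import pytest

import ssedetect as sd
from ssedetect.annotation import AnnotationParams, cb_distances_from_pdb


def brute_force_contacts(segments, cb_dist, params):
    """Independent oracle: direct pair enumeration per the contact rules."""
    out = []
    segs = sorted(segments, key=lambda s: s.start)
    for x in range(len(segs)):
        for y in range(x + 1, len(segs)):
            a, b = segs[x], segs[y]
            if a.kind != b.kind:
                continue
            cells = {
                (i, j)
                for i in range(a.start, a.end)
                for j in range(b.start, b.end)
                if cb_dist[i, j] < params.d_contact
            }
            n_min = params.n_min_hh if a.kind == "H" else params.n_min_ee
            if len(cells) >= n_min:
                out.append((a.start, a.end, b.start, b.end, frozenset(cells)))
    return out


class TestSegmentSSE:
    @pytest.mark.parametrize(
        "ss,expected",
        [
            ("CCHHHHHCCEEEC", [("H", 2, 7), ("E", 9, 12)]),
            ("HHH", []),
            ("", []),
            ("HHHHCEEEEECHHHH", [("H", 0, 4), ("E", 5, 10), ("H", 11, 15)]),
        ],
    )
    def test_maximal_runs_with_minimum_lengths(self, ss, expected):
        params = AnnotationParams(min_len_h=4, min_len_e=3)
        segs = sd.segment_sse(ss, params)
        assert [(s.kind, s.start, s.end) for s in segs] == expected

    def test_single_coil_breaks_a_run(self):
        segs = sd.segment_sse("HHHHCHHHH", AnnotationParams(min_len_h=4))
        assert [(s.start, s.end) for s in segs] == [(0, 4), (5, 9)]


class TestOrientation:
    def test_increasing_cells_are_parallel(self):
        assert sd.orientation_of({(0, 10), (1, 11), (2, 12)}) == "EE_PAR"

    def test_decreasing_cells_are_antiparallel(self):
        assert sd.orientation_of({(0, 12), (1, 11), (2, 10)}) == "EE_ANTI"

    def test_degenerate_geometry_ties_to_antiparallel_with_warning(self):
        with pytest.warns(UserWarning):
            assert sd.orientation_of({(0, 10), (0, 11)}) == "EE_ANTI"


class TestAnnotateContacts:
    def _dist(self, L, close_cells):
        d = np.full((L, L), 20.0)
        np.fill_diagonal(d, 0.0)
        for (i, j) in close_cells:
            d[i, j] = d[j, i] = 5.0
        return d

    def test_distant_helices_make_no_contact(self):
        ss = "HHHHHCCCCCHHHHH"
        segs = sd.segment_sse(ss)
        contacts = sd.annotate_contacts(segs, self._dist(15, []))
        assert contacts == []

    def test_parallel_strand_pair_from_crafted_distances(self):
        ss = "EEEE" + "C" * 6 + "EEEE" + "CC"
        segs = sd.segment_sse(ss)
        cells = {(0, 10), (1, 11), (2, 12), (3, 13)}
        contacts = sd.annotate_contacts(segs, self._dist(16, cells))
        assert len(contacts) == 1
        c = contacts[0]
        assert c.type == "EE_PAR"
        assert c.cells == frozenset(cells)
        assert c.region.as_tuple() == (0, 4, 10, 14)
        # agrees with the brute-force oracle
        oracle = brute_force_contacts(segs, self._dist(16, cells), AnnotationParams())
        assert oracle == [(0, 4, 10, 14, frozenset(cells))]

    def test_mirrored_geometry_is_antiparallel(self):
        ss = "EEEE" + "C" * 6 + "EEEE" + "CC"
        segs = sd.segment_sse(ss)
        cells = {(0, 13), (1, 12), (2, 11), (3, 10)}
        contacts = sd.annotate_contacts(segs, self._dist(16, cells))
        assert [c.type for c in contacts] == ["EE_ANTI"]

    def test_mixed_kind_pairs_are_ignored(self):
        ss = "HHHH" + "C" * 6 + "EEEE"
        segs = sd.segment_sse(ss)
        cells = {(0, 10), (1, 11), (2, 12)}
        assert sd.annotate_contacts(segs, self._dist(14, cells)) == []

    def test_dimension_mismatch_raises(self):
        segs = sd.segment_sse("C" * 10 + "HHHH" + "C" * 6 + "HHHH")
        with pytest.raises(ValueError):
            sd.annotate_contacts(segs, np.zeros((10, 10)))

    def test_transpose_symmetry_and_oracle_agreement_on_random_geometries(self):
        rng = np.random.default_rng(5)
        params = AnnotationParams()
        for _ in range(25):
            L = 40
            ss = ["C"] * L
            pos = 0
            while pos + 6 < L:
                kind = "H" if rng.random() < 0.5 else "E"
                n = int(rng.integers(3, 7))
                ss[pos:pos + n] = kind * n
                pos += n + int(rng.integers(2, 5))
            segs = sd.segment_sse("".join(ss), params)
            d = np.full((L, L), 20.0)
            hits = rng.random((L, L)) < 0.08
            d[hits] = 4.0
            d = np.minimum(d, d.T)
            np.fill_diagonal(d, 0.0)
            contacts = sd.annotate_contacts(segs, d, params)
            again = sd.annotate_contacts(list(reversed(segs)), d.T.copy(), params)
            key = lambda cs: sorted((c.region.as_tuple(), c.type) for c in cs)
            assert key(contacts) == key(again)
            for c in contacts:
                kinds = (c.a.kind, c.b.kind)
                assert (c.type == "HH") == (kinds == ("H", "H"))
                assert c.type.startswith("EE") == (kinds == ("E", "E"))
            oracle = brute_force_contacts(segs, d, params)
            assert sorted(o[:4] for o in oracle) == sorted(
                c.region.as_tuple() for c in contacts
            )

    def test_orientation_recovers_planted_strand_geometry(self):
        # ideal parallel / anti-parallel pairings constructed directly
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            j0 = int(rng.integers(15, 30))
            par = {(i, j0 + i) for i in range(n)}
            anti = {(i, j0 + n - 1 - i) for i in range(n)}
            assert sd.orientation_of(par) == "EE_PAR"
            assert sd.orientation_of(anti) == "EE_ANTI"


_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   1.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.000   4.000   1.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      6  N   SER A   3       9.000   9.000   9.000  1.00  0.00           N
END
"""


class TestCbDistancesFromPdb:
    def test_cb_geometry_glycine_and_missing_residues(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(_PDB)
        _ss, d = cb_distances_from_pdb(p, "A")
        assert d.shape == (3, 3)
        # ALA CB at origin, GLY falls back to CA at (3,4,0): a 3-4-5 triangle
        assert d[0, 1] == pytest.approx(5.0)
        # SER has no CA/CB: never a contact
        assert np.isinf(d[0, 2]) and np.isinf(d[2, 1])

    def test_absent_chain_raises(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(_PDB)
        with pytest.raises(KeyError):
            cb_distances_from_pdb(p, "B")
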