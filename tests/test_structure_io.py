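"""Parsing, selection filters, renumbering and sequence identity."""

import numpy as np
import pytest

from fabcompare import (
    check_resolution,
    extract_chain,
    parse_structure,
    sequence_identity,
    write_chain_pdb,
)
from fabcompare.errors import DiscontinuityError, MissingChainError, ParseError
from fabcompare.structure_io import chain_to_pdb

from conftest import make_pdb_text, pdb_atom_line, straight_backbone
from oracles import enumerate_alignment_identity


class TestParse:
    def test_minimal_three_residue_structure(self):
        residues = [
            ("ALA", 1, " ", atoms) for atoms in straight_backbone(1)
        ] + [
            ("GLY", 2, " ", straight_backbone(2)[1]),
            ("SER", 3, " ", straight_backbone(3)[2]),
        ]
        rec = parse_structure(make_pdb_text(residues), entry_id="MINI")
        assert list(rec.chains) == ["A"]
        chain = rec.chains["A"]
        assert len(chain) == 3
        assert [r.aa for r in chain] == ["A", "G", "S"]
        np.testing.assert_allclose(chain[1].backbone_coords["CA"], [3.8, 0, 0])

    def test_no_atom_records_raises(self):
        with pytest.raises(ParseError):
            parse_structure("REMARK nothing here\nEND\n", entry_id="EMPT")

    def test_altloc_keeps_highest_occupancy(self):
        bb = straight_backbone(1)[0]
        lines = [
            pdb_atom_line(1, "N", "ALA", "A", 1, bb["N"]),
            pdb_atom_line(2, "CA", "ALA", "A", 1, (1.0, 0, 0), occ=0.6,
                          altloc="A"),
            pdb_atom_line(3, "CA", "ALA", "A", 1, (9.0, 0, 0), occ=0.4,
                          altloc="B"),
            pdb_atom_line(4, "C", "ALA", "A", 1, bb["C"]),
            "END",
        ]
        rec = parse_structure("\n".join(lines), entry_id="ALTL")
        ca = rec.chains["A"][0].backbone_coords["CA"]
        np.testing.assert_allclose(ca, [1.0, 0, 0])

    def test_altloc_tie_prefers_first_altloc(self):
        bb = straight_backbone(1)[0]
        lines = [
            pdb_atom_line(1, "N", "ALA", "A", 1, bb["N"]),
            pdb_atom_line(2, "CA", "ALA", "A", 1, (9.0, 0, 0), occ=0.5,
                          altloc="B"),
            pdb_atom_line(3, "CA", "ALA", "A", 1, (1.0, 0, 0), occ=0.5,
                          altloc="A"),
            pdb_atom_line(4, "C", "ALA", "A", 1, bb["C"]),
            "END",
        ]
        rec = parse_structure("\n".join(lines), entry_id="TIE")
        np.testing.assert_allclose(rec.chains["A"][0].backbone_coords["CA"],
                                   [1.0, 0, 0])

    def test_resolution_read_from_header(self):
        residues = [("ALA", i + 1, " ", a)
                    for i, a in enumerate(straight_backbone(3))]
        rec = parse_structure(make_pdb_text(residues, header_resolution=2.20))
        assert rec.resolution == pytest.approx(2.20)

    def test_waters_and_hetero_dropped(self):
        residues = [("ALA", i + 1, " ", a)
                    for i, a in enumerate(straight_backbone(3))]
        text = make_pdb_text(residues)
        text = text.replace(
            "END",
            "HETATM   99  O   HOH A 501      40.000   0.000   0.000"
            "  1.00  0.00           O\nEND",
        )
        rec = parse_structure(text)
        assert len(rec.chains["A"]) == 3


class TestResolutionFilter:
    @pytest.mark.parametrize(
        "resolution, passed, warning",
        [(2.2, True, False), (3.5, False, False), (None, True, True)],
    )
    def test_threshold_verdicts(self, resolution, passed, warning):
        residues = [("ALA", i + 1, " ", a)
                    for i, a in enumerate(straight_backbone(3))]
        rec = parse_structure(
            make_pdb_text(residues, header_resolution=resolution))
        verdict = check_resolution(rec)
        assert verdict.passed is passed
        assert verdict.warning is warning
        if resolution is not None:
            assert verdict.resolution == pytest.approx(resolution)


class TestExtractChain:
    def _record(self, n=10, skip=None, icodes=None):
        residues = []
        bbs = straight_backbone(n)
        for i, atoms in enumerate(bbs):
            if skip and (i + 1) in skip:
                continue
            if icodes:
                resseq, icode = icodes[i]
            else:
                resseq, icode = i + 1, " "
            residues.append(("ALA", resseq, icode, atoms))
        return parse_structure(make_pdb_text(residues), entry_id="SYN0")

    def test_renumbers_sequentially(self):
        chain = extract_chain(self._record(), "A", "heavy")
        assert [r.seq_index for r in chain.residues] == list(range(1, 11))
        assert chain.sequence == "A" * 10

    def test_insertion_codes_become_sequential(self):
        icodes = [(100, " "), (100, "A"), (101, " ")]
        chain = extract_chain(self._record(n=3, icodes=icodes), "A", "heavy")
        assert [r.seq_index for r in chain.residues] == [1, 2, 3]
        assert [r.author_number for r in chain.residues] == ["100", "100A", "101"]

    def test_gap_raises_discontinuity(self):
        with pytest.raises(DiscontinuityError):
            extract_chain(self._record(skip={5}), "A", "heavy")

    def test_missing_chain(self):
        with pytest.raises(MissingChainError):
            extract_chain(self._record(), "B", "heavy")

    def test_window_selects_copy_before_renumbering(self):
        chain = extract_chain(self._record(), "A", "heavy", span=(3, 7))
        assert len(chain) == 5
        assert chain.residues[0].author_number == "3"
        assert chain.residues[0].seq_index == 1

    def test_synthetic_chains_are_continuous(self, couple_b1):
        # generator output re-serialised must pass the continuity filter
        text = chain_to_pdb([couple_b1.bound_heavy, couple_b1.bound_light])
        rec = parse_structure(text, entry_id="SYNB")
        for cid in ("H", "L"):
            chain = extract_chain(rec, cid, "heavy")
            assert len(chain) == 218


class TestSequenceIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY", 1.0),
            ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWA", 0.95),
            ("ACDEF", "ACEF", 0.8),
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert sequence_identity(a, b) == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        alphabet = "ACDG"
        for _ in range(30):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            assert sequence_identity(a, b) == pytest.approx(
                enumerate_alignment_identity(a, b)
            ), (a, b)

    def test_symmetry(self):
        assert sequence_identity("ACDEF", "ACEF") == sequence_identity(
            "ACEF", "ACDEF")


class TestRoundTrip:
    def test_write_parse_preserves_chain(self, tmp_path, couple_b2):
        chain = couple_b2.free_heavy
        path = tmp_path / "prep.pdb"
        write_chain_pdb([chain], path, entry_id="RT01", resolution=1.9)
        rec = parse_structure(path.read_text(), entry_id="RT01")
        assert rec.resolution == pytest.approx(1.9)
        back = extract_chain(rec, "H", "heavy")
        assert back.sequence == chain.sequence
        assert len(back) == len(chain)
        for orig, rt in zip(chain.residues, back.residues):
            for name, xyz in orig.backbone_coords.items():
                np.testing.assert_allclose(
                    rt.backbone_coords[name], xyz, atol=1.5e-3)
            if orig.sidechain_anchor is not None:
                np.testing.assert_allclose(
                    rt.sidechain_anchor, orig.sidechain_anchor, atol=1.5e-3)
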