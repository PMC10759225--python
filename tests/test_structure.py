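"""PDB parsing, geometric H-bond detection, per-residue structural properties."""

import itertools

import numpy as np
import pytest

import tcrbind as tb
from tcrbind.structure import (ComplexAnnotation, cdr3_span_heuristic,
                               detect_hbonds, read_complex,
                               residue_properties, map_calls_to_structure)
from tcrbind.synthetic import write_toy_pdb

AA3 = {"A": "ALA", "C": "CYS", "S": "SER", "V": "VAL", "G": "GLY",
       "L": "LEU", "F": "PHE", "I": "ILE", "T": "THR", "N": "ASN"}


def grid_atoms(chain, seqs, origin, spacing=10.0, with_no=False):
    """One CA per residue on a 1-D grid; optional backbone N and O atoms."""
    atoms = []
    for i, aa in enumerate(seqs, start=1):
        base = np.array(origin) + np.array([spacing * i, 0.0, 0.0])
        atoms.append((chain, i, AA3[aa], "CA", "C", base))
        if with_no:
            atoms.append((chain, i, AA3[aa], "N", "N", base + [0.5, 0.5, 0.0]))
            atoms.append((chain, i, AA3[aa], "O", "O", base + [-0.5, -0.5, 0.0]))
    return atoms


def toy_annotation():
    return ComplexAnnotation("TOY1", "A", "B", "C", 2, 4, 2, 5)


def build_toy(tmp_path, extra=(), with_no=False):
    """Chains A (CAVG), B (CASSL), C (GIL peptide), spans A2-4 / B2-5."""
    atoms = (grid_atoms("A", "CAVG", (0, 0, 0), with_no=with_no)
             + grid_atoms("B", "CASSL", (0, 50, 0), with_no=with_no)
             + grid_atoms("C", "GIL", (0, 100, 0), with_no=with_no)
             + list(extra))
    path = tmp_path / "toy.pdb"
    write_toy_pdb(atoms, path)
    return read_complex(path, toy_annotation())


class TestReadComplex:
    def test_round_trips_coordinates(self, tmp_path):
        model = build_toy(tmp_path)
        res = model.residue("A", 3)
        assert res.aa == "V"
        name, el, xyz = res.atoms[0]
        assert name == "CA" and np.allclose(xyz, [30.0, 0.0, 0.0], atol=1e-3)

    def test_missing_chain_errors(self, tmp_path):
        path = tmp_path / "toy.pdb"
        write_toy_pdb(grid_atoms("A", "CAVG", (0, 0, 0)), path)
        with pytest.raises(ValueError, match="chain 'B'"):
            read_complex(path, toy_annotation())

    def test_empty_file_is_valid(self, tmp_path):
        path = tmp_path / "empty.pdb"
        write_toy_pdb([], path)
        assert path.read_text().strip() == "END"


class TestDetectHbonds:
    def test_planted_n_o_pair(self, tmp_path):
        extra = [("C", 2, "GLY", "OD1", "O", np.array([20.0, 0.0, 2.9]))]
        # pairs residue A2's N-ish? place an N near it instead:
        extra = [("A", 2, "ALA", "ND1", "N", np.array([500.0, 0, 0])),
                 ("C", 2, "ILE", "OD1", "O", np.array([500.0, 0, 2.9]))]
        model = build_toy(tmp_path, extra=extra)
        bonds = detect_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-6)
        assert bonds[0].donor[2] == "ND1"      # nitrogen taken as donor

    def test_cutoff_excludes_3p6(self, tmp_path):
        extra = [("A", 2, "ALA", "ND1", "N", np.array([500.0, 0, 0])),
                 ("C", 2, "ILE", "OD1", "O", np.array([500.0, 0, 3.6]))]
        assert detect_hbonds(build_toy(tmp_path, extra=extra)) == []

    def test_carbon_pairs_never_bond(self, tmp_path):
        extra = [("A", 2, "ALA", "CB", "C", np.array([500.0, 0, 0])),
                 ("C", 2, "ILE", "CG", "C", np.array([500.0, 0, 2.9]))]
        assert detect_hbonds(build_toy(tmp_path, extra=extra)) == []

    def test_backbone_peptide_bond_neighbors_excluded(self, tmp_path):
        # adjacent residues of one chain with N/O at peptide-bond distance
        extra = [("A", 2, "ALA", "O", "O", np.array([600.0, 0, 0])),
                 ("A", 3, "VAL", "N", "N", np.array([600.0, 0, 2.3]))]
        bonds = detect_hbonds(build_toy(tmp_path, extra=extra))
        assert all({b.donor[:2], b.acceptor[:2]} != {("A", 2), ("A", 3)}
                   for b in bonds)

    def test_matches_all_pairs_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        extra = []
        for i in range(12):
            chain = "ABC"[i % 3]
            seq = {"A": 4, "B": 5, "C": 3}[chain]
            extra.append((chain, int(rng.integers(1, seq + 1)), "ALA",
                          f"X{i}", rng.choice(["N", "O", "S"]),
                          np.array([400.0, 0, 0]) + rng.normal(0, 2.5, 3)))
        model = build_toy(tmp_path, extra=extra)
        bonds = detect_hbonds(model)
        # independent oracle: enumerate every atom pair from the parsed model
        atoms = [(c, r.seqid, n, e, xyz) for c, residues in model.chains.items()
                 for r in residues for n, e, xyz in r.atoms]
        expected = set()
        for a1, a2 in itertools.combinations(atoms, 2):
            if a1[3] not in "NOS" or a2[3] not in "NOS":
                continue
            if (a1[0], a1[1]) == (a2[0], a2[1]):
                continue
            if a1[0] == a2[0] and abs(a1[1] - a2[1]) == 1 and \
                    {a1[2], a2[2]} <= {"N", "O"}:
                continue
            if np.linalg.norm(a1[4] - a2[4]) <= 3.5:
                expected.add(frozenset([(a1[0], a1[1], a1[2]),
                                        (a2[0], a2[1], a2[2])]))
        got = {frozenset([b.donor, b.acceptor]) for b in bonds}
        assert got == expected

    def test_residue_pair_symmetry(self, tmp_path):
        extra = [("A", 2, "ALA", "ND1", "N", np.array([500.0, 0, 0])),
                 ("C", 2, "ILE", "OD1", "O", np.array([500.0, 0, 2.9]))]
        bonds = detect_hbonds(build_toy(tmp_path, extra=extra))
        pairs = {frozenset(b.residues()) for b in bonds}
        assert frozenset([("A", 2), ("C", 2)]) in pairs


class TestResidueProperties:
    def test_edge_positions_cdr3_len15(self):
        from tcrbind.structure import _edge_positions
        assert _edge_positions(15, 4) == {1, 2, 3, 4, 12, 13, 14, 15}

    def test_edge_positions_peptide_len9(self):
        from tcrbind.structure import _edge_positions
        assert _edge_positions(9, 3) == {1, 2, 3, 7, 8, 9}

    def test_planted_bond_sets_flags_and_counts(self, tmp_path):
        # bond between CDR3a residue A3 and peptide residue C2
        extra = [("A", 3, "VAL", "ND1", "N", np.array([500.0, 0, 0])),
                 ("C", 2, "ILE", "OD1", "O", np.array([500.0, 0, 2.9]))]
        model = build_toy(tmp_path, extra=extra)
        bonds = detect_hbonds(model)
        props = residue_properties(model, toy_annotation(), bonds)
        a3 = props[(props.chain == "A") & (props.seqid == 3)].iloc[0]
        assert a3["hb_peptide"] and a3["n_hbonds"] == 1
        assert a3["n_hbonds_peptide"] == 1 and a3["n_hbonds_self_cdr3"] == 0
        assert not a3["hb_cdr3"] and not a3["hb_tcr"]
        c2 = props[(props.chain == "C") & (props.seqid == 2)].iloc[0]
        assert c2["hb_cdr3"] and c2["hb_tcr"] and not c2["hb_noncdr3_tcr"]

    def test_derived_boolean_consistency(self, tmp_path):
        rng = np.random.default_rng(1)
        extra = []
        for i in range(10):
            chain = "AB"[i % 2]
            seq = {"A": 4, "B": 5}[chain]
            extra.append((chain, int(rng.integers(1, seq + 1)), "ALA",
                          f"Y{i}", "N" if i % 2 else "O",
                          np.array([700.0, 0, 0]) + rng.normal(0, 2.0, 3)))
        model = build_toy(tmp_path, extra=extra)
        props = residue_properties(model, toy_annotation(),
                                   detect_hbonds(model))
        tcr = props[props.role.isin(["cdr3a", "cdr3b"])]
        assert (tcr.hb_tcr == (tcr.hb_cdr3 | tcr.hb_noncdr3_tcr)).all()
        assert (tcr.hb_cdr3 == (tcr.hb_cdr3_own | tcr.hb_cdr3_opp)).all()
        assert (props.closest_distance.dropna() >= 0).all()

    def test_row_counts_match_spans(self, tmp_path):
        props = residue_properties(build_toy(tmp_path), toy_annotation(), [])
        assert (props.role == "cdr3a").sum() == 3   # span 2-4
        assert (props.role == "cdr3b").sum() == 4   # span 2-5
        assert (props.role == "peptide").sum() == 3


class TestMapCalls:
    def test_positions_map_and_colon_skipped(self, tmp_path):
        model = build_toy(tmp_path)
        rec = tb.InteractionRecord("AVG", "ASSL", "GIL", 1)
        ann = ComplexAnnotation("TOY1", "A", "B", "C", 2, 4, 2, 5)
        # TCR axis: A V G : A S S L  (colon at position 4)
        out = map_calls_to_structure([1, 4, 5], rec, ann, model)
        assert out == [("A", 2, "A"), ("B", 2, "A")]

    def test_sequence_mismatch_errors(self, tmp_path):
        model = build_toy(tmp_path)
        rec = tb.InteractionRecord("AVV", "ASSL", "GIL", 1)
        with pytest.raises(ValueError, match="mismatch"):
            map_calls_to_structure([1], rec, toy_annotation(), model)


def test_cdr3_span_heuristic(tmp_path):
    model = build_toy(tmp_path)
    span = cdr3_span_heuristic(model.chains["B"])
    assert span is None or span[0] < span[1]
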