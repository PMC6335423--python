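"""Structure parsing, distance queries, and interface detection vs brute force."""

import math

import numpy as np
import pytest

from pparpipe.simulate import make_toy_heterodimer, write_pdb
from pparpipe.structure import (
    Atom,
    FormatError,
    LookupErrorStruct,
    Residue,
    StructureModel,
    contact_partners,
    interface_residues,
    map_mutations_to_structure,
    read_structure,
    residue_min_distance,
)
from pparpipe.variants import IsoformMap, parse_protein_change


def brute_min_distance(res_a, res_b):
    """All-pairs heavy-atom minimum distance, pure python."""
    best = math.inf
    for a in res_a.atoms:
        for b in res_b.atoms:
            d = math.dist(a.coord, b.coord)
            best = min(best, d)
    return best


def _atom_line(serial, name, resname, chain, resseq, x, y, z, record="ATOM",
               element=None):
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for chain, x0 in (("A", 0.0), ("B", 8.0)):
        for i in range(3):
            lines.append(_atom_line(serial, "CA", "GLY", chain, i + 1,
                                    x0, 0.0, 1.5 * i))
            serial += 1
    lines.append("END")
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadStructure:
    def test_two_chains_six_residues(self, two_chain_pdb):
        model = read_structure(two_chain_pdb)
        assert sorted(model.chains) == ["A", "B"]
        assert len(model.chains["A"]) == 3
        assert len(model.chains["B"]) == 3

    def test_multi_model_selection(self, tmp_path):
        lines = ["MODEL     1",
                 _atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
                 "ENDMDL",
                 "MODEL     2",
                 _atom_line(1, "CA", "GLY", "A", 1, 9.0, 0.0, 0.0),
                 "ENDMDL", "END"]
        path = tmp_path / "nmr.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path, model_index=1)
        assert model.chains["A"][0].atoms[0].coord[0] == pytest.approx(9.0)
        with pytest.raises(FormatError):
            read_structure(path, model_index=5)

    def test_hetatm_only_rejected(self, tmp_path):
        lines = [_atom_line(1, "C1", "LIG", "A", 1, 0, 0, 0, record="HETATM",
                            element="C"), "END"]
        path = tmp_path / "ligand_only.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="polymer"):
            read_structure(path)

    def test_ligands_kept_separately(self, tmp_path):
        lines = [
            _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _atom_line(2, "C1", "LIG", "A", 2, 1, 0, 0, record="HETATM",
                       element="C"),
            "END",
        ]
        path = tmp_path / "with_ligand.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert len(model.chains["A"]) == 1
        assert len(model.ligands["A"]) == 1

    def test_hydrogens_and_waters_excluded(self, tmp_path):
        lines = [
            _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _atom_line(2, "H", "GLY", "A", 1, 0.5, 0, 0, element="H"),
            _atom_line(3, "O", "HOH", "A", 2, 3, 0, 0, record="HETATM"),
            "END",
        ]
        path = tmp_path / "h_and_water.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert len(model.chains["A"][0].atoms) == 1
        assert "A" not in model.ligands

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("JUNK\n")
        with pytest.raises(FormatError):
            read_structure(path)


class TestDistances:
    def test_three_four_five_triangle(self):
        model = StructureModel(chains={
            "A": [Residue("1", "GLY", (Atom("CA", (0.0, 0.0, 0.0)),))],
            "B": [Residue("1", "GLY", (Atom("CA", (3.0, 4.0, 0.0)),))],
        })
        assert residue_min_distance(model, "A", 1, "B", 1) == pytest.approx(5.0)

    def test_self_distance_zero(self, toy_dimer):
        model, _ = toy_dimer
        assert residue_min_distance(model, "A", 1, "A", 1) == 0.0

    def test_symmetry(self, toy_dimer):
        model, _ = toy_dimer
        d1 = residue_min_distance(model, "A", 3, "B", 7)
        d2 = residue_min_distance(model, "B", 7, "A", 3)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_missing_residue_named_in_error(self, toy_dimer):
        model, _ = toy_dimer
        with pytest.raises(LookupErrorStruct, match="999"):
            residue_min_distance(model, "A", 999, "B", 1)

    def test_matches_brute_force_oracle(self, toy_dimer):
        model, _ = toy_dimer
        rng = np.random.default_rng(0)
        for _ in range(25):
            i = int(rng.integers(1, 21)); j = int(rng.integers(1, 21))
            expected = brute_min_distance(model.residue("A", i),
                                          model.residue("B", j))
            assert residue_min_distance(model, "A", i, "B", j) == pytest.approx(
                expected, abs=1e-12
            )


def _rigid_transform(model, seed):
    """Random rotation + translation applied to every atom."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    new_chains = {}
    for cid, residues in model.chains.items():
        new_chains[cid] = [
            Residue(res.res_seq, res.name, tuple(
                Atom(a.name, tuple(q @ np.array(a.coord) + t))
                for a in res.atoms
            ))
            for res in residues
        ]
    return StructureModel(chains=new_chains)


class TestInterface:
    def test_matches_construction_truth(self, toy_dimer):
        model, truth = toy_dimer
        report = interface_residues(model, "A", "B", cutoff=truth["cutoff"])
        assert set(report.interface_residues_a) == truth["interface_a"]
        assert set(report.interface_residues_b) == truth["interface_b"]

    def test_far_apart_chains_empty(self):
        model, truth = make_toy_heterodimer(10, inter_chain_gap=100.0,
                                            truth_cutoff=5.0)
        report = interface_residues(model, "A", "B", cutoff=5.0)
        assert not report.interface_residues_a
        assert not truth["interface_a"]

    @pytest.mark.parametrize("cut_lo,cut_hi", [(4.0, 6.0), (4.5, 5.0)])
    def test_monotone_in_cutoff(self, toy_dimer, cut_lo, cut_hi):
        model, _ = toy_dimer
        lo = interface_residues(model, "A", "B", cutoff=cut_lo)
        hi = interface_residues(model, "A", "B", cutoff=cut_hi)
        assert lo.interface_residues_a <= hi.interface_residues_a
        assert lo.interface_residues_b <= hi.interface_residues_b

    def test_missing_chain_rejected(self, toy_dimer):
        model, _ = toy_dimer
        with pytest.raises(LookupErrorStruct):
            interface_residues(model, "A", "Z")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_transform_invariance(self, toy_dimer, seed):
        model, _ = toy_dimer
        moved = _rigid_transform(model, seed)
        ref = interface_residues(model, "A", "B", 5.0)
        new = interface_residues(moved, "A", "B", 5.0)
        assert ref.interface_residues_a == new.interface_residues_a
        d_ref = residue_min_distance(model, "A", 5, "B", 5)
        d_new = residue_min_distance(moved, "A", 5, "B", 5)
        assert d_new == pytest.approx(d_ref, abs=1e-6)


class TestContacts:
    def test_distant_in_sequence_close_in_space(self):
        # residues 1 and 6 placed 3.8 A apart; 2..5 pushed far away
        chain = [
            Residue("1", "ALA", (Atom("CA", (0.0, 0.0, 0.0)),)),
            Residue("2", "ALA", (Atom("CA", (50.0, 0.0, 0.0)),)),
            Residue("3", "ALA", (Atom("CA", (60.0, 0.0, 0.0)),)),
            Residue("4", "ALA", (Atom("CA", (70.0, 0.0, 0.0)),)),
            Residue("5", "ALA", (Atom("CA", (80.0, 0.0, 0.0)),)),
            Residue("6", "ALA", (Atom("CA", (3.8, 0.0, 0.0)),)),
        ]
        model = StructureModel(chains={"A": chain})
        partners = contact_partners(model, "A", 1, cutoff=4.5)
        assert [c.res_b for c in partners] == ["6"]
        assert partners[0].min_distance == pytest.approx(3.8)

    def test_sequence_neighbors_excluded(self):
        chain = [
            Residue(str(i), "ALA", (Atom("CA", (1.0 * i, 0.0, 0.0)),))
            for i in range(1, 6)
        ]
        model = StructureModel(chains={"A": chain})
        partners = contact_partners(model, "A", 3, cutoff=4.5, min_seq_sep=3)
        assert partners == []
        relaxed = contact_partners(model, "A", 3, cutoff=4.5, min_seq_sep=1)
        assert {c.res_b for c in relaxed} == {"1", "2", "4", "5"}

    def test_sorted_by_distance_matches_brute_force(self, toy_dimer):
        model, _ = toy_dimer
        partners = contact_partners(model, "A", 10, cutoff=6.0, min_seq_sep=3)
        dists = [c.min_distance for c in partners]
        assert dists == sorted(dists)
        target = model.residue("A", 10)
        expected = {
            r.res_seq
            for r in model.chains["A"]
            if abs(r.number - 10) >= 3
            and brute_min_distance(target, r) <= 6.0
        }
        assert {c.res_b for c in partners} == expected


class TestRoundTrip:
    def test_pdb_write_read_within_field_precision(self, toy_dimer, tmp_path):
        model, _ = toy_dimer
        path = tmp_path / "toy.pdb"
        write_pdb(model, path)
        reread = read_structure(path)
        for cid in model.chains:
            for r1, r2 in zip(model.chains[cid], reread.chains[cid]):
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    assert np.allclose(a1.coord, a2.coord, atol=1e-3)


class TestMutationMapping:
    def test_interface_mutation_flagged(self, toy_dimer):
        model, truth = toy_dimer
        pos = sorted(truth["interface_a"], key=int)[0]
        change = parse_protein_change(f"A{pos}V", "PPARG2")
        annotations = map_mutations_to_structure(
            [("PPARG", change)], model, {"PPARG": "A"},
            partner_of_chain={"A": "B"},
        )
        ann = annotations[0]
        assert ann.resolved and ann.in_interface

    def test_position_outside_construct_unresolved(self, toy_dimer):
        model, _ = toy_dimer
        change = parse_protein_change("E3K", "PPARG2")
        # the toy chain covers residues 1..20 but an LBD-style construct
        # numbering offset pushes position 3 out of the model
        offset = IsoformMap("PPARG2", "construct", offset=-230)
        annotations = map_mutations_to_structure(
            [("PPARG", change)], model, {"PPARG": "A"},
            numbering_offset={"PPARG": offset},
        )
        assert annotations[0].resolved is False

    def test_empty_mutation_list(self, toy_dimer):
        model, _ = toy_dimer
        assert map_mutations_to_structure([], model, {}) == []

    def test_unmapped_gene_rejected(self, toy_dimer):
        model, _ = toy_dimer
        change = parse_protein_change("A5V", "PPARG2")
        with pytest.raises(KeyError):
            map_mutations_to_structure([("RXRA", change)], model,
                                       {"PPARG": "A"})
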