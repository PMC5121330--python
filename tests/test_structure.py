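"""Structure parsing, contact mapping and chain labeling."""

import numpy as np
import pytest

from conftest import brute_force_contacts
from nabind.structure import (
    Atom, Chain, PDBParseError, Residue, StructureModel,
    align_full_to_structure, classify_chain, filter_sequences, label_chains,
    map_contacts, mask_unresolved, parse_pdb,
)
from nabind.synthetic import ToyStructureSpec, make_toy_structure


def _atom_line(serial, name, resname, chain, resseq, x, y, z, element):
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:>5d} {padded} {resname:>3s} {chain}{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}")


TWO_RESIDUE_PDB = "\n".join([
    _atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
    _atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, "C"),
    "END",
]) + "\n"


class TestParsePdb:
    def test_two_residue_single_chain_fixture(self):
        model = parse_pdb(TWO_RESIDUE_PDB)
        assert len(model.chains) == 1
        assert len(model.chains[0].residues) == 2
        assert model.chains[0].atom_sequence == "AG"

    def test_seqres_longer_than_resolved_residues(self):
        # deposited sequence of 10, only 8 with coordinates
        seq3 = ["MET", "ALA", "GLY", "LYS", "LEU", "VAL", "SER", "THR",
                "GLU", "ASP"]
        lines = [
            "SEQRES   1 A   10  " + " ".join(f"{r:>3s}" for r in seq3)]
        for i, rn in enumerate(seq3[1:9], start=2):   # residues 2..9 resolved
            lines.append(_atom_line(i, "CA", rn, "A", i, 3.8 * i, 0.0, 0.0, "C"))
        model = parse_pdb("\n".join(lines + ["END"]))
        chain = model.chains[0]
        assert len(chain.seqres_sequence) == 10
        assert chain.seqres_sequence == "MAGKLVSTED"
        assert len(chain.residues) == 8

    def test_hydrogen_flag_from_element_column(self):
        text = "\n".join([
            _atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            _atom_line(2, "HB1", "ALA", "A", 1, 1.0, 0.0, 0.0, "H"),
            "END"])
        atoms = parse_pdb(text).chains[0].residues[0].atoms
        flags = {a.name: a.is_hydrogen for a in atoms}
        assert flags == {"CA": False, "HB1": True}

    def test_hydrogen_fallback_name_heuristic(self):
        # no element column: names like 1HB2 are hydrogens after digit strip
        line = (f"ATOM      2 1HB2 ALA A   1    {1.0:8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}")
        text = "\n".join([
            _atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            line, "END"])
        atoms = parse_pdb(text).chains[0].residues[0].atoms
        assert {a.name: a.is_hydrogen for a in atoms}["1HB2"] is True

    def test_malformed_coordinates_name_the_line(self):
        bad = TWO_RESIDUE_PDB.replace("   3.800", "  3.8..0")
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(bad)

    def test_modified_residue_maps_to_parent_code(self):
        line = (f"HETATM    1  CA  MSE A   1    {0.0:8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          SE")
        text = "\n".join([line,
                          _atom_line(2, "CA", "GLY", "A", 2, 3.8, 0, 0, "C"),
                          "END"])
        chain = parse_pdb(text).chains[0]
        assert chain.atom_sequence == "MG"

    def test_water_and_ligands_dropped(self):
        hoh = (f"HETATM    3  O   HOH A 100    {9.0:8.3f}{0.0:8.3f}{0.0:8.3f}"
               f"{1.0:6.2f}{0.0:6.2f}           O")
        model = parse_pdb(TWO_RESIDUE_PDB.replace("END", hoh + "\nEND"))
        assert len(model.chains[0].residues) == 2


class TestClassifyChain:
    @pytest.mark.parametrize("names,expected", [
        (["DA", "DC", "DG", "DT"], "DNA"),
        (["A", "C", "G", "U"], "RNA"),
        (["ALA", "GLY", "LYS"], "protein"),
    ])
    def test_alphabet_rule(self, names, expected):
        chain = Chain(chain_id="X", kind="other", residues=[
            Residue(index=i, name=n, one_letter="X", atoms=[])
            for i, n in enumerate(names)])
        assert classify_chain(chain) == expected

    def test_empty_chain_is_an_error(self):
        with pytest.raises(ValueError):
            classify_chain(Chain(chain_id="X", kind="other", residues=[]))


class TestMapContacts:
    def test_strict_five_angstrom_boundary(self, two_chain_model):
        contacts = map_contacts(two_chain_model, "DNA")
        assert ("A", 0) in contacts          # 4.99 A, strictly below
        assert ("A", 1) not in contacts      # exactly 5.00 A

    def test_missing_na_chain_is_an_error(self, two_chain_model):
        with pytest.raises(ValueError, match="RNA"):
            map_contacts(two_chain_model, "RNA")

    def test_equals_brute_force_scan_on_random_toy_structures(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 30
            positions = set(map(int, rng.choice(n, size=rng.integers(0, 6),
                                                replace=False)))
            text, truth = make_toy_structure(
                ToyStructureSpec(n_residues=n, binding_positions=positions,
                                 seed=seed))
            model = parse_pdb(text)
            got = map_contacts(model, "DNA")
            assert got == brute_force_contacts(model, "DNA")
            assert {ri for _c, ri in got} == truth

    def test_invariant_under_chain_and_atom_permutation(self, two_chain_model):
        before = map_contacts(two_chain_model, "DNA")
        flipped = StructureModel(
            structure_id="TST",
            chains=list(reversed(two_chain_model.chains)))
        for chain in flipped.chains:
            for res in chain.residues:
                res.atoms = list(reversed(res.atoms))
        assert map_contacts(flipped, "DNA") == before


class TestLabelChains:
    def test_contact_free_chains_are_dropped(self, two_chain_model):
        far = Chain(chain_id="C", kind="protein", residues=[
            Residue(index=0, name="ALA", one_letter="A", atoms=[
                Atom(name="CA", element="C", coords=np.array([0., 500., 0.]),
                     is_hydrogen=False)])], seqres_sequence="A")
        model = StructureModel(structure_id="TST",
                               chains=two_chain_model.chains + [far])
        labeled = label_chains(model, map_contacts(model, "DNA"), "DNA")
        assert [c.chain_id for c in labeled] == ["A"]

    def test_labels_exactly_at_contact_indices(self):
        text, _ = make_toy_structure(
            ToyStructureSpec(n_residues=12, binding_positions={3, 7}, seed=0))
        model = parse_pdb(text)
        (chain,) = label_chains(model, map_contacts(model, "DNA"), "DNA")
        assert set(np.where(chain.labels == 1)[0]) == {3, 7}
        assert chain.resolved_mask.all()

    def test_contact_free_model_gives_empty_list(self):
        text, _ = make_toy_structure(
            ToyStructureSpec(n_residues=10, binding_positions=frozenset(),
                             seed=0))
        model = parse_pdb(text)
        assert label_chains(model, map_contacts(model, "DNA"), "DNA") == []


class TestFilterSequences:
    def _chain(self, seq):
        n = len(seq)
        from nabind.structure import LabeledChain
        labels = np.zeros(n, int)
        labels[0] = 1
        return LabeledChain("S", "A", seq, labels, np.ones(n, bool), "DNA")

    def test_length_threshold_is_thirty(self):
        short, exact = self._chain("A" * 29), self._chain("A" * 30)
        assert filter_sequences([short, exact]) == [exact]

    def test_chains_with_undetermined_residues_removed(self):
        with_x = self._chain("A" * 25 + "X" + "A" * 24)
        assert filter_sequences([with_x]) == []

    def test_idempotent_and_empty_input(self):
        chains = [self._chain("A" * 40), self._chain("A" * 10)]
        once = filter_sequences(chains)
        assert filter_sequences(once) == once
        assert filter_sequences([]) == []


class TestAlignment:
    def test_identical_sequences_identity_mapping(self):
        assert align_full_to_structure("ACDEFG", "ACDEFG") == [0, 1, 2, 3, 4, 5]

    def test_internal_deletion_maps_to_none(self):
        # structure lacks an internal 2-residue stretch
        full = "MAGKLVSTED"
        struct = "MAGKSTED"       # LV missing
        mapping = align_full_to_structure(full, struct)
        assert mapping[:4] == [0, 1, 2, 3]
        assert mapping[4:6] == [None, None]
        assert mapping[6:] == [4, 5, 6, 7]

    def test_single_residue_gap_dp_oracle(self):
        mapping = align_full_to_structure("ACDEFG", "ACDFG")
        assert mapping[3] is None                      # E unmatched
        assert sum(m is not None for m in mapping) == 5

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            align_full_to_structure("", "ACD")


class TestMaskUnresolved:
    def test_mask_false_exactly_where_mapping_none(self):
        from nabind.structure import LabeledChain
        chain = LabeledChain("S", "A", "ACDEF", [1, 0, 0, 0, 0],
                             np.ones(5, bool), "DNA")
        masked = mask_unresolved(chain, [0, 1, None, None, 2])
        assert masked.resolved_mask.tolist() == [True, True, False, False, True]

    def test_labels_cleared_on_unresolved_positions(self):
        from nabind.structure import LabeledChain
        chain = LabeledChain("S", "A", "ACD", [0, 1, 0], np.ones(3, bool), "DNA")
        masked = mask_unresolved(chain, [0, None, 1])
        assert masked.labels.tolist() == [0, 0, 0]

    def test_length_mismatch_is_an_error(self):
        from nabind.structure import LabeledChain
        chain = LabeledChain("S", "A", "ACD", [0, 0, 0], np.ones(3, bool), "DNA")
        with pytest.raises(ValueError):
            mask_unresolved(chain, [0, 1])
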