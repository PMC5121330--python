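import numpy as np
import pytest

from nabind.featurize import TrackSet
from nabind.structure import Atom, Chain, Residue, StructureModel


def brute_force_contacts(model, na_kind, cutoff=5.0):
    """Exhaustive all-pairs heavy-atom distance scan (independent oracle)."""
    na_atoms = [
        atom.coords
        for chain in model.chains if chain.kind == na_kind
        for res in chain.residues
        for atom in res.atoms if not atom.is_hydrogen
    ]
    out = set()
    for chain in model.chains:
        if chain.kind != "protein":
            continue
        for res in chain.residues:
            for atom in res.atoms:
                if atom.is_hydrogen:
                    continue
                for na in na_atoms:
                    if float(np.linalg.norm(atom.coords - na)) < cutoff:
                        out.add((chain.chain_id, res.index))
                        break
                else:
                    continue
                break
    return out


def protein_residue(index, one_letter="A", atoms=()):
    return Residue(index=index, name="ALA", one_letter=one_letter,
                   atoms=list(atoms))


def single_atom(coords, name="CA", element="C"):
    return Atom(name=name, element=element, coords=np.asarray(coords, float),
                is_hydrogen=element.upper() in ("H", "D"))


@pytest.fixture
def two_chain_model():
    """One protein chain (2 residues) + one DNA chain, distances controlled:
    residue 0 has an atom at 4.99 A from the DNA, residue 1 at exactly 5.00 A."""
    prot = Chain(chain_id="A", kind="protein", residues=[
        protein_residue(0, atoms=[single_atom([0.0, 4.99, 0.0])]),
        protein_residue(1, atoms=[single_atom([10.0, 5.00, 0.0])]),
    ], seqres_sequence="AA")
    dna = Chain(chain_id="B", kind="DNA", residues=[
        Residue(index=0, name="DA", one_letter="A", atoms=[
            single_atom([0.0, 0.0, 0.0], name="P", element="P"),
            single_atom([10.0, 0.0, 0.0], name="P", element="P"),
        ]),
    ])
    return StructureModel(structure_id="TST", chains=[prot, dna])


def random_tracks(n, rng):
    rel = rng.uniform(0, 1, n)
    return TrackSet(
        conservation=rng.uniform(0, 1, n),
        entropy=rng.uniform(0, 4.3, n),
        n_align=np.full(n, float(rng.integers(1, 500))),
        ss3=rng.dirichlet((1, 1, 1), size=n),
        accessibility=np.column_stack([rel, (rel > 0.25).astype(float)]),
        disorder=rng.uniform(0, 1, n),
    )
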