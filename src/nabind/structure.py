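"""Co-complex structure parsing, contact mapping and chain labeling.

A residue is a binding residue when any of its heavy (non-hydrogen) atoms
lies strictly within 5 A of any heavy atom of a nucleic-acid chain in the
same co-complex.  Chains are labeled over their full deposited (SEQRES)
sequence; residues without coordinates cannot be labeled and are masked out
of training, though they still appear as sliding-window neighbours.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from nabind.alignment import global_align_blocks

DNA_RESIDUE_NAMES = {"DA", "DC", "DG", "DT", "DI"}
RNA_RESIDUE_NAMES = {"A", "C", "G", "U", "I"}
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# parent one-letter codes for standard and modified amino acids (MSE -> M, ...)
_PROTEIN_3TO1 = {k.strip(): v for k, v in protein_letters_3to1_extended.items()
                 if len(v) == 1 and v in AA20}
_PROTEIN_NAMES = set(_PROTEIN_3TO1)


class PDBParseError(ValueError):
    """Raised for malformed PDB input, naming the offending line."""


def _one_letter(resname: str) -> str:
    name = resname.strip().upper()
    if name in DNA_RESIDUE_NAMES or name in RNA_RESIDUE_NAMES:
        return name[-1]
    return _PROTEIN_3TO1.get(name, "X")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    index: int                 # 0-based position among the chain's resolved residues
    name: str
    one_letter: str
    atoms: list[Atom]
    author_number: Optional[int] = None   # recorded, never used for arithmetic

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    kind: str                  # protein | DNA | RNA | other
    residues: list[Residue]
    seqres_sequence: str = ""

    @property
    def atom_sequence(self) -> str:
        """Sequence of the structure-resolved residues, in file order."""
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain]

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in structure model")

    def chains_of_kind(self, kind: str) -> list[Chain]:
        return [c for c in self.chains if c.kind == kind]


@dataclass
class LabeledChain:
    """A protein chain's full sequence with per-residue binding labels.

    ``labels`` and ``resolved_mask`` are indexed over ``sequence`` (the
    SEQRES-derived full sequence).  A label may be 1 only at resolved
    positions.
    """

    structure_id: str
    chain_id: str
    sequence: str
    labels: np.ndarray
    resolved_mask: np.ndarray
    na_kind: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool)
        n = len(self.sequence)
        if len(self.labels) != n or len(self.resolved_mask) != n:
            raise ValueError(
                f"{self.structure_id}:{self.chain_id}: labels/mask length "
                f"does not match sequence length {n}"
            )
        if np.any(self.labels[~self.resolved_mask] == 1):
            raise ValueError("binding label on an unresolved residue")

    @property
    def id(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"


def _is_hydrogen(element: str, atom_name: str) -> bool:
    el = element.strip().upper()
    if el:
        return el in ("H", "D")
    # fallback: atom name with leading digits stripped starts with H
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() == "H"


def _keep_residue(resname: str) -> bool:
    name = resname.strip().upper()
    if name in ("HOH", "DOD", "WAT"):
        return False
    return (name in DNA_RESIDUE_NAMES or name in RNA_RESIDUE_NAMES
            or name in _PROTEIN_NAMES or name == "UNK")


def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field on line {lineno}: "
                        f"{line[lo:hi]!r}"
                    ) from None


def _parse_seqres(text: str) -> dict[str, str]:
    names: dict[str, list[str]] = {}
    for line in text.splitlines():
        if line.startswith("SEQRES"):
            chain_id = line[11:12].strip() or " "
            names.setdefault(chain_id, []).extend(line[19:].split())
    return {cid: "".join(_one_letter(n) for n in codes)
            for cid, codes in names.items()}


def parse_pdb(text: str, structure_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    The first model and the first-listed alternate location of each atom
    are kept; HETATM amino acids and nucleotides (e.g. MSE) stay attached
    to their polymer chain while waters and non-polymer ligands are
    dropped.  SEQRES records, when present, provide the full chain
    sequence; otherwise it is reconstructed from the resolved residues.
    """
    if "ATOM" not in text and "HETATM" not in text:
        raise PDBParseError("no ATOM records found")
    _validate_coordinate_fields(text)
    if not structure_id:
        for line in text.splitlines():
            if line.startswith("HEADER") and len(line) >= 66:
                structure_id = line[62:66].strip()
                break
        structure_id = structure_id or "STRUCT"

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure(structure_id, io.StringIO(text))
    model = next(iter(bio_structure))  # first model only
    seqres = _parse_seqres(text)

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            resname = bio_res.get_resname().strip()
            if not _keep_residue(resname):
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for bio_atom in bio_res.get_unpacked_list():
                name = bio_atom.get_name()
                if name in seen:
                    continue  # keep first-listed altloc only
                seen.add(name)
                element = (bio_atom.element or "").strip()
                atoms.append(Atom(
                    name=name,
                    element=element,
                    coords=np.array(bio_atom.get_coord(), dtype=float),
                    is_hydrogen=_is_hydrogen(element, name),
                ))
            residues.append(Residue(
                index=len(residues),
                name=resname,
                one_letter=_one_letter(resname),
                atoms=atoms,
                author_number=bio_res.get_id()[1],
            ))
        if not residues:
            continue
        chain = Chain(
            chain_id=bio_chain.id,
            kind="other",
            residues=residues,
            seqres_sequence=seqres.get(bio_chain.id, ""),
        )
        chain.kind = classify_chain(chain)
        chains.append(chain)
    return StructureModel(structure_id=structure_id, chains=chains)


def classify_chain(chain: Chain) -> str:
    """Classify a chain as protein, DNA, RNA or other by majority residue type."""
    if not chain.residues:
        raise ValueError("cannot classify an empty chain")
    counts = {"DNA": 0, "RNA": 0, "protein": 0, "other": 0}
    for res in chain.residues:
        name = res.name.strip().upper()
        if name in DNA_RESIDUE_NAMES:
            counts["DNA"] += 1
        elif name in RNA_RESIDUE_NAMES:
            counts["RNA"] += 1
        elif name in _PROTEIN_NAMES or name == "UNK":
            counts["protein"] += 1
        else:
            counts["other"] += 1
    best = max(counts, key=counts.get)
    return best if counts[best] * 2 > len(chain.residues) else "other"


def map_contacts(
    model: StructureModel, na_kind: str, cutoff_angstrom: float = 5.0
) -> set[tuple[str, int]]:
    """Protein residues with any heavy atom strictly below ``cutoff_angstrom``
    of any heavy atom of a chain of ``na_kind``.

    Returns ``(chain_id, residue_index)`` pairs; indices refer to the
    chain's resolved residue list.
    """
    na_chains = model.chains_of_kind(na_kind)
    if not na_chains:
        raise ValueError(f"no {na_kind} chain present in {model.structure_id}")
    na_coords = np.array([
        atom.coords
        for chain in na_chains
        for res in chain.residues
        for atom in res.heavy_atoms()
    ])
    contacts: set[tuple[str, int]] = set()
    if na_coords.size == 0:
        return contacts
    tree = cKDTree(na_coords)
    for chain in model.chains_of_kind("protein"):
        coords, owners = [], []
        for res in chain.residues:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                owners.append(res.index)
        if not coords:
            continue
        dist, _ = tree.query(np.asarray(coords))
        for d, idx in zip(dist, owners):
            if d < cutoff_angstrom:
                contacts.add((chain.chain_id, idx))
    return contacts


def align_full_to_structure(full_seq: str, struct_seq: str) -> list[Optional[int]]:
    """Map every position of the full (deposited) sequence to its resolved
    structure position, or ``None`` where the structure lacks the residue.

    Needleman-Wunsch global alignment with BLOSUM62, gap open 10 and gap
    extend 0.5.  The mapping is monotonic by construction.
    """
    if full_seq == struct_seq:
        return list(range(len(full_seq)))
    mapping: list[Optional[int]] = [None] * len(full_seq)
    for a0, b0, length in global_align_blocks(full_seq, struct_seq):
        for k in range(length):
            mapping[a0 + k] = b0 + k
    return mapping


def label_chains(
    model: StructureModel,
    contacts: set[tuple[str, int]],
    na_kind: str,
) -> list[LabeledChain]:
    """One :class:`LabeledChain` per protein chain with at least one contact.

    Labels live on the SEQRES-derived full sequence; contact indices (which
    refer to resolved residues) are carried over through the global
    alignment of full to resolved sequence.  Contact-free chains are
    dropped.
    """
    out: list[LabeledChain] = []
    for chain in model.chains_of_kind("protein"):
        contact_idx = {ri for cid, ri in contacts if cid == chain.chain_id}
        if not contact_idx:
            continue
        struct_seq = chain.atom_sequence
        full_seq = chain.seqres_sequence or struct_seq
        mapping = align_full_to_structure(full_seq, struct_seq)
        labels = np.zeros(len(full_seq), dtype=int)
        resolved = np.zeros(len(full_seq), dtype=bool)
        for fi, si in enumerate(mapping):
            if si is not None:
                resolved[fi] = True
                if si in contact_idx:
                    labels[fi] = 1
        out.append(LabeledChain(
            structure_id=model.structure_id,
            chain_id=chain.chain_id,
            sequence=full_seq,
            labels=labels,
            resolved_mask=resolved,
            na_kind=na_kind,
        ))
    return out


def filter_sequences(
    chains: Iterable[LabeledChain], min_len: int = 30
) -> list[LabeledChain]:
    """Drop chains shorter than ``min_len`` or containing undetermined ('X')
    residues."""
    return [
        c for c in chains
        if len(c.sequence) >= min_len and "X" not in c.sequence
    ]


def mask_unresolved(
    labeled: LabeledChain, mapping: Sequence[Optional[int]]
) -> LabeledChain:
    """Return a copy whose ``resolved_mask`` is False exactly where
    ``mapping`` is None.

    Unresolved residues are excluded as training examples but keep their
    place in the sequence, so they still contribute window channels to
    their neighbours.
    """
    if len(mapping) != len(labeled.sequence):
        raise ValueError(
            f"mapping length {len(mapping)} != sequence length "
            f"{len(labeled.sequence)}"
        )
    resolved = np.array([m is not None for m in mapping], dtype=bool)
    labels = np.where(resolved, labeled.labels, 0)
    return replace(labeled, labels=labels, resolved_mask=resolved)


def write_labeled_fasta(chains: Iterable[LabeledChain], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n{c.sequence}\n")


def write_labeled_tsv(chains: Iterable[LabeledChain], path) -> None:
    import pandas as pd

    rows = [
        (c.structure_id, c.chain_id, i, c.sequence[i],
         int(c.labels[i]), int(c.resolved_mask[i]))
        for c in chains
        for i in range(len(c.sequence))
    ]
    pd.DataFrame(rows, columns=[
        "structure_id", "chain_id", "residue_index", "one_letter",
        "label", "resolved",
    ]).to_csv(path, sep="\t", index=False)
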