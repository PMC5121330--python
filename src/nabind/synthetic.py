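"""Synthetic fixtures: toy co-complexes, controlled MSAs and planted-signal
datasets.

The generators provide ground truth that the analysis modules must
recover: toy structures whose contact set is known by construction, MSAs
with chosen conserved columns, and feature datasets in which binding
residues of binder proteins carry a tunable mean shift (in SD units) on a
fixed channel subset (conservation, relative accessibility, disorder).
Geometry is deliberately minimal — the contact rule only cares about
atom-atom distances, not chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from nabind.featurize import LOG2_20, TrackSet
from nabind.structure import AA20, parse_pdb, map_contacts

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


class GeometryError(ValueError):
    """The requested toy-structure constraints cannot be satisfied."""


@dataclass
class ToyStructureSpec:
    n_residues: int
    binding_positions: frozenset[int] = frozenset()
    contact_distance: float = 4.5
    non_contact_distance: float = 8.0
    na_kind: str = "DNA"
    seed: int = 0
    spacing: float = 10.0          # backbone step along x

    def __post_init__(self):
        self.binding_positions = frozenset(self.binding_positions)
        if any(not 0 <= p < self.n_residues for p in self.binding_positions):
            raise ValueError("binding positions outside the chain")
        if not self.contact_distance < 5.0 < self.non_contact_distance:
            raise GeometryError(
                "need contact_distance < 5 A < non_contact_distance")
        # a contact atom is jittered by <= 1 A off its residue's x plane
        if np.hypot(self.spacing - 1.0, 0.0) <= self.non_contact_distance:
            raise GeometryError(
                "backbone spacing too small to keep non-binding residues "
                f"beyond {self.non_contact_distance} A")


def _atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
               xyz: np.ndarray, element: str) -> str:
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {padded}{'':1s}{resname:>3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def _seqres_lines(chain: str, resnames: Sequence[str]) -> list[str]:
    lines = []
    for ser, start in enumerate(range(0, len(resnames), 13), start=1):
        chunk = resnames[start:start + 13]
        lines.append(
            f"SEQRES{ser:4d} {chain}{len(resnames):5d}  "
            + " ".join(f"{r:>3s}" for r in chunk)
        )
    return lines


def make_toy_structure(spec: ToyStructureSpec) -> tuple[str, set[int]]:
    """PDB text for a toy protein/NA co-complex plus its true contact set.

    Protein residues sit on a straight backbone; each binding position
    gets one NA phosphate-proxy atom placed exactly ``contact_distance``
    away, while every other residue's nearest NA atom is farther than
    ``non_contact_distance``.  A decoy NA hydrogen is parked close to a
    non-binding residue so that hydrogen exclusion is exercised.  The text
    round-trips through :func:`nabind.structure.parse_pdb` and the ground
    truth is re-verified with :func:`map_contacts` before returning.
    """
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list(AA20), size=spec.n_residues))
    resnames = [_AA3[c] for c in sequence]
    na_res = "DA" if spec.na_kind == "DNA" else "A"

    lines = ["HEADER    SYNTHETIC TOY CO-COMPLEX                29-SEP-26   TOY "]
    lines += _seqres_lines("A", resnames)
    serial = 1
    for i, rn in enumerate(resnames):
        x = spec.spacing * i
        lines.append(_atom_line(serial, "CA", rn, "A", i + 1,
                                np.array([x, 0.0, 0.0]), "C")); serial += 1
        lines.append(_atom_line(serial, "CB", rn, "A", i + 1,
                                np.array([x, 1.5, 0.0]), "C")); serial += 1
    lines.append("TER")

    resseq = 1
    binding = sorted(spec.binding_positions)
    jitter = min(1.0, spec.contact_distance / 2.0)
    for i in binding:
        dx, dz = rng.uniform(-jitter, jitter, size=2)
        dy = -np.sqrt(spec.contact_distance ** 2 - dx ** 2 - dz ** 2)
        pos = np.array([spec.spacing * i + dx, dy, dz])
        lines.append(_atom_line(serial, "P", na_res, "B", resseq, pos, "P"))
        serial += 1
        resseq += 1
    # keep the NA chain non-empty and place a decoy hydrogen near a
    # non-binding residue (heavy-atom scans must ignore it)
    far = np.array([0.0, -100.0, 0.0])
    lines.append(_atom_line(serial, "P", na_res, "B", resseq, far, "P"))
    serial += 1
    non_binding = [i for i in range(spec.n_residues) if i not in spec.binding_positions]
    if non_binding:
        j = int(rng.choice(non_binding))
        hpos = np.array([spec.spacing * j, -3.0, 0.0])
        lines.append(_atom_line(serial, "H5'", na_res, "B", resseq, hpos, "H"))
    lines.append("END")
    text = "\n".join(lines) + "\n"

    model = parse_pdb(text, structure_id=f"TOY{spec.seed}")
    found = {ri for _cid, ri in map_contacts(model, spec.na_kind)}
    if found != set(spec.binding_positions):
        raise GeometryError(
            f"constructed contacts {sorted(found)} do not match requested "
            f"{sorted(spec.binding_positions)}")
    return text, set(spec.binding_positions)


def make_synthetic_msa(
    seq: str,
    n_seqs: int,
    conserved_positions: Sequence[int] = (),
    mutation_rate: float = 0.3,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """An gapless alignment around ``seq``: conserved columns are copied
    verbatim into every row, all other columns mutate i.i.d. at
    ``mutation_rate``.  Row 0 is the query itself."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0,1]")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    rows = [("query", seq)]
    alphabet = list(AA20)
    for r in range(1, n_seqs):
        chars = list(seq)
        for j in range(len(seq)):
            if j in conserved:
                continue
            if rng.random() < mutation_rate:
                chars[j] = alphabet[rng.integers(20)]
        rows.append((f"hom{r}", "".join(chars)))
    return rows


def write_msa_fasta(msa: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in msa:
            fh.write(f">{sid}\n{seq}\n")


# baseline channel distributions (mean, SD) before clipping; the planted
# shift is expressed in these SD units
_BASELINES = {
    "conservation": (0.5, 0.15),
    "disorder": (0.3, 0.15),
    "rel_acc": (0.4, 0.2),
}
_SHIFTED_CHANNELS = ("conservation", "rel_acc", "disorder")


@dataclass
class PlantedDatasetSpec:
    n_proteins: int = 200
    fraction_binders: float = 0.5
    length_range: tuple[int, int] = (60, 140)
    n_patches_range: tuple[int, int] = (1, 3)
    patch_length_range: tuple[int, int] = (4, 10)
    effect_size: float = 2.0        # mean shift of binding residues, in SD units
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction_binders < 1.0:
            raise ValueError("fraction_binders must lie in (0,1)")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


@dataclass
class SyntheticChain:
    chain_id: str
    sequence: str
    tracks: TrackSet
    residue_labels: np.ndarray
    is_binder: bool


@dataclass
class PlantedDataset:
    chains: list[SyntheticChain]
    spec: PlantedDatasetSpec

    @property
    def ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    @property
    def protein_labels(self) -> np.ndarray:
        return np.array([int(c.is_binder) for c in self.chains])


def make_planted_dataset(spec: PlantedDatasetSpec) -> PlantedDataset:
    """Chains with descriptor tracks in which binder proteins carry
    contiguous binding patches shifted by ``effect_size`` SDs on the
    conservation, relative-accessibility and disorder channels.

    Non-binders have no patches; an exact ``round(n * fraction_binders)``
    count of binders is planted at seeded random positions.  Everything is
    bit-reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_binders = round(spec.n_proteins * spec.fraction_binders)
    binder_flags = np.zeros(spec.n_proteins, dtype=bool)
    binder_flags[rng.permutation(spec.n_proteins)[:n_binders]] = True

    chains: list[SyntheticChain] = []
    for p in range(spec.n_proteins):
        n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        sequence = "".join(rng.choice(list(AA20), size=n))
        raw = {
            name: rng.normal(mu, sd, size=n)
            for name, (mu, sd) in _BASELINES.items()
        }
        entropy = np.clip(rng.normal(2.5, 0.8, size=n), 0.0, LOG2_20)
        n_align = int(rng.integers(50, 501))
        ss3 = rng.dirichlet((1.0, 1.0, 1.0), size=n)

        labels = np.zeros(n, dtype=int)
        if binder_flags[p]:
            lo, hi = spec.n_patches_range
            for _ in range(int(rng.integers(lo, hi + 1))):
                plo, phi = spec.patch_length_range
                length = int(rng.integers(plo, min(phi, n) + 1))
                start = int(rng.integers(0, n - length + 1))
                labels[start:start + length] = 1
        if spec.effect_size > 0 and labels.any():
            mask = labels.astype(bool)
            for name in _SHIFTED_CHANNELS:
                _mu, sd = _BASELINES[name]
                raw[name][mask] += spec.effect_size * sd

        conservation = np.clip(raw["conservation"], 0.0, 1.0)
        disorder = np.clip(raw["disorder"], 0.0, 1.0)
        rel_acc = np.clip(raw["rel_acc"], 0.0, 1.0)
        accessibility = np.column_stack([rel_acc, (rel_acc > 0.25).astype(float)])
        tracks = TrackSet(
            conservation=conservation,
            entropy=entropy,
            n_align=np.full(n, n_align, dtype=float),
            ss3=ss3,
            accessibility=accessibility,
            disorder=disorder,
        )
        chains.append(SyntheticChain(
            chain_id=f"syn{p:04d}",
            sequence=sequence,
            tracks=tracks,
            residue_labels=labels,
            is_binder=bool(binder_flags[p]),
        ))
    return PlantedDataset(chains=chains, spec=spec)


def write_planted_dataset(dataset: PlantedDataset, out_dir) -> None:
    """Write FASTA, per-chain track TSVs, a label table and a manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "sequences.fasta", "w") as fh:
        for c in dataset.chains:
            fh.write(f">{c.chain_id}\n{c.sequence}\n")
    label_rows = []
    for c in dataset.chains:
        tdir = out / "tracks" / c.chain_id
        tdir.mkdir(parents=True, exist_ok=True)
        n = len(c.sequence)
        idx = np.arange(n)
        t = c.tracks
        pd.DataFrame({"residue_index": idx, "conservation": t.conservation}
                     ).to_csv(tdir / "conservation.tsv", sep="\t", index=False)
        pd.DataFrame({"residue_index": idx, "entropy": t.entropy}
                     ).to_csv(tdir / "entropy.tsv", sep="\t", index=False)
        pd.DataFrame({"residue_index": idx, "n_align": t.n_align}
                     ).to_csv(tdir / "n_align.tsv", sep="\t", index=False)
        pd.DataFrame({"residue_index": idx, "helix": t.ss3[:, 0],
                      "strand": t.ss3[:, 1], "other": t.ss3[:, 2]}
                     ).to_csv(tdir / "ss3.tsv", sep="\t", index=False)
        pd.DataFrame({"residue_index": idx, "rel_acc": t.accessibility[:, 0],
                      "exposed": t.accessibility[:, 1]}
                     ).to_csv(tdir / "accessibility.tsv", sep="\t", index=False)
        pd.DataFrame({"residue_index": idx, "disorder": t.disorder}
                     ).to_csv(tdir / "disorder.tsv", sep="\t", index=False)
        for i in range(n):
            label_rows.append((c.chain_id, i, int(c.residue_labels[i])))
    pd.DataFrame(label_rows, columns=["chain_id", "residue_index", "label"]
                 ).to_csv(out / "residue_labels.tsv", sep="\t", index=False)
    pd.DataFrame({
        "chain_id": dataset.ids,
        "is_binder": dataset.protein_labels,
    }).to_csv(out / "protein_labels.tsv", sep="\t", index=False)
    manifest = {
        "seed": dataset.spec.seed,
        "n_proteins": dataset.spec.n_proteins,
        "fraction_binders": dataset.spec.fraction_binders,
        "effect_size": dataset.spec.effect_size,
        "length_range": list(dataset.spec.length_range),
        "n_binders": int(dataset.protein_labels.sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
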