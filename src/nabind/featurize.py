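"""Windowed per-residue feature vectors (246 features by default).

Each residue is described by sliding windows over sequence and
per-residue descriptor tracks: a window of nine residues for the
evolutionary profile (amino-acid identity, conservation, entropy) and a
window of seven for predicted secondary structure, disorder and solvent
accessibility, plus chain-level alignment depth, physicochemical
descriptors of the central residue and a terminal-distance feature.
Positions beyond the chain termini are zero-padded so every vector has
the full schema width.

The total of 246 is fixed by the method; the exact decomposition below is
this package's documented schema and any alternative schema with the same
total can be plugged in via YAML.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from nabind.structure import AA20, LabeledChain

LOG2_20 = math.log2(20.0)

# Kyte-Doolittle hydrophobicity (scaled to [-1,1]), net charge at pH 7,
# polarity flag, side-chain volume (A^3, scaled by TRP = 227.8)
_PHYSCHEM: dict[str, tuple[float, float, float, float]] = {
    "A": (1.8 / 4.5, 0, 0, 88.6 / 227.8),
    "C": (2.5 / 4.5, 0, 0, 108.5 / 227.8),
    "D": (-3.5 / 4.5, -1, 1, 111.1 / 227.8),
    "E": (-3.5 / 4.5, -1, 1, 138.4 / 227.8),
    "F": (2.8 / 4.5, 0, 0, 189.9 / 227.8),
    "G": (-0.4 / 4.5, 0, 0, 60.1 / 227.8),
    "H": (-3.2 / 4.5, 0.1, 1, 153.2 / 227.8),
    "I": (4.5 / 4.5, 0, 0, 166.7 / 227.8),
    "K": (-3.9 / 4.5, 1, 1, 168.6 / 227.8),
    "L": (3.8 / 4.5, 0, 0, 166.7 / 227.8),
    "M": (1.9 / 4.5, 0, 0, 162.9 / 227.8),
    "N": (-3.5 / 4.5, 0, 1, 114.1 / 227.8),
    "P": (-1.6 / 4.5, 0, 0, 112.7 / 227.8),
    "Q": (-3.5 / 4.5, 0, 1, 143.8 / 227.8),
    "R": (-4.5 / 4.5, 1, 1, 173.4 / 227.8),
    "S": (-0.8 / 4.5, 0, 1, 89.0 / 227.8),
    "T": (-0.7 / 4.5, 0, 1, 116.1 / 227.8),
    "V": (4.2 / 4.5, 0, 0, 140.0 / 227.8),
    "W": (-0.9 / 4.5, 0, 0, 227.8 / 227.8),
    "Y": (-1.3 / 4.5, 0, 1, 193.6 / 227.8),
}


@dataclass
class TrackSet:
    """Aligned per-residue descriptor channels for one chain.

    conservation in [0,1]; entropy in bits (0..log2 20); n_align >= 1
    (alignment depth, broadcast per residue); ss3 rows ~ 1-simplex
    (helix, strand, other); accessibility = (relative accessibility in
    [0,1], exposed flag); disorder in [0,1].
    """

    conservation: np.ndarray
    entropy: np.ndarray
    n_align: np.ndarray
    ss3: np.ndarray
    accessibility: np.ndarray
    disorder: np.ndarray

    def __post_init__(self):
        self.conservation = np.asarray(self.conservation, dtype=float)
        self.entropy = np.asarray(self.entropy, dtype=float)
        n = len(self.conservation)
        n_align = np.asarray(self.n_align, dtype=float)
        if n_align.ndim == 0:
            n_align = np.full(n, float(n_align))
        self.n_align = n_align
        self.ss3 = np.asarray(self.ss3, dtype=float)
        self.accessibility = np.asarray(self.accessibility, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.conservation)

    def validate(self) -> None:
        n = len(self.conservation)
        shapes = {
            "conservation": (self.conservation, (n,)),
            "entropy": (self.entropy, (n,)),
            "n_align": (self.n_align, (n,)),
            "ss3": (self.ss3, (n, 3)),
            "accessibility": (self.accessibility, (n, 2)),
            "disorder": (self.disorder, (n,)),
        }
        for name, (arr, shape) in shapes.items():
            if arr.shape != shape:
                raise ValueError(f"track {name}: shape {arr.shape} != {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"track {name}: non-finite values")
        _range_check("conservation", self.conservation, 0.0, 1.0)
        _range_check("entropy", self.entropy, 0.0, LOG2_20 + 1e-9)
        _range_check("disorder", self.disorder, 0.0, 1.0)
        _range_check("accessibility", self.accessibility[:, 0], 0.0, 1.0)
        if np.any(self.n_align < 1):
            raise ValueError("track n_align: alignment depth below 1")
        sums = self.ss3.sum(axis=1)
        bad = np.where((sums < 0.9) | (sums > 1.1))[0]
        if bad.size:
            raise ValueError(
                f"track ss3: row {bad[0]} sums to {sums[bad[0]]:.3f}, "
                "outside the 0.9-1.1 simplex tolerance"
            )


def _range_check(name: str, arr: np.ndarray, lo: float, hi: float) -> None:
    if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
        raise ValueError(f"track {name}: values outside [{lo}, {hi}]")


@dataclass(frozen=True)
class Channel:
    name: str
    values_per_residue: int
    window: int              # odd; 1 means no neighbours
    padding: float = 0.0

    def __post_init__(self):
        if self.window % 2 != 1:
            raise ValueError(f"channel {self.name}: window must be odd")

    @property
    def width(self) -> int:
        return self.values_per_residue * self.window


@dataclass(frozen=True)
class FeatureSchema:
    channels: tuple[Channel, ...]

    @property
    def total(self) -> int:
        return sum(c.width for c in self.channels)

    @property
    def fingerprint(self) -> str:
        desc = ";".join(
            f"{c.name}:{c.values_per_residue}x{c.window}p{c.padding}"
            for c in self.channels
        )
        return hashlib.sha1(desc.encode()).hexdigest()[:12]

    def column_names(self) -> list[str]:
        names = []
        for c in self.channels:
            half = c.window // 2
            for off in range(-half, half + 1):
                for j in range(c.values_per_residue):
                    suffix = f".{j}" if c.values_per_residue > 1 else ""
                    names.append(f"{c.name}[{off:+d}]{suffix}")
        return names

    def channel_slice(self, name: str) -> slice:
        start = 0
        for c in self.channels:
            if c.name == name:
                return slice(start, start + c.width)
            start += c.width
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                [{"name": c.name, "values_per_residue": c.values_per_residue,
                  "window": c.window, "padding": c.padding}
                 for c in self.channels],
                fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tuple(Channel(**entry) for entry in raw))


#: 20x9 + 1x9 + 1x9 + 1x1 + 3x7 + 1x7 + 2x7 + 4x1 + 1x1 = 246
DEFAULT_SCHEMA = FeatureSchema((
    Channel("aa_onehot", 20, 9),
    Channel("conservation", 1, 9),
    Channel("entropy", 1, 9),
    Channel("n_align", 1, 1),
    Channel("ss3", 3, 7),
    Channel("disorder", 1, 7),
    Channel("accessibility", 2, 7),
    Channel("physchem", 4, 1),
    Channel("terminal_distance", 1, 1),
))


@dataclass
class FeatureMatrix:
    values: np.ndarray           # n_residues x schema.total
    mask: np.ndarray             # training-eligible residues
    column_names: list[str]
    schema_fingerprint: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.mask):
            raise ValueError("feature matrix / mask shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


def conservation_from_msa(
    msa: Sequence[tuple[str, str]] | Mapping[str, str],
    query: Union[int, str] = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue conservation, entropy (bits) and alignment depth from an
    alignment.

    Columns are taken where the query row is ungapped.  Amino-acid
    frequencies use a pseudocount of 1/20 per symbol; entropy is computed
    over the 20 standard residues with gaps excluded from the counts, and
    conservation = 1 - entropy / log2(20).  ``n_align`` is the number of
    sequences with a non-gap character at the column.
    """
    if isinstance(msa, Mapping):
        items = list(msa.items())
    else:
        items = list(msa)
    rows = [seq.upper() for _sid, seq in items]
    ids = [sid for sid, _seq in items]
    if isinstance(query, str):
        if query not in ids:
            raise ValueError(f"query {query!r} not in MSA")
        qrow = rows[ids.index(query)]
    else:
        if not 0 <= query < len(rows):
            raise ValueError(f"query row {query} not in MSA")
        qrow = rows[query]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("MSA rows have unequal lengths")

    aa_index = {a: i for i, a in enumerate(AA20)}
    cols = [j for j, c in enumerate(qrow) if c not in "-."]
    conservation = np.zeros(len(cols))
    entropy = np.zeros(len(cols))
    n_align = np.zeros(len(cols))
    for out_i, j in enumerate(cols):
        counts = np.full(20, 1.0 / 20.0)          # pseudocount
        depth = 0
        for row in rows:
            c = row[j]
            if c in "-.":
                continue
            depth += 1
            if c in aa_index:
                counts[aa_index[c]] += 1.0
        p = counts / counts.sum()
        h = float(-(p * np.log2(p)).sum())
        entropy[out_i] = h
        conservation[out_i] = max(0.0, 1.0 - h / LOG2_20)
        n_align[out_i] = max(depth, 1)
    return conservation, entropy, n_align


_TRACK_FILES = {
    "conservation": 1, "entropy": 1, "n_align": 1,
    "ss3": 3, "accessibility": 2, "disorder": 1,
}


def load_tracks(files: Mapping[str, Union[str, Path]], n_residues: int) -> TrackSet:
    """Load one TSV per channel (residue_index, value columns) and validate.

    Row counts must equal ``n_residues``; out-of-range or non-numeric
    entries are rejected with the file and row named.
    """
    import pandas as pd

    arrays: dict[str, np.ndarray] = {}
    for name, ncols in _TRACK_FILES.items():
        path = files[name]
        df = pd.read_csv(path, sep="\t")
        if len(df) != n_residues:
            raise ValueError(
                f"{path}: {len(df)} rows for a {n_residues}-residue chain")
        value_cols = [c for c in df.columns if c != "residue_index"]
        if len(value_cols) != ncols:
            raise ValueError(f"{path}: expected {ncols} value columns")
        block = df[value_cols].to_numpy()
        try:
            block = block.astype(float)
        except (TypeError, ValueError):
            bad = df[value_cols].apply(
                pd.to_numeric, errors="coerce").isna().any(axis=1)
            raise ValueError(
                f"{path}: non-numeric entry at row {int(np.where(bad)[0][0])}"
            ) from None
        arrays[name] = block[:, 0] if ncols == 1 else block
    return TrackSet(**arrays)


def _sequence_channels(sequence: str) -> dict[str, np.ndarray]:
    n = len(sequence)
    onehot = np.zeros((n, 20))
    phys = np.zeros((n, 4))
    for i, c in enumerate(sequence):
        j = AA20.find(c)
        if j >= 0:
            onehot[i, j] = 1.0
            phys[i] = _PHYSCHEM[c]
    pos = np.arange(n, dtype=float)
    term = np.minimum(pos, n - 1 - pos)[:, None] / max(n, 1)
    return {"aa_onehot": onehot, "physchem": phys, "terminal_distance": term}


def _channel_matrix(name: str, sequence: str, tracks: TrackSet) -> np.ndarray:
    seq_channels = _sequence_channels(sequence)
    if name in seq_channels:
        return seq_channels[name]
    if name == "conservation":
        return tracks.conservation[:, None]
    if name == "entropy":
        return tracks.entropy[:, None]
    if name == "n_align":
        return np.log10(tracks.n_align)[:, None]
    if name == "ss3":
        return tracks.ss3
    if name == "disorder":
        return tracks.disorder[:, None]
    if name == "accessibility":
        return tracks.accessibility
    raise KeyError(f"unknown feature channel {name!r}")


def _windowed(values: np.ndarray, window: int, padding: float) -> np.ndarray:
    n, k = values.shape
    half = window // 2
    out = np.full((n, window * k), padding, dtype=float)
    for w, off in enumerate(range(-half, half + 1)):
        lo, hi = max(0, -off), min(n, n - off)
        out[lo:hi, w * k:(w + 1) * k] = values[lo + off:hi + off]
    return out


def featurize_chain(
    chain: Union[LabeledChain, str],
    tracks: TrackSet,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> FeatureMatrix:
    """One feature row per residue; the row mask marks training-eligible
    (structure-resolved) residues.  Unresolved residues are masked out of
    training but still contribute their channel values to neighbouring
    windows."""
    if isinstance(chain, LabeledChain):
        sequence, mask = chain.sequence, chain.resolved_mask
    else:
        sequence, mask = chain, np.ones(len(chain), dtype=bool)
    if len(tracks) != len(sequence):
        raise ValueError(
            f"tracks length {len(tracks)} != chain length {len(sequence)}")
    blocks = [
        _windowed(_channel_matrix(c.name, sequence, tracks), c.window, c.padding)
        for c in schema.channels
    ]
    return FeatureMatrix(
        values=np.hstack(blocks),
        mask=mask,
        column_names=schema.column_names(),
        schema_fingerprint=schema.fingerprint,
    )


def assemble_vector(
    chain: Union[LabeledChain, str],
    tracks: TrackSet,
    schema: FeatureSchema,
    i: int,
) -> np.ndarray:
    """The single feature vector of residue ``i`` (schema order, termini
    zero-padded)."""
    n = len(chain.sequence if isinstance(chain, LabeledChain) else chain)
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for length {n}")
    return featurize_chain(chain, tracks, schema).values[i]
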