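"""Protein-level features summarising the per-residue score distribution.

The second-stage classifier never sees the sequence, only 15 features of
the first stage's score track: the chain length, the highest score, seven
counts of residues scoring strictly above 0.7 ... 0.1, the number of
4-residue windows in which at least two residues score above 0.3, and
counts of residues whose within-protein Z-score exceeds 3, 2, 1 and 0.5
or falls below -2.  All "above"/"below" comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

PROTEIN_FEATURE_NAMES: tuple[str, ...] = (
    "length",
    "max_score",
    "n_above_0.7",
    "n_above_0.6",
    "n_above_0.5",
    "n_above_0.4",
    "n_above_0.3",
    "n_above_0.2",
    "n_above_0.1",
    "n_windows4_2above_0.3",
    "n_z_above_3",
    "n_z_above_2",
    "n_z_above_1",
    "n_z_above_0.5",
    "n_z_below_-2",
)

SCORE_THRESHOLDS = (0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class ResidueScoreTrack:
    """Per-residue binding-site scores in [0,1] for one chain."""

    scores: np.ndarray
    chain_id: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) < 1:
            raise ValueError("score track must be a non-empty 1-D array")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0,1]")

    def __len__(self) -> int:
        return len(self.scores)


def _as_scores(track) -> np.ndarray:
    if isinstance(track, ResidueScoreTrack):
        return track.scores
    arr = np.asarray(track, dtype=float)
    if arr.ndim != 1 or len(arr) < 1:
        raise ValueError("score track must be a non-empty 1-D array")
    return arr


def zscores(track) -> np.ndarray:
    """Within-protein standardized scores (population SD; all zero when the
    track is constant)."""
    s = _as_scores(track)
    sd = float(np.std(s))          # population SD
    if sd == 0.0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def aggregate(track, z3_two_sided: bool = False) -> np.ndarray:
    """The 15 protein-level distribution features of a score track.

    ``z3_two_sided`` switches the Z>3 count to |Z|>3 (an alternative
    reading of the tail feature); the default is the upper tail only,
    since the below-tail has its own feature (Z < -2).
    """
    s = _as_scores(track)
    n = len(s)
    z = zscores(s)
    features = [float(n), float(s.max())]
    features += [float(np.sum(s > t)) for t in SCORE_THRESHOLDS]
    if n >= 4:
        above = (s > 0.3).astype(int)
        window_hits = np.convolve(above, np.ones(4, dtype=int), mode="valid")
        features.append(float(np.sum(window_hits >= 2)))
    else:
        features.append(0.0)
    z3 = np.sum(np.abs(z) > 3) if z3_two_sided else np.sum(z > 3)
    features.append(float(z3))
    features += [float(np.sum(z > t)) for t in (2, 1, 0.5)]
    features.append(float(np.sum(z < -2)))
    return np.array(features)


def aggregate_many(tracks: Iterable, z3_two_sided: bool = False) -> np.ndarray:
    """Stack :func:`aggregate` over several tracks into an n x 15 matrix."""
    return np.vstack([aggregate(t, z3_two_sided=z3_two_sided) for t in tracks])


def write_protein_features_tsv(ids, F: np.ndarray, path) -> None:
    import pandas as pd

    df = pd.DataFrame(F, columns=list(PROTEIN_FEATURE_NAMES))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)
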