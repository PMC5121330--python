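"""Random-forest stages, grouped cross-validation and the majority rule.

Stage 1 scores residues (fraction of trees voting "binding"); stage 2
scores whole proteins from the 15 aggregated track features.  Both use
1,000 trees by default and 3-fold cross-validation in which homologous
chains (same redundancy cluster) never straddle a train/test boundary.
The final protein score is the 2-of-3 majority combination over the fold
models: the largest cutoff at which at least two models still call the
protein positive, which equals the median of the three scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from nabind.aggregate import ResidueScoreTrack, aggregate
from nabind.featurize import DEFAULT_SCHEMA, FeatureMatrix, TrackSet, featurize_chain
from nabind.redundancy import ClusterAssignment, FoldAssignment


@dataclass
class TrainingConfig:
    n_trees: int = 1000
    seed: int = 0
    max_features: Union[str, int, float] = "sqrt"   # per-tree feature sampling
    class_weight: Optional[str] = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class SchemaMismatchError(ValueError):
    pass


@dataclass
class FittedModel:
    """A fitted forest plus the schema fingerprint it expects."""

    estimator: RandomForestClassifier
    schema_fingerprint: str
    n_features: int
    fold_id: Optional[int] = None

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise SchemaMismatchError(
                f"model expects {self.n_features} features, got {X.shape[1]}")
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(X)[:, pos]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedModel":
        return joblib.load(path)


ResidueModel = FittedModel
ProteinModel = FittedModel


def _fit(X, y, cfg: TrainingConfig, fingerprint: str,
         fold_id: Optional[int]) -> FittedModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return FittedModel(
        estimator=est,
        schema_fingerprint=fingerprint,
        n_features=X.shape[1],
        fold_id=fold_id,
    )


def train_residue_model(
    X: Union[FeatureMatrix, np.ndarray],
    y: Sequence[int],
    cfg: TrainingConfig,
    fold_id: Optional[int] = None,
) -> ResidueModel:
    """Fit the stage-1 forest on residue feature rows; deterministic given
    the config seed."""
    if isinstance(X, FeatureMatrix):
        fingerprint, values = X.schema_fingerprint, X.values
    else:
        fingerprint, values = "", np.asarray(X, dtype=float)
    return _fit(values, y, cfg, fingerprint, fold_id)


def predict_residues(
    model: ResidueModel, X: Union[FeatureMatrix, np.ndarray],
    chain_id: str = "",
) -> ResidueScoreTrack:
    """Score every residue row; scores are tree-vote fractions in [0,1]."""
    if isinstance(X, FeatureMatrix):
        if model.schema_fingerprint and X.schema_fingerprint != model.schema_fingerprint:
            raise SchemaMismatchError(
                "feature matrix schema does not match the model's schema")
        values = X.values
    else:
        values = X
    return ResidueScoreTrack(model.predict_scores(values), chain_id=chain_id)


def train_protein_model(
    F: np.ndarray, y: Sequence[int], cfg: TrainingConfig,
    fold_id: Optional[int] = None,
) -> ProteinModel:
    """Fit the stage-2 forest on 15-feature protein rows."""
    return _fit(F, y, cfg, fingerprint="protein15", fold_id=fold_id)


@dataclass
class ChainExamples:
    """Featurized training material for one chain."""

    chain_id: str
    X: FeatureMatrix
    y: np.ndarray                # per-residue labels (full-length)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.values.shape[0]:
            raise ValueError(f"{self.chain_id}: labels do not match matrix rows")


@dataclass
class CrossValResult:
    models: dict[int, FittedModel]           # fold -> model trained OFF that fold
    oof_tracks: dict[str, ResidueScoreTrack]  # chain id -> out-of-fold scores
    fold_of_chain: dict[str, int]


def cross_validate(
    dataset: Sequence[ChainExamples],
    clusters: ClusterAssignment,
    folds: FoldAssignment,
    cfg: TrainingConfig,
) -> CrossValResult:
    """Grouped k-fold: each fold's model is trained on the other folds'
    residues (masked rows excluded) and scores only its own fold's chains.

    Raises if any chain would be scored by a model whose training folds
    include its own cluster — the homology-leakage guard.
    """
    fold_of_chain = {
        c.chain_id: folds.fold_of(clusters, c.chain_id) for c in dataset
    }
    models: dict[int, FittedModel] = {}
    oof: dict[str, ResidueScoreTrack] = {}
    for f in range(folds.k):
        train_chains = [c for c in dataset if fold_of_chain[c.chain_id] != f]
        test_chains = [c for c in dataset if fold_of_chain[c.chain_id] == f]
        if not train_chains or not test_chains:
            raise ValueError(f"fold {f} has an empty train or test side")
        X = np.vstack([c.X.values[c.X.mask] for c in train_chains])
        y = np.concatenate([c.y[c.X.mask] for c in train_chains])
        fold_cfg = TrainingConfig(
            n_trees=cfg.n_trees, seed=cfg.seed + f,
            max_features=cfg.max_features, class_weight=cfg.class_weight)
        model = _fit(X, y, fold_cfg,
                     train_chains[0].X.schema_fingerprint, fold_id=f)
        models[f] = model
        for c in test_chains:
            if fold_of_chain[c.chain_id] != f:   # leakage guard
                raise RuntimeError(
                    f"chain {c.chain_id} scored by a model trained on its fold")
            oof[c.chain_id] = predict_residues(model, c.X, chain_id=c.chain_id)
    return CrossValResult(models=models, oof_tracks=oof,
                          fold_of_chain=fold_of_chain)


def cross_validate_proteins(
    ids: Sequence[str],
    F: np.ndarray,
    y: Sequence[int],
    clusters: ClusterAssignment,
    folds: FoldAssignment,
    cfg: TrainingConfig,
) -> tuple[dict[int, ProteinModel], dict[str, float]]:
    """Grouped k-fold for the stage-2 classifier; returns the fold models
    and each protein's out-of-fold score."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=int)
    fold_of = {pid: folds.fold_of(clusters, pid) for pid in ids}
    models: dict[int, ProteinModel] = {}
    oof: dict[str, float] = {}
    for f in range(folds.k):
        train_idx = [i for i, pid in enumerate(ids) if fold_of[pid] != f]
        test_idx = [i for i, pid in enumerate(ids) if fold_of[pid] == f]
        if not train_idx or not test_idx:
            raise ValueError(f"fold {f} has an empty train or test side")
        fold_cfg = TrainingConfig(
            n_trees=cfg.n_trees, seed=cfg.seed + 100 + f,
            max_features=cfg.max_features, class_weight=cfg.class_weight)
        model = train_protein_model(F[train_idx], y[train_idx], fold_cfg, fold_id=f)
        models[f] = model
        scores = model.predict_scores(F[test_idx])
        for i, s in zip(test_idx, scores):
            oof[ids[i]] = float(s)
    return models, oof


def combine_majority(scores: Sequence[float]) -> float:
    """2-of-3 majority combination of the fold models' scores.

    The combined score is the largest cutoff t at which at least two of
    the three models still score >= t; that quantity is exactly the median
    of the three scores.
    """
    if len(scores) != 3:
        raise ValueError("majority combination requires exactly three scores")
    arr = np.asarray(scores, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("model scores must lie in [0,1]")
    return float(np.median(arr))


def end_to_end_predict(
    sequence: str,
    tracks: TrackSet,
    residue_models: Sequence[ResidueModel],
    protein_models: Sequence[ProteinModel],
    schema=DEFAULT_SCHEMA,
    z3_two_sided: bool = False,
) -> tuple[float, ResidueScoreTrack, list[float]]:
    """Score a novel sequence with the full two-stage pipeline.

    The residue track averages the fold models' votes; the protein score
    is the majority combination of the three stage-2 models applied to the
    aggregated track features.  Returns (combined protein score, residue
    track, per-model protein scores).
    """
    if not residue_models or len(protein_models) != 3:
        raise ValueError("need residue models and exactly three protein models")
    X = featurize_chain(sequence, tracks, schema)
    per_model = np.vstack([predict_residues(m, X).scores for m in residue_models])
    track = ResidueScoreTrack(per_model.mean(axis=0))
    F = aggregate(track, z3_two_sided=z3_two_sided)[None, :]
    protein_scores = [float(m.predict_scores(F)[0]) for m in protein_models]
    return combine_majority(protein_scores), track, protein_scores
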