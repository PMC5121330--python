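"""End-to-end orchestration: simulate/build -> featurize -> train -> evaluate.

``run_two_stage`` is the in-memory core: grouped 3-fold CV of the residue
classifier, aggregation of the out-of-fold score tracks into the 15
protein features, grouped CV of the protein classifier, and both levels'
evaluation.  ``run_pipeline`` wraps it for the CLI, writing every
intermediate artifact as plain-text tables plus a manifest carrying the
config hash and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from nabind.aggregate import (
    PROTEIN_FEATURE_NAMES, ResidueScoreTrack, aggregate_many,
    write_protein_features_tsv,
)
from nabind.config import RunConfig
from nabind.featurize import DEFAULT_SCHEMA, FeatureSchema, featurize_chain
from nabind.metrics import auc, pr_curve, random_baseline, roc_curve
from nabind.models import (
    ChainExamples, TrainingConfig, cross_validate, cross_validate_proteins,
)
from nabind.redundancy import ClusterAssignment, cluster, make_folds
from nabind.synthetic import (
    PlantedDataset, PlantedDatasetSpec, make_planted_dataset,
    write_planted_dataset,
)

logger = logging.getLogger("nabind")


@dataclass
class TwoStageResult:
    stage1_auc: float                 # residue-level out-of-fold ROC AUC
    stage1_pr_auc: float
    stage2_auc: float                 # protein-level out-of-fold ROC AUC
    stage2_pr_auc: float
    residue_baseline: float           # fraction of binding residues
    protein_baseline: float           # fraction of binder proteins
    oof_tracks: dict[str, ResidueScoreTrack]
    oof_protein_scores: dict[str, float]
    residue_models: dict
    protein_models: dict
    fold_of_chain: dict[str, int]


def run_two_stage(
    dataset: PlantedDataset,
    n_trees: int = 1000,
    k: int = 3,
    seed: int = 0,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    clusters: Optional[ClusterAssignment] = None,
    z3_two_sided: bool = False,
) -> TwoStageResult:
    """Run both classification stages with grouped cross-validation.

    Synthetic chains are mutually non-homologous by construction, so the
    default grouping is one singleton cluster per chain; pass ``clusters``
    to use a redundancy clustering instead.
    """
    if clusters is None:
        clusters = ClusterAssignment.singletons(dataset.ids)
    weights = {
        clusters.assignment[c.chain_id]: 0 for c in dataset.chains
    }
    for c in dataset.chains:
        weights[clusters.assignment[c.chain_id]] += len(c.sequence)
    folds = make_folds(clusters, k=k, seed=seed, weights=weights)

    examples = [
        ChainExamples(
            chain_id=c.chain_id,
            X=featurize_chain(c.sequence, c.tracks, schema),
            y=c.residue_labels,
        )
        for c in dataset.chains
    ]
    logger.info("featurized %d chains (%d residues, %d features)",
                len(examples), sum(len(e.y) for e in examples),
                examples[0].X.values.shape[1] if examples else 0)

    cfg = TrainingConfig(n_trees=n_trees, seed=seed)
    cv = cross_validate(examples, clusters, folds, cfg)

    res_scores = np.concatenate(
        [cv.oof_tracks[c.chain_id].scores for c in dataset.chains])
    res_labels = np.concatenate([c.residue_labels for c in dataset.chains])
    stage1_auc = auc(roc_curve(res_scores, res_labels))
    stage1_pr = auc(pr_curve(res_scores, res_labels))

    tracks = [cv.oof_tracks[c.chain_id] for c in dataset.chains]
    F = aggregate_many(tracks, z3_two_sided=z3_two_sided)
    y_prot = dataset.protein_labels
    prot_models, oof_prot = cross_validate_proteins(
        dataset.ids, F, y_prot, clusters, folds, cfg)
    prot_scores = np.array([oof_prot[pid] for pid in dataset.ids])
    stage2_auc = auc(roc_curve(prot_scores, y_prot))
    stage2_pr = auc(pr_curve(prot_scores, y_prot))

    return TwoStageResult(
        stage1_auc=stage1_auc,
        stage1_pr_auc=stage1_pr,
        stage2_auc=stage2_auc,
        stage2_pr_auc=stage2_pr,
        residue_baseline=random_baseline(res_labels),
        protein_baseline=random_baseline(y_prot),
        oof_tracks=cv.oof_tracks,
        oof_protein_scores=oof_prot,
        residue_models=cv.models,
        protein_models=prot_models,
        fold_of_chain=cv.fold_of_chain,
    )


def run_pipeline(config: RunConfig, out_dir, use_clustering: bool = True) -> dict:
    """Demo pipeline over a planted synthetic dataset; writes all artifacts.

    Stages: simulate -> cluster -> fold -> featurize -> stage-1 CV ->
    aggregate -> stage-2 CV -> evaluate.  Any failure aborts with the
    stage named.  Returns the manifest dictionary.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        spec = PlantedDatasetSpec(
            n_proteins=config.sim_n_proteins,
            fraction_binders=config.sim_fraction_binders,
            effect_size=config.sim_effect_size,
            seed=config.seed,
        )
        dataset = make_planted_dataset(spec)
        write_planted_dataset(dataset, out / "dataset")
        logger.info("simulated %d chains (%d binders)",
                    len(dataset.chains), int(dataset.protein_labels.sum()))

        stage = "cluster"
        if use_clustering:
            clusters = cluster(
                {c.chain_id: c.sequence for c in dataset.chains},
                identity_thr=config.identity_thr,
                coverage_thr=config.coverage_thr,
            )
        else:
            clusters = ClusterAssignment.singletons(dataset.ids)
        logger.info("%d clusters from %d chains",
                    len(clusters.representatives), len(dataset.chains))

        stage = "train-evaluate"
        schema = (FeatureSchema.from_yaml(config.schema_path)
                  if config.schema_path else DEFAULT_SCHEMA)
        result = run_two_stage(
            dataset, n_trees=config.n_trees, k=config.k_folds,
            seed=config.seed, schema=schema, clusters=clusters,
            z3_two_sided=config.z3_two_sided,
        )

        stage = "write-artifacts"
        rows = []
        for c in dataset.chains:
            track = result.oof_tracks[c.chain_id]
            for i, s in enumerate(track.scores):
                rows.append((c.chain_id, i, float(s), int(c.residue_labels[i])))
        pd.DataFrame(rows, columns=["chain_id", "residue_index", "score", "label"]
                     ).to_csv(out / "residue_scores.tsv", sep="\t", index=False)
        F = aggregate_many([result.oof_tracks[pid] for pid in dataset.ids],
                           z3_two_sided=config.z3_two_sided)
        write_protein_features_tsv(dataset.ids, F, out / "protein_features.tsv")
        pd.DataFrame({
            "chain_id": dataset.ids,
            "oof_score": [result.oof_protein_scores[p] for p in dataset.ids],
            "is_binder": dataset.protein_labels,
            "fold": [result.fold_of_chain[p] for p in dataset.ids],
        }).to_csv(out / "protein_scores.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "stage1_roc_auc": result.stage1_auc,
            "stage1_pr_auc": result.stage1_pr_auc,
            "stage2_roc_auc": result.stage2_auc,
            "stage2_pr_auc": result.stage2_pr_auc,
            "residue_random_baseline": result.residue_baseline,
            "protein_random_baseline": result.protein_baseline,
        }]).to_csv(out / "metrics.tsv", sep="\t", index=False)

        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for f, m in result.residue_models.items():
            m.save(models_dir / f"residue_fold{f}.joblib")
        for f, m in result.protein_models.items():
            m.save(models_dir / f"protein_fold{f}.joblib")

        manifest = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "n_chains": len(dataset.chains),
            "n_binders": int(dataset.protein_labels.sum()),
            "n_clusters": len(clusters.representatives),
            "n_residues": int(sum(len(c.sequence) for c in dataset.chains)),
            "stage1_roc_auc": result.stage1_auc,
            "stage2_roc_auc": result.stage2_auc,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
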