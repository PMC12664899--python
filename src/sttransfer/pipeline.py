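"""End-to-end orchestration: align -> integrate -> teach -> graph -> annotate.

One global seed fans out to per-stage seeds by fixed offsets (+1 VAE,
+2 teacher, +3 annotator) and is recorded, with a config hash, in the run
manifest. When an output directory is given, each stage's artifact is
cached there and reused on rerun if the config hash matches, so a run is
resumable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotator import AnnotatorConfig, AnnotatorState, predict_labels, train_annotator
from .graph import SpatialGraph, build_graph, normalize_adjacency
from .io import DEFAULT_LABEL_KEY, ExpressionDataset, align_genes, read_dataset
from .metrics import EvaluationReport, evaluate
from .teacher import (TeacherModel, predict_distribution, predict_linear_distribution,
                      train_linear_teacher, train_teacher)
from .vae import LatentEmbedding, VAEConfig, VAEModel, encode_cells, fit_vae

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ref_path: str | None = None
    spatial_path: str | None = None
    out_dir: str | None = None
    label_key: str = DEFAULT_LABEL_KEY
    seed: int = 0
    vae: VAEConfig = field(default_factory=VAEConfig)
    skip_vae: bool = False          # ablation: joint log1p-PCA instead of the VAE
    teacher_backend: str = "xgboost"  # or "linear"
    k_n_fold: int = 5
    k_neighbors: int = 30
    theta: float | str = "auto"
    annotator: AnnotatorConfig = field(default_factory=AnnotatorConfig)

    def __post_init__(self):
        # fan the global seed out to the stages unless explicitly overridden
        if self.vae.seed == 0:
            self.vae.seed = self.seed + 1
        if self.annotator.seed == 0:
            self.annotator.seed = self.seed + 3

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PredictionResult:
    labels: np.ndarray
    probs: np.ndarray
    classes: list[str]
    cell_ids: list[str]
    teacher_labels: np.ndarray
    manifest: dict


def _pca_embedding(ref: ExpressionDataset, spatial: ExpressionDataset,
                   n_comp: int, seed: int) -> tuple[LatentEmbedding, LatentEmbedding]:
    """Joint log1p-CP10K PCA of both modalities (the no-VAE ablation)."""
    from sklearn.decomposition import PCA

    x = np.concatenate([ref.counts, spatial.counts]).astype(float)
    depth = np.maximum(x.sum(axis=1, keepdims=True), 1.0)
    x = np.log1p(x / depth * 1e4)
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    return (LatentEmbedding(emb[:ref.n_cells], list(ref.cell_ids), "reference"),
            LatentEmbedding(emb[ref.n_cells:], list(spatial.cell_ids), "spatial"))


def run_pipeline(cfg: PipelineConfig,
                 ref: ExpressionDataset | None = None,
                 spatial: ExpressionDataset | None = None,
                 ) -> tuple[PredictionResult, EvaluationReport | None]:
    """Run the five-stage annotation transfer; datasets may be passed
    in-memory or read from the configured paths."""
    t0 = time.time()
    if ref is None:
        if cfg.ref_path is None:
            raise ValueError("no reference dataset: set ref_path or pass ref")
        ref = read_dataset(cfg.ref_path, role="reference", label_key=cfg.label_key)
    if spatial is None:
        if cfg.spatial_path is None:
            raise ValueError("no spatial dataset: set spatial_path or pass spatial")
        spatial = read_dataset(cfg.spatial_path, role="spatial", label_key=cfg.label_key)
    if ref.labels is None:
        raise ValueError("stage 'teach' needs reference labels; none found "
                         f"(label key {cfg.label_key!r})")

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    chash = cfg.config_hash()
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # stage 0: gene alignment
    ref_a, sp_a = align_genes(ref, spatial)
    logger.info("aligned on %d shared genes", ref_a.n_genes)

    # stage 1: integration
    ssi = tti = None
    cache = out_dir / "embeddings.npz" if out_dir else None
    if cache and cache.exists():
        with np.load(cache, allow_pickle=True) as npz:
            if str(npz["config_hash"]) == chash:
                ssi = LatentEmbedding(npz["ssi"], list(ref_a.cell_ids), "reference")
                tti = LatentEmbedding(npz["tti"], list(sp_a.cell_ids), "spatial")
                logger.info("stage 1 skipped: cached embeddings reused")
    if ssi is None:
        if cfg.skip_vae:
            ssi, tti = _pca_embedding(ref_a, sp_a, cfg.vae.latent_dim, cfg.vae.seed)
        else:
            model = fit_vae(ref_a, sp_a, cfg.vae)
            if out_dir:
                model.save(out_dir / "vae")
            ssi = encode_cells(model, ref_a)
            tti = encode_cells(model, sp_a)
        if cache:
            np.savez(cache, ssi=ssi.values, tti=tti.values, config_hash=chash)

    # stage 2: teacher
    if cfg.teacher_backend == "linear":
        lt = train_linear_teacher(ssi, ref_a.labels, seed=cfg.seed + 2)
        d = predict_linear_distribution(lt, tti)
    else:
        teacher = train_teacher(ssi, ref_a.labels, k_n_fold=cfg.k_n_fold,
                                seed=cfg.seed + 2)
        if out_dir:
            teacher.save(out_dir / "teacher")
        d = predict_distribution(teacher, tti)
    teacher_labels = d.argmax_labels()

    # stage 3: spatial graph
    g = build_graph(sp_a.coords, k_neighbors=cfg.k_neighbors, theta=cfg.theta)
    normalize_adjacency(g)

    # stages 4-5: annotator training and prediction
    state = train_annotator(tti, g, d, cfg.annotator)
    if out_dir:
        state.save(out_dir / "annotator")
    labels, probs = predict_labels(state, tti, g)

    manifest = {
        "sttransfer_version": __version__,
        "config": asdict(cfg),
        "config_hash": chash,
        "stage_seeds": {"vae": cfg.vae.seed, "teacher": cfg.seed + 2,
                        "annotator": cfg.annotator.seed},
        "n_shared_genes": ref_a.n_genes,
        "n_spatial_cells": sp_a.n_cells,
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = PredictionResult(labels=labels, probs=probs, classes=state.classes,
                              cell_ids=list(sp_a.cell_ids),
                              teacher_labels=teacher_labels, manifest=manifest)

    report = None
    if spatial.labels is not None:
        report = evaluate(np.asarray(spatial.labels), labels,
                          spatial=sp_a, reference=ref_a)
        manifest["evaluation"] = {"accuracy": report.accuracy,
                                  "weighted_f1": report.weighted_f1}
        logger.info("accuracy %.4f, weighted F1 %.4f", report.accuracy, report.weighted_f1)

    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        pd.DataFrame({"cell_id": result.cell_ids, "predicted_type": labels,
                      "teacher_type": teacher_labels}).to_csv(
            out_dir / "predictions.tsv", sep="\t", index=False)
        adata = sp_a.to_anndata(label_key=cfg.label_key)
        adata.obs["sttransfer_pred"] = pd.Categorical(labels.astype(str))
        adata.obsm["sttransfer_probs"] = probs
        adata.uns["sttransfer_classes"] = list(state.classes)
        adata.write_h5ad(out_dir / "annotated_spatial.h5ad")
        if report is not None:
            (out_dir / "report.json").write_text(
                json.dumps(report.to_dict(), indent=2, default=str))
    return result, report
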