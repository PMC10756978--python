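"""End-to-end orchestration: preprocess -> embed -> render -> train -> evaluate.

One global seed fans out deterministically to per-stage seeds (a stable
hash of the stage name mixed with the global seed), so stages stay
independently reproducible while the whole run hangs off a single knob.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cnn_model, evaluation, gsn_image, io_preprocess, pacmap_core
from .io_preprocess import (
    FeatureMatrix, MultiOmicsDataset, NormalizeMethod, ValidationError,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Paths plus every knob of the five stages."""

    expression_path: str = ""
    methylation_path: str = ""
    cna_path: str = ""
    labels_path: str = ""
    gene_list_path: str | None = None
    approved_symbols_path: str | None = None
    out_dir: str = "run_output"

    variance_threshold: float = 0.002
    normalization: str = "minmax_per_gene"
    n_top_genes: int = 14  # fallback when no gene list is supplied

    n_nb: int = 10
    n_mn: int = 5
    n_fp: int = 20

    image_width: int = 64
    image_height: int = 64
    radius: float = 4.0
    margin: float = 2.0
    blend: str = "max"

    learning_rate: float = 0.05
    epochs: int = 80
    train_fraction: float = 0.70
    batch_size: int = 32
    stratified: bool = True

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    report: dict
    dataset: MultiOmicsDataset
    embedding: pacmap_core.Embedding2D
    template: gsn_image.GSNTemplate
    history: list[dict]
    manifest: dict = field(default_factory=dict)


def preprocess_dataset(
    expr: FeatureMatrix,
    meth: FeatureMatrix,
    cna: FeatureMatrix,
    labels: dict[str, int],
    class_names: list[str],
    config: PipelineConfig,
    gene_list: list[str] | None = None,
    approved: set[str] | None = None,
) -> MultiOmicsDataset:
    """Variance-filter expression, normalize, symbol-filter, align, subset.

    The variance filter runs on the raw expression values (it precedes
    normalization, which would rescale every gene into [0, 1] and void an
    absolute threshold); normalization and the approved-symbol filter then
    apply to all three omics.
    """
    expr = io_preprocess.filter_low_variance(expr, config.variance_threshold)
    method = NormalizeMethod(config.normalization)
    expr = io_preprocess.normalize_matrix(expr, method)
    meth = io_preprocess.normalize_matrix(meth, method)
    cna = io_preprocess.normalize_matrix(cna, method)
    if approved:
        expr = io_preprocess.filter_symbols(expr, approved)
        meth = io_preprocess.filter_symbols(meth, approved)
        cna = io_preprocess.filter_symbols(cna, approved)
    if gene_list is None:
        gene_list = io_preprocess.top_variance_genes(expr, config.n_top_genes)
        logger.info("no gene list supplied; using top-%d variance genes", config.n_top_genes)
    return io_preprocess.assemble_dataset(expr, meth, cna, labels, gene_list, class_names)


def run_from_matrices(
    expr: FeatureMatrix,
    meth: FeatureMatrix,
    cna: FeatureMatrix,
    labels: dict[str, int],
    class_names: list[str],
    config: PipelineConfig,
    gene_list: list[str] | None = None,
    approved: set[str] | None = None,
    write_artifacts: bool = True,
) -> PipelineResult:
    """Run every stage on in-memory matrices; optionally persist artifacts."""
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)

    dataset = preprocess_dataset(expr, meth, cna, labels, class_names, config,
                                 gene_list=gene_list, approved=approved)
    logger.info("dataset: %d genes x %d samples, %d classes",
                len(dataset.gene_ids), len(dataset.sample_ids), dataset.n_classes)

    # Genes are the embedded observations: one point per gene, its
    # coordinates the normalized expression across samples.
    pac_cfg = pacmap_core.PacmapConfig(
        n_nb=config.n_nb, n_mn=config.n_mn, n_fp=config.n_fp,
        seed=stage_seed(config.seed, "embed"),
    )
    embedding = pacmap_core.pacmap_embed(
        dataset.expression.values, pac_cfg, point_ids=dataset.gene_ids
    )

    template = gsn_image.fit_template(
        embedding, width=config.image_width, height=config.image_height,
        radius=config.radius, margin=config.margin,
    )
    images = gsn_image.render_dataset(
        dataset, template, blend=config.blend,
        out_dir=out / "images" if write_artifacts else None,
    )
    sample_ids, stack = gsn_image.image_stack(images)
    y = np.array([dataset.labels[s] for s in sample_ids])

    train_cfg = cnn_model.TrainConfig(
        learning_rate=config.learning_rate, epochs=config.epochs,
        train_fraction=config.train_fraction, batch_size=config.batch_size,
        seed=stage_seed(config.seed, "train"),
    )
    train_idx, test_idx = cnn_model.split_train_test(
        len(sample_ids), y, train_fraction=config.train_fraction,
        seed=stage_seed(config.seed, "split"), stratified=config.stratified,
    )
    model = cnn_model.build_cnn(
        (config.image_height, config.image_width, 3), dataset.n_classes,
        seed=stage_seed(config.seed, "init"),
    )
    history = cnn_model.train_cnn(
        model, stack[train_idx], y[train_idx], train_cfg,
        val_images=stack[test_idx], val_labels=y[test_idx],
    )
    probs = cnn_model.predict(model, stack[test_idx])
    report = evaluation.evaluate_predictions(y[test_idx], probs, dataset.class_names)
    report["n_train"] = int(train_idx.size)
    report["n_test"] = int(test_idx.size)
    report["final_train_accuracy"] = history[-1]["accuracy"]

    manifest = {"config": asdict(config), "stage_seeds": {
        s: stage_seed(config.seed, s) for s in ("embed", "split", "init", "train")
    }}
    if write_artifacts:
        pacmap_core.write_embedding_tsv(embedding, out / "embedding.tsv")
        template.to_json(out / "template.json")
        dataset.write_manifest(out / "dataset_manifest.json")
        with open(out / "history.csv", "w") as fh:
            cols = list(history[0].keys())
            fh.write(",".join(cols) + "\n")
            for row in history:
                fh.write(",".join(str(row[c]) for c in cols) + "\n")
        evaluation.write_report(report, out / "evaluation.json")
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(report=report, dataset=dataset, embedding=embedding,
                          template=template, history=history, manifest=manifest)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load the input tables named in ``config`` and run every stage."""
    try:
        expr = io_preprocess.read_omics_table(config.expression_path, "expression")
        meth = io_preprocess.read_omics_table(config.methylation_path, "methylation")
        cna = io_preprocess.read_omics_table(config.cna_path, "cna")
        labels, class_names = io_preprocess.read_labels(config.labels_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    gene_list = (io_preprocess.read_symbol_list(config.gene_list_path)
                 if config.gene_list_path else None)
    approved = (set(io_preprocess.read_symbol_list(config.approved_symbols_path))
                if config.approved_symbols_path else None)
    return run_from_matrices(expr, meth, cna, labels, class_names, config,
                             gene_list=gene_list, approved=approved)
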