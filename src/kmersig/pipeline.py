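"""End-to-end orchestration: extract → preprocess → train → ensemble → evaluate.

``run_pipeline`` drives all stages from a single validated config, writes
per-k reports (JSON + TSV), and records provenance (config echo, seed,
library versions, per-stage timings). Reports are deterministic for a
fixed config and seed; timings live only in the provenance record so a
rerun produces byte-identical report files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .classifiers import ModelConfig
from .config import PipelineConfig
from .errors import ConfigError, MetadataError
from .evaluation import MODEL_ORDER, FoldResult, MetricsReport, cross_validate
from .preprocess import PreprocessRecipe
from .signature import (
    FeatureTable,
    build_feature_table,
    enumerate_kmers,
    extract_cohort,
    read_feature_table,
    read_manifest,
    write_feature_table,
)

logger = logging.getLogger(__name__)


def recipe_from_config(cfg: PipelineConfig) -> PreprocessRecipe:
    return PreprocessRecipe(
        smote=cfg.preprocess.smote.enabled,
        smote_neighbors=cfg.preprocess.smote.neighbors,
        lasso_rule=cfg.preprocess.lasso.rule,
        lasso_link=cfg.preprocess.lasso.link,
        pca_dims=cfg.preprocess.pca.dims,
        scope=cfg.preprocess.scope,
    )


def model_configs_from_config(cfg: PipelineConfig) -> list[ModelConfig]:
    return [
        ModelConfig(
            kind=kind,
            seed=cfg.seed + i,
            lr_max_iterations=cfg.models.lr_max_iterations,
            svm_C=cfg.models.svm_C,
            nb_var_smoothing=cfg.models.nb_var_smoothing,
            ffnn_max_epochs=cfg.models.ffnn.max_epochs,
            ffnn_patience=cfg.models.ffnn.patience,
            ffnn_val_fraction=cfg.models.ffnn.val_fraction,
        )
        for i, kind in enumerate(MODEL_ORDER)
    ]


def binary_labels(table: FeatureTable, positive: list[str], negative: list[str]):
    """Collapse multi-class labels to the binary task; rows outside both sets are dropped."""
    pos, neg = set(positive), set(negative)
    if pos & neg:
        raise ConfigError(f"labels {sorted(pos & neg)} appear in both positive and negative sets")
    keep, y = [], []
    for i, lab in enumerate(table.labels):
        if lab in pos:
            keep.append(i)
            y.append(1)
        elif lab in neg:
            keep.append(i)
            y.append(0)
    if not keep:
        raise MetadataError("no samples match the task's label sets")
    dropped = table.n_samples - len(keep)
    if dropped:
        logger.info("task label mapping dropped %d samples outside the binary task", dropped)
    idx = np.array(keep)
    return idx, np.array(y, dtype=int)


def evaluate_table(
    table: FeatureTable, cfg: PipelineConfig
) -> tuple[list[FoldResult], MetricsReport]:
    """Run cross-validated training + ensembling + metrics on one feature table."""
    idx, y = binary_labels(table, cfg.task.positive, cfg.task.negative)
    return cross_validate(
        table.matrix[idx],
        y,
        sample_ids=[table.sample_ids[i] for i in idx],
        recipe=recipe_from_config(cfg),
        model_configs=model_configs_from_config(cfg),
        n_folds=cfg.evaluation.folds,
        seed=cfg.seed,
        weight_rule=cfg.ensemble.weight_rule,
        auc_source=cfg.ensemble.auc_source,
        soft=cfg.ensemble.soft,
        bootstrap_reps=cfg.evaluation.bootstrap_reps,
        ci_level=cfg.evaluation.ci_level,
    )


def _report_tsv(report: MetricsReport, path: Path) -> None:
    metrics = None
    with open(path, "w") as fh:
        for model, block in report.models.items():
            if metrics is None:
                metrics = list(block["fold_mean"].keys())
                fh.write("model\t" + "\t".join(f"{m}\t{m}_sd" for m in metrics) + "\n")
            cells = []
            for m in metrics:
                cells.append(f"{block['fold_mean'][m]['mean']:.6g}")
                cells.append(f"{block['fold_mean'][m]['sd']:.6g}")
            fh.write(model + "\t" + "\t".join(cells) + "\n")


def _fold_record(fr: FoldResult) -> dict:
    return {
        "fold_index": fr.fold_index,
        "val_ids": fr.val_ids,
        "y_true": fr.y_true.tolist(),
        "weights": list(fr.weights.weights),
        "raw_auc": list(fr.weights.raw_auc),
        "n_selected": fr.n_selected,
        "effective_dims": fr.effective_dims,
        "scores": {m: s.tolist() for m, s in fr.model_scores.items()},
        "labels": {m: l.tolist() for m, l in fr.model_labels.items()},
    }


def run_pipeline(cfg: PipelineConfig) -> dict[int, tuple[list[FoldResult], MetricsReport]]:
    """Execute all configured stages and write reports under paths.outdir.

    Returns ``{k: (fold_results, report)}``; with a precomputed feature
    table the single entry is keyed by its own k (or −1 when unknown, e.g.
    taxon-abundance tables).
    """
    outdir = Path(cfg.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    tables: dict[int, FeatureTable] = {}

    if cfg.paths.feature_table:
        t0 = time.perf_counter()
        table = read_feature_table(cfg.paths.feature_table)
        k = int(table.provenance.get("k", -1))
        tables[k] = table
        timings["load_table"] = time.perf_counter() - t0
    elif cfg.paths.manifest:
        manifest = read_manifest(cfg.paths.manifest)
        for sid, _, label in manifest:
            if label == "":
                raise MetadataError(f"sample {sid!r} has no label in the manifest")
        for k in cfg.k:
            t0 = time.perf_counter()
            spec = enumerate_kmers(k)
            sigs = extract_cohort(manifest, spec, workers=cfg.workers)
            labels = {sid: label for sid, _, label in manifest}
            table = build_feature_table(sigs, labels, provenance={"source": "fastq"})
            write_feature_table(table, outdir / f"features_k{k}.tsv")
            tables[k] = table
            timings[f"extract_k{k}"] = time.perf_counter() - t0
            logger.info(
                "k=%d: extracted %d samples x %d features in %.1fs",
                k, table.n_samples, table.n_features, timings[f"extract_k{k}"],
            )
    else:
        raise ConfigError("config must provide paths.manifest or paths.feature_table")

    results: dict[int, tuple[list[FoldResult], MetricsReport]] = {}
    for k, table in tables.items():
        t0 = time.perf_counter()
        folds, report = evaluate_table(table, cfg)
        timings[f"evaluate_k{k}"] = time.perf_counter() - t0
        results[k] = (folds, report)
        payload = {
            "k": k,
            "task": {"positive": cfg.task.positive, "negative": cfg.task.negative},
            "report": report.to_dict(),
            "folds": [_fold_record(fr) for fr in folds],
        }
        with open(outdir / f"report_k{k}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        _report_tsv(report, outdir / f"report_k{k}.tsv")
        if cfg.plots:
            from .plots import plot_report

            plot_report(report, outdir / f"curves_k{k}.png")

    _write_provenance(cfg, timings, outdir)
    return results


def _write_provenance(cfg: PipelineConfig, timings: dict, outdir: Path) -> None:
    import sklearn

    prov = {
        "config": cfg.model_dump(),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
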