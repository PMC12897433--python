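"""End-to-end pipeline: simulate → features → select → cluster → cv →
angles → report.

Each stage consumes and produces declared file artifacts only, so any
stage can be re-run in isolation; per-stage seeds are expanded
deterministically from the single global seed, and every run writes the
resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, cohort, features, orientation, selection
from .classifier import kfold_cv, predict, train_neuron
from .config import PipelineConfig, dump_config
from .imgio import LabeledDataset, read_manifest
from .synth import generate_dataset

logger = logging.getLogger(__name__)


def _stage_simulate(config: PipelineConfig, outdir: Path) -> LabeledDataset:
    dataset = generate_dataset(config.cohorts(), config.synth_config(),
                               seed=config.stage_seed("simulate"),
                               outdir=outdir, image_format=config.image_format)
    logger.info("simulate: %d images, %d fibrotic", len(dataset),
                int(dataset.labels.sum()))
    return dataset


def _stage_features(config: PipelineConfig, dataset: LabeledDataset,
                    outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    wtab = features.window_feature_table(
        dataset.images, window_size=config.window_size,
        stride=config.window_stride, factor=config.factor_window)
    itab = features.image_feature_table(dataset.images,
                                        factor=config.factor_image)
    wtab.to_csv(outdir / "window_features.csv", index=False)
    itab.to_csv(outdir / "image_features.csv", index=False)
    logger.info("features: %d window rows, %d image rows", len(wtab), len(itab))
    return wtab, itab


def _stage_select(config: PipelineConfig, wtab: pd.DataFrame,
                  dataset: LabeledDataset, outdir: Path):
    label_map = dict(zip(dataset.manifest["image_id"], dataset.labels))
    labels = wtab["image_id"].map(label_map).to_numpy(dtype=int)
    if len(wtab) > config.select_max_rows:
        rng = np.random.default_rng(config.stage_seed("select"))
        keep = rng.choice(len(wtab), size=config.select_max_rows, replace=False)
        wtab, labels = wtab.iloc[keep], labels[keep]
    ranking = selection.rank_features(
        wtab, labels, n_trees=config.n_trees,
        max_depth=config.max_depth or None, seed=config.stage_seed("select"))
    ranking.as_frame().to_csv(outdir / "importance.csv", index=False)
    try:
        from .plots import plot_importances
        plot_importances(ranking, outdir / "importance.png")
    except Exception:  # plotting is best-effort
        logger.exception("importance plot failed")
    logger.info("select: top features %s", ranking.ranked_names[:4])
    return ranking


def _stage_cluster(config: PipelineConfig, itab: pd.DataFrame,
                   dataset: LabeledDataset, outdir: Path):
    assignment = clustering.cluster_image_features(
        itab, standardize=config.kmeans_standardize,
        max_iter=config.kmeans_max_iter, tol=config.kmeans_tol,
        seed=config.stage_seed("cluster"), n_init=config.n_init)
    agreement = clustering.label_agreement(assignment, dataset.labels)
    out = itab.loc[:, ["image_id", "group", "animal"]].copy()
    out["cluster"] = assignment.labels
    out.to_csv(outdir / "clusters.csv", index=False)
    (outdir / "cluster_agreement.json").write_text(json.dumps({
        "agreement": agreement, "iterations": assignment.iterations,
        "converged": assignment.converged, "inertia": assignment.inertia,
        "standardized": assignment.standardized,
    }, indent=2))
    try:
        from .plots import plot_cluster_scatter
        plot_cluster_scatter(
            itab, assignment.labels,
            [("mean", "std", "mode"), ("mean", "std", "frac_above")],
            outdir / "clusters.png")
    except Exception:
        logger.exception("cluster plot failed")
    logger.info("cluster: agreement with labels %.3f", agreement)
    return assignment, agreement


def _stage_cv(config: PipelineConfig, itab: pd.DataFrame,
              dataset: LabeledDataset, outdir: Path):
    feature_names = [f.strip() for f in config.cv_features.split(",")]
    X = itab.loc[:, feature_names].to_numpy(dtype=float)
    label_map = dict(zip(dataset.manifest["image_id"], dataset.labels))
    y = itab["image_id"].map(label_map).to_numpy(dtype=int)
    report = kfold_cv(X, y, k=config.k_folds, seed=config.stage_seed("cv"),
                      stratified=config.stratified, lr=config.lr,
                      epochs=config.epochs)
    agg = report.aggregate
    (outdir / "cv_report.json").write_text(json.dumps({
        "k": report.k, "features": feature_names,
        "aggregate": {"tp": agg.tp, "fp": agg.fp, "tn": agg.tn, "fn": agg.fn},
        "f1": report.f1, "sensitivity": report.sensitivity,
        "specificity": report.specificity, "accuracy": report.accuracy,
    }, indent=2))
    pd.DataFrame([{"fold": i, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}
                  for i, m in enumerate(report.fold_matrices)]).to_csv(
        outdir / "cv_folds.csv", index=False)
    try:
        from .plots import plot_confusion
        plot_confusion(agg, outdir / "confusion.png")
    except Exception:
        logger.exception("confusion plot failed")
    logger.info("cv: F1=%.3f sens=%.3f spec=%.3f", report.f1,
                report.sensitivity, report.specificity)
    return report


def _stage_angles(config: PipelineConfig, dataset: LabeledDataset,
                  predictions: dict[str, int], outdir: Path):
    """Hough orientation analysis of the fiber-positive images, per group."""
    angle_sets = {}
    rows = []
    seed = config.stage_seed("angles")
    groups = [g.strip() for g in config.groups.split(",") if g.strip()]
    for gi, group in enumerate(groups):
        dirs_per_image = []
        for img in dataset.images:
            if img.group != group or not predictions.get(img.image_id, 0):
                continue
            dirs = orientation.detect_fiber_directions(
                img, theta_step=config.theta_step,
                min_votes=config.effective_min_votes(),
                max_lines=config.max_lines, nms_window=config.nms_window)
            dirs_per_image.append(dirs)
            for d in dirs:
                rows.append({"group": group, "image_id": img.image_id,
                             "direction_deg": d})
        if sum(d.size for d in dirs_per_image) < 2:
            logger.warning("angles: group %s has <2 detected fibers; skipped",
                           group)
            continue
        angle_sets[group] = orientation.analyze_angles(
            dirs_per_image, seed=seed + gi,
            reference_mode=config.reference_mode, bin_width=config.bin_width,
            width_method=config.width_method)
    pd.DataFrame(rows).to_csv(outdir / "fiber_angles.csv", index=False)
    widths = {g: a.width for g, a in angle_sets.items()}
    pd.DataFrame([{"group": g, "width_deg": w,
                   "method": config.width_method}
                  for g, w in widths.items()]).to_csv(
        outdir / "angular_widths.csv", index=False)
    if angle_sets:
        try:
            from .plots import plot_angle_histograms
            plot_angle_histograms(angle_sets, outdir / "angle_histograms.png")
        except Exception:
            logger.exception("angle histogram plot failed")
    logger.info("angles: widths %s", {g: round(w, 2) for g, w in widths.items()})
    return angle_sets, widths


def _stage_report(config: PipelineConfig, predictions: dict[str, int],
                  manifest: pd.DataFrame, widths: dict[str, float],
                  outdir: Path):
    summaries = cohort.group_fiber_percentages(
        predictions, manifest, sd_unit=config.sd_unit,
        seed=config.stage_seed("report"))
    frame, text = cohort.render_report(summaries, widths)
    frame.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.txt").write_text(text)
    logger.info("report:\n%s", text)
    return summaries


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "resolved_config.yaml")

    dataset = _stage_simulate(config, outdir)
    wtab, itab = _stage_features(config, dataset, outdir)
    _stage_select(config, wtab, dataset, outdir)
    _stage_cluster(config, itab, dataset, outdir)
    _stage_cv(config, itab, dataset, outdir)

    # whole-dataset predictions for the cohort mapping: model trained on all
    # images, evaluated on all images (CV already estimated generalization)
    feature_names = [f.strip() for f in config.cv_features.split(",")]
    X = itab.loc[:, feature_names].to_numpy(dtype=float)
    label_map = dict(zip(dataset.manifest["image_id"], dataset.labels))
    y = itab["image_id"].map(label_map).to_numpy(dtype=int)
    model = train_neuron(X, y, lr=config.lr, epochs=config.epochs)
    _, hard = predict(model, X)
    predictions = {iid: int(h) for iid, h in zip(itab["image_id"], hard)}
    pd.DataFrame({"image_id": itab["image_id"], "prediction": hard}).to_csv(
        outdir / "predictions.csv", index=False)

    _, widths = _stage_angles(config, dataset, predictions, outdir)
    _stage_report(config, predictions, dataset.manifest, widths, outdir)
    return outdir


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Convenience loader used by the stage-wise CLI."""
    return read_manifest(manifest_path)
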