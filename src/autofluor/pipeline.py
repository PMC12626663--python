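"""End-to-end orchestration: simulate -> calibrate -> extract -> select ->
classify -> report, reproducibly under a single seed.

A run directory contains the (optionally simulated) cohort, calibrated
blocks, the feature table, per-comparison selection and result JSONs, ROC
plots and a manifest with config hash, software version and counts.  Result
JSONs are written with sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationModel, calibrate_block, fit_calibration
from .channels import ChannelTable, default_channel_table, read_channel_table
from .classify import CVResult, group_pairs, run_comparison
from .errors import AutofluorError, ValidationError
from .features import FeatureCatalog, extract_features
from .io import (read_data_block, read_label_image, read_reference_set,
                 write_data_block, write_feature_table)
from .model import FeatureTable, masks_from_label_image
from .selection import rank_and_select
from .synthetic import Cohort, CohortConfig, generate_cohort, write_cohort

log = logging.getLogger("autofluor")


@dataclass
class RunConfig:
    """Everything that determines a pipeline run's outputs."""

    out_dir: str
    cohort_dir: Optional[str] = None          # None -> simulate into the run dir
    cohort: CohortConfig = field(default_factory=CohortConfig)
    channel_table_path: Optional[str] = None
    families: Tuple[str, ...] = ("mean", "sd", "skew", "ratio")
    k: int = 8
    selection_mode: str = "fold"              # "fold" | "global"
    redundancy_rho: float = 0.95
    classifiers: Tuple[str, ...] = ("random_forest",)
    backend: Optional[dict] = None
    n_folds: int = 5
    grouping: str = "cell"
    smooth_sigma: float = 1.0
    flat_field_sigma: float = 4.0
    seed: int = 0
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _load_cohort_dir(directory: Path) -> Tuple[ChannelTable, list, dict, object]:
    table = read_channel_table(directory / "channel_table.json")
    blocks = []
    label_images = {}
    for block_dir in sorted((directory / "blocks").iterdir()):
        if not block_dir.is_dir():
            continue
        block = read_data_block(block_dir, channel_table=table)
        blocks.append(block)
        label_images[block.sample_id] = read_label_image(
            directory / "masks" / f"{block.sample_id}.tif")
    refs = read_reference_set(directory / "references", table)
    return table, blocks, label_images, refs


def validate_inputs(table: ChannelTable, blocks, label_images,
                    n_folds: int = 5) -> dict:
    """Consistency checks: channel coverage, mask bounds, class counts,
    fold feasibility.  Returns a machine-readable pass/fail report."""
    failures: List[str] = []
    warnings_: List[str] = []
    group_counts: Dict[str, int] = {}
    for block in blocks:
        missing = set(table.channel_ids) - set(block.channel_images)
        for cid in sorted(missing):
            failures.append(f"block {block.sample_id}: missing channel {cid}")
        label = label_images.get(block.sample_id)
        if label is None:
            failures.append(f"block {block.sample_id}: no mask image")
            continue
        if label.shape != block.pixel_shape:
            failures.append(f"block {block.sample_id}: mask shape mismatch")
        n = int(np.count_nonzero(np.unique(label)))
        if n == 0:
            warnings_.append(f"block {block.sample_id}: patient has zero cells")
        group_counts[block.group_label] = group_counts.get(block.group_label, 0) + n
    for g, n in group_counts.items():
        if n < n_folds:
            failures.append(f"group {g}: only {n} cells for {n_folds}-fold CV")
    return {"failures": failures, "warnings": warnings_,
            "group_cell_counts": group_counts,
            "ok": not failures}


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: cohort (simulate or load) ------------------------------------
    if config.cohort_dir is None:
        cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(cfg)
        write_cohort(cohort, out / "cohort")
        table = cohort.channel_table
        blocks = cohort.blocks
        label_images = cohort.label_images
        refs = cohort.reference
        log.info("simulated cohort: %d blocks, %d cells", len(blocks), cohort.n_cells)
    else:
        table, blocks, label_images, refs = _load_cohort_dir(Path(config.cohort_dir))
        log.info("loaded cohort: %d blocks", len(blocks))
    if config.channel_table_path:
        table = read_channel_table(config.channel_table_path)

    report_path = out / "validation.json"
    report = validate_inputs(table, blocks, label_images, config.n_folds)
    _dump_json(report, report_path)
    if not report["ok"]:
        raise ValidationError(f"input validation failed; see {report_path}")

    # -- stage: calibration ---------------------------------------------------
    model = fit_calibration(refs, table, smooth_sigma=config.smooth_sigma,
                            flat_field_sigma=config.flat_field_sigma)
    model.save(out / "calibration_model")
    calib_dir = out / "calibrated"
    feature_frames = []
    catalog = FeatureCatalog(channel_ids=table.channel_ids,
                             families=config.families)
    for block in blocks:
        cal = calibrate_block(block, model)
        write_data_block(cal, calib_dir / cal.sample_id)
        masks = masks_from_label_image(
            label_images[block.sample_id],
            cell_ids=[f"{block.patient_id}_c{i + 1:02d}"
                      for i in range(int(label_images[block.sample_id].max()))])
        ft = extract_features(cal, masks, catalog=catalog)
        feature_frames.append(ft.data)
    data = pd.concat(feature_frames, ignore_index=True)
    features = FeatureTable(data)
    write_feature_table(features, out / "features.csv")
    counts = features.data["group_label"].value_counts().to_dict()
    log.info("extracted %d features for %d cells in total (%s)",
             len(features.feature_names), features.n_cells,
             ", ".join(f"{v} cells in the {k} group" for k, v in sorted(counts.items())))

    # -- stage: selection + classification per pairwise comparison -----------
    groups = sorted(features.data["group_label"].unique())
    manifest_results = {}
    for i, (a, b) in enumerate(group_pairs(groups)):
        pair_seed = (config.seed * 1009 + 97 * (i + 1)) % (2 ** 31)
        sub = features.subset([a, b])
        sel = rank_and_select(sub, a, b, k=config.k,
                              redundancy_rho=config.redundancy_rho)
        sel.to_json(out / f"selection_{a}_vs_{b}.json")
        results = run_comparison(
            features, a, b, k=config.k, selection_mode=config.selection_mode,
            redundancy_rho=config.redundancy_rho,
            classifiers=config.classifiers, backend_config=config.backend,
            n_folds=config.n_folds, grouping=config.grouping, seed=pair_seed)
        payload = {name: res.to_dict() for name, res in results.items()}
        result_path = out / f"result_{a}_vs_{b}.json"
        _dump_json(payload, result_path)
        manifest_results[f"{a}_vs_{b}"] = result_path.name
        if config.make_plots:
            _plot_roc(results, a, b, out / "plots" / f"roc_{a}_vs_{b}.png")
        for name, res in results.items():
            if res.per_fold_auc:
                log.info("%s vs %s [%s]: mean AUC %.3f (95%% CI %.3f-%.3f)",
                         a, b, name, res.mean_auc, *res.ci95)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cells": features.n_cells,
        "group_cell_counts": counts,
        "n_features": len(features.feature_names),
        "results": manifest_results,
        "features_file": "features.csv",
    }
    _dump_json(manifest, out / "run_manifest.json")
    return out


def _plot_roc(results: Dict[str, CVResult], a: str, b: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        if not res.per_fold_auc:
            continue
        pts = np.asarray(res.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post",
                label=f"{res.classifier_id}: AUC {res.mean_auc:.2f} "
                      f"± {res.mean_auc - res.ci95[0]:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(f"{a} vs {b}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
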