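"""End-to-end experiment orchestration.

One experiment cell = (retention p, augmentation N): split parents into
train/validation/test with the donor-safe stratified splitter, downsample
every partition to retention p, augment *only* the training partition to N
subsamples per parent, featurize, train the chosen integration
architecture, and score on the test partition. Cells are compared against
the unaugmented (N=1) baseline with paired t-tests over the CV folds, and
the early-integration model is interpreted with integrated gradients.

The augmentation grid the full study found best per retention is kept as a
canonical constant; the desk-scale defaults train without per-fold HPO
(fixed mid-range hyperparameters) — the full budgets are reachable through
the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .attribution import attribute_cohort, class_mean_attributions
from .evaluate import (CohortSplit, MetricsReport, assert_no_donor_leakage,
                       paired_ttest, score, significance_stars,
                       stratified_group_shuffle_split)
from .features import build_feature_matrix, normalize_block
from .io_formats import BinIndex, GeneRegionTable, LabelTable, SampleVariants
from .net import (Hyperparams, IntegrationModel, IntegrationSpec,
                  TrainingSchedule, build_model)
from .sparsify import augment_training_set, derive_seed, downsample

log = logging.getLogger(__name__)

#: Best augmentation level per retention found by the full-scale study.
BEST_AUGMENTATION = {0.70: 20, 0.25: 20, 0.10: 30, 0.05: 50, 0.02: 50}

DEFAULT_HYPERPARAMS = Hyperparams(learning_rate=1e-3, l2_penalty=1e-4,
                                  dropout=0.1, n_layers=2, n_nodes=64,
                                  activation="relu")


@dataclass
class ExperimentConfig:
    retention_grid: tuple[float, ...] = (1.0, 0.25, 0.02)
    augmentation_grid: tuple[int, ...] = (1, 10)
    architecture: str = "early"
    feature_sets: tuple[str, ...] = ("bins", "tri", "drivers")
    n_splits: int = 3
    seed: int = 0
    epochs: int = 50
    batch_size: int = 32
    normalization: str = "log1p"
    attribution_steps: int = 50
    attribute: bool = True

    def __post_init__(self) -> None:
        if not self.retention_grid or not self.augmentation_grid:
            raise ValueError("retention and augmentation grids must be non-empty")


def default_spec(architecture: str, feature_sets: tuple[str, ...],
                 hp: Hyperparams | None = None) -> IntegrationSpec:
    hp = hp or DEFAULT_HYPERPARAMS
    n = 1 if architecture == "early" else len(feature_sets)
    return IntegrationSpec(architecture, [Hyperparams(**vars(hp)) for _ in range(n)],
                           feature_order=list(feature_sets))


@dataclass
class CellData:
    """Featurized, normalized train/val/test blocks for one experiment cell."""

    Xs_train: list[np.ndarray]
    y_train: np.ndarray
    Xs_val: list[np.ndarray]
    y_val: np.ndarray
    Xs_test: list[np.ndarray]
    y_test: np.ndarray
    class_names: list[str]
    test_labels: list[str]
    feature_names: dict[str, list[str]]


def prepare_cell(samples_by_id: dict[str, SampleVariants], split: CohortSplit,
                 p: float, n_augment: int, seed: int, bins: BinIndex,
                 genes: GeneRegionTable, genome, feature_sets: tuple[str, ...],
                 normalization: str = "log1p") -> CellData:
    """Downsample, augment (train only), featurize and normalize one cell.

    At p = 1.0 there is nothing to resample, so the training partition is
    the parents themselves regardless of N.
    """
    class_names = sorted({s.label for s in samples_by_id.values()})
    cls_idx = {c: i for i, c in enumerate(class_names)}

    if p == 1.0:
        train = [samples_by_id[s] for s in split.train]
    else:
        train = [sub for sub, _ in augment_training_set(
            [samples_by_id[s] for s in split.train], n_augment, p,
            derive_seed(seed, "augment", split.split_index))]

    def one_subsample(ids: tuple[str, ...], tag: str) -> list[SampleVariants]:
        if p == 1.0:
            return [samples_by_id[s] for s in ids]
        return [downsample(samples_by_id[s], p,
                           derive_seed(seed, tag, split.split_index, s))
                for s in ids]

    val = one_subsample(split.val, "val")
    test = one_subsample(split.test, "test")

    parts = {}
    names = None
    for key, cohort in (("train", train), ("val", val), ("test", test)):
        blocks, labels, names = build_feature_matrix(cohort, bins, genes, genome)
        Xs = [normalize_block(blocks[fs], normalization) for fs in feature_sets]
        parts[key] = (Xs, np.asarray([cls_idx[l] for l in labels]), labels)
    return CellData(
        Xs_train=parts["train"][0], y_train=parts["train"][1],
        Xs_val=parts["val"][0], y_val=parts["val"][1],
        Xs_test=parts["test"][0], y_test=parts["test"][1],
        class_names=class_names, test_labels=parts["test"][2],
        feature_names={fs: names[fs] for fs in feature_sets},
    )


def train_cell(data: CellData, spec: IntegrationSpec, seed: int,
               epochs: int = 50, batch_size: int = 32,
               ) -> tuple[IntegrationModel, MetricsReport]:
    model = build_model(spec, [X.shape[1] for X in data.Xs_train],
                        len(data.class_names), data.class_names, seed=seed)
    model.fit(data.Xs_train, data.y_train, data.Xs_val, data.y_val,
              TrainingSchedule(batch_size=batch_size, epochs=epochs),
              seed=derive_seed(seed, "fit"))
    probs = model.predict_proba(data.Xs_test)
    report = score(data.test_labels, probs, data.class_names)
    return model, report


def run_condition(samples_by_id: dict[str, SampleVariants], labels: LabelTable,
                  splits: list[CohortSplit], p: float, n_augment: int,
                  bins: BinIndex, genes: GeneRegionTable, genome,
                  config: ExperimentConfig,
                  spec: IntegrationSpec | None = None,
                  ) -> tuple[list[MetricsReport], list[IntegrationModel], list[CellData]]:
    """Train and score one (retention, augmentation) cell across all splits."""
    spec = spec or default_spec(config.architecture, config.feature_sets)
    reports, models, datas = [], [], []
    for split in splits:
        assert_no_donor_leakage(split, labels)
        data = prepare_cell(samples_by_id, split, p, n_augment, config.seed,
                            bins, genes, genome, config.feature_sets,
                            config.normalization)
        model, report = train_cell(
            data, spec, derive_seed(config.seed, "model", p, n_augment, split.split_index),
            epochs=config.epochs, batch_size=config.batch_size)
        reports.append(report)
        models.append(model)
        datas.append(data)
        log.info("cell p=%.2f N=%d split=%d: accuracy %.3f",
                 p, n_augment, split.split_index, report.accuracy)
    return reports, models, datas


def run_experiment(cohort: list[SampleVariants], labels: LabelTable,
                   bins: BinIndex, genes: GeneRegionTable, genome,
                   config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> dict:
    """Full experiment grid; returns (and optionally writes) the results.

    For every retention level, every augmentation level in the grid is
    compared against the N=1 baseline at that retention with a paired
    t-test on per-fold accuracy. Attributions (class means over the first
    split's test set) are produced for early-integration models.
    """
    samples_by_id = {s.sample_id: s for s in cohort}
    splits = stratified_group_shuffle_split(labels, config.n_splits, seed=config.seed)
    results: dict = {"config": asdict(config), "cells": {}}
    baseline_acc: dict[float, list[float]] = {}
    for p in config.retention_grid:
        for n_aug in sorted(set(config.augmentation_grid) | {1}) if p < 1.0 else [1]:
            reports, models, datas = run_condition(
                samples_by_id, labels, splits, p, n_aug, bins, genes, genome, config)
            accs = [r.accuracy for r in reports]
            cell: dict = {
                "retention": p, "augmentation": n_aug,
                "fold_accuracy": accs,
                "mean_accuracy": float(np.mean(accs)),
                "mean_macro_f1": float(np.mean([r.macro_f1 for r in reports])),
                "mean_topk": {str(k): float(np.mean([r.topk_accuracy[k] for r in reports]))
                              for k in reports[0].topk_accuracy},
                "reports": [r.to_dict() for r in reports],
            }
            if n_aug == 1:
                baseline_acc[p] = accs
            elif p in baseline_acc:
                t, pval = paired_ttest(accs, baseline_acc[p])
                cell["vs_unaugmented"] = {"t": t, "p": pval,
                                          "stars": significance_stars(pval)}
            if config.attribute and config.architecture == "early":
                attr = attribute_cohort(models[0], datas[0].Xs_test,
                                        steps=config.attribution_steps)
                feat_names = [n for fs in config.feature_sets
                              for n in datas[0].feature_names[fs]]
                mat = class_mean_attributions(attr, datas[0].test_labels,
                                              datas[0].class_names, feat_names)
                cell["attribution_raw_mean"] = np.nan_to_num(mat.values).tolist()
            results["cells"][f"p{p}_N{n_aug}"] = cell
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, indent=2))
        (out / "run_manifest.json").write_text(json.dumps(
            {"seed": config.seed, "n_splits": config.n_splits,
             "splits": [asdict(s) for s in splits]}, indent=2))
    return results
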