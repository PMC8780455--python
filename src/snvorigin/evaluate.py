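"""Group-safe stratified shuffle-split cross-validation and metrics.

The evaluation design follows the study protocol: three shuffle-split
rounds, each allocating 60% of samples to training and 20% each to
validation and test, stratified by cancer type. Because augmentation
derives many subsamples from one parent, the splitter operates on *donors*:
all derivatives of a donor land in a single partition, which is the leakage
rule that makes augmented training sets safe.

Metrics: per-class F1 (class imbalance aware), micro average accuracy
(fraction of correctly classified samples), top-k accuracy for ranked
prediction lists, confusion matrices, and paired t-tests between
configurations across CV folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, f1_score

from .io_formats import LabelTable
from .sparsify import derive_seed


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/validation/test sets of parent sample ids."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    split_index: int = 0


def assert_no_donor_leakage(split: CohortSplit, labels: LabelTable) -> None:
    """Raise if any donor appears in more than one partition."""
    donor = {s: d for s, d, _ in labels.rows}
    parts = [{donor[s] for s in ids} for ids in (split.train, split.val, split.test)]
    for i in range(3):
        for j in range(i + 1, 3):
            common = parts[i] & parts[j]
            if common:
                raise AssertionError(f"donor leakage between partitions: {sorted(common)}")


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_group_shuffle_split(
    labels: LabelTable, n_splits: int = 3,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0,
) -> list[CohortSplit]:
    """Per split: classes allocated 60/20/20 by largest-remainder rounding,
    donors kept intact, deterministic under the seed.

    Donors carrying fewer than 3 samples-worth of a class still split
    cleanly because allocation counts donors; a class too small to cover
    all three partitions is allocated whole to training with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    donors_by_class: dict[str, list[str]] = {}
    samples_by_donor: dict[str, list[str]] = {}
    donor_class: dict[str, str] = {}
    for sample_id, donor_id, label in labels.rows:
        samples_by_donor.setdefault(donor_id, []).append(sample_id)
        if donor_id not in donor_class:
            donor_class[donor_id] = label
            donors_by_class.setdefault(label, []).append(donor_id)
        elif donor_class[donor_id] != label:
            warnings.warn(f"donor {donor_id} carries multiple labels; "
                          f"stratifying by its first label", stacklevel=2)
    splits = []
    for s in range(n_splits):
        rng = np.random.default_rng(derive_seed(seed, "split", s))
        parts: tuple[list[str], list[str], list[str]] = ([], [], [])
        for label in sorted(donors_by_class):
            donors = sorted(donors_by_class[label])
            if len(donors) < 3:
                warnings.warn(f"class {label!r} has {len(donors)} donor(s); "
                              f"allocated whole to training", stacklevel=2)
                for d in donors:
                    parts[0].extend(samples_by_donor[d])
                continue
            perm = rng.permutation(len(donors))
            counts = _largest_remainder(len(donors), fractions)
            offset = 0
            for part, count in zip(parts, counts):
                for k in perm[offset:offset + count]:
                    part.extend(samples_by_donor[donors[k]])
                offset += count
        split = CohortSplit(tuple(sorted(parts[0])), tuple(sorted(parts[1])),
                            tuple(sorted(parts[2])), split_index=s)
        assert_no_donor_leakage(split, labels)
        splits.append(split)
    return splits


@dataclass
class MetricsReport:
    class_names: list[str]
    per_class_f1: dict[str, float]
    macro_f1: float
    accuracy: float
    topk_accuracy: dict[int, float]
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "per_class_f1": self.per_class_f1,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "topk_accuracy": {str(k): v for k, v in self.topk_accuracy.items()},
            "confusion": self.confusion.tolist(),
        }


def score(y_true: list[str], y_pred_proba: np.ndarray, class_names: list[str],
          k_list: tuple[int, ...] = (1, 2, 3)) -> MetricsReport:
    """Score probabilistic predictions against true class names.

    Top-k accuracy counts a sample correct when its true class is among the
    k highest-probability classes (probability ties broken by class index),
    so it is non-decreasing in k.
    """
    unknown = sorted(set(y_true) - set(class_names))
    if unknown:
        raise ValueError(f"true labels not in class_names: {unknown}")
    y_pred_proba = np.asarray(y_pred_proba, dtype=float)
    if y_pred_proba.shape != (len(y_true), len(class_names)):
        raise ValueError("probability matrix shape mismatch")
    idx = {c: i for i, c in enumerate(class_names)}
    y_true_idx = np.asarray([idx[c] for c in y_true])
    y_pred_idx = y_pred_proba.argmax(axis=1)
    f1 = f1_score(y_true_idx, y_pred_idx, labels=range(len(class_names)),
                  average=None, zero_division=0.0)
    order = np.argsort(-y_pred_proba, axis=1, kind="stable")
    topk = {}
    for k in k_list:
        if not 1 <= k <= len(class_names):
            raise ValueError(f"k={k} out of range")
        topk[k] = float(np.mean([t in row[:k] for t, row in zip(y_true_idx, order)]))
    return MetricsReport(
        class_names=list(class_names),
        per_class_f1={c: float(v) for c, v in zip(class_names, f1)},
        macro_f1=float(np.mean(f1)),
        accuracy=float(np.mean(y_pred_idx == y_true_idx)),
        topk_accuracy=topk,
        confusion=confusion_matrix(y_true_idx, y_pred_idx, labels=range(len(class_names))),
    )


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Classical paired t-test on per-fold metrics (two-sided).

    Identical vectors are degenerate: p is reported as 1 with a warning.
    Zero-variance but non-zero differences leave the statistic undefined
    (NaN) with a warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired values")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            warnings.warn("identical paired metrics; p reported as 1", stacklevel=2)
            return float("nan"), 1.0
        warnings.warn("zero-variance non-zero differences; t undefined", stacklevel=2)
        return float("nan"), float("nan")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""
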