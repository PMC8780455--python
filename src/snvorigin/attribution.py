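"""Integrated-gradients interpretation of trained classifiers.

Attribution of a prediction to its input features follows the
path-integral definition: with a zero baseline, feature j of sample x
receives

    IG_j(x) = x_j * (1/m) * sum_k  dF_c(alpha_k * x) / dx_j

where the alpha_k are m interpolation points on [0, 1] (midpoint rule) and
F_c is the score of the sample's *top predicted* class c, taken on the
pre-softmax logit by default. The completeness axiom —
sum_j IG_j(x) = F_c(x) - F_c(0) in the m -> infinity limit — is the natural
correctness check and tightens as m grows.

Per-class summaries average the per-sample attributions over all test
samples of each cancer type; for heatmap comparison across sparsity levels
the class means go through a sign-preserving log-modulus transform
L(f) = sign(f) * log(|f|+1) and per-matrix scaling into [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .net import IntegrationModel


@dataclass
class AttributionMatrix:
    """Per-(class, feature) attribution values at a processing stage."""

    values: np.ndarray                 # (n_classes, n_features)
    class_names: list[str]
    feature_names: list[str]
    stage: str = "raw_mean"            # raw_mean | log_modulus | scaled


def integrated_gradients(model: IntegrationModel, xs: list[np.ndarray],
                         steps: int = 50, target: int | None = None,
                         mode: str = "logit") -> list[np.ndarray]:
    """Attributions of one sample w.r.t. its top predicted class.

    ``xs`` holds one 1-D vector per feature set. Returns attribution
    vectors in the same block structure. ``target`` overrides the class;
    ``mode='prob'`` attributes the softmax probability instead of the
    pre-softmax logit.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    xs = [np.asarray(x, dtype=float).reshape(1, -1) for x in xs]
    if target is None:
        target = int(model.predict_proba(xs).argmax())
    alphas = (np.arange(steps) + 0.5) / steps
    interp = [np.concatenate([a * x for a in alphas], axis=0) for x in xs]
    grads = model.input_gradients(interp, target, mode=mode)
    for g in grads:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradients during integrated gradients")
    return [x[0] * g.mean(axis=0) for x, g in zip(xs, grads)]


def attribute_cohort(model: IntegrationModel, Xs: list[np.ndarray],
                     steps: int = 50, mode: str = "logit") -> np.ndarray:
    """Per-sample attributions (rows) over the concatenated feature blocks."""
    n = Xs[0].shape[0]
    out = np.zeros((n, sum(x.shape[1] for x in Xs)))
    for i in range(n):
        blocks = integrated_gradients(model, [X[i] for X in Xs], steps=steps, mode=mode)
        out[i] = np.concatenate(blocks)
    return out


def class_mean_attributions(attributions: np.ndarray, labels: list[str],
                            class_names: list[str],
                            feature_names: list[str]) -> AttributionMatrix:
    """Average per-sample attributions over the samples of each class."""
    values = np.full((len(class_names), attributions.shape[1]), np.nan)
    for i, cls in enumerate(class_names):
        mask = np.asarray([l == cls for l in labels])
        if mask.any():
            values[i] = attributions[mask].mean(axis=0)
        else:
            warnings.warn(f"no samples for class {cls!r}; attribution row is NaN",
                          stacklevel=2)
    return AttributionMatrix(values, list(class_names), list(feature_names), "raw_mean")


def log_modulus(values: np.ndarray) -> np.ndarray:
    """Sign-preserving log compression L(f) = sign(f) * ln(|f| + 1)."""
    values = np.asarray(values, dtype=float)
    return np.sign(values) * np.log1p(np.abs(values))


def log_modulus_matrix(matrix: AttributionMatrix) -> AttributionMatrix:
    return replace(matrix, values=log_modulus(matrix.values), stage="log_modulus")


def scale_attributions(matrix: AttributionMatrix, literal: bool = False) -> AttributionMatrix:
    """Scale a (log-modulus) matrix into [-1, 1] by its signed extremes.

    Positive entries divide by the matrix maximum, negative entries by the
    magnitude of the matrix minimum so that signs survive (the default).
    ``literal=True`` divides negatives by the signed minimum instead, which
    maps them to positive values. Zeros are untouched; an all-zero matrix
    is returned unchanged with a warning.
    """
    v = matrix.values.copy()
    finite = np.isfinite(v)
    pos, neg = finite & (v > 0), finite & (v < 0)
    if not pos.any() and not neg.any():
        warnings.warn("all-zero attribution matrix; scaling is a no-op", stacklevel=2)
        return replace(matrix, stage="scaled")
    if pos.any():
        v[pos] = v[pos] / v[pos].max()
    if neg.any():
        f_min = v[neg].min()
        v[neg] = v[neg] / (f_min if literal else abs(f_min))
    return replace(matrix, values=v, stage="scaled")


def top_features(matrix: AttributionMatrix, blocks: dict[str, np.ndarray],
                 k: dict[str, int] | None = None) -> dict[str, list[str]]:
    """Union of per-class top features, per feature type.

    ``blocks`` maps a feature-type name to the column indices of that type;
    ``k`` gives how many top features each class contributes per type
    (default: 1 bin, 2 trinucleotides, 2 driver genes). Ranking is by
    absolute attribution within the class; features with zero attribution
    in every class are excluded.
    """
    if matrix.stage != "raw_mean":
        raise ValueError("top_features expects the raw_mean stage")
    k = dict(k or {"bins": 1, "tri": 2, "drivers": 2})
    out: dict[str, list[str]] = {}
    for block_name, cols in blocks.items():
        cols = np.asarray(cols)
        kk = k.get(block_name, 1)
        if kk > len(cols):
            warnings.warn(f"k={kk} exceeds {len(cols)} {block_name} features; capped",
                          stacklevel=2)
            kk = len(cols)
        sub = np.nan_to_num(matrix.values[:, cols])
        alive = np.abs(sub).sum(axis=0) > 0
        union: set[int] = set()
        for row in np.abs(sub):
            ranked = np.argsort(-row, kind="stable")
            union.update(int(j) for j in ranked[:kk] if alive[j])
        out[block_name] = sorted(matrix.feature_names[int(cols[j])] for j in union)
    return out


def display_order(reference: AttributionMatrix) -> dict[str, list[int]]:
    """Per-class feature order (descending attribution) in a reference matrix.

    Sparse-data matrices are displayed in the order derived from the
    full-data matrix, so profiles stay comparable across sparsity levels.
    """
    return {
        cls: np.argsort(-np.nan_to_num(reference.values[i]), kind="stable").tolist()
        for i, cls in enumerate(reference.class_names)
    }
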