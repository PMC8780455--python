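"""Liquid-biopsy sparsity simulation and training-set augmentation.

Sparse profiles are modelled by retaining a fixed fraction p of a sample's
somatic SNVs, drawn uniformly without replacement. The study grid is
p in {0.02, 0.05, 0.10, 0.25, 0.70, 1.00}. Augmentation generates N
independent subsamples per training sample (N in {10, 20, 30, 40, 50});
validation and test samples always receive exactly one subsample, and a
provenance record ties every subsample to its parent and donor so that the
cross-validation splitter can keep all derivatives of a donor in one
partition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .io_formats import SampleVariants

RETENTION_GRID = (0.02, 0.05, 0.10, 0.25, 0.70, 1.00)
AUGMENTATION_GRID = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class SubsampleProvenance:
    """Where a subsample came from: parent, replicate index, retention, seed."""

    parent_sample_id: str
    donor_id: str
    replicate_index: int
    retention: float
    seed: int


def retained_count(n: int, p: float) -> int:
    """Number of SNVs kept at retention p: round(p*n), floored at 1.

    Banker's rounding is avoided: ties round half up so that the count is
    the conventional rounded percentage of the SNV total.
    """
    return max(1, int(np.floor(p * n + 0.5)))


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable child seed from a master seed and identifying parts (< 2**31).

    Hash-based so that adding parents or replicates never reshuffles the
    seeds of existing ones.
    """
    h = hashlib.sha256(repr((master_seed,) + parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def downsample(sample: SampleVariants, p: float, seed: int,
               bernoulli: bool = False, suffix: str | None = None) -> SampleVariants:
    """Randomly retain a fraction p of a sample's SNVs.

    Default mode keeps exactly k = max(1, round(p*n)) variants, sampled
    uniformly without replacement; ``bernoulli=True`` instead keeps each
    variant independently with probability p (k then varies).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"retention fraction must be in (0, 1], got {p}")
    n = len(sample)
    if n < 1:
        raise ValueError(f"sample {sample.sample_id} has no variants to downsample")
    sid = sample.sample_id if suffix is None else f"{sample.sample_id}{suffix}"
    if p == 1.0 and not bernoulli:
        return sample.with_variants(sample.variants, sample_id=sid)
    rng = np.random.default_rng(seed)
    if bernoulli:
        mask = rng.random(n) < p
        idx = np.flatnonzero(mask)
    else:
        idx = rng.choice(n, size=retained_count(n, p), replace=False)
    kept = [sample.variants[i] for i in sorted(idx.tolist())]
    return sample.with_variants(kept, sample_id=sid)


def augment_training_set(
    train: list[SampleVariants], n_augment: int, p: float, seed: int,
) -> list[tuple[SampleVariants, SubsampleProvenance]]:
    """Generate ``n_augment`` independent subsamples at retention p per parent.

    Child seeds are derived from (seed, parent_sample_id, replicate_index),
    so the replicate set of one parent is unaffected by the others.
    """
    if n_augment < 1:
        raise ValueError(f"augmentation level must be >= 1, got {n_augment}")
    out = []
    for parent in train:
        for r in range(n_augment):
            child_seed = derive_seed(seed, parent.sample_id, r)
            sub = downsample(parent, p, child_seed, suffix=f"__aug{r}")
            prov = SubsampleProvenance(parent.sample_id, parent.donor_id, r, p, child_seed)
            out.append((sub, prov))
    return out


def write_provenance(records: list[SubsampleProvenance], path) -> None:
    lines = ["parent_sample_id\tdonor_id\treplicate_index\tretention\tseed"]
    lines += [f"{r.parent_sample_id}\t{r.donor_id}\t{r.replicate_index}\t{r.retention}\t{r.seed}"
              for r in records]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
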