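"""SNV-derived feature vectors: 1 Mb bin densities, 96 trinucleotide motif
counts and driver-gene mutation densities.

Trinucleotide classes follow the COSMIC convention: every substitution is
reported on the pyrimidine strand, i.e. when the mutated reference base is a
purine (A/G) the 3-mer context and the alternate allele are
reverse-complemented. Six substitution types x 4 x 4 flanking bases give the
96 classes (e.g. ``ACA>AGA``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import BinIndex, GeneRegionTable, SampleVariants, normalize_chrom

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"


def _enumerate_classes() -> list[str]:
    names = []
    for sub in _SUBSTITUTIONS:
        ref, alt = sub[0], sub[2]
        for five in _FLANKS:
            for three in _FLANKS:
                names.append(f"{five}{ref}{three}>{five}{alt}{three}")
    return names


#: The 96 pyrimidine-strand trinucleotide classes in COSMIC display order
#: (substitution-major: C>A, C>G, C>T, T>A, T>C, T>G; flanks alphabetical).
TRINUCLEOTIDE_CLASSES: tuple[str, ...] = tuple(_enumerate_classes())
_CLASS_INDEX = {name: i for i, name in enumerate(TRINUCLEOTIDE_CLASSES)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def canonical_class(context: str, alt: str) -> str:
    """Map a stranded 3-mer context + alt base to its pyrimidine-strand class.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine-centred contexts are reverse-complemented, so e.g. TGC with G>A
    becomes GCA with C>T, class GCA>GTA.
    """
    context = context.upper()
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context) or alt not in _COMPLEMENT:
        raise ValueError(f"invalid context/alt: {context!r} {alt!r}")
    ref = context[1]
    if alt == ref:
        raise ValueError(f"alt equals ref in context {context}")
    if ref in "AG":
        context = reverse_complement(context)
        alt = _COMPLEMENT[alt]
    return f"{context}>{context[0]}{alt}{context[2]}"


@dataclass
class FeatureBundle:
    """The three per-sample feature vectors consumed by the classifiers."""

    sample_id: str
    label: str
    bin_counts: np.ndarray      # len |BinIndex|
    tri_counts: np.ndarray      # len 96
    driver_counts: np.ndarray   # len |GeneRegionTable|
    bin_names: list[str]
    tri_names: list[str]
    driver_names: list[str]


def _positions_by_chrom(sample: SampleVariants) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for v in sample.variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in by_chrom.items()}


def bin_counts(sample: SampleVariants, bins: BinIndex) -> np.ndarray:
    """SNVs per bin (inclusive bounds); off-manifest variants logged as unbinned."""
    pos = _positions_by_chrom(sample)
    counts = np.zeros(len(bins), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(bins.bins):
        arr = pos.get(chrom)
        if arr is not None:
            counts[i] = np.searchsorted(arr, end, "right") - np.searchsorted(arr, start, "left")
    unbinned = len(sample) - int(counts.sum())
    if unbinned:
        log.info("bin_counts(%s): %d variants outside all bins", sample.sample_id, unbinned)
    return counts


def trinucleotide_counts(sample: SampleVariants, genome) -> np.ndarray:
    """Count each variant's pyrimidine-strand trinucleotide class.

    ``genome`` is an indexed FASTA accessor (``pyfaidx.Fasta``). Variants
    whose reference base disagrees with the genome, or that lack a flanking
    base (position 1 / chromosome end), are skipped and logged rather than
    raising: masked or divergent reference bases should not corrupt the
    remaining counts.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    keys = {normalize_chrom(k): k for k in genome.keys()}
    for v in sample.variants:
        key = keys.get(v.chrom)
        if key is None or v.pos < 2 or v.pos + 1 > len(genome[key]):
            skipped += 1
            continue
        context = str(genome[key][v.pos - 2:v.pos + 1]).upper()
        if len(context) != 3 or context[1] != v.ref or any(b not in _COMPLEMENT for b in context):
            skipped += 1
            continue
        counts[_CLASS_INDEX[canonical_class(context, v.alt)]] += 1
    if skipped:
        log.info("trinucleotide_counts(%s): skipped %d variants without resolvable context",
                 sample.sample_id, skipped)
    return counts


def driver_counts(sample: SampleVariants, genes: GeneRegionTable) -> np.ndarray:
    """SNVs per driver-gene span (inclusive); overlapping spans both count."""
    pos = _positions_by_chrom(sample)
    counts = np.zeros(len(genes), dtype=np.int64)
    for i, (_, chrom, start, end) in enumerate(genes.rows):
        arr = pos.get(chrom)
        if arr is not None:
            counts[i] = np.searchsorted(arr, end, "right") - np.searchsorted(arr, start, "left")
    return counts


def featurize(sample: SampleVariants, bins: BinIndex, genes: GeneRegionTable, genome) -> FeatureBundle:
    return FeatureBundle(
        sample_id=sample.sample_id,
        label=sample.label,
        bin_counts=bin_counts(sample, bins),
        tri_counts=trinucleotide_counts(sample, genome),
        driver_counts=driver_counts(sample, genes),
        bin_names=bins.names,
        tri_names=list(TRINUCLEOTIDE_CLASSES),
        driver_names=genes.names,
    )


def build_feature_matrix(
    cohort: list[SampleVariants], bins: BinIndex, genes: GeneRegionTable, genome,
) -> tuple[dict[str, np.ndarray], list[str], dict[str, list[str]]]:
    """Featurize a cohort into three (n_samples, width) blocks.

    Returns ``(blocks, labels, names)`` where ``blocks`` maps feature-set
    name ("bins", "tri", "drivers") to its matrix with rows in cohort order.
    """
    names = {"bins": bins.names, "tri": list(TRINUCLEOTIDE_CLASSES), "drivers": genes.names}
    blocks = {
        "bins": np.zeros((len(cohort), len(bins)), dtype=np.int64),
        "tri": np.zeros((len(cohort), 96), dtype=np.int64),
        "drivers": np.zeros((len(cohort), len(genes)), dtype=np.int64),
    }
    labels = []
    for i, sample in enumerate(cohort):
        fb = featurize(sample, bins, genes, genome)
        blocks["bins"][i] = fb.bin_counts
        blocks["tri"][i] = fb.tri_counts
        blocks["drivers"][i] = fb.driver_counts
        labels.append(sample.label)
    return blocks, labels, names


def normalize_block(X: np.ndarray, method: str = "log1p") -> np.ndarray:
    """Per-sample input scaling applied before model ingestion.

    ``log1p`` (default) compresses the 3-orders-of-magnitude spread of
    mutation burdens; ``total`` divides each row by its sum; ``none`` passes
    raw counts through.
    """
    X = np.asarray(X, dtype=np.float64)
    if method == "log1p":
        return np.log1p(X)
    if method == "total":
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return X / totals
    if method == "none":
        return X
    raise ValueError(f"unknown normalization {method!r}")
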