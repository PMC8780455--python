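"""Feature extraction: trinucleotide canonicalization, bin/driver counting,
conservation and linearity."""

import itertools

import numpy as np
import pytest

from snvorigin.features import (TRINUCLEOTIDE_CLASSES, bin_counts,
                                build_feature_matrix, canonical_class,
                                driver_counts, featurize,
                                trinucleotide_counts)
from snvorigin.io_formats import (BinIndex, GeneRegionTable, SampleVariants,
                                  VariantRecord)
from snvorigin.sparsify import downsample

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_canonical(context, alt):
    """Independent canonicalizer: enumerate both strand readings and keep
    the one whose central base is a pyrimidine."""
    fwd = (context, alt)
    rev = ("".join(COMP[b] for b in reversed(context)), COMP[alt])
    ctx, a = fwd if context[1] in "CT" else rev
    return f"{ctx}>{ctx[0]}{a}{ctx[2]}"


def sample_of(variants, label="A", sid="s"):
    return SampleVariants(sid, f"{sid}_d", label, tuple(variants))


class TestTrinucleotideClasses:
    def test_exactly_96_distinct_classes(self):
        assert len(TRINUCLEOTIDE_CLASSES) == 96
        assert len(set(TRINUCLEOTIDE_CLASSES)) == 96

    def test_agrees_with_brute_force_over_all_192_contexts(self):
        """Every stranded (context, alt) combination maps into the 96 classes
        identically under the implementation and the brute-force oracle."""
        seen = set()
        for five, ref, three in itertools.product("ACGT", "ACGT", "ACGT"):
            for alt in "ACGT":
                if alt == ref:
                    continue
                ctx = five + ref + three
                name = canonical_class(ctx, alt)
                assert name == brute_force_canonical(ctx, alt)
                assert name in TRINUCLEOTIDE_CLASSES
                seen.add(name)
        assert len(seen) == 96

    def test_cosmic_example(self):
        # reference ACAG, SNV at position 2, C>G: class ACA>AGA
        assert canonical_class("ACA", "G") == "ACA>AGA"

    def test_purine_context_reverse_complemented(self):
        # TGC with G>A reads GCA with C>T on the pyrimidine strand
        assert canonical_class("TGC", "A") == "GCA>GTA"


class TestTrinucleotideCounts:
    def test_counts_example_contexts(self):
        genome = {"1": "ACAG"}
        s = sample_of([VariantRecord("1", 2, "C", "G")])
        counts = trinucleotide_counts(s, genome)
        assert counts.sum() == 1
        assert counts[TRINUCLEOTIDE_CLASSES.index("ACA>AGA")] == 1

    def test_conservation_when_all_contexts_resolve(self):
        genome = {"1": "AACATGCAT"}
        s = sample_of([VariantRecord("1", 3, "C", "T"), VariantRecord("1", 6, "G", "A")])
        assert trinucleotide_counts(s, genome).sum() == 2

    def test_edge_positions_and_ref_mismatch_skipped(self):
        genome = {"1": "ACAG"}
        s = sample_of([
            VariantRecord("1", 1, "A", "T"),   # no 5' flank
            VariantRecord("1", 4, "G", "T"),   # no 3' flank
            VariantRecord("1", 3, "T", "G"),   # genome says A at pos 3
        ])
        assert trinucleotide_counts(s, genome).sum() == 0

    def test_unknown_chromosome_skipped(self):
        s = sample_of([VariantRecord("9", 2, "C", "A")])
        assert trinucleotide_counts(s, {"1": "ACAG"}).sum() == 0


class TestBinCounts:
    BINS = BinIndex((("1", 1, 1_000_000), ("1", 1_000_001, 2_000_000)))

    def test_inclusive_boundary(self):
        s = sample_of([VariantRecord("1", 1_000_000, "A", "C")])
        assert bin_counts(s, self.BINS).tolist() == [1, 0]

    def test_next_position_falls_in_second_bin(self):
        s = sample_of([VariantRecord("1", 1_000_001, "A", "C")])
        assert bin_counts(s, self.BINS).tolist() == [0, 1]

    def test_conservation_inside_bins(self):
        rng = np.random.default_rng(0)
        s = sample_of([VariantRecord("1", int(p), "A", "C")
                       for p in rng.choice(2_000_000, size=200, replace=False) + 1])
        assert bin_counts(s, self.BINS).sum() == len(s)

    def test_off_manifest_variants_uncounted(self):
        s = sample_of([VariantRecord("5", 10, "A", "C"),
                       VariantRecord("1", 2_500_000, "A", "C")])
        assert bin_counts(s, self.BINS).sum() == 0


class TestDriverCounts:
    GENES = GeneRegionTable((("G1", "1", 100, 200), ("G2", "1", 150, 250)))

    def test_inclusive_end_boundary(self):
        s = sample_of([VariantRecord("1", 200, "A", "C")])
        assert driver_counts(s, self.GENES).tolist() == [1, 1]

    def test_one_past_end_not_counted(self):
        s = sample_of([VariantRecord("1", 251, "A", "C")])
        assert driver_counts(s, self.GENES).tolist() == [0, 0]

    def test_overlap_double_counts(self):
        s = sample_of([VariantRecord("1", 175, "A", "C"),
                       VariantRecord("1", 120, "A", "C")])
        counts = driver_counts(s, self.GENES)
        assert counts.tolist() == [2, 1]
        assert counts.sum() > len(s) - 1  # sum may exceed variant count


class TestMatrixAndProperties:
    def test_matrix_shapes_and_order(self, tiny_cohort):
        cohort = tiny_cohort.samples[:10]
        blocks, labels, names = build_feature_matrix(
            cohort, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        assert blocks["bins"].shape == (10, len(tiny_cohort.bins))
        assert blocks["tri"].shape == (10, 96)
        assert blocks["drivers"].shape == (10, len(tiny_cohort.genes))
        assert labels == [s.label for s in cohort]

    def test_empty_cohort_keeps_feature_names(self, tiny_cohort):
        blocks, labels, names = build_feature_matrix(
            [], tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        assert blocks["tri"].shape == (0, 96)
        assert names["tri"] == list(TRINUCLEOTIDE_CLASSES)

    def test_linearity_under_disjoint_union(self, tiny_cohort):
        s = tiny_cohort.samples[0]
        half = len(s) // 2
        a = s.with_variants(s.variants[:half], sample_id="a")
        b = s.with_variants(s.variants[half:], sample_id="b")
        fa = featurize(a, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        fb = featurize(b, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        fs = featurize(s, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        for attr in ("bin_counts", "tri_counts", "driver_counts"):
            assert np.array_equal(getattr(fa, attr) + getattr(fb, attr),
                                  getattr(fs, attr))

    def test_downsampling_monotonicity(self, tiny_cohort):
        s = tiny_cohort.samples[3]
        sub = downsample(s, 0.25, seed=4)
        f_full = featurize(s, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        f_sub = featurize(sub, tiny_cohort.bins, tiny_cohort.genes, tiny_cohort.genome)
        for attr in ("bin_counts", "tri_counts", "driver_counts"):
            assert np.all(getattr(f_sub, attr) <= getattr(f_full, attr))

    def test_synthetic_variants_all_resolve_context(self, tiny_cohort):
        """Generated cohorts place refs straight off the genome, so the
        96-motif counts conserve the variant total."""
        s = tiny_cohort.samples[0]
        assert trinucleotide_counts(s, tiny_cohort.genome).sum() == len(s)
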