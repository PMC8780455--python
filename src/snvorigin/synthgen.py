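"""Self-contained synthetic cohorts for exercising the pipeline.

The real study cohort (consensus somatic SNV calls of 2374 primary tumors
across 16 cancer types) is controlled-access, so this module generates a
cohort carrying the same *statistical structure* the classifier exploits,
without imitating human biology: classes differ in

1. genome-wide bin-density profile (a per-class Dirichlet draw over bins —
   the stand-in for chromatin-organization imprints),
2. trinucleotide substitution spectrum (a per-class preference over the six
   pyrimidine substitution types), and
3. driver-gene mutation rates (a per-class set of enriched gene spans with
   a rate multiplier).

Everything — reference FASTA, per-sample VCFs, bin manifest, gene table,
label TSV — is a pure function of the config and master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (BinIndex, GeneRegionTable, LabelTable, SampleVariants,
                         VariantRecord, make_tiling_bins, write_bin_manifest,
                         write_gene_regions, write_labels, write_vcf)
from .sparsify import derive_seed

_PYR_SUBS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the desk-scale study conditions."""

    n_classes: int = 4
    samples_per_class: int = 20
    n_chromosomes: int = 2
    chromosome_length: int = 3_000_000
    bin_size: int = 1_000_000
    n_driver_genes: int = 12
    gene_length: int = 50_000
    burden_median: float = 2_000.0     # log-normal median SNVs per sample
    burden_sigma: float = 0.4          # log-scale dispersion
    bin_profile_alpha: float = 0.3     # Dirichlet conc.; smaller = more distinct classes
    substitution_alpha: float = 0.5    # Dirichlet conc. over the 6 substitution types
    n_enriched_genes: int = 3          # per class
    driver_multiplier: float = 20.0    # enrichment over the baseline per-bp rate
    seed: int = 0

    def class_names(self) -> list[str]:
        return [f"class{chr(65 + i)}" for i in range(self.n_classes)]

    def genome_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length


#: Named fixture profiles. ``tiny`` builds in seconds and drives the unit
#: tests; ``standard`` carries enough samples for the end-to-end study.
FIXTURE_PROFILES: dict[str, SyntheticConfig] = {
    "tiny": SyntheticConfig(),
    "standard": SyntheticConfig(
        n_classes=6, samples_per_class=40, n_chromosomes=4,
        chromosome_length=5_000_000, n_driver_genes=24, n_enriched_genes=3,
        burden_median=1_500.0, bin_profile_alpha=8.0, substitution_alpha=15.0,
        driver_multiplier=10.0,
    ),
}


@dataclass
class SyntheticTruth:
    """The generating parameters actually drawn, recorded pre-downsampling."""

    class_names: list[str]
    bin_profiles: np.ndarray            # (n_classes, n_bins)
    substitution_prefs: np.ndarray      # (n_classes, 6) over C>A..T>G
    enriched_genes: dict[str, list[str]]
    burdens: dict[str, int] = field(default_factory=dict)


def generate_reference(config: SyntheticConfig, seed: int | None = None,
                       ) -> tuple[dict[str, str], BinIndex, GeneRegionTable]:
    """I.i.d. uniform-base genome, 1 Mb bin tiling, non-overlapping gene spans."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, "reference"))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        str(c + 1): bases[rng.integers(0, 4, size=config.chromosome_length)].tobytes().decode()
        for c in range(config.n_chromosomes)
    }
    bins = make_tiling_bins({c: len(s) for c, s in genome.items()}, config.bin_size)
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for g in range(config.n_driver_genes):
        for attempt in range(1000):
            chrom = str(rng.integers(config.n_chromosomes) + 1)
            start = int(rng.integers(2, config.chromosome_length - config.gene_length - 1))
            end = start + config.gene_length - 1
            if all(end < s or start > e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                rows.append((f"GENE{g:03d}", chrom, start, end))
                break
        else:
            raise ValueError("could not place driver genes without overlap; "
                             "reduce n_driver_genes or gene_length")
    rows.sort(key=lambda r: (r[1], r[2]))
    return genome, bins, GeneRegionTable(tuple(rows))


def _draw_alt(rng: np.random.Generator, ref: str, sub_pref: np.ndarray) -> str:
    """Pick an alt base given the class's pyrimidine-strand substitution taste."""
    pyr = ref if ref in "CT" else _COMPLEMENT[ref]
    idx = [i for i, (r, _) in enumerate(_PYR_SUBS) if r == pyr]
    w = sub_pref[idx]
    alt_pyr = _PYR_SUBS[idx[rng.choice(3, p=w / w.sum())]][1]
    return alt_pyr if ref in "CT" else _COMPLEMENT[alt_pyr]


def generate_cohort(config: SyntheticConfig,
                    reference: tuple[dict[str, str], BinIndex, GeneRegionTable] | None = None,
                    ) -> tuple[list[SampleVariants], LabelTable, SyntheticTruth]:
    """Draw the full cohort; byte-identical for a fixed config."""
    genome, bins, genes = reference if reference is not None else generate_reference(config)
    if config.burden_median * 3 > config.genome_length():
        raise ValueError("mutation burden exceeds available genome positions")
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    names = config.class_names()
    truth = SyntheticTruth(
        class_names=names,
        bin_profiles=rng.dirichlet(np.full(len(bins), config.bin_profile_alpha),
                                   size=config.n_classes),
        substitution_prefs=rng.dirichlet(np.full(6, config.substitution_alpha),
                                         size=config.n_classes),
        enriched_genes={},
    )
    gene_rows = list(genes.rows)
    for c, cls in enumerate(names):
        chosen = rng.choice(len(gene_rows), size=min(config.n_enriched_genes, len(gene_rows)),
                            replace=False)
        truth.enriched_genes[cls] = sorted(gene_rows[i][0] for i in chosen)

    samples: list[SampleVariants] = []
    label_rows = []
    baseline_rate = config.burden_median / config.genome_length()  # SNVs per bp
    for c, cls in enumerate(names):
        for s in range(config.samples_per_class):
            srng = np.random.default_rng(derive_seed(config.seed, "sample", cls, s))
            burden = max(1, int(round(srng.lognormal(np.log(config.burden_median),
                                                     config.burden_sigma))))
            seen: set[tuple[str, int]] = set()
            variants: list[VariantRecord] = []

            def place(chrom: str, pos: int) -> None:
                if (chrom, pos) in seen or pos < 2 or pos > len(genome[chrom]) - 1:
                    return
                ref = genome[chrom][pos - 1]
                variants.append(VariantRecord(
                    chrom, pos, ref, _draw_alt(srng, ref, truth.substitution_prefs[c])))
                seen.add((chrom, pos))

            alloc = srng.multinomial(burden, truth.bin_profiles[c])
            for b, count in enumerate(alloc):
                chrom, start, end = bins.bins[b]
                for pos in srng.integers(start, end + 1, size=count):
                    place(chrom, int(pos))
            # enriched driver genes: extra mutations over the genome-wide rate
            for gene, chrom, start, end in gene_rows:
                if gene in truth.enriched_genes[cls]:
                    lam = (config.driver_multiplier - 1.0) * baseline_rate * (end - start + 1)
                    for pos in srng.integers(start, end + 1, size=srng.poisson(lam)):
                        place(chrom, int(pos))

            sid = f"{cls}_s{s:03d}"
            samples.append(SampleVariants(sid, f"{cls}_d{s:03d}", cls, tuple(variants)))
            truth.burdens[sid] = len(variants)
            label_rows.append((sid, f"{cls}_d{s:03d}", cls))
    return samples, LabelTable(tuple(label_rows)), truth


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(profile_name: str, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Write a named fixture cohort to disk; returns the checksum manifest."""
    if profile_name not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; "
                         f"choose from {sorted(FIXTURE_PROFILES)}")
    config = FIXTURE_PROFILES[profile_name]
    if seed is not None:
        config = SyntheticConfig(**{**vars(config), "seed": seed})
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    genome, bins, genes = generate_reference(config)
    samples, labels, truth = generate_cohort(config, reference=(genome, bins, genes))
    files = {
        "reference.fa": write_fasta(genome, out / "reference.fa"),
        "bins.tsv": write_bin_manifest(bins, out / "bins.tsv"),
        "genes.tsv": write_gene_regions(genes, out / "genes.tsv"),
        "labels.tsv": write_labels(labels, out / "labels.tsv"),
    }
    for s in samples:
        files[f"vcf/{s.sample_id}.vcf"] = write_vcf(
            s, out / "vcf" / f"{s.sample_id}.vcf",
            contigs={c: len(seq) for c, seq in genome.items()})
    manifest = {
        "profile": profile_name,
        "seed": config.seed,
        "n_samples": len(samples),
        "checksums": {name: _sha256(p) for name, p in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
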