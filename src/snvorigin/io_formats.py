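"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates in this package are 1-based inclusive (the VCF
convention). The tab-separated interval manifests (1 Mb bins, driver-gene
spans) use the same convention and say so in their header line; they are
deliberately *not* BED half-open files.

Chromosome names are normalised internally by stripping a leading ``chr``
prefix; the input's convention is remembered per sample and restored on
write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: GRCh37 (hg19) autosome lengths, used to build the shipped 1 Mb bin manifest.
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

DEFAULT_BIN_MANIFEST = Path(__file__).parent / "data" / "grch37_bins.tsv"


class FormatError(ValueError):
    """A file violated its declared format."""


class ValidationError(ValueError):
    """Parsed content violated an invariant (ordering, overlap, bounds)."""


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: 1..22, X, Y, MT, then others lexically."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A single somatic SNV: 1-based position, single-base ref and alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValidationError(f"alt equals ref at {self.chrom}:{self.pos}")


@dataclass
class SampleVariants:
    """One tumor sample's SNV set plus identity needed for leakage-safe CV.

    ``donor_id`` is stable across every downsampled or augmented derivative
    of a sample; the cross-validation splitter groups on it.
    """

    sample_id: str
    donor_id: str
    label: str
    variants: tuple[VariantRecord, ...]
    chr_prefix: bool = False  # input used 'chr' names; restored on write

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for v in self.variants:
            key = (v.chrom, v.pos, v.ref, v.alt)
            if key not in seen:
                seen.add(key)
                deduped.append(v)
        self.variants = tuple(sorted(deduped))

    def __len__(self) -> int:
        return len(self.variants)

    def with_variants(self, variants: Iterable[VariantRecord], sample_id: str | None = None) -> "SampleVariants":
        return SampleVariants(
            sample_id=sample_id if sample_id is not None else self.sample_id,
            donor_id=self.donor_id,
            label=self.label,
            variants=tuple(variants),
            chr_prefix=self.chr_prefix,
        )


@dataclass(frozen=True)
class BinIndex:
    """Ordered, non-overlapping genomic bins (1-based inclusive), each <= 1 Mb."""

    bins: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        order = [chrom_sort_key(c) for c, _, _ in self.bins]
        if order != sorted(order):
            raise ValidationError("bins are not sorted by chromosome order")
        for chrom, start, end in self.bins:
            if start > end:
                raise ValidationError(f"bin {chrom}:{start}-{end} has start > end")
            if end - start + 1 > 1_000_000:
                raise ValidationError(f"bin {chrom}:{start}-{end} exceeds 1 Mb")
            if chrom in prev and start <= prev[chrom]:
                raise ValidationError(
                    f"bin {chrom}:{start}-{end} overlaps or disorders previous bin")
            prev[chrom] = end

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def names(self) -> list[str]:
        return [f"bin_{c}:{s}-{e}" for c, s, e in self.bins]


@dataclass(frozen=True)
class GeneRegionTable:
    """Driver-gene spans, first-exon start to last-exon end, 1-based inclusive.

    Spans may overlap each other; a variant inside two spans counts in both.
    """

    rows: tuple[tuple[str, str, int, int], ...]  # (gene, chrom, start, end)

    def __post_init__(self) -> None:
        genes = [g for g, _, _, _ in self.rows]
        if len(genes) != len(set(genes)):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicate gene symbols: {dup}")
        for g, c, s, e in self.rows:
            if s > e:
                raise ValidationError(f"gene {g} ({c}:{s}-{e}) has start > end")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def names(self) -> list[str]:
        return [g for g, _, _, _ in self.rows]


@dataclass(frozen=True)
class LabelTable:
    """sample_id -> (donor_id, label) assignment, one row per sample."""

    rows: tuple[tuple[str, str, str], ...]  # (sample_id, donor_id, label)

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_id in label table")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> list[str]:
        return [l for _, _, l in self.rows]

    def donor_of(self, sample_id: str) -> str:
        for s, d, _ in self.rows:
            if s == sample_id:
                return d
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_id: str, donor_id: str, label: str) -> SampleVariants:
    """Read somatic SNVs from a VCF (plain or bgzipped).

    Multi-allelic lines are split; each single-base alt becomes its own
    record. Indels, MNVs and symbolic alts are dropped (counted in the log).
    The FILTER column is ignored: consensus calls are assumed pre-filtered.
    Duplicate (chrom, pos, ref, alt) entries collapse to one.
    """
    path = Path(path)
    variants: list[VariantRecord] = []
    dropped = 0
    chr_prefix = False
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.chrom.lower().startswith("chr"):
                    chr_prefix = True
                ref = rec.ref or ""
                for alt in rec.alts or ():
                    if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and alt != ref:
                        variants.append(VariantRecord(normalize_chrom(rec.chrom), rec.pos, ref, alt))
                    else:
                        dropped += 1
    except (ValueError, OSError) as exc:
        raise FormatError(f"unparseable VCF {path}: {exc}") from exc
    if dropped:
        log.info("read_vcf(%s): dropped %d non-SNV alt alleles", path.name, dropped)
    if not variants:
        warnings.warn(f"VCF {path} contained no SNVs", stacklevel=2)
    return SampleVariants(sample_id, donor_id, label, tuple(variants), chr_prefix=chr_prefix)


def write_vcf(sample: SampleVariants, path: str | Path,
              contigs: dict[str, int] | None = None) -> Path:
    """Write a minimal VCF 4.2 for one sample, restoring its 'chr' convention.

    ``contigs`` maps chromosome name to length; when given, every variant
    chromosome must be declared. When omitted, contig headers are derived
    from the variants themselves (length = max position seen).
    """
    path = Path(path)
    if contigs is not None:
        declared = {normalize_chrom(c) for c in contigs}
        missing = sorted({v.chrom for v in sample.variants} - declared)
        if missing:
            raise ValidationError(f"variant chromosomes not in declared contigs: {missing}")
        contig_items = sorted(((normalize_chrom(c), l) for c, l in contigs.items()),
                              key=lambda cl: chrom_sort_key(cl[0]))
    else:
        lengths: dict[str, int] = {}
        for v in sample.variants:
            lengths[v.chrom] = max(lengths.get(v.chrom, 0), v.pos)
        contig_items = sorted(lengths.items(), key=lambda cl: chrom_sort_key(cl[0]))

    pre = "chr" if sample.chr_prefix else ""
    lines = ["##fileformat=VCFv4.2", f"##source=snvorigin sample={sample.sample_id}"]
    lines += [f"##contig=<ID={pre}{c},length={l}>" for c, l in contig_items]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sample.variants:
        lines.append(f"{pre}{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# TSV manifests
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line.split("\t")


def read_bin_manifest(path: str | Path | None = None) -> BinIndex:
    """Load a bin manifest (chrom, start, end; 1-based inclusive).

    With no argument, loads the shipped GRCh37 manifest of 2897 1 Mb
    autosomal bins.
    """
    path = DEFAULT_BIN_MANIFEST if path is None else Path(path)
    bins = []
    for i, cols in _read_tsv_rows(path):
        if cols[0] in ("chrom", "chr"):  # header row
            continue
        if len(cols) < 3:
            raise FormatError(f"{path}:{i}: expected >=3 columns, got {len(cols)}")
        try:
            chrom, start, end = normalize_chrom(cols[0]), int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
        if start > end:
            raise ValidationError(f"{path}:{i}: start {start} > end {end}")
        bins.append((chrom, start, end))
    if not bins:
        warnings.warn(f"bin manifest {path} is empty", stacklevel=2)
    return BinIndex(tuple(bins))


def read_gene_regions(path: str | Path) -> GeneRegionTable:
    """Load driver-gene spans (gene, chrom, start, end; 1-based inclusive)."""
    rows = []
    for i, cols in _read_tsv_rows(path):
        if cols[0] in ("gene", "gene_symbol"):
            continue
        if len(cols) < 4:
            raise FormatError(f"{path}:{i}: expected >=4 columns, got {len(cols)}")
        try:
            gene, chrom, start, end = cols[0], normalize_chrom(cols[1]), int(cols[2]), int(cols[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
        if start > end:
            raise ValidationError(f"{path}:{i}: start {start} > end {end}")
        rows.append((gene, chrom, start, end))
    if not rows:
        warnings.warn(f"gene table {path} is empty", stacklevel=2)
    return GeneRegionTable(tuple(rows))


def read_labels(path: str | Path) -> LabelTable:
    """Load the sample/donor/label table."""
    rows = []
    for i, cols in _read_tsv_rows(path):
        if cols[0] in ("sample_id", "sample"):
            continue
        if len(cols) < 3:
            raise FormatError(f"{path}:{i}: expected 3 columns, got {len(cols)}")
        rows.append((cols[0], cols[1], cols[2]))
    if not rows:
        warnings.warn(f"label table {path} is empty", stacklevel=2)
    return LabelTable(tuple(rows))


def write_labels(table: LabelTable, path: str | Path) -> Path:
    path = Path(path)
    lines = ["sample_id\tdonor_id\tlabel"]
    lines += [f"{s}\t{d}\t{l}" for s, d, l in table.rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_bin_manifest(bins: BinIndex, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# 1-based inclusive coordinates", "chrom\tstart\tend"]
    lines += [f"{c}\t{s}\t{e}" for c, s, e in bins.bins]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_gene_regions(genes: GeneRegionTable, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# 1-based inclusive coordinates, first-exon start to last-exon end",
             "gene\tchrom\tstart\tend"]
    lines += [f"{g}\t{c}\t{s}\t{e}" for g, c, s, e in genes.rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def make_tiling_bins(chrom_lengths: dict[str, int], bin_size: int = 1_000_000) -> BinIndex:
    """Tile chromosomes with fixed-size bins; the final partial bin is kept.

    Tiling the GRCh37 autosomes at 1 Mb this way yields the 2897-bin
    genome-wide density feature space.
    """
    bins = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        length = chrom_lengths[chrom]
        start = 1
        while start <= length:
            bins.append((normalize_chrom(chrom), start, min(start + bin_size - 1, length)))
            start += bin_size
    return BinIndex(tuple(bins))
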