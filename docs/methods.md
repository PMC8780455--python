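# Methods

## Problem and model

The package classifies the cell of origin of a tumor from its somatic SNV
set, under the sparsity characteristic of liquid biopsies. A sample is an
unordered set of single-base substitutions; all information used downstream
is derived from three per-sample count vectors:

* **bin densities** — SNVs per 1 Mb genomic window. On GRCh37 the shipped
  manifest tiles the 22 autosomes at 1 Mb with the final partial window
  kept, giving 2897 bins; sex chromosomes are excluded. The manifest is
  generated from the published autosome lengths and shipped as
  `src/snvorigin/data/grch37_bins.tsv`; synthetic genomes are tiled the
  same way.
* **trinucleotide motifs** — each SNV mapped to one of the 96 classes
  (6 pyrimidine-strand substitutions × 4 × 4 flanking bases, COSMIC
  convention): purine-centred contexts are reverse-complemented so e.g.
  TGC:G>A counts as GCA>GTA. Variants at a sequence edge or whose reference
  base disagrees with the FASTA are skipped and logged rather than raised —
  a masked reference base should not corrupt the remaining 95 counts.
* **driver-gene densities** — SNVs per gene span (first-exon start to
  last-exon end, 1-based inclusive). Overlapping spans each count a shared
  variant, because each gene feature is defined independently. The gene
  table is an input, not a constant: published driver lists vary by release.

All interval arithmetic in the package is 1-based inclusive (the VCF
convention); the TSV manifests declare this in their header lines rather
than using BED half-open coordinates, so no mixed conventions exist
internally. Chromosome names are normalised by stripping a leading `chr`
and the input's convention is restored on write.

The classifier is a softmax feed-forward network over the three feature
blocks in one of three wirings — early (concatenate, one stack),
multi-branch (one stack per block, late fusion), consecutive (each stage's
last hidden layer concatenated with the next raw block). Inputs are
`log1p`-transformed counts by default, which compresses the ~3 orders of
magnitude spread in mutation burden; raw and total-normalised modes are
config switches.

## Sparsity and augmentation

Retention of a fraction *p* keeps exactly k = max(1, ⌊pn + 0.5⌋) variants,
drawn uniformly without replacement (ties round half up so k is the
conventional rounded percentage). A per-variant Bernoulli mode exists
behind a flag, but the fixed-k form matches the "retain x% of SNVs"
protocol and makes cardinality exactly testable. Augmentation draws N
independent subsamples per training parent; validation and test parents
always receive exactly one subsample at the experiment's retention.
Provenance records (parent, donor, replicate, seed) travel with every
subsample, and the splitter partitions *donors*, so no derivative of a
training donor can reach validation or test.

Child seeds are SHA-256 hashes of (master seed, parent id, replicate
index) reduced mod 2³¹: adding parents or replicates never reshuffles the
draws of existing ones, and every byte of output is a pure function of the
config and master seed.

## Training, tuning and evaluation

Training uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 32, 50
epochs, glorot-uniform kernels and zero biases. Choices the protocol
leaves open were fixed as follows: the loss is categorical cross-entropy;
final-epoch weights are kept (no early stopping — validation data serve
only the tuning objective and reporting); the L2 penalty applies to dense
kernels, not biases; dropout follows each hidden layer and is not applied
to raw inputs; the consecutive wiring's default feature order is bins →
trinucleotides → drivers (widest to narrowest) and is configurable. Top-k
prediction lists break probability ties by ascending class index so
rankings are deterministic.

Hyperparameters (learning rate 1e-5–1e-2 log-uniform, L2 1e-6–1e-2
log-uniform, dropout 0–0.5, 1–4 layers, 32–512 nodes, activation ∈ {relu,
tanh, elu, sigmoid}) are searched by sequential GP minimization: 10 random
initial evaluations, then Matern-5/2 expected-improvement proposals chosen
from a 512-point random candidate pool. Multi-branch and consecutive
models are tuned per entry point, sequentially, with earlier winners
frozen. The desk-scale default budget is 25 calls per entry point; the
full 200-call budget is a config value. A failing objective evaluation is
recorded at the worst value seen and the search continues.

Cross-validation is 3× stratified shuffle-split with 60/20/20 fractions.
Class allocation uses largest-remainder rounding over donors, which keeps
per-partition class proportions within rounding of the global ones and is
reproducible; classes with fewer than three donors go whole to training
with a warning. Metrics: per-class F1 (zero when precision+recall is
zero), unweighted class-mean F1, micro accuracy, top-1/2/3 accuracy, and
confusion matrices. Configuration comparisons use classical paired
t-tests on per-fold accuracy (3 pairs, 2 df — a deliberately conservative
pairing; per-class pairing is available). Identical paired vectors report
p = 1 with a warning; zero-variance non-zero differences leave the
statistic NaN.

## Attribution

Integrated gradients uses a zero baseline, a midpoint Riemann rule with 50
steps by default, and differentiates the *pre-softmax* score of the top
predicted class (a softmax-probability mode is a switch; the pre-softmax
score keeps attributions linear in the final layer and is exact for linear
scorers at any step count). Completeness — Σ IG_j = F_c(x) − F_c(0) — is
the numerical control; with smooth activations the midpoint rule reaches
relative error ~1e-4 at 300 steps.

Class summaries average per-sample attributions over each class's test
samples. For cross-sparsity heatmaps the class means are log-modulus
transformed and scaled per feature-type matrix: positive entries divide by
the matrix maximum and negative entries by the *magnitude* of the matrix
minimum, preserving sign. The sign-preserving form was chosen over the
literal f/f_min variant (available via `literal=True`) because dividing a
negative value by a negative minimum flips its sign, which contradicts a
signed diverging colour scale. Top-feature selection ranks by absolute
class-mean attribution within each feature type (defaults: 1 bin, 2
trinucleotides, 2 drivers per class), unions across classes, and drops
features with zero attribution in every class.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes classes
differ in: a per-class bin-density profile (Dirichlet draw over bins), a
per-class preference over the six pyrimidine substitution types, and a
per-class set of driver genes enriched by a rate multiplier. Genomes are
i.i.d. uniform bases; per-sample burden is log-normal; mutations are
multinomially allocated to bins, uniformly placed within them, and
deduplicated by position.

Two frozen profiles define the study conditions:

* `tiny` — 4 classes × 20 samples, 2 × 3 Mb chromosomes, burden median
  2000, strongly separated classes (bin Dirichlet α = 0.3). Builds in
  seconds; drives unit tests and examples where learnability, not
  difficulty, is the point.
* `standard` — 6 classes × 40 samples, 4 × 5 Mb chromosomes, burden median
  1500, weakly separated classes (bin α = 8, substitution α = 15, driver
  multiplier 10). These values place the cohort in the method's operating
  regime: near-ceiling accuracy on full profiles, marked degradation at 2%
  retention (~30 SNVs/sample), and a clear augmentation benefit — the same
  qualitative behaviour the method was designed around, at a size where
  the full grid runs in minutes on one CPU.

What the generator does **not** model: real human mutational signatures or
chromatin-derived density profiles, sequencing error, allele-frequency- or
coverage-dependent dropout, germline contamination, clonal haematopoiesis,
CNV/SV/indel events, or realistic class imbalance. Passing tests on these
cohorts therefore demonstrate that the pipeline's machinery behaves as
specified (leakage-free augmentation, feature conservation, sparsity
response, attribution axioms) — not that the reported accuracies transfer
to real tumors.

## Numerical choices and degenerate inputs

* Retained count rounds half up and floors at 1; p = 1 is an exact
  identity.
* Fold-averaged accuracy comparisons across the retention grid use an
  equality slack of 0.02: with 144 test predictions per point, binomial
  noise near the accuracy ceiling is ~0.03, so adjacent grid points may
  tie; the full-data vs 2% comparison is strict.
* Multi-allelic VCF lines split into one record per single-base alt;
  non-SNV alleles are dropped with a logged count; FILTER is ignored
  (consensus calls are assumed pre-filtered upstream, as are germline and
  white-blood-cell variants).
* An all-zero attribution matrix scales to itself with a warning; empty
  classes average to NaN rows with a warning; over-large top-k requests
  are capped with a warning.
* Everything is single-threaded NumPy; with a fixed master seed all
  metrics files reproduce exactly.

## Known limitations

The networks are desk-scale (hundreds to thousands of inputs, ≤ 4 hidden
layers); no GPU path exists. The GP search treats integer dimensions by
rounding on a continuous lattice encoding, which is standard but can
propose duplicate candidates at small budgets. The paired t-test on three
folds has little power — stars should be read as the protocol's
convention, not as strong evidence. Real-data performance claims are out
of scope by construction.
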