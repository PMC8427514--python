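# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `epiatlas`, and what passing tests do and do not show
about real data.

## Coordinates, binning and intervals

All internal coordinates are 0-based half-open (BED convention); 1-based
inputs — GWAS catalog positions and Bismark-style CpG coverage files — are
converted once, at the parser boundary.  The genome is an ordered
chromosome table; fixed-width bins (default 200 bp) are numbered globally
in assembly order, terminal bins may be short and are retained so the
ordinal ↔ coordinate mapping stays bijective.  Bin membership of an
interval is decided by ≥ 1 bp overlap by default (`min_overlap`
configurable); peak–promoter overlap for the proximal/distal split likewise
uses ≥ 1 bp.  Promoter windows are TSS − 2000 / TSS + 500 bp, strand-aware
and clipped to chromosome bounds.

## Binarization

A bin's mark call is 1 when the Poisson upper-tail probability of its read
count, under expectation λ = max(depth-scaled control count, genome-wide
mean signal per bin), is ≤ 1e-4.  Flooring at the global mean prevents
near-zero control bins from producing spurious calls; without a control the
expectation is the global mean.  The procedure is monotone in the count.
The p-threshold and control handling are exposed as configuration because
upstream conventions vary.

## The chromatin-state HMM

Emissions are product-Bernoulli per state (marks conditionally independent
given the state); this is the standard model class for multi-mark
chromatin-state maps, and its parameters are directly interpretable as
per-state mark frequencies.  Chromosomes are independent observation
sequences — no transition is learned or applied across a chromosome
boundary.

*Numerics.* Forward–backward uses per-position scaling plus a per-bin
log-max shift, never raw probability products; posteriors sum to 1 within
1e-9 and match an exhaustive path-enumeration oracle to < 1e-10 on
instances small enough to enumerate.  Decoding is per-bin max posterior
(not Viterbi), with ties broken to the lowest state ordinal — a fixed,
deterministic convention.

*Training.* Baum–Welch with emissions initialised from seeded k-means
cluster means of the binary mark vectors (subsampled to 100k bins when
larger), transitions at 0.9 self / uniform off-diagonal, uniform initial
distribution.  Iteration stops when the log-likelihood gain drops below
1e-4 or after 200 rounds.  All probabilities are clamped to
[1e-6, 1 − 1e-6]; clamping can in principle cause sub-epsilon likelihood
decreases, so monotonicity is asserted with 1e-9 slack (observed gains are
strictly positive away from degenerate inputs).  Training is
seed-deterministic.

*Model I/O.* Models round-trip through the ChromHMM text dialect
(probinit / transitionprobs / emissionprobs lines) with probabilities at 10
significant digits, and through paired emission/transition TSV tables.  A
file without probinit lines gets a uniform initial distribution.

*Enrichment.* Overlap enrichment is computed at bin resolution,
fold(s) = P(s ∩ A)/(P(s)·P(A)); states with no bins are reported as
missing (NaN), never 0, because a zero fold is a meaningful observation
while an absent state is not.  Neighborhood enrichment mirrors offsets for
minus-strand anchors and drops off-chromosome positions from the
denominator of that offset.

## UMR/LMR segmentation

Candidate regions are maximal runs of consecutive retained CpGs
(coverage ≥ 5) with level < 0.5, of length ≥ n.  n is selected as the
smallest value ≥ 5 whose permutation FDR — mean candidate count over 20
methylomes with levels shuffled globally across retained positions,
divided by the observed count — is < 0.05; the search stops at n = 50 and
returns nothing (with a warning) if no n qualifies.  Region intervals span
the first to last CpG of the run, end-exclusive at last position + 1.  The
UMR/LMR split at 30 CpGs follows the conventional CpG-count distinction
between promoter-like and distal hypomethylated segments and is
configurable.  This is a deliberate simplification of full
hidden-Markov/alpha-distribution methylome segmenters: it preserves the
published cutoffs (level 0.5, ≥ 5 CpGs, FDR 0.05) as testable contracts
while remaining exactly analysable.  Partially methylated domains are out
of scope; synthetic methylomes are generated PMD-free, and a pre-masked
exclusion set can be applied upstream.

The permutation is global rather than per-chromosome: retained positions
are fixed and levels are permuted across all of them, which preserves the
CpG spacing structure that determines run-length statistics.

## Expression classification

The GMM input is the per-gene mean of log2(TPM + 0.01) across samples
(mean of logs, the convention that matches the bimodal density actually
fitted; mean-then-log is available by transforming upstream).  EM is
initialised deterministically at the 25th/75th percentile means, pooled sd
and equal weights; with a strongly bimodal input this lands in the
dominant basin, so no random restarts are needed by default (the seed
argument is reserved for optional restarts).  Components are reported in
ascending mean order — component 1 repressed, component 2 expressed —
regardless of initialisation.  Genes are assigned at posterior ≥ 0.9;
genes between the modes are reported as an explicit `ambiguous` class
rather than silently forced into one component.  Variances are floored at
1e-12 to avoid collapse.

Specificity calls use linear TPM (the Human Protein Atlas convention),
fold 4, group sizes 2–5, and a strict TPM > 1 filter in the target tissue.
The group-enriched search grows the group greedily from the
highest-expressing tissues (smallest qualifying group wins); an exhaustive
subset search is available behind a flag — greedy differs from exhaustive
only in contrived near-tie configurations.  Quantile normalization maps
every column onto the mean order-statistic profile with ties receiving the
mean of their tied reference values; batch removal is per-gene batch-mean
equalization that preserves each gene's grand mean exactly.

## Enhancer atlas

The presence matrix keeps only bins active in ≥ 1 epigenome; rows are
global bin ordinals, so calls re-project exactly onto the genome.
"Specific" means column-sum exactly 1 — active in the target and in no
other panel member — before merging adjacent bins into regions.  The
shared fraction is computed at bin level by default (the region-level
variant, counting merged union regions fully shared, is
`shared_fraction_regions`).  Similarity uses Pearson r on the binary
columns, complete linkage on d = 1 − r, and classical (Torgerson) MDS on
d; constant columns are rejected by name since their correlation is
undefined.  K-means on enhancer signal uses seeded k-means++ with 10
restarts, and labels are renumbered 1..k by descending cluster mean
intensity so cluster identities are comparable across runs.  Gene–enhancer
linking is a pure ±20 kb TSS-window overlap (≥ 1 bp, half-open); no
chromatin-contact information is used.

## GWAS enrichment

Pruning is the greedy genomic-order scan: keep a SNP iff no already-kept
SNP on the same chromosome lies strictly closer than 1 Mb (exactly 1 Mb is
kept).  chrY is excluded and chrX retained; the ≥ 2 SNP study filter is
applied to the pre-pruning study size (a post-pruning variant is
flag-selectable).  The background is the pooled pruned catalog with SNPs
deduplicated by position across studies (configurable).  p-values are raw
hypergeometric upper tails via the log-space survival function; no
multiple-testing correction is applied by default, matching the
convention of thresholding raw p at 0.05, with Benjamini–Hochberg
available downstream.  The active-enhancer state set defaults to
{9_EnhA1, 10_EnhA2} of the 18-state vocabulary and is configurable.

## Synthetic study conditions

The generators define the study conditions; their defaults are fixed and
not tuned per run:

* **Toy genome**: 2 chromosomes × 2 Mb (20,000 bins of 200 bp) — large
  enough for stable frequencies, small enough that the full demo runs in
  about a second.
* **Marks**: 6 canonical histone marks emitted from a well-separated
  5-state model (promoter, transcription, enhancer, Polycomb, quiescent)
  with 0.97 self-transition; raw counts are Poisson(2)/Poisson(30) for
  absent/present calls.
* **Methylome**: 50,000 CpGs, background levels Beta(9,1), 30 planted
  regions of 20 CpGs at Beta(1,9), coverage Poisson(22), methylated counts
  Binomial(coverage, level) — reproducing the bimodal methylation
  histogram of normal somatic tissue.
* **Expression**: mean log2(TPM+0.01) mixture 0.45·N(−6,1) + 0.55·N(4,1.5²)
  across 14 tissues with per-tissue jitter sd 0.25.  Planted specificity
  genes are constructed *exactly* at their fold ratios (4.5× for positives,
  3.9× for boundary negatives, TPM 0.8 for low-expression negatives) with
  no noise on the planted rows, so the fold-rule boundary tests are sharp
  rather than probabilistic.
* **Epigenome panel**: 20 epigenomes sharing a 2% backbone of common
  enhancer bins plus 1% noise bins, with 200 bins planted exclusively in
  the target.  Noise bins are each assigned to ≥ 2 epigenomes so the
  planted bins are provably the only single-epigenome bins — the
  specific-enhancer test asserts exact set equality.
* **GWAS**: a 10 × 50 Mb genome divided into 2-Mb slots whose first 1 Mb
  holds SNPs (so per-study SNPs always survive megabase pruning), with the
  leading 30% of each window as enhancer territory.  The null calibration
  uses 1,000 studies of 40–120 SNPs at background overlap 0.3; study sizes
  are varied so the discrete hypergeometric attainable levels average out
  near the nominal 0.05.  The planted-enrichment check uses 50 studies
  with one at 0.8 overlap versus 0.1 background.

What these simulations do **not** model: mappability and blacklist
artefacts, copy-number and GC biases, linkage disequilibrium structure in
GWAS catalogs (spacing is geometric, not population-genetic), partially
methylated domains, batch effects in expression (the batch-removal routine
is tested on constructed shifts), and the correlated mark co-occurrence of
real chromatin beyond what the HMM itself induces.  Passing the recovery
tests therefore demonstrates correctness of the algorithms under their
stated models, not robustness to every artefact of real sequencing data.

## Problem sizes

The validation suite uses: 20 enumeration instances of ≤ 8 bins / 3 states
for HMM exactness; 10,000 bins for state recovery; 50,000 bins for
Baum–Welch recovery; 50,000 CpGs (plus 20 null seeds) for UMR/LMR; 10,000
genes for the GMM; 1,000 genes for specificity; a 20-epigenome panel for
the atlas; and 1,000 null + 50 planted studies for GWAS calibration.  The
whole suite runs in well under a minute of compute on one CPU; sizes were
chosen as the smallest at which sampling error is comfortably inside the
asserted tolerances.

## Known limitations

* The Bernoulli-emission HMM assumes mark independence given the state;
  correlated assay noise violates this and inflates state confidence.
* The run-based methylome segmenter has no notion of region-internal
  heterogeneity; a single high-methylation CpG splits a region.
* The greedy group-enriched search can miss a qualifying non-greedy group
  when tissue expressions are nearly tied (exhaustive flag available).
* Hypergeometric enrichment treats SNPs within a study as exchangeable
  after pruning; residual long-range LD is not modelled.
* Classical MDS on 1 − r can produce small negative eigenvalues for
  strongly non-Euclidean inputs; negative components are truncated at 0.
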