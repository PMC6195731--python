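# Methods

This note documents the models, conventions, parameters and design
choices behind tilescope, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and gene models

Genomic intervals are 0-based half-open; amino-acid and coding-nucleotide
positions are 1-based. The CDS of a transcript includes the stop codon and
must be a multiple of 3; the protein length L excludes the stop
(`L = cds_length/3 − 1`). This single convention is asserted in the
`Transcript` constructor and used everywhere, which makes arithmetic at
exon borders unambiguous.

Residue-level mapping always uses the transcript flagged principal
(GFF3 attribute `principal=1`, first transcript otherwise); the isoform
fraction of a cut site is computed over all transcripts of the gene.

## Cut sites and amino-acid mapping

SpCas9 is modeled as a blunt cut 3 bp 5′ of the PAM, between protospacer
positions 17 and 18 (1-based). The stored cut coordinate is the 0-based
genomic position of the base immediately 3′ of the break on the + strand,
so a + strand protospacer `[i, i+20)` cuts at `i+17` and a − strand one at
`i+3`.

A guide maps to the two residues flanking the break: with k the coding
position of the base 5′ of the break on the coding strand, the pair is
`(ceil(k/3), ceil((k+1)/3))`; when both flanking bases share a codon the
pair is collapsed to that codon and the next downstream, clipped at L.
When only the 3′-flanking base is coding (cut exactly at a CDS boundary),
its coding position supplies k; when neither flanking base is coding the
guide is excluded from residue-level analyses but retained for counting.
Exon-level features (exon length, border distances) are taken from the
exon containing the coding base used for k, reported in transcript
orientation.

Nonsense-mediated decay: a frameshift at coding position k is predicted to
trigger NMD when k lies more than 55 nt upstream of the last junction
between coding exons; otherwise (including single-coding-exon
transcripts) it escapes. `nmd_escape` is therefore a monotone function of
k along the transcript.

## Counting and scoring

A read maps when the 20-nt window at a configured offset (or after a 5′
anchor) equals a library spacer exactly; the synthetic reads place the
spacer at offset 0, the simplest architecture satisfying this contract.
Real read layouts vary by vector, hence both the offset and the anchor are
configurable.

The ALFC score is the replicate-averaged difference of log2
counts-per-million with pseudocount 1:
`log2((t_i + 1)/N_t) − log2((u_i + 1)/N_u)`. The shrinkage variant
multiplies the ALFC estimate by `w = S/(S + τ)` (S = the guide's total
count in the comparison, τ = 100 by default), pulling low-count — hence
noisy — estimates toward 0. This reproduces, with an explicit closed-form
weight, the qualitative behavior of count-model shrinkage estimators:
guides supported by many reads are essentially unshrunken while guides at
the detection limit are strongly attenuated. Guides undetected in all
samples are reported but excluded from score-based analyses.

Scores are normalized by subtracting the median score of negative-control
guides (neutral genome-targeting controls preferred over non-targeting
ones, to account for gene-independent cutting toxicity). Normalization is
idempotent and leaves the control median at exactly 0. Guides with an MIT
off-target specificity score below 5 (0–100 scale, low = promiscuous) are
removed by default; the threshold is user-adjustable and guides with a
missing score are kept with a warning.

QC per sample: total/mapped/percent-mapped reads, the Gini coefficient of
the count distribution (`G = Σ(2i − n − 1)x₍ᵢ₎ / (nΣx)`, ascending order),
count summaries (mean, sd, min, p10, median, p90, max; percentiles by
linear interpolation), and the all-pairs Pearson correlation of raw
counts.

## LOESS smoothing

Scores of residues with no guide are interpolated by locally weighted
quadratic regression with tricube weights and no robustness iterations,
evaluated at every residue 1..L. The span is expressed as data per local
fit: 100 residues' worth, i.e. fraction `min(1, 100/L)` — small proteins
use all points, large proteins a sliding window of ~100 residues of
coverage. Each local fit is floored at 4 points (a quadratic is otherwise
underdetermined), and when the outermost included points carry exactly
zero tricube weight the bandwidth is nudged by 1e-9 so the local system
stays full rank. Proteins with fewer than 8 distinct guide positions fall
back to linear interpolation with constant edge extension, with a
warning, since quadratic local fits are degenerate at tiny n. Multiple
guides mapping to one residue are averaged before fitting. Outside the
guide-covered range the local polynomial extrapolates; the per-residue
`raw` track records which residues were actually observed.

## Annotations

Conservation is consumed as PROVEAN single-residue deletion scores (more
negative = more conserved); disorder as a [0, 1] propensity (1 =
disordered); both are inputs produced by external predictors, not
recomputed. The consensus secondary structure sums per-tool probabilities
per state {helix H, strand B, coil C}, divides by the grand total, and
labels each residue by the arg-max weight; exact ties resolve to coil and
are logged. Unobserved states count as probability 0.

The 13 non-mutually-exclusive amino-acid classes (polar, nonpolar,
hydrophobic, hydrophilic, positively/negatively charged, aliphatic,
aromatic, acidic, basic, hydroxylic, sulfur-containing, amidic) are fixed
lookup sets; non-canonical letters (e.g. selenocysteine U, too rare to
analyze) get an empty set with a warning. Domain membership of a guide is
true when **either** mapped residue overlaps any domain interval
(intervals 1-based inclusive) — the edge case is not otherwise defined, so
the inclusive choice is used and documented here.

## Gene statistics and hit calling

Per gene: mean, sd, quartiles (linear interpolation), IQR, the 1-D
Wasserstein-1 (earth mover's) distance between the gene's guide-score
distribution and the negative-control distribution, guide density
(guides/L) and mean successive distance between guide aa1 positions.

A gene is a hit when at least 75% of its guides share a sign, i.e. the
IQR of its normalized scores excludes 0; operationally `q1 > 0 or q3 < 0`.
When a quartile lands exactly on 0 the gene is *not* called — the strict
inequality is the operative rule. Direction is positive when the median
exceeds 0, else negative. A user-supplied hit list overrides the rule
entirely. Rank-based tests against controls are deliberately not used for
hit calling: with hundreds of guides per gene even trivial effect sizes
reach significance.

Association tests follow annotation arity: Spearman correlation for
continuous annotations, two-sided Mann-Whitney for binary ones,
Kruskal-Wallis for multi-level ones (amino-acid identity, codon,
secondary structure, and the amino-acid classes one-vs-rest). Pooled
analyses z-score each gene's scores (population sd) before pooling so no
single gene dominates; per-gene analyses test each hit gene separately.
Raw p-values are reported; a Benjamini-Hochberg column is optional.
Grouped means split guides by conservation (PROVEAN ≤ −6 by default) and
by domain membership or a disorder threshold (≤ 0.5), reporting the mean
score and percentage of guides per cell.

## Structure mapping

Structure chains are aligned to the protein sequence by Smith-Waterman
local alignment with BLOSUM62, gap open −10, gap extend −0.5. Aligned
residues — including mismatched-but-aligned ones — map to protein
positions; unalignable structure residues map to nothing and are colored
as no-data.

The color scale is calibrated once per dataset: the outermost bin edge is
`max(|p5|, |p95|)` of the full score distribution, bins (17 by default, 9
optional) evenly spaced and symmetric around 0, scores beyond the edges
clipped into the outermost bins. LOESS-smoothed scores are mapped by
default (raw optional). Every atom of a mapped residue receives the
residue score in the B-factor column (2 decimals); unmapped residues get
the sentinel 999.00, documented in a REMARK header, and yellow in the
emitted color table. Output is viewer-agnostic text — recolored PDB, TSV
color table, optional PyMOL-syntax command script — rather than a binary
session file, so it is diffable and testable. Linear per-gene figures
stack guide points, the smoothed curve, conservation, disorder, secondary
structure and domain tracks, and export their underlying table
byte-deterministically.

## Score prediction

Targets: per gene, scores are multiplied by −1 when the gene's mean is
negative, then z-scored (population sd), so a high scaled score always
means a strong effect regardless of screen direction. Genes with < 2
guides or zero variance are dropped; an optional training filter drops
genes whose raw mean exceeds a threshold (−1 in the dropout-screen
setting) as outliers.

Features: one-hot amino-acid identity of the two targeted residues,
single-nucleotide identity at spacer positions 0–19 and dinucleotide
identity at positions 0–18 (0-indexed from the 5′ end, a mapping the
feature names carry directly), domain/NMD/exon-frame/strand flags, and
numeric context (PROVEAN and disorder of both residues, protein fraction,
GC content of the 20-mer, exon length, off-target score, both exon-border
distances). Missing numeric values are imputed with the training median
plus a missingness indicator.

Model: LightGBM gradient-boosted trees with `bagging_freq` 0,
`colsample_bytree` 1/3, `learning_rate` 0.01, `max_depth` −1,
`min_child_samples` 32, `n_estimators` 1024, `max_bin` 63; all other
parameters at library defaults; boosting seed fixed (default 7) and
recorded in the saved model archive. Feature importance is total
information gain of splits. Evaluation is strictly gene-grouped: 10-fold
cross-validation holds out all guides of ~10% of genes per fold (a hard
no-leakage assertion), and performance is the Spearman correlation of
observed vs held-out predicted scaled scores per gene, averaged over
genes with ≥ 3 guides.

## Synthetic data: what it emulates and what it does not

The generator builds, from a seed, per-gene contigs (GC-biased random
codons, multi-exon layout with GT..AG introns, both strands exercised),
enumerates real guides at real PAMs, and plants: a central domain
(~40% of the protein) that is conserved, ordered and helical; a
per-residue effect profile `w₁·conservation + w₂·order + domain offset`
(defaults 0.4/0.3/0.3, min-max scaled); per-guide true log2 fold changes
`hit_strength · (0.5 + 0.5·profile)` plus Gaussian noise (sd 0.3); and
counts as Poisson draws at 100k reads/sample, two replicates per arm, with
the test arm reweighted by 2^lfc. Defaults describe a two-gene screen —
one strong negative hit (strength −3), one neutral gene — with 40 guides
per gene and 50 neutral control guides. Reads are exact spacers at offset
0 with constant quality.

The prediction fixture (40 genes × 50 guides, seed 7, noise sd 0.5)
plants `scaled = −provean1/3 − disorder1 + noise` at the feature level,
with raw per-gene dropout scores reconstructed so the target transform
recovers the planted values exactly.

What passing tests therefore show: coordinate arithmetic, counting,
scoring, smoothing, testing, binning and the learning pipeline are
mutually consistent and recover planted truth under idealized read
structure, Poisson counting noise, and effect models that mirror the
expected conservation/order/domain associations. What they do not show:
robustness to sequencing errors, UMI/PCR artifacts, guide synthesis
errors, real indel-spectrum variability, or the harder covariate
structure of real screens; the planted signal is far cleaner than
biological data, so cross-validated correlations here are upper bounds,
not forecasts.

## Numerical choices and degenerate inputs

- Gini is undefined for all-zero vectors (error); percentiles use linear
  interpolation throughout.
- Score binning requires ≥ 20 finite scores and a non-degenerate
  distribution; constant scores raise.
- Consensus ties go to coil; alignment with no positive-scoring local
  match returns an empty mapping with a warning.
- The biallelic-outcome simulator draws two independent allele repairs
  per cell; the closed forms p² and 1 − p² follow from independence and
  are reported alongside the empirical fractions.
- All randomness flows through `numpy.random.default_rng(seed)`; a config
  plus seed reproduces every output byte-for-byte.

## Known limitations

Only the SpCas9 NGG geometry is tested (the cut offset is configurable);
mmCIF structures, UMI handling, paired-end reconciliation and
negative-binomial dispersion modeling are out of scope. The LOESS span
default (100 residues of data) follows the plateau observed when
calibrating span against conservation/disorder agreement; it is exposed
as a parameter rather than re-optimized per dataset.
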