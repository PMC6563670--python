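# Methods

## Scope and conventions

All statistics are computed from 64-slot codon count tables. Input CDS
are read in frame 0 from the record start; no ORF finding or frameshift
repair is attempted. Codons containing a non-ACGT base are skipped and
tallied (`n_skipped`), never imputed, so every downstream total remains
auditable: `n_codons + n_skipped == len(seq) // 3`. The genetic code is
fixed to the standard nuclear table, appropriate for ascomycete nuclear
CDS. All reporting is in the RNA alphabet.

Stop codons are treated as codons of the CDS for overall composition
(GC, GC1–GC3) and their family RSCU is reported, but they are excluded
from GC3s/x3s, ENC, CAI and the optimal-codon contrast. Internal stop
codons are not rejected by default (an optional QC flag exists): whole
annotated CDS sets are analyzed as annotated.

### x3s definition

A3s/T3s/C3s/G3s are defined as the fraction of synonymous sense codons
(all sense codons except AUG and UGG) whose third base is the given
base. This keeps A3s+T3s+C3s+G3s = 1 and GC3s = C3s+G3s exactly. The
alternative codonW normalization (per-base denominators restricted to
families where that base is usable) is deliberately not implemented;
the simple definition is self-consistent and matches the
near-complementary genome-wide means reported for GC-rich fungal gene
sets.

## ENC

Wright's estimator with bias-corrected family homozygosity
F = (nΣp̂² − 1)/(n − 1), family means within degeneracy classes
(9 two-fold, Ile alone three-fold, 5 four-fold, 3 six-fold; six-fold
families are kept whole, which is what the 3/F̄₆ term implies), and
N_c = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆.

Numerical choices:

- Families with n < 2 are uninformative (F undefined at n = 1).
- If Ile is uninformative, F̄₃ = (F̄₂ + F̄₄)/2 (Wright's fallback).
- Classes 2/4/6 require at least half their families informative,
  otherwise ENC is undefined (NaN) — a class mean extrapolated from one
  or two stray families is worse than no estimate.
- Because the corrected F sits slightly below 1/k even for perfectly
  uniform counts (and can be exactly 0 for an n = 2 family split 1/1),
  raw estimates above 61 — including the infinite-raw limit — are
  routine sampling outcomes; they are capped at 61 and flagged
  (`enc_capped`). The floor of 20 is attained exactly when every family
  uses one codon.

## CAI

Weights are relative adaptiveness w = RSCU/RSCU_max per family on a
reference pool. Lacking expression data, the default reference is the
pooled counts of the 5 % of genes with the lowest ENC (most biased,
the standard proxy for highly expressed genes); a user-supplied count
table can replace it, and the provenance string is recorded in the run
manifest. Codons unobserved in the reference get a floor weight of
0.01 (never 0, which would make log-weights singular); floored codons
are listed on the weights object. CAI is the count-weighted geometric
mean of w over a gene's synonymous sense codons, so it is invariant to
gene length at fixed codon proportions and lies in (0, 1].

## Neutrality regression

Unweighted OLS of per-gene GC12 on GC3 (`scipy.stats.linregress`),
with Pearson r and its two-sided p. The slope × 100 is reported as the
mutational share and (1 − slope) × 100 as "other factors", the
conventional reading of the neutrality plot. NaN pairs are dropped;
zero GC3 variance yields an undefined fit. Gene-length weighting was
considered and left out: the source analysis gives no weighting, and
the unweighted fit is the field default.

## ENC–GC3s null curve

ENC_exp(s) = 2 + s + 29/(s² + (1−s)²), defined on s ∈ (0, 1). "Below
the curve" is residual < 0 with no tolerance band, since no band is
standard.

## Correspondence analysis

Input is the gene × 59-codon RSCU matrix (AUG, UGG, stops excluded) —
RSCU rather than raw counts removes amino-acid-composition effects,
the codonW default for this analysis. A gene lacking a family entirely
has that family's codons filled with the neutral value 1 so every row
is complete; filled genes are reported. The algorithm is the standard
one: correspondence matrix P, standardized residuals
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, SVD, principal coordinates for rows
and columns. The axis sign is unidentifiable; it is fixed by forcing
the codon with the largest |loading| on each axis positive, and tests
compare up to sign regardless. Rank-deficient input returns fewer axes
(zero-filled columns) with the rank flagged.

## Spearman matrix

Pairwise Spearman rho with average ranks for ties and pairwise
deletion of undefined entries. P-values use the t approximation, except
at n ≤ 8 where the permutation null is enumerated exactly (40,320
permutations at most). The design target was exactness up to n = 10,
but n = 10 means 3.6 M permutations per pair across a 16-variable
matrix; n ≤ 8 keeps exactness where the approximation is genuinely
poor at negligible cost. Reports annotate p < 0.05 / p < 0.01 with
one/two stars; no multiple-testing correction by default (matching the
reporting convention the pipeline mirrors), with a Benjamini–Hochberg
helper available.

## Optimal codons

Genes are ranked ascending by ENC (undefined ENC excluded, id
tie-break); the first and last ⌈fraction·N⌉ genes form the high- and
low-bias pools. The default fraction is 0.05: applied to a ~10k-gene
genome it produces pool codon totals in the hundreds of thousands,
the scale at which the reference contrast tables were built. Per codon,
a 2×2 chi-square of (codon vs rest of family) × (high vs low) is used,
with Yates continuity correction whenever any expected cell is below 5
(Fisher's exact test available behind a flag for small tables). A
codon is optimal iff RSCU_high > 1, ΔRSCU ≥ 0.08 and p < α = 0.01; all
three thresholds are configurable. AUG, UGG and stops are never
testable or optimal. Swapping pool labels negates every ΔRSCU and
leaves chi-square unchanged; the optimal count is monotone in both
thresholds.

## Synthetic data generator

Each gene draws a length (log-normal, median 400 codons, σ = 0.45 —
mean ≈ 440 codons, matching a ~5.2 M-codon / ~10k-gene genome), a
mutational third-position GC bias m ~ Beta(12, 6) (mean 0.667,
sd 0.108, emulating a GC-rich ascomycete's wide per-gene GC3s spread),
and a highly-expressed flag. Amino acids are i.i.d. uniform over 20 by
default. Codons are chosen per amino acid: with probability s
(highly-expressed genes only) the planted preferred codon — by default
the C-ending codon of each degenerate family, else G-ending,
alphabetical tie-break (18 codons, one per family) — otherwise the
third base is G/C with probability m and the codon uniform within the
compatible synonymous subset. A stop from {UAA, UAG, UGA} is appended
uniformly.

Coupling k ∈ [0, 1] tilts the per-gene amino-acid frequencies by
exp(k·G·(m − 0.5)·(gc12(aa) − mean)) with gain G = 6, so
first/second-position GC co-varies with m and the fitted neutrality
slope rises with k (≈ 0.18/0.36/0.73 at k = 0.25/0.5/1.0 with 500
genes); at k = 0 the slope is 0 in expectation because each family's
G/C- and A/U-ending codon subsets happen to have identical mean
position-1/2 GC.

Randomness uses one global seed with counter-based per-gene
substreams, so extending `n_genes` never reshuffles earlier genes and
equal specs give byte-identical FASTA.

Known asymmetry: Ile has no G-ending codon, so the G/C outcome maps to
AUC alone and the A/U outcome uniformly to {AUU, AUA}; this keeps
third-position composition targets exact but makes Ile usage non-
uniform (RSCU(AUC) = 1.5 at m = 0.5) even with no selection — the
uniform-usage validation therefore excludes the Ile family.

What the generator does not emulate: amino-acid composition differences
between genes (beyond the k-tilt), intron/UTR structure, codon-pair or
neighbor effects, expression-correlated gene length, and phylogenetic
correlation between genes. Passing recovery tests therefore show the
estimators are correct under independent-site mutation–selection
mixing, not that real genomes satisfy those assumptions.

## Validation problem sizes

Recovery tests use 500 genes of ~400-codon median (neutrality-slope
grid, planted-optimal-codon recovery at s = 0.5, highly-expressed
fraction 0.1, pool fraction 0.05), 10,000 random count tables for the
RSCU-conservation/CAI-range sweep, and 10×59 random matrices for the
CA cross-implementation check — sizes at which every statistic is
stable yet the full suite runs in seconds. Published-value checks feed
the transcribed genome-wide and pool count tables through the same
RSCU code path used everywhere else and compare at the printed
precision (±0.01). Two low-pool cells are garbled in the printed
source and are stored under their natural reading with an `ambiguous`
flag; they are excluded from assertions.

## Known limitations

- Genome-wide means (composition, ENC, CAI distributions) of the
  original CDS set are reproducible only given that FASTA; the package
  validates the arithmetic on the printed count tables and on synthetic
  ground truth instead.
- The auto CAI reference (lowest-ENC pool) is a bias proxy, not an
  expression measurement; CAI values depend on the chosen reference
  and the manifest records which was used.
- ENC is undefined for very short genes (informative-family rules
  above); such genes are excluded from the ENC ranking and logged.
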