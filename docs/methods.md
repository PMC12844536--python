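# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the design decisions behind
`strainatac`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and coordinate conventions

The package analyzes a two-strain (B6 reference, 129 alternate) x
two-diet (chow, high-fat) bulk ATAC-seq + RNA-seq design with 5–6
replicates per group. All internal coordinates are 0-based, half-open
(BED convention); VCF positions are converted by subtracting one on
read. Only SNVs are modeled: strain differences that preserve
coordinates make the 129-to-B6 lift the identity map, which isolates
the concordance logic from alignment complexity. An `OffsetMap` of
piecewise-constant shifts (with inverse and round-trip support) covers
the general case and is exercised directly in tests; indel-aware
lifting and chain files are out of scope.

## Differential testing

Counts are normalized to logCPM with a prior count of 0.5:
`log2((c + 0.5) / (libsize + 1) * 1e6)`. Peaks with mean logCPM ≤ −3
across all samples are removed before testing.

The differential engine is deliberately simple and calibration-testable
rather than a reimplementation of a negative-binomial framework: a
cell-means ordinary-least-squares model over the four strain x diet
groups, fit on batch-corrected logCPM. Each named comparison
(129-vs-B6 within a diet; HFD-vs-chow within a strain) is the contrast
of two group means. The residual variance is pooled across all groups
(residual df = N − 4, as one linear model over the full design gives)
and shrunk toward the global mean variance with prior weight d0 = 4:

    s²_mod = (d0 · s̄² + d · s²) / (d0 + d),   t ~ t(d0 + d)

Pooling the variance over the whole design rather than per comparison
is what limma/csaw/DESeq2-style engines do with a single model matrix;
it nearly doubles the variance degrees of freedom at this sample size
and stabilizes the moderated denominator. Under the generator's null
(gamma-Poisson counts, no planted effects) the resulting p-values are
uniform by Kolmogorov–Smirnov at 10⁴ features — the moderation prior is
well matched to the variance heterogeneity that NB counts induce on the
log scale. BH-FDR is computed within each comparison.

Classification thresholds: DAR iff FDR < 0.01 **and** |log2FC| >
log2(1.5) in a comparison (a 50% fold change); Common/Chow/HFD by
which strain comparisons qualify; the representative FDR of a peak is
the smaller of its two comparison FDRs. DEG iff FDR < 0.05; class
precedence DietStrain > Strain > Diet, so a gene significant in both
strain comparisons and a diet comparison is Diet+strain (the more
specific description). A gene significant in exactly one strain
comparison and no diet comparison matches none of the literal class
definitions and is grouped NonDEG.

## Batch detection and correction

The contaminating cell-type cluster is detected by standardizing
features, projecting samples onto the top 10 principal components, and
splitting with seeded 2-means; the smaller cluster is labelled 2. This
replaces visual UMAP clustering with a deterministic, testable rule.

Correction residualizes the batch term while preserving the strain x
diet group means exactly: the batch indicator is centered within each
group, its coefficient estimated jointly with the group means, and only
the centered term subtracted. (Subtracting the uncentered term, as
limma's removeBatchEffect does, would shift group means whenever batch
membership is unbalanced across groups.) A batch that coincides exactly
with a design cell leaves nothing estimable and raises an error. One
corrected layer is shared by differential testing and all correlation
linking.

## Statistical kernels

*Fisher's exact test*: two-sided p sums hypergeometric probabilities of
tables (at fixed margins) no more probable than the observed one; the
implementation is checked exhaustively against full enumeration for all
margins ≤ 12. Odds ratios use the Haldane–Anscombe +0.5 correction only
when a cell is zero and only for the ratio and its CI; the p-value
always comes from the uncorrected exact distribution. CIs are normal
approximations on the corrected log-OR (95% default) — adequate for
ranking, and the method of choice absent a stated alternative.

*Spearman*: rho is the Pearson correlation of mid-ranks; p is exact by
permutation enumeration for n ≤ 8 and a t-approximation otherwise. The
bulk pair-linking stages use a vectorized rank-then-dot-product path.

*Wilcoxon rank-sum*: exact for n_x + n_y ≤ 10 without ties, otherwise
the tie-corrected normal approximation; the effect size is
r = |z|/√n with z from the normal approximation in both cases.

*Gene-set enrichment* replaces a polyenrich-style model with a
hypergeometric test on nearest-TSS gene assignment against the
expressed-gene universe, BH-corrected across sets; the spline-based
length correction is intentionally not reproduced and outputs are
labelled accordingly.

## Motif engine

PWMs are base-probability matrices (L ≥ 4). Log-odds use probabilities
regularized with a pseudocount of 0.8 split by the background
(0.2/base), avoiding −∞ scores; the background is uniform. Information
content is computed on the raw probabilities (IC = 2 + Σ p log2 p);
motifs with average IC ≤ 0.75 are discarded before merging. Similarity
is the maximum Pearson correlation of aligned probability columns over
all offsets with ≥ 4 overlapping columns and both orientations;
single-linkage clusters at ≥ 0.95 merge by averaging aligned columns
over the union extent (background-padded), anchored on the longest
member. The member map is a partition, verified against a brute-force
alignment oracle.

The exact score distribution convolves per-position score masses on a
lattice of 0.01 bits, so the total discretization error is bounded by
L·0.005 bits — negligible at the 1e-4 tails used. `threshold(p)` is the
smallest lattice score whose exact tail is ≤ p; when a motif is too
short for any achievable score to reach the tail (top mass 4^-L > p),
the threshold sits above the support and no hit can be significant —
the correct behavior for short motifs. `survival()` snaps queries to
the nearest lattice point and tolerates rounding overshoot up to
L·granularity/2 above the support maximum.

Allelic scoring takes, per allele, the best log-odds score over all
motif-length windows covering the variant on both strands (verified
against exhaustive window x strand enumeration), min-max scales scores
by the PWM's achievable range, and reports Δ = s̃_alt − s̃_ref.
Significance requires the better allele's exact p ≤ 1e-4 (the scan
threshold). Strength classes — neutral |Δ| ≤ 0.1, strong |Δ| ≥ 0.4,
weak between — mirror motifbreakR's scaled-effect convention; the
published defaults are not printed anywhere authoritative, so these
values are declared substitutes and are configurable. Note that with a
0.8 pseudocount a single-base change in a long, information-rich motif
cannot move the scaled score by 0.4; strong-class effects arise only in
short motifs whose range is concentrated in few positions, and such
motifs are simultaneously too short to reach p ≤ 1e-4. Strong and
significant are therefore nearly disjoint under these conventions,
which the generator reflects.

## Footprints

A site's score on a cut-site profile over center ± 30 bp is the mean of
depth-normalized counts in the flank (offsets 11–30 on each side) minus
the mean in the center (±10 bp): deeper TF protection ⇒ higher score.
This flank-minus-center statistic replaces a bias-corrected continuous
footprint score; it captures the same depletion geometry, is exactly
testable (invariant to joint rescaling of counts and depth), and the
downstream concordance logic consumes only a per-site scalar. Profiles
are pooled per strain x diet group before scoring (per-sample pooling is
not stated in any source; pooled is the default). Depth factors are
estimated as each group's total cut count relative to the mean.

Bound/unbound is a seeded 2-means split of each group's score
distribution (≥ 20 sites required; degenerate distributions are all
unbound), replacing bimodal-threshold detection. The strain score
difference is the signed 129 − B6 difference whose absolute value is
maximal over diet-matched pairs. A site is an **AC-footprint** iff its variant's allelic motif
effect is significant and sign(Δ_motif) = sign(Δ_footprint), both
nonzero. Enrichment of AC-footprints per DAR class uses non-AC sites as
background against NonDAR; per-class Spearman relates score differences
to allelic scores; Wilcoxon compares |score difference| across motif
strength classes. Per-TF statistics restrict occupancy denominators to
NFRs hosting at least one footprint, and report the fraction of each
TF's motif-altering variants with AC-footprints, flagging TFs at ≥ 0.9
(TFs with < 5 sites carry a low-count flag and are excluded from
headline lists).

## Variant integration

The variant-fraction curve sorts peaks by representative FDR and
reports the fraction containing ≥ 1 variant in consecutive windows of
100 peaks. Class-wise enrichment tests every ordered class pair on the
2x2 of membership x has-variant. Zone enrichment measures variant
offsets from feature centers, counts center (±25 bp for peaks, ±10 bp
for footprints) and flank (to ±250 bp) zones in features and in a
width-matched random background (10 regions per feature, chromosome
drawn proportional to length, start uniform, seeded), and tests
variant-bp against non-variant-bp per zone. Base-pair denominators make
the unequally wide zones comparable; the counting unit is recorded in
output metadata. Density profiles are Gaussian-kernel estimates
(bandwidth 10 bp) of variant offsets within ±250 bp, normalized per
class.

## Linking

DAR pairs: all unordered same-chromosome pairs with center distance
≤ 1 Mb (inclusive), Spearman across all samples on the corrected layer;
significant-positive means p < 0.05 and rho > 0. The rolling curve is
the mean rho of consecutive distance-sorted pairs in windows of 501
pairs advancing by 100 (module parameters allow smaller windows for
small datasets), separately per variant combination (both/one/neither).
Gene linking correlates each expressed gene (most-active TSS as the
anchor point) with every DAR whose center falls in cumulative windows
{±2 kb promoter, 10 k, 50 k, 100 k, 500 k, 1 M}; per DEG class and
window the summary is the fraction of genes with ≥ 1 qualifying DAR and
a Fisher test against NonDEG. Window boundaries are inclusive; the
promoter window matches the ±2 kb nearest-TSS convention used for
feature annotation. Cumulative DAR counts per gene (±1 Mb), stratified
by activity and variant overlap, are compared per class to NonDEG by
Wilcoxon with effect size r.

## Synthetic-data generator

The generator emulates the statistical structure of the study with
complete ground truth; all randomness flows from one seed and outputs
are byte-identical across runs.

**Genome and features.** Three 12-Mb chromosomes of uniform random
sequence; 2000 non-overlapping peaks (200–400 bp) placed in regular
slots with a 2-kb trailing buffer so one peak's H3K27ac mark can never
fall within the activity flank of the next — making planted activity
labels exactly recoverable. 600 genes with strand and most-active-TSS
positions; 20 are flagged unexpressed.

**DAR structure.** 180 Common, 140 Chow, 100 HFD DARs, assigned with
spatial clustering around sparse domain anchors (DARs concentrate in
regulatory domains), plus 50 low-abundance decoy peaks that the logCPM
filter must drop. Strain effects are multiplicative with |log2FC| = 1.5
applied to 129 samples in the relevant diets; diet effects on chromatin
are zero. Effect signs are spatially coherent (nearby DARs in a domain
shift the same way, coherence decaying on the 100-kb co-accessibility
scale), which is what produces distance-decaying positive correlation
among significant DAR pairs. Center SNVs are planted within ±25 bp of
the center for 80% / 60% / 40% / 12% of Common/Chow/HFD/NonDAR peaks —
the Common-vs-HFD contrast mirrors the reported large gap in variant
overlap between always-differential and diet-conditional DARs — on top
of uniform background SNVs (1 per 3 kb).

**Counts.** Gamma-Poisson (negative binomial) with dispersion 0.1 and
gamma-distributed baselines (mean 3000); library-size factors vary
≤ 2x. The added variance components (co-accessibility latent factors,
sd 0.25 with loads ≤ 0.6; linked-pair noise, sd 0.2) are kept small so
the NB dispersion remains the dominant noise source — the regime the
recovery bands are defined for. The contamination batch adds a
2-log2-unit shift on a 500-peak / 100-gene marker program in 7 samples
spanning strains and diets; marker features have 4x-depleted baselines
(a contaminating cell type's program is largely closed/silent in the
host tissue), which also keeps the library-composition artifact of the
shift small. The marker program's size is what makes the contamination
axis dominate the sample covariance, as a genuine cell-type admixture
does; with spatially coherent strain effects a smaller program would
lose the top principal component to strain and 2-means would split the
samples by genotype instead.

**Genes.** 60 Strain, 40 Diet, 40 DietStrain DEGs (|log2FC| 1.5 strain,
1.2 diet). 60% of Strain-DEGs sit at the promoter (±500 bp) of a
Common-DAR in a dense domain and share that peak's effect sign and a
small per-sample noise term, so expression tracks accessibility;
remaining strain-dependent DEGs are placed near domain anchors,
creating the DAR-dense neighborhoods the cumulative-count comparison
detects.

**Motifs and footprints.** Seven motifs in three architectures: three
8-bp high-IC "core" motifs (significant, weak-class allelic effects),
two 4-bp "strong" motifs (strong-class effects, never significant), two
8-bp "neutral" motifs with split columns (near-zero deltas between the
top two bases). 500 footprint sites: 120 concordant (variant in a core
motif at a Common/Chow-DAR center; occupancy of each strain is the
logistic — slope 10, midpoint 0.75 — of its own allele's scaled motif
score, so sign concordance holds by construction, and the host peak's
effect sign follows the motif delta: pioneer-like coupling), 40
discordant (occupancy computed from the swapped alleles, concentrated
in two TFs so a third TF retains a ≥ 90% concordant variant set), 60
strong, 60 neutral, and 220 graded no-variant sites (consensus
instances with 0–5 mismatches, giving a spread of occupancies for
score-monotonicity and bound-calling tests; one core TF's graded sites
are planted only in DAR hosts). Cut profiles are Poisson with base rate
30/bp per group, center rates depressed by 0.8 x occupancy, and ±15%
group depth factors.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artifacts (Tn5 sequence bias,
fragment-length structure, mappability), indels and structural variants,
LD and mutation-rate heterogeneity in the variant null, dependence of
diet effects on chromatin, TMM-style compositional normalization needs,
and cell-type deconvolution beyond a single additive contamination
program. The recovery numbers certify the inference chain, not
biological effect sizes.

## Problem sizes and runtime

Default analyses run on 2000 peaks / 600 genes / 500 footprints, the
null-calibration suite on 20 replicates of an 800-peak zero-effect
configuration, and the exhaustive motif oracles on all 4^L sequences up
to L = 8 — sizes chosen so the full validation suite completes in well
under a minute per stage on one CPU while keeping every statistical
regime (BH thresholds, exact-test discreteness, NB overdispersion)
representative.

## Known limitations

- The moderated-OLS engine ignores the mean–variance relationship that
  NB GLMs model explicitly; at very low counts its power is
  conservative relative to csaw/DESeq2.
- Exact Fisher p-values are discrete and conservative for small
  classes; permutation-null uniformity holds only where class sizes
  make the support dense.
- The merged-motif averaging weights members equally rather than by
  information content.
- Strength-class thresholds on the scaled delta are convention, not
  estimates; conclusions stratified by strength depend on them.
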