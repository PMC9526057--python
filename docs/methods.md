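# Methods

## The mapping model

The mapping substrate is a panel of fully inbred recombinant strains whose
genomes are mosaics of two parental backgrounds (N2 and CB4856). Genotypes
are coded N2 → −1, CB4856 → +1, so every effect estimate is oriented as
CB4856 minus N2. For a trait vector y over n strains and a marker genotype
vector g, the association statistic is the correlation LOD

    LOD = −n · ln(1 − R²) / (2 ln 10)

with R the Pearson correlation of g and y. This is equivalent to the LOD of
a single-marker least-squares regression (LOD = (n/2)·log10(1/(1−R²))); the
test suite asserts equality with an explicit design-matrix regression oracle
to 1e−10 at every marker. Markers with missing calls are handled
complete-case, each with its own n; monomorphic markers and constant traits
score 0; R² is clamped at 1 − 1e−12 so degenerate toy inputs stay finite.

**Genome-wide threshold.** The trait is permuted across strains N times
(default 1,000), each permutation scanned genome-wide, and the threshold
taken as the ⌈(1−α)·N⌉-th order statistic of the max-LOD null distribution
(no interpolation — deterministic and slightly conservative). With α = 0.05
and N = 1,000 that is the 950th smallest maximum. Calibration under the
null is checked empirically: over 400 independent null traits on a
291-strain, 204-marker panel the genome-wide false-positive rate stays
inside the 99% binomial band around 0.05.

**Forward search.** QTL are mapped iteratively: scan, take the maximum-LOD
marker (ties broken by lowest chromosome/bp coordinate), and if it exceeds
the threshold record it as a QTL and absorb it as a cofactor. Cofactor
integration is implemented as least-squares residualization of the trait on
the cofactor genotype columns (plus intercept) before rescanning, which
keeps the per-iteration statistic identical to the first scan. The search
stops when the maximum LOD no longer clears the threshold or `max_qtl` is
reached. The threshold is computed once on the original trait and reused
across iterations; per-iteration recomputation is available via
`recompute_threshold=True`.

**Intervals and annotation.** Each QTL's confidence interval is the maximal
contiguous run of same-chromosome markers containing the peak whose LOD is
within 1.5 units of the peak LOD, reported as the bp positions of the run's
endpoints. Variance explained is 100·R² at the peak marker and effect size
is the CB4856-minus-N2 class-mean difference, both computed on the trait *as
scanned in the detection iteration* (i.e. after residualization on earlier
cofactors). With ±1 coding, a planted additive effect a corresponds to a
class-mean difference of 2a; the effect-size convention is the full mean
difference, not the half-difference regression coefficient.

## Interaction scan

For marker pairs (thinned to every k-th marker; same-chromosome pairs
closer than 1 cM and exactly collinear pairs are excluded) the statistic is
the nested-model LOD, (n/2)·log10(RSS_additive/RSS_full), where the additive
model has intercept plus both marker codes and the full model adds their
product. RSS values come from QR projections, so RSS_full ≤ RSS_additive and
the statistic is nonnegative by construction. The genome-wide threshold is
the same order-statistic construction applied to the maximum pairwise
interaction LOD over permuted traits (default 100 permutations), with the
same permutations reused across pairs.

## Sorter processing

Raw sorter records carry per-object TOF (time of flight, a length proxy)
and EXT (optical extinction); EXT/TOF (norm.EXT) proxies width. Animals are
separated from debris by fitting Gaussian mixtures with 1..3 full-covariance
components on (log TOF, log EXT), choosing the component count by BIC, and
calling the component with the largest mean log TOF the animal cluster; any
component whose mean lies within Mahalanobis distance 3 of that cluster is
merged into it. The log feature space stabilizes the size spread; the
largest-mean-log-TOF rule encodes the biological expectation that debris
(bacterial clumps, cuticles, next-generation larvae) is smaller than the
assayed animals. Gating is deterministic given its seed.

Micron conversion is an affine map per measure with identity defaults —
instrument calibration coefficients are deployment-specific, and the
correlation-based mapping downstream is invariant to affine trait
transforms, so defaults do not affect QTL results. Wells are summarized by
the median length and width over animal objects (pandas median: mean of the
central pair at even counts); wells with fewer than 3 or more than 100
animals are removed, boundaries inclusive. Assay-day batch effects are
removed by least squares on batch indicators with intercept, which reduces
to within-batch centering; residuals sum to zero per batch, the operation
is idempotent, and a singleton batch yields a zero residual (logged).
Per-timepoint strain comparisons use Welch's t on well medians with
Benjamini–Hochberg adjustment across hours; the test and adjustment are
configurable since no single choice is canonical for these assays.

## Validation of introgression lines

NIL/CSS assays are analyzed by one-way ANOVA (phenotype ~ strain) with
all-pairs Tukey HSD (Tukey–Kramer for unbalanced groups, via statsmodels),
α = 0.05. A line *recapitulates* a QTL iff (i) its Tukey-adjusted p against
its background parent is below α and (ii) the sign of the line-minus-
background mean difference equals the direction predicted by the donor
allele and the QTL effect sign. Only the line-vs-background comparison
enters the call — the minimal reading of the recapitulation definition —
but all pairwise comparisons are reported. Because the Tukey adjustment is
familywise and the direction requirement halves the null rejection region,
the false-recapitulation rate under the null sits below the nominal 5%;
the acceptance check bounds it at 0.05 plus the 99% binomial band.

## Candidate-gene triage

Genes are triaged against a QTL interval with half-open [start, end)
overlap semantics and any-overlap inclusion (the convention is a package
choice; callers must supply coordinates on a single assembly). In-interval
genes partition by precedence: no variants and no eQTL mapping into the
interval → *no variation*; any protein-coding variant (missense, nonsense,
coding splice-site, frameshift, in-frame indel — a configurable whitelist)
or an eQTL mapping into the interval → *protein-coding variation and/or
eQTL*; otherwise → *noncoding only*. Genes outside the interval whose eQTL
maps into it form a fourth, non-overlapping class. Genes overlapping
supplied hyper-divergent regions (segments where short-read variant calls
between wild strains are unreliable) are flagged but not reclassified. The
module consumes caller-provided annotation/variant/eQTL tables; it does not
perform variant-effect prediction.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
not the biology of the cross:

- **Maps**: markers evenly (or uniformly at random) spaced, cM linear in bp
  (default 2.5 cM/Mb over 20 Mb chromosomes ≈ 50 cM each, six chromosomes
  named I–V and X).
- **RIAIL genotypes**: per chromosome, a homozygous two-state Markov chain —
  first allele Bernoulli(0.5), flip probability between adjacent markers
  min(0.5, expansion · r_Haldane) with r_Haldane = (1 − e^(−2d/100))/2. The
  Haldane function is a standard closed-form choice; the expansion
  multiplier (default 3) mimics the extra effective recombination of
  advanced-intercross panels. This matches marginal allele frequencies and
  the distance decay of linkage, which is what single-marker mapping sees;
  it does not reproduce pedigree-level features (shared descent between
  strains, selection against incompatibility loci, residual
  heterozygosity).
- **Traits**: y = Σ a_k·code(g_k) + batch + noise, with per-batch offsets
  Normal(0, batch_sd²) and strain noise Normal(0, noise_sd²). For a single
  QTL at allele frequency 0.5, the planted variance fraction is
  a²/(a² + batch_sd² + noise_sd²); with several QTL the denominator includes
  all planted effects so the truth fractions sum to at most 1.
- **NIL panels**: parents uniform, introgression lines equal to the
  background except donor alleles at markers inside the interval; a CSS is
  the whole-chromosome case.
- **Sorter clouds**: independent log-normal (TOF, EXT) per component, with
  defaults placing the animal and debris clusters far apart on log TOF
  (means 5.7 vs 3.4 at sd ≤ 0.35, i.e. well beyond 4 sd) and a 30% debris
  fraction; truth labels are retained. Real sorter data additionally show
  TOF–EXT correlation within clusters and occupancy drift over hours, which
  the generator omits — passing gating tests demonstrate separability-driven
  accuracy, not robustness to every real-data artifact.

All generators are bit-reproducible given their seeds.

## Problem sizes and study conditions

The statistical checks run at the scale of the mapping study they emulate:
291–300 strains, ~200 markers (six chromosomes × 34), a planted QTL at 8.6%
variance (the scale of the chromosome-X width QTL), 1,000 permutations at
α = 0.05, 400 null traits for threshold calibration, 100 replicates for
power/coverage, 50 for the interaction null, 20 seeds for gating, and 100
null replicates for the recapitulation rate. Interaction scans default to
thinning (every 2nd–4th marker) so the pair count stays near 10³–10⁴.

## Known limitations

- Single-marker mapping only: no interval mapping between markers, no
  mixed-model/kinship correction, no multi-trait mapping.
- The forward search residualizes the trait on cofactors rather than
  refitting a joint multi-QTL model; closely linked QTL may be absorbed
  into one peak.
- Estimated variance explained at detected peaks carries the usual
  selection (winner's-curse) bias of reporting at the scan maximum — in the
  replicate studies the mean estimate runs ~1 point above the planted 8.6%.
- The per-timepoint strain comparison (Welch + BH) is a defensible default,
  not a canonical choice.
- Gene triage trusts the supplied variant classes; it performs no
  consequence calling and no functional ranking of candidates.
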