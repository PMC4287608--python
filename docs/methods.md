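# Methods

This note records the models the package implements, the defaults and why,
the numerical conventions, and the known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The noise phenotype

For each (line, experiment, trait) with at least `min_reps` (default 2)
replicates, the phenotype is the coefficient of variation of the absolute
replicate values, CV = s/m, with s the sample SD (n−1 denominator) and m
the replicate mean. The n−1 denominator is chosen for unbiased variance on
duplicates and is documented so results are reproducible. The per-line
noise phenotype carried into mapping is the arithmetic mean of the
per-experiment CVs (two experiments give two independent biological
replicate measures of noise); pooling replicates across experiments
before taking one CV is a defensible alternative but would conflate
between-experiment shifts with within-line noise, so it is not the
default. CVs are flagged undefined — never silently zeroed — when there
are too few replicates or when |m| falls at or below a floor (default
1e−12 × the trait's largest absolute value), which guards against
near-zero means exploding the ratio; abundance-like signals are bounded
away from zero so the floor is essentially never binding in practice.

Population-level spread of a line-level statistic is summarised by the
genetic coefficient of variation ("population CV"): SD across lines ÷
mean across lines. Percentile grouping of traits uses a configurable tail
fraction, default 0.05; descriptions of such groupings sometimes use the
5th and sometimes the 10th percentile, so the tail is an explicit
parameter rather than a guess. Ties in percentile ranks break by stable
trait-id order for determinism.

## Heritability decomposition

With cytoplasm classes c, lines g nested in cytoplasm, and experiments e,
the model is

    y_cge = µ + C_c + G_g(C_c) + E_e + ε

fitted to the per-experiment line values (one observation per line ×
experiment; blocks are absorbed into the residual). On balanced data the
components come from equating mean squares to expectations:

    E[MS_G] = σ²_ε + e·σ²_G
    E[MS_E] = σ²_ε + N·σ²_E          (N = number of lines)
    E[MS_C] = σ²_ε + e·σ²_G + e·n₀·σ²_C

with n₀ the standard unequal-class-size coefficient (equal to the
per-class line count when classes balance). Negative moment estimates are
truncated to zero and flagged. Cytoplasm is F-tested against the
line-within-cytoplasm mean square, line and experiment against residual.
Heritabilities are H_nuclear = σ²_G/σ²_P, H_organellar = σ²_C/σ²_P with
σ²_P the sum of all four components; a config flag can exclude the
experiment component from σ²_P, but the default keeps it since the total
phenotypic variance of the design includes it. Unbalanced data fall back
to REML (statsmodels MixedLM variance components) with a warning; on
balanced data the two estimators agree (asserted in tests).

Two conventions resolve ambiguities in the source model statement: the
cytoplasmic variance is pulled from the C term itself (a stray marker
subscript in the written model is read as a typo), and block indices in
the response subscript are treated as absorbed into the residual since
blocks do not appear as model terms.

## Composite interval mapping

Conditional genotype probabilities on a 1 cM grid (all marker positions
included exactly) treat the RIL genotype process as Markov along the
chromosome with two-point switch probabilities R(d) = 2r/(1+2r),
r = (1−e^(−2d/100))/2 (Haldane, then RIL-by-selfing expansion). Between
informative flanks the four flank-state paths are combined; beyond
terminal markers the single flank is used; missing genotypes condition on
the nearest non-missing flank. Haldane is preferred to Kosambi because
the RIL expansion composes exactly along a Markov chain.

The scan is Haley–Knott regression: at each position the phenotype is
regressed on the expected genotype (2·P(A)−1) plus the retained
cofactors, and LOD = (n/2)·log₁₀(RSS_reduced/RSS_full). For fully inbred
RILs with complete marker data this is essentially exact and admits a
clean least-squares oracle, which the tests exploit. Three cofactors per
trait are chosen by greedy forward regression on the genotyped markers
(ties by map order, near-collinear candidates skipped); cofactors within
the 10 cM window of the test position on the same chromosome are dropped.
The additive effect a is the regression coefficient on the ±1 scale, i.e.
half the difference between genotype-class means; percent effect is
100·|2a|/|trait mean| (the allelic-substitution difference relative to
the population mean — the conventional scaling, adopted here explicitly
as the formula).

Significance: the default peak-calling rule is the conservative fixed
LOD ≥ 2, with per-trait permutation thresholds (phenotype permuted across
lines, genome-wide maximum LOD, type-1 empirical quantile = the
⌈(1−α)·n_perm⌉-th order statistic) also computed and reported when
requested; both are config options. Cofactors are reselected inside each
permutation by default, which is the statistically correct null; a fast
mode freezes them. LOD is capped at 300 (flagged) for degenerate perfect
fits.

Peaks are local maxima above the threshold; two maxima on one chromosome
are distinct peaks only if the curve dips at least 1 LOD below the
smaller of them (our concretization of "define peak"), and the support
interval is the widest contiguous run with LOD ≥ peak − 1, clipped to the
chromosome. A known behaviour of CIM inherited by this rule: near a
strong QTL, the discontinuities where cofactors enter or leave the
exclusion window can create secondary local maxima that satisfy the dip
rule, so one strong QTL occasionally reports an extra proximal peak.

## Hotspots

Each trait contributes 1 at each of its peak positions; windows are
half-open intervals [c − w/2, c + w/2) at a 1 cM step (half-open so
membership is unambiguous), default width 5 cM. The permutation null
relocates every trait's peaks to uniform random map positions
(per-trait peak counts preserved, chromosome drawn proportional to its cM
length); this scheme is a declared choice — seeded and configurable —
since sliding-window QTL summation methods do not pin down a unique null.
Thresholds from a differently specified null would differ, so absolute
threshold counts are not comparable across schemes. A window is
hotspot-significant when its count strictly exceeds the threshold;
contiguous significant windows merge into one hotspot at their
maximal-count center (ties → leftmost), named `PREFIX.CHROM.cM`.

## Marker models and epistasis networks

The marker for each hotspot is the genotyped marker nearest its cM
position (ties → leftmost); the cytoplasm enters as one extra ±1 locus.
The additive model has all markers as main effects; the epistasis model
adds every pairwise product and nothing higher. Terms are assessed by
Type III sums of squares (drop-one-column F-tests on the ±1 sum-to-zero
coding; with balanced biallelic markers the design is near-orthogonal and
Type III equals sequential SS, asserted in tests). The fits use direct
least squares for speed; a test cross-checks F and p against statsmodels'
OLS Type III ANOVA. Benjamini–Hochberg FDR is applied across the terms of
one model for one trait ("within a model"); across traits, the network
keeps a locus pair only if its interaction is significant (q < 0.05) for
at least 10% of traits — the boundary case of exactly 10% is retained
(≥ rule). Effect signs are positive when the first-parent allele
increases the trait. Pairs with an empty 2×2 genotype cell are untestable
and skipped; identical (confounded) marker columns drop all but one with
a warning.

## Structured permutation control

The permutation unit is the complete multi-phenotype sample vector (all
traits measured on one plant). Within each randomized block the vectors
are reassigned to lines by a uniform random permutation, which preserves
every per-sample statistic and the trait × trait correlation structure
exactly while destroying the genotype–phenotype link. The census then
recomputes per-line CV and mean and re-runs the full scan per trait,
counting significant QTL per permutation. By default the census uses the
fixed LOD ≥ 2 rule rather than re-deriving per-trait permutation
thresholds inside each dataset permutation (a full-fidelity switch
exists): the fixed rule is what the census compares against, and it keeps
the nested permutation cost linear. A per-trait (vector-splitting)
shuffle mode exists for testing only and is labelled as such.

## The synthetic-data generator

The generator emulates the study design: 316 reciprocal RILs (cytoplasm
split ⌈n/2⌉/⌊n/2⌋, order shuffled under the seed), a five-chromosome map
of 90 cM with 5 cM marker spacing, two experiments × two randomized
complete blocks, and trait panels named like the study's (hundreds of
metabolite-like traits, a small defense set, a small growth set).
Line means and line-level log SDs are separate linear functions of
genotype:

    µ_lt     = grand_mean + Σ a·x + cyto_mean·z + Σ interaction terms
    log σ_lt = log base_sd + Σ b·x + cyto_sd·z

with x, z ∈ {−1, +1}, so a mean-QTL's additive effect equals half the
class-mean difference and a variance-QTL multiplies the within-line SD by
e^(2b) between classes. The log-linear SD model is the simplest
multiplicative noise model that keeps σ > 0 and makes CV the natural
assayed phenotype. Observations are µ + experiment shift + block shift +
σ·ε with ε standard normal; the observation-level distribution is an open
modelling choice (abundance data could equally be lognormal), so a
lognormal switch is exposed in config with normal as default. Experiments
and blocks enter as additive shifts only; micro-environmental structure
beyond σ_lt is deliberately outside the generative model, because the
randomized complete block design it emulates randomizes such structure
away. Residual heterozygosity, dominance and segregation distortion are
not modelled (fully inbred lines, fair Mendelian sampling).

Default architecture effect sizes (mean effects 0.8 on a grand mean of
10, SD effects log 1.5, doubled for defense traits; ~8 shared hotspot
loci) are set so percent effects land in the 10–25% range typical of
metabolite QTL and defense-trait noise QTL run about twice that, and so
multiple traits share loci to create hotspots.

What passing tests on this generator do and do not show: recovery and
calibration results demonstrate the estimators are correct under the
stated generative model (normal replicates, log-linear SD, additive
shifts, no GxE); they do not certify behaviour under heavy-tailed
measurement error, batch structure that survives randomization, or
CV–mean couplings absent from the model.

## Problem sizes and numerical conventions

The validation battery (`scripts/acceptance.py` and the statistical tests
in `tests/test_acceptance.py`) uses: a 100-line × 20-marker fixture for
exact oracle agreement (tolerance 1e−8); 200 null traits × 200 scan
permutations at 316 lines for type-I error; 100 planted-vQTL traits
(b = log 1.5, 2 experiments × 2 replicates) for power, localization and
mean-scan specificity; 100 component simulations over a (σ²_C, σ²_G)
grid for heritability bias; a 20-trait planted dataset with 10 dataset
permutations for the census control; and 434 traits × 3 peaks with a
1000-permutation threshold and 400 fresh draws for hotspot calibration.
These sizes give Monte-Carlo error comfortably inside the asserted bands
on a single CPU in a few minutes.

Numerical conventions collected in one place: sample SD uses n−1; the
empirical quantile everywhere is the type-1 order statistic; LOD cap 300;
collinearity tolerance 1e−10 on QR diagonals; forward-selection and
nearest-marker ties break by map order (leftmost); hotspot argmax ties
break leftmost; all randomness flows from one root seed through a
`SeedSequence`-based per-stage splitter, and fixed seeds make simulator
output bit-reproducible.

## Configuration and pipeline

One YAML config drives the pipeline (`noiseqtl run-all`); it is validated
by a typed pydantic schema, which provides the same guarantees as a JSON
schema with less machinery. Each stage writes plain-text tables with
explicit headers (per-line CV table, heritability components, scan and
peak tables, hotspot profiles, ANOVA p-value and Type III SS tables,
SIF + node attribute network files) plus a JSON manifest of parameters,
seeds, output hashes and wall clock, so every table is re-derivable from
the manifest alone. An XLSX loader is included for reading externally
published supplementary tables shaped like the per-line-CV and QTL-peak
tables, for use in spot-check scripts.

## Known limitations

* Haley–Knott regression slightly misstates the mixture likelihood far
  from markers; immaterial for dense RIL maps, and exactness at markers
  is what the oracle tests pin down.
* CV from duplicate measurements is very noisy (a chi distribution with
  one df per experiment), so single-trait heritabilities of CV are small
  even for fully penetrant variance loci; power comes from the number of
  lines.
* The fixed LOD ≥ 2 census rule is liberal for heavy-tailed CV
  phenotypes; the observed-vs-null comparison is designed to be robust to
  this since both use the same rule.
* Secondary cofactor-window peaks (above) can inflate per-trait peak
  counts by one near very strong QTL.
* Three-way epistasis, dominance, kinship corrections, X-chromosome
  conventions and missing-marker imputation beyond flank conditioning are
  out of scope.
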