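# Methods

## The model

All traits are concentrations of boar-taint compounds in adipose tissue,
right-skewed and analysed after a natural-log transform (the log of a
typical raw androstenone mean of ~1160 ng/g is ~7.06, while the mean of the
logs is ~6.77; both magnitudes are consistent with base e, which is what the
package uses throughout).  The analysis model is the univariate animal model

y = 1·mu + X·b + W·a + e,

where b is a *random* day-of-analysis effect with independent levels
(capturing reagent-batch and handling variation between HPLC runs), a is
the additive genetic effect with covariance K·sigma2_a, and e is an
independent residual.  K is the pedigree numerator relationship matrix A
for pedigree-based BLUP, or VanRaden's genomic relationship matrix G for
GBLUP; the solver is agnostic to which.  Some formulations of G describe
p_i as the "minor allele frequency"; centring by the minor-allele frequency
is inconsistent with Z = M − 2p, so the package uses the observed frequency
of the counted allele (the standard VanRaden construction) and accepts
supplied frequencies for reproducibility across subsets.

### Heritability definition

h2 = sigma2_a / (sigma2_a + sigma2_e), excluding the day variance.  The
rationale: prediction accuracies are computed against phenotypes already
adjusted for the day effect, and the accuracy formula divides by sqrt(h2) —
the two are only consistent if h2 refers to the day-adjusted scale.
Including sigma2_day in the denominator is available via
`heritability(vc, include_day=True)`.

## REML

Variance components (sigma2_a, sigma2_day, sigma2_e) are estimated by
restricted maximum likelihood on the phenotype covariance
V = sigma2_a·WKW' + sigma2_day·XX' + sigma2_e·I, using the projection
matrix P = V⁻¹ − V⁻¹1(1'V⁻¹1)⁻¹1'V⁻¹.  The default is AI-REML: Newton-type
updates with the average-information matrix AI_ij = ½·y'P V_i P V_j P y.
Whenever an AI step proposes a non-positive component (or the AI matrix is
numerically singular, as happens when two components are not separately
identifiable), the iteration falls back to an EM step, whose likelihood
ascent is guaranteed; pure EM is available as `method="em"`.

Numerical choices: starting values split the sample phenotypic variance
equally across the free components; components are floored at 1e-8 times
the phenotypic variance; convergence requires a relative change below 1e-8
in every component (max 500 iterations); non-convergence returns the last
iterate flagged `converged=False` rather than raising.  The SE of h2 is a
delta-method approximation from the inverse AI matrix at convergence and is
labelled approximate — the exact estimator used by mainstream REML software
for its reported SEs is not documented, so agreement is expected only to
first order.

Dense linear algebra throughout: the package targets desk scale (a few
thousand animals), where forming V and the full inverse of the mixed-model
coefficient matrix is cheap and gives exact PEV without iterative
approximations.

## BLUP, PEV, blending

The mixed-model equations carry lambda_day = sigma2_e/sigma2_day on the day
block and lambda_a·K⁻¹ on the animal block.  PEV is sigma2_e times the
animal block of the inverse coefficient matrix; reliability is
1 − PEV/(sigma2_a·K_ii).  The full PEV block is retained because SNP-effect
standard errors need it.

G centred by observed sample frequencies is *always* singular (centred
columns imply G·1 = 0), so the animal block is blended as (1−w)G + wI
before inversion, w = 0.01 by default for G and 0 for A (A is positive
definite by construction).  `blend_and_invert` verifies its result
numerically — Cholesky can silently "succeed" on a singular matrix — and an
exact inverse of a singular G raises with advice to blend.  The blend
weight is recorded on every solution and reused by the GWAS back-solve so
that the transform stays consistent with the solve.

## Cross-validation

Phenotypes are first adjusted with the full-data fit:
y_adj = y − mu_hat − b_hat(day).  Animals are split into 5 random
equally-sized folds (seeded); each fold's records are dropped from the data
and the system re-solved with the *full-data* variance components, so the
validation animals' (G)EBVs derive purely from relationships.  Predictions
are pooled across folds before computing r, R = r/sqrt(h2), and the bias
slope of y_adj on EBV.  Re-estimating variance components per fold is
deliberately not the default (the adjustment itself uses the full-data
model).  The Hotelling–Williams test compares the two methods' correlations
with y_adj; it needs the EBV–EBV correlation r12 and n, which the pipeline
computes from the pooled predictions (n = number of validated animals).

## GWAS

SNP effects are back-solved from GEBV, g_hat = k·Z'G⁻¹·u_hat with
k = 1/(2Σp(1−p)), using the blended G⁻¹ if the solve was blended.  With an
unblended full-rank G, Z·g_hat reconstructs u_hat exactly and g_hat equals
the ridge-regression SNP-BLUP solution with shrinkage d·lambda_a — both
identities are enforced in the test suite at 1e-6.  Var(g_hat) propagates
Var(u_hat) = sigma2_a·G − PEV through the same transform; p-values are
two-sided normal on g_hat/sd(g_hat), and the genome-wide threshold is
Bonferroni 0.05/m.

Windows are consecutive, non-overlapping 0.4 Mb spans of adjacent SNPs
(the average haplotype block size in commercial pig lines), anchored at
each chromosome's first SNP (anchoring at bp 0 is a flag; at chip density
the window count is nearly identical).  A window's share of genetic
variance is 100·var(Z_w·g_w)/var(u_hat) across animals — i.e. percentages
of the *realized* genomic variance; sigma2_a as the denominator is a flag,
since "total genetic variance" admits either reading.  Windows at or above
0.5 % (inclusive) become putative QTL; windows of different traits on the
same chromosome whose intervals overlap are merged into shared regions,
with region boundaries taken from the constituent SNP positions.  The lead
SNP is the largest |g_hat| in the window.  Candidate genes are genes whose
1-based inclusive interval intersects the closed ±200 kb flank of a lead
SNP, deduplicated per region and ordered by distance.  Coordinates: SNP map
1-based; windows half-open; BED input (0-based half-open) is converted on
read.

## The simulator

The generator emulates the structure of a single-line boar-taint study:

- **Pedigree**: discrete generations; founders alternate sex; each
  generation mates `n_founders // 2` sampled sire/dam pairs.  Defaults
  (50 founders, 4 generations, 10 offspring per mating → 1050 animals)
  approximate the ~1075 genotyped boars of such a study.  Real pedigree
  depth and family structure are unpublished, so these are free parameters,
  not calibrated claims.
- **Genotypes**: gene-dropped founder haplotypes with Bernoulli(p) alleles,
  p uniform on `maf_range`, and Haldane recombination at 1 cM/Mb without
  interference — the simplest map consistent with ~0.4 Mb haplotype blocks.
  Defaults: 29,844 SNPs on 18 chromosomes of 90 Mb, chosen so the genome
  tiles into ~4040 windows of 0.4 Mb as in the emulated study.
- **Phenotypes**: y = mu + day + TBV + residual on the log scale
  (raw scale = exp(y)).  TBV sums QTL effects times centred gene content;
  effects are drawn normal and rescaled post hoc so the realized var(TBV)
  equals sigma2_a exactly, which makes recovery tests sharp.  Days are
  assigned in contiguous blocks (batched lab analysis) with i.i.d. normal
  day effects.  Defaults target the androstenone-like log-scale mean 6.77,
  SD 0.76, h2 0.30, 91 day levels; the day share of variance is set to 0.10
  (the emulated study reports only that between-day variation exceeded
  within-day variation; 10 % of phenotypic variance is a realistic batch
  effect for HPLC concentration data).
- **Planted-QTL mode** (`qtl_effect_dist="equal"`): QTL are drawn among
  common variants (realized MAF ≥ 0.2) with effects scaled by the realized
  dosage SD, so each QTL carries an equal, guaranteed share of the genetic
  variance.  This is the mode used for detection benchmarks; rare planted
  alleles are weakly tagged by markers and would make the benchmark measure
  tagging rather than the window machinery.
- Missing genotypes are injected by a separate corruption step so QC is
  testable; a single global seed drives fixed, independent substreams for
  pedigree, genotypes, phenotypes and corruption, making every output
  bit-reproducible.

What the simulator does **not** model: selection, non-random mating,
genotype-by-environment interaction, multi-trait genetic correlations
between the compounds, sexual-maturity biology, or genotyping error beyond
random missingness.  Passing tests therefore demonstrate correctness of the
estimators under the assumed model, not robustness to violations of it.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make Monte-Carlo error small
relative to the tested tolerance while keeping the suite fast: h2 recovery
uses 20 replicates of the ~1050-animal default pedigree; the A-matrix
oracle drops 100,000 gametic replicates through a 200-animal pedigree
(MC error ≈ 0.004 per entry against a 0.02 tolerance); the GBLUP/SNP-BLUP
identity uses 200 animals × ~490 markers; null-GWAS uniformity uses 900
animals × 1000 markers; planted-QTL ranking uses 20 replicates of 1000
animals × 2000 markers on a 5 × 20 Mb genome (chip-like density of ~8 SNPs
per window) with a 250-founder single-generation pedigree, whose LD is
block-scale — a very narrow founder base instead produces megabase-range LD
in which distant windows shadow the QTL.  The Hotelling–Williams size check
uses 5000 null replicates at n = 200.

## Known limitations

- FImpute-style pedigree-haplotype imputation is out of scope; missing
  calls are filled with the mean dosage 2p (or its rounded hard call).
  This is adequate after the 95 % call-rate filter but is not a substitute
  for family-based imputation at high missingness.
- Per-animal call-rate filtering is not implemented (the emulated QC
  filters SNPs only).
- The exact GBLUP ≡ SNP-BLUP equivalence requires a full-rank unblended G,
  i.e. more markers than animals and non-sample allele frequencies; with
  observed frequencies or blending the identity holds only approximately.
- Single-trait models only; no H-matrix (single-step) combination of A
  and G; no sparse-matrix path for populations far beyond ~5000 animals.
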