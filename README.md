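# boargp

Genomic prediction and GWAS for boar-taint compounds in pigs.

Boar taint is the off-odor of pork from intact male pigs, driven by the
accumulation of androstenone, skatole and indole in adipose tissue.
Selecting against these compounds requires predicting each animal's additive
genetic merit from pedigree or SNP-chip data, and locating the genomic
regions that carry the (small, polygenic) effects.  `boargp` implements that
analysis end to end for breeders and quantitative geneticists: pedigree-based
BLUP and genomic BLUP under one univariate animal model, REML variance
components, cross-validated accuracy comparison, and a GBLUP-based GWAS with
window-level variance partitioning and candidate-gene lookup.  Because
individual boar-taint datasets are typically proprietary, the package ships
a gene-drop simulator that reproduces the statistical structure of such a
study (~1000 genotyped boars, ~30k SNPs on 18 autosomes, log-normal
phenotypes, a 91-level day-of-analysis effect), so every stage is testable.

## Model

Phenotypes are log-transformed concentrations analysed with the mixed model

```
y = 1·mu + X·b + W·a + e
```

with `b ~ N(0, I·sigma2_day)` the random day-of-analysis effect,
`a ~ N(0, K·sigma2_a)` the additive genetic effect — `K = A` (pedigree
numerator relationship matrix, Henderson's tabular method) for PBLUP or
`K = G` for GBLUP — and `e ~ N(0, I·sigma2_e)`.  G is VanRaden's genomic
relationship matrix

```
G = ZZ' / (2·sum_i p_i(1 - p_i)),   Z = M - 2p
```

from gene content `M` in {0,1,2}.  Variance components are estimated by
AI-REML (average information, with EM fallback steps).  Heritability is
`h2 = sigma2_a / (sigma2_a + sigma2_e)`, consistent with accuracies measured
against day-adjusted phenotypes.

Prediction accuracy is assessed by 5-fold cross-validation with masked
phenotypes: `R = r(EBV, y_adj) / sqrt(h2)`, bias as the slope of `y_adj` on
EBV, and the PBLUP/GBLUP difference tested with the Hotelling–Williams test
for dependent correlations.  For the GWAS, SNP effects are back-solved from
GEBV as

```
g_hat = Z' G^-1 u_hat / (2·sum_i p_i(1 - p_i))
```

with p-values `2(1 - Phi(|g_i|/sd(g_i)))` from the prediction-error
covariance of the GEBV, a Bonferroni genome-wide threshold `0.05/m`, and the
percentage of genetic variance explained by consecutive 0.4 Mb windows of
adjacent SNPs.  Windows at or above 0.5 % of the genetic variance become
putative QTL regions; genes within ±200 kb of a region's lead SNP are
candidate genes.

## Worked example

```python
import boargp as bg

cfg = bg.SimConfig(n_founders=40, n_generations=3, offspring_per_mating=5,
                   n_chromosomes=5, n_snps=2000, chrom_length_bp=20_000_000,
                   n_qtl=100, n_day_levels=20, seed=7)
ped, geno, snp_map, pheno, truth = bg.simulate_dataset(cfg)
geno, snp_map, qc = bg.filter_snps(geno, snp_map)   # MAF >= 1%, call rate >= 95%

A, G = bg.build_A(ped), bg.build_G(geno)
spec = bg.ModelSpec(trait="and_log")
vc = bg.reml_estimate(pheno, spec, A, method="ai")

cv_p = bg.cross_validate(pheno, spec, A, vc, k=5, seed=1)
cv_g = bg.cross_validate(pheno, spec, G, vc, k=5, seed=1)
hw = bg.compare_cv(cv_p, cv_g)

sol = bg.solve_blup(pheno, spec, G, vc)
eff = bg.snp_pvalues(bg.backsolve_snp_effects(sol, geno, G), sol, geno, G)
windows = bg.window_variance(geno, eff, bg.make_windows(snp_map), sol, G,
                             snp_map=snp_map)
```

With print statements over these results, the run produces:

```
340 animals, 1989 of 2000 SNPs pass QC
sigma2_a=0.1180 sigma2_day=0.0368 sigma2_e=0.3482 h2=0.25 (SE 0.10)
PBLUP: r=0.213 accuracy=0.423 beta=0.91
GBLUP: r=0.347 accuracy=0.690 beta=1.18
Hotelling-Williams: t=-4.08 p=0.0001
-log10 significance threshold: 4.6
chrom  start_bp  n_snps  pct_variance  lead_snp
    5  17228444      12      0.208413 SNP001949
    3   7611835      13      0.127127 SNP000968
    3  11211835      10      0.125422 SNP001037
```

Reading the output: the simulated trait has an estimated heritability of
0.25 ± 0.10 on the log scale; genomic prediction is clearly more accurate
than pedigree prediction on this deep-pedigree population (0.69 vs 0.42,
Hotelling–Williams p = 0.0001); regression slopes near 1 indicate little
bias.  The window table lists the genomic regions explaining the largest
share of the genetic variance of the GEBV, each with its lead SNP.  On a
small polygenic simulation no window is expected to pass a QTL threshold —
mirroring the situation in real boar-taint data, where many loci each
explain a fraction of a percent.

The same pipeline is scriptable from the shell:

```
boargp simulate --out data/ --seed 7
boargp qc --geno data/genotypes.tsv --map data/snp_map.tsv --out qc/
boargp reml --pheno data/phenotypes.csv --trait and_log --ped data/pedigree.csv --out vc.json
boargp cv   --pheno data/phenotypes.csv --trait and_log --grm G.tsv --vc vc.json --out cv.json
boargp gwas --pheno data/phenotypes.csv --trait and_log --geno qc/genotypes_qc.tsv \
            --map qc/snp_map_qc.tsv --vc vc.json --out gwas/
```

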