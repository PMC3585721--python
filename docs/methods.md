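# Methods

## Model and procedure

`pathgwas` tests pathway-level association in case-control GWAS data. The
per-SNP model is additive logistic regression,

    logit P(case) = b0 + b_age·age + b_sex·sex + b_py·packyears
                    + Σ_k c_k·PC_k + β·g,    g ∈ {0,1,2},

fit by Newton/IRLS; the SNP effect is summarized by the Wald statistic
z = β̂/SE. Principal components are computed once per dataset from the
EIGENSTRAT-normalized genotype matrix (centre by 2p̂, scale by √(p̂(1−p̂)),
missing genotypes mean-imputed) and reused unchanged across permutations,
since label shuffling does not alter genotypes.

Genes receive the statistic of their representative SNP — the assigned SNP
(within 50 kb of the gene boundaries, inclusive at exactly 50,000 bp) with
the smallest p, ties broken by genomic position then SNP id — on the
1-df chi-square scale r = z². Ranking genes by r descending, the enrichment
score of a gene set S with N_H members in a list of N genes is the maximum
value attained by the running sum that adds |r_j|^w / N_R at members
(N_R = Σ_members |r_j|^w) and subtracts 1/(N − N_H) at non-members. The
default weight w = 1 gives the "weighted" statistic; w is exposed in
`GseaParams`. The signed-maximum convention is the default; the
maximum-absolute-deviation variant is available via `convention="max_abs"`.

The null distribution comes from B phenotype permutations: case-control
labels are shuffled (covariates stay attached to their samples), and the
whole scan → gene score → ES chain is re-run. NES standardizes each pathway's
ES by its own permutation mean and SD (ddof = 1); p = (1 + #{ES_perm ≥ ES}) /
(B + 1), one-sided toward enrichment, so the smallest attainable p is
1/(B+1); FDR at NES* is the fraction of all pathway-standardized permuted NES
≥ NES* divided by the fraction of observed NES ≥ NES*, clipped at 1, with
FDR = 1 assigned to negative-NES pathways.

The two-stage design selects discovery pathways at P ≤ 0.05 and FDR ≤ 0.50,
replicates at P ≤ 0.05 (no FDR rule at this stage), and confirms in the
pooled individual-level data at P ≤ 0.05. The pooled stage re-applies SNP QC
(pooled HWE at 1e-5 plus per-site at 1e-4), recomputes PCs on the pooled
matrix, and adds a study-site indicator covariate. Each stage draws a fresh
permutation stream from a per-stage substream of the run seed, so stage order
never affects results.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 50,000 | SNP-to-gene distance window (bp, inclusive at the edge) |
| `weight_exp` | 1.0 | exponent on \|r\| in the ES hit increment |
| `B` | 1,000 | phenotype permutations |
| `n_pcs` | 4 | principal components in the adjustment |
| `size_min`/`size_max` | 10 / 200 | pathway size bounds after restriction to scored genes |
| `QcThresholds` | 0.95 / 0.05 / 1e-5 / 1e-4 / 0.95 / 6 SD | SNP call rate, MAF, pooled HWE, per-site HWE, sample call rate, heterozygosity cut |
| `StagePlan` | 0.05 / 0.50 / 0.05 / 0.05 | discovery P and FDR, replication P, combined P |

The heterozygosity outlier cut (±6 SD) quantifies an otherwise qualitative
"extreme heterozygosity" rule and is deliberately loose; it is configurable.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the analysis assumes:

- biallelic autosomal SNPs, MAF uniform on a configurable range
  (default 0.05–0.5), 1% missingness;
- genes as contiguous runs of 1–30 SNPs laid round-robin across 22
  autosomes, with intergenic gaps drawn long enough that SNPs occur exactly
  at the 50 kb window edge;
- pathways drawn from a configurable size range; consecutive pathways share
  a configurable fraction of genes, all other pairs are disjoint;
- optional two-subpopulation stratification (allele frequencies p ± δ/2 and
  a subpopulation main effect on disease, the minimal structure that makes
  PC adjustment consequential);
- a logistic disease model with covariate effects (age 0.02/yr, gender 0.40,
  pack-years 0.012 log-odds) and one causal SNP with a configurable
  per-allele OR in each "causal" member gene of an enriched pathway;
- case-control ascertainment from a simulated ~10%-prevalence source
  population, mirroring frequency-matched hospital sampling; generation
  fails explicitly if the requested counts are unreachable in a bounded
  number of sampling rounds.

What it does **not** emulate: linkage disequilibrium (SNPs are independent
given subpopulation), X-chromosome variation, imputation uncertainty,
genotyping batch effects, or relatedness. Passing tests therefore validate
the statistical machinery — calibration of the permutation null, selection
logic, QC arithmetic — not robustness to LD-induced correlation between
gene scores, which the permutation procedure is designed to absorb but the
simulations do not stress.

## Numerical choices

- **Batched IRLS.** All SNP models are fit simultaneously; the covariate
  block of each Hessian comes from one shared cross-product matrix, the
  genotype border is added analytically, and all (n × S) intermediates are
  preallocated. Fits agree with `statsmodels.Logit` to < 1e-8 on test
  fixtures. Separation (|β̂| > 15) or a singular Hessian flags the SNP
  (p = 1) and excludes it from gene scoring; with MAF ≥ 0.05 and n in the
  hundreds this is rare. Samples with a missing genotype enter that SNP's
  fit with zero weight (exact complete-case analysis).
- **Permutation scans in float32.** The null only needs z to ~1e-4, and the
  halved memory traffic roughly doubles throughput; observed associations
  are always fit in float64. Convergence tolerances: 1e-8 (float64),
  5e-4 (float32, the Newton-step noise floor at that precision).
- **HWE** via the 1-df chi-square goodness-of-fit test (adequate at
  MAF ≥ 0.05 and n in the hundreds, and closed-form testable); monomorphic
  SNPs return p = 1 by convention.
- **PCA** uses scikit-learn's exact SVD below 500×500 and seeded randomized
  SVD above; scores are deterministic up to sign. `k` larger than
  min(n_samples, n_snps) raises; a rank-deficient matrix inside that bound
  does not (randomized SVD cannot detect it reliably).
- **Ties.** Representative-SNP ties break by position then id; equal gene
  statistics keep a stable (gene-id) order in the ranking. Both rules are
  data-independent, so permutation and observed runs treat ties identically.
- **Degenerate inputs.** A pathway whose members all carry zero statistics
  is an error in `enrichment_score` and a dropped (NaN) column inside the
  permutation machinery; a pathway with zero permutation spread gets
  NES = NaN and is flagged rather than silently kept.
- **Pathway overlap** divides shared genes by the *sum* of the two set
  sizes (so identical 10-gene sets overlap 50%, and two 16-gene sets sharing
  2 genes overlap 6.25%); a union denominator is available as an option.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at desk scale, chosen once as the package's own
defaults (in `pathgwas.experiments`):

- type-I error: 20 datasets (10 in the acceptance script), 250+250 samples,
  1,000 SNPs, 50 pathways of 10–12 genes, B = 200 — rejection rate at
  p ≤ 0.05 expected in [0.02, 0.08];
- power: 20 replicates (10 in the script), one planted 20-gene pathway with
  50% causal genes at OR 1.5, 500+500 samples, 800 SNPs, 25 pathways,
  B = 200 — planted pathway must take the top NES with p ≤ 0.05 in ≥ 80%;
- two-stage: 10 replicates (6 in the script), shared planted effect at
  OR 1.4, 500+500 discovery and 400+400 replication, 560 SNPs, 20 pathways,
  B = 200 — final flag in ≥ 80%, flag implications on 100%;
- self-normalization: B = 500 on a 150+150-sample, 400-SNP study.

## Known limitations

- No LD simulation (see above); no sex-chromosome QC (gender checks,
  relatedness pruning are out of scope); no genomic-control correction.
- The FDR is the GSEA ratio estimate, which is noisy at small B and is
  clipped at 1; it is not a Benjamini–Hochberg FDR.
- The permutation p floor of 1/(B+1) bounds attainable significance; B must
  be raised for genome-wide pathway catalogs.
- Combined-stage analysis pools individual-level data; no meta-analytic
  combination of stage statistics is offered.
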