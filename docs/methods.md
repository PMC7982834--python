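# Methods

## The model

`bmmscan` implements a case-control GWAS for a polygenic binary trait (the
motivating application is cruciate-ligament rupture in dogs) as a Bayesian
mixture model over all SNPs simultaneously, plus a cross-population
haplotype-based selection scan between case and control subpopulations.

The linear model is

    y = X b + Z beta + e,        e ~ N(0, sigma_e^2 I)

where `y` is the 0/1 case indicator (or a continuous liability), `X` the
fixed-effect design (intercept; sex, age, weight, neuter status, standardized;
the top five principal components of the variance-standardized genomic
relationship matrix), and `Z` the SNP design with column `j` centered by
`2 p_j` and divided by `sqrt(2 p_j (1 - p_j))`. Each SNP effect is drawn from
a four-component normal mixture

    beta_j ~ sum_k pi_k N(0, gamma_k sigma_g^2),
    gamma = (0, 1e-4, 1e-3, 1e-2),

a zero spike plus three effect tiers expressed as fractions of the additive
genetic variance scale `sigma_g^2` (BayesR). In the annotation-informed mode
(BayesRC) every SNP carries one biological prior-class label — A&S, ACL, SYN,
LIT or NA, from differential-expression and literature candidate-gene lists
with a ±25 kb flank — and each class keeps its own mixing proportions
`pi^(c)` under a Dirichlet(1,1,1,1) prior. With one class the two modes are
identical by construction.

Binary phenotypes are fitted directly as a linear model on 0/1, matching the
original software's treatment; effect sizes are therefore on the
observed (risk) scale and comparable across SNPs, not liability-scale
coefficients.

## Inference

Single-site Gibbs sampling, numba-compiled:

1. fixed effects jointly from their Gaussian full conditional (Cholesky of
   `X'X`, flat prior);
2. per SNP: the component indicator from its discrete full conditional with
   `beta_j` integrated out, then `beta_j` from its Gaussian full conditional
   (`beta_j = 0` in the spike), with incremental `O(n)` residual updates;
3. per class: `pi^(c) ~ Dirichlet(alpha + component counts)`;
4. `sigma_g^2`, `sigma_e^2` from scaled inverse-chi-squared full conditionals
   with `nu_0 = 4` and scales `h2_init * var(y)` and `(1 - h2_init) * var(y)`
   (`h2_init = 0.5`). Sensitivity to this prior is below Monte-Carlo error in
   the recovery tests.

The default schedule is 200,000 iterations with 100,000 burn-in and five
replicate chains whose per-SNP posterior means are averaged; chain seeds are
derived deterministically from one base seed. Storage is streaming running
means (`O(m)` memory, no thinning). Initialization is a cold start: all
effects zero, spike indicators, `pi = alpha / sum(alpha)`, variances at their
prior scales.

Two distinct variance summaries are reported. `sigma_g2` is the mixture
*scale* (the full-conditional posterior of the parameter the component
variances are fractions of). The heritability estimate `h2` instead uses the
genomic variance `var(Z beta)`, accumulated each iteration from the
maintained identity `Z beta = y - X b - r` at `O(n)` cost:
`h2 = var(Z beta) / (var(Z beta) + sigma_e2)`. The scale parameter
systematically exceeds the realized genetic variance whenever many
small-component SNPs are transiently nonzero, so it is not a heritability.

Ranking uses `|posterior mean effect|` with ties broken by chromosome then
position; effects are attached to genes within a gene body ±25 kb, distance 0
inside the body.

## Selection scan

EHH at offset `x` from a core SNP is the probability that two random carrier
haplotypes of the same core allele are identical over `[core, x]`:
`sum_h C(n_h, 2) / C(n_c, 2)` over distinct extended haplotypes. Curves are
walked marker-by-marker in both directions and stop at the chromosome end or
below a floor of 0.05; fewer than two carriers makes the curve (and any
statistic built on it) missing, not zero. The site statistic integrates the
allele-frequency-weighted combination of the ancestral- and derived-allele
curves by the trapezoid rule over physical distance, restricted to the
contiguous region around the core where the combined curve stays at or above
the floor. Ancestral orientation is metadata carried with the panel (the
simulator records the founder-major allele); no external inference is done.

XP-EHH is `ln(iES_cases / iES_controls)`, standardized to mean 0 / SD 1 over
all scored SNPs genome-wide (unbinned: the published statistic/p-value pairs
are consistent with unbinned standardization). Two-sided p-values come from
the standard-normal tail of the standardized score, computed on the log scale
so scores up to |z| = 40 do not underflow. Tier thresholds are inclusive:
candidate at p <= 1e-5, genome-wide at p <= 1e-8. Haplotype spans
(`calc_haplen`) report the outermost marker positions with EHH at or above
the same 0.05 threshold, per allele and population; the GWAS-overlap report
uses the union of the four spans of a hit.

These thresholds and the standardization assume genome-scale scans (hundreds
of thousands of SNPs). Desk-scale runs of a few thousand simulated SNPs
rarely reach |z| > 4; scaled-down analyses should scale the thresholds
accordingly (the pipeline exposes them as configuration).

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, with
ground truth:

* **LD / haplotypes** — founder-mosaic block copying: within each block
  (default 20 kb, ~ the average haplotype-block size in a dense within-breed
  panel) every haplotype copies one of 8 founders, switching founders between
  blocks with probability 0.1. This produces block LD and EHH decaying with
  distance at negligible cost; it is not coalescent-exact and has no
  within-block recombination, mutation, or gene conversion.
* **Sites** — 1 kb marker spacing, derived-allele frequencies drawn within a
  configurable MAF range (default 0.05–0.5) at the founder level.
* **Phenotype** — liability = genetic value + covariate terms + Gaussian
  noise scaled so var(g)/(var(g)+var(e)) equals the configured h2 (default
  0.4); cases are the top `prevalence` fraction (default 0.4, mirroring a
  156/397 case fraction). Effects are drawn per SNP from the four-component
  mixture with class-specific probabilities; the default class fractions
  mirror a 443k-SNP array with 2,614 / 7,850 / 703 / 1,042 SNPs in
  ACL/SYN/A&S/LIT, background component probabilities mirror the realized
  ~0.8% nonzero split, and biological classes get a ~8x enrichment of the
  nonzero components. Forced-component QTLs are planted at the component's
  RMS magnitude `sqrt(gamma_k sigma_g^2)` with seed-determined sign so the
  planted size is representative and reproducible rather than a lucky draw.
* **Covariates** — sex and neuter status Bernoulli, age ~ N(8, 2.5) years,
  weight ~ N(35, 6) kg, with modest liability effects by default so
  fixed-effect correction is exercised.
* **Sweep** — within a configured span, one donor haplotype is copied into
  randomly chosen case haplotypes until it reaches the target case frequency;
  controls are untouched. This emulates the case-enriched extended haplotype
  an XP-EHH scan should flag, not a generative selection model.
* **Annotation** — gene intervals are slotted uniformly with enough
  separation that flanked intervals never overlap, and DEG/literature gene
  lists are emitted such that re-assignment through the prior-class module
  reproduces the configured per-class SNP coverage.

What passing tests on this generator do **not** show about real data:
realistic allele-frequency spectra, variable recombination, genotyping error
beyond uniform missingness, cryptic relatedness, or ascertainment; the
linkage structure is piecewise-constant. Conclusions from the test suite are
about correctness of the algorithms under the assumed structure, not about
power on any particular cohort.

## Numerical and design choices

* HWE uses the two-sided exact test (probability mass of heterozygote counts
  no more likely than observed, conditional on allele counts), the de-facto
  standard at p = 1e-7 thresholds; monomorphic sites give p = 1.
* QC filters run sequentially (MAF < 0.01, call rate < 0.90, HWE p < 1e-7,
  then any remaining missingness) and report per-filter counts, which
  therefore sum exactly to input minus output. MAF uses non-missing calls.
* GRM standardization uses observed allele frequencies with per-SNP unit
  variance (VanRaden method 2 style); PCs are eigenvectors scaled by the
  square root of their eigenvalues, computed after QC.
* Coordinates are 1-based inclusive internally; BED is 0-based half-open on
  disk. Flank boundaries are inclusive on both sides.
* Class overlap precedence is A&S > ACL > SYN > LIT (the both-tissue class
  carries the least uncertainty about candidacy); ties within a class go to
  the nearest gene; gene symbols match case-insensitively; a gene on both a
  DEG list and the literature list keeps its expression-derived class.
* Degenerate inputs: an all-case (or all-control) response, zero-variance
  SNPs entering the GRM or model build, and sweeps outside chromosome bounds
  all raise informative errors; an all-zero effect draw falls back to h2 = 0
  with a warning.

## Test problem sizes

The suite exercises the sampler at up to n = 1,000 samples x m = 5,000
unlinked SNPs for 20,000 iterations (heritability recovered within ±0.1 and a
planted 1%-variance QTL ranked first), paired annotation-informed vs
single-class comparisons at n = 400 x m = 800 over 10 seeds (average
precision at 20), and sweep localization over 20 seeded cohorts of 150
samples x 1,000 SNPs (top XP-EHH SNP inside the injected span in >= 18/20).
Unlinked genotypes are used for the sampler-recovery checks so effect
attribution is unambiguous; the liability (not the 0/1 indicator) is the
response there, since observed-scale heritability of a thresholded trait is
attenuated by design. Exhaustive checks (Hardy-Weinberg vs full enumeration)
cover every genotype count up to n = 200.

## Known limitations

* No probit/threshold likelihood; effects on binary traits are observed-scale.
* No genomic prediction / polygenic-score machinery.
* The selection module consumes already-phased haplotypes; phasing (and its
  cluster-count selection) is an upstream concern.
* Within-population statistics (iHS, Rsb) are out of scope.
* The ped/map reader infers ref/alt lexicographically, so a monomorphic-alt
  site does not round-trip orientation (simulated panels keep MAF >= 0.05).
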