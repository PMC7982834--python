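# bmmscan

Annotation-informed Bayesian mixture-model GWAS (BayesR / BayesRC) with
cross-population extended-haplotype-homozygosity (XP-EHH) selection scans,
for case-control cohorts with strong linkage disequilibrium — the motivating
setting is spontaneous cruciate-ligament rupture in purebred dogs, where the
trait is highly polygenic and the breed history leaves long haplotypes.

For geneticists who want to (a) fit all SNPs jointly instead of one marker at
a time, (b) let differential-expression and literature candidate genes raise
the prior probability of effect for the SNPs near them, and (c) ask whether
trait-associated haplotypes are also under artificial selection.

## The model

SNP effects are modeled as a four-component normal mixture,

    y = Xb + Zβ + e,   β_j ~ Σ_k π_k N(0, γ_k σ_g²),   γ = (0, 10⁻⁴, 10⁻³, 10⁻²),

with a zero spike and three effect tiers as fractions of the additive genetic
variance σ_g². `X` holds the intercept, sex, age, weight, neuter status and
the top five PCs of the variance-standardized genomic relationship matrix;
`Z` is the centered, variance-scaled SNP design. In BayesRC mode every SNP
carries a biological prior class (A&S / ACL / SYN / LIT / NA from
differentially-expressed-gene and literature candidate lists, gene bodies
±25 kb) and each class keeps its own Dirichlet(1,1,1,1)-updated mixing
proportions π^(c); with a single class the model is exactly BayesR.
Inference is Gibbs sampling (default 200,000 iterations, 100,000 burn-in,
five averaged chains), numba-compiled.

The selection scan computes EHH curves per core allele, integrates them into
the site statistic iES, and standardizes ln(iES_cases/iES_controls)
genome-wide; two-sided normal p-values are computed on the log scale, with
candidate (p ≤ 1e-5) and genome-wide (p ≤ 1e-8) tiers and per-allele
haplotype spans around each hit.

A synthetic-cohort generator (founder-mosaic block LD, liability-threshold
case-control phenotypes with class-enriched mixture effects, covariates, and
an optional engineered partial sweep in cases) provides ground truth for
every downstream stage.

## Worked example

```python
import numpy as np
import bmmscan as bm

cfg = bm.SimConfig(n_samples=250, n_snps=1600, n_chroms=2, seed=17, h2=0.5,
                   covariate_effects={}, force_component={400: 3},
                   sweep=bm.SweepConfig("chr1", 400_000, 0.9, 200.0))
panel, genotypes, cov, truth, genes, lists, _ = bm.simulate_cohort(cfg)

qc_g, report = bm.apply_qc(genotypes)
print("QC removed:", report.removed)

pcs = bm.GRMPCA(n_components=5).fit(qc_g).scores_
classes = bm.build_gene_classes(lists["deg_acl"], lists["deg_syn"], lists["lit"])
assignment = bm.assign_snps(qc_g, genes, classes)
data = bm.build_model_data(qc_g, cov, pcs, assignment)
post = bm.run_replicates(data, n_chains=5, n_iter=4000, burn_in=2000, seed=2)
print(bm.effects_to_genes(post.to_frame(qc_g.variants, assignment.snp_class),
                          genes, top_n=5).to_string(index=False))

case = np.flatnonzero(cov["case"] == 1); ctrl = np.flatnonzero(cov["case"] == 0)
scan = bm.xpehh_scan(panel.subset_samples(case), panel.subset_samples(ctrl))
hits = bm.classify_hits(scan, candidate_p=1e-2, genomewide_p=1e-4)
print(hits[["chrom", "pos", "xpehh", "neglog10_p", "tier"]].head(3).to_string(index=False))
```

prints

```
QC removed: {'maf': 0, 'call_rate': 0, 'hwe': 30, 'any_missing': 0}
      locus class    effect    gene  distance
chr1:493000   SYN  0.035087 SYNG001         0
chr1:474000   SYN -0.030219 SYNG001      6000
chr1:482000   SYN  0.027710 SYNG001         0
chr1:487000   SYN  0.025848 SYNG001         0
chr1:483000   SYN -0.022578 SYNG001         0
chrom    pos    xpehh  neglog10_p      tier
 chr1 334000 3.285248    2.991857 candidate
 chr1 315000 3.240304    2.922988 candidate
 chr1 472000 3.200178    2.862194 candidate
```

This cohort carries an engineered partial sweep in cases over chr1:300–500 kb
(one donor haplotype copied to 90% of case haplotypes). The largest posterior
SNP effects sit inside that span — the donor haplotype is genuinely
case-associated — and the XP-EHH scan flags the same region, which is exactly
the GWAS × selection overlap the pipeline's report stage tabulates. The
candidate threshold here is scaled to the 1,600-SNP demo; the genome-scale
defaults are p ≤ 1e-5 / 1e-8. The two rankings differ by construction: the
GWAS table orders by |posterior mean effect| (signed values shown), the scan
by standardized XP-EHH.

The same pipeline is scriptable end-to-end with a reproducibility manifest:

```
bmmscan all --out-dir run1            # simulate → QC → priors → GWAS → selscan → report
bmmscan qc cohort.vcf --maf 0.01 --callrate 0.90 --hwe 1e-7 --out qc.tsv
bmmscan gwas cohort.vcf --covariates covariates.tsv --classes priors.tsv \
        --iters 200000 --burnin 100000 --chains 5 --seed 1 --out effects.tsv
bmmscan selscan --cases cases.vcf --controls controls.vcf --out scan.tsv
```

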