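"""Synthetic case-control cohort generator.

The generator produces every object the downstream pipeline consumes, with
ground truth attached:

* phased haplotypes with block LD (founder-mosaic copying: within a haplotype
  block every haplotype is a copy of one of a small set of founders, and at
  each block boundary a haplotype switches founders with a configurable
  probability) — this yields extended-haplotype homozygosity that decays with
  distance;
* diploid genotypes, covariates (sex, age, weight, neuter status) and a
  liability-threshold binary phenotype whose SNP effects are drawn from a
  four-component normal mixture with class-specific component probabilities;
* gene annotation plus DEG/literature gene lists that reproduce the configured
  per-class SNP fractions when fed through the prior-assignment module;
* optionally, an engineered partial sweep: one donor haplotype copied into
  case haplotypes over a span until it reaches a target frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GAMMA, SimConfig
from .datatypes import MISSING, GenotypeMatrix, HaplotypePanel

log = logging.getLogger(__name__)

_GENE_BODY_BP = 20_000
_FLANK_BP = 25_000


@dataclass
class TrueEffects:
    """Simulation ground truth: per-SNP effects and per-sample liabilities."""

    effect: np.ndarray          # (m,) liability-scale effect of the standardized genotype
    component: np.ndarray       # (m,) mixture component index 0..3
    liability: np.ndarray       # (n,)
    genetic_value: np.ndarray   # (n,)
    case_threshold: float
    h2_realized: float


def _variant_table(config: SimConfig) -> pd.DataFrame:
    chroms, pos = [], []
    for name, m in zip(config.chrom_names(), config.snps_per_chrom()):
        chroms += [name] * m
        pos += list(np.arange(1, m + 1) * config.snp_spacing_bp)
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"}
    )


def simulate_haplotypes(config: SimConfig) -> HaplotypePanel:
    """Generate 2*n_samples phased haplotypes with founder-mosaic block LD."""
    rng = config.rng()
    variants = _variant_table(config)
    n_hap = 2 * config.n_samples
    haps = np.empty((n_hap, config.n_snps), dtype=np.uint8)
    ancestral = np.empty(config.n_snps, dtype=np.uint8)

    block_snps = max(1, int(round(config.block_len_kb * 1000 / config.snp_spacing_bp)))
    lo, hi = config.maf_range
    nf = config.n_founders
    # founder allele counts whose frequency lies inside the MAF range
    if nf == 1:
        count_choices = np.array([0])  # degenerate: one founder, no variation
    else:
        counts = np.arange(1, nf)
        ok = (counts / nf >= lo) & (counts / nf <= hi)
        if not ok.any():
            ok = np.ones_like(counts, dtype=bool)
        count_choices = counts[ok]

    col = 0
    for m in config.snps_per_chrom():
        n_blocks = (m + block_snps - 1) // block_snps
        # founder mosaic per haplotype: switch founders between blocks
        founder = np.empty((n_hap, n_blocks), dtype=np.int64)
        founder[:, 0] = rng.integers(0, nf, size=n_hap)
        for b in range(1, n_blocks):
            switch = rng.random(n_hap) < config.recomb_between_blocks
            founder[:, b] = np.where(switch, rng.integers(0, nf, size=n_hap), founder[:, b - 1])
        for b in range(n_blocks):
            width = min(block_snps, m - b * block_snps)
            # founder alleles per site: derived-allele count chosen within MAF range
            fa = np.zeros((nf, width), dtype=np.uint8)
            k = rng.choice(count_choices, size=width)
            for s in range(width):
                carriers = rng.choice(nf, size=k[s], replace=False)
                fa[carriers, s] = 1
            haps[:, col : col + width] = fa[founder[:, b]]
            col += width
    # ancestral allele = founder-major allele (recorded, not inferred)
    freq = haps.mean(axis=0)
    ancestral[:] = (freq > 0.5).astype(np.uint8)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    return HaplotypePanel(samples, variants, haps, ancestral)


def simulate_annotation(
    config: SimConfig, variants: pd.DataFrame, flank_bp: int = _FLANK_BP
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Place non-overlapping genes so that SNP coverage per prior class roughly
    matches ``config.class_fractions`` after +-flank assignment.

    Returns (gene table, gene lists keyed deg_acl / deg_syn / lit).
    """
    rng = np.random.default_rng(config.seed + 7)
    spacing = config.snp_spacing_bp
    snps_per_gene = (_GENE_BODY_BP + 2 * flank_bp) // spacing + 1
    targets = {c: int(round(f * config.n_snps)) for c, f in config.class_fractions.items()}
    want: list[str] = []
    for cls, t in targets.items():
        want += [cls] * max(1, int(round(t / snps_per_gene)))
    rng.shuffle(want)

    # slot genes uniformly across chromosomes with enough separation that
    # flanked intervals never overlap
    slot_bp = _GENE_BODY_BP + 2 * flank_bp + 2 * spacing
    rows = []
    gi = 0
    chrom_sizes = {
        name: m * spacing for name, m in zip(config.chrom_names(), config.snps_per_chrom())
    }
    total_bp = sum(chrom_sizes.values())
    n_genes = len(want)
    stride = max(slot_bp, total_bp // (n_genes + 1))
    cursor = stride // 2
    for cls in want:
        # map linear cursor onto a chromosome
        off = cursor
        for chrom, size in chrom_sizes.items():
            if off < size:
                break
            off -= size
        start = min(max(flank_bp + spacing, off), chrom_sizes[chrom] - _GENE_BODY_BP - flank_bp)
        if start < 1:
            cursor += stride
            continue
        rows.append(
            {"gene": f"{cls.replace('&', 'N')}G{gi:03d}", "chrom": chrom,
             "start": int(start), "end": int(start + _GENE_BODY_BP), "class": cls}
        )
        gi += 1
        cursor += stride
    genes = pd.DataFrame(rows)
    lists = {
        "deg_acl": genes.loc[genes["class"].isin(["ACL", "A&S"]), "gene"].tolist(),
        "deg_syn": genes.loc[genes["class"].isin(["SYN", "A&S"]), "gene"].tolist(),
        "lit": genes.loc[genes["class"] == "LIT", "gene"].tolist(),
    }
    return genes.drop(columns="class"), lists


def _standardize(dosage: np.ndarray) -> np.ndarray:
    p = dosage.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[sd == 0] = 1.0
    return (dosage - 2.0 * p) / sd


def simulate_phenotypes(
    panel: HaplotypePanel,
    config: SimConfig,
    snp_class: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, TrueEffects]:
    """Draw mixture-distributed SNP effects, liabilities and case status.

    ``snp_class`` gives each SNP's prior class label (default: all "NA").
    Liability = genetic value + covariate terms + Gaussian noise scaled so the
    genetic fraction of (genetic + noise) variance equals ``config.h2``.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = panel.n_variants
    n = panel.n_samples
    if snp_class is None:
        snp_class = np.full(m, "NA", dtype=object)

    component = np.zeros(m, dtype=np.int64)
    for cls, probs in config.effect_mixture.items():
        idx = np.flatnonzero(np.asarray(snp_class) == cls)
        if idx.size:
            component[idx] = rng.choice(4, size=idx.size, p=probs)
    effect = np.zeros(m)
    gam = np.asarray(GAMMA)
    nz = component > 0
    effect[nz] = rng.normal(0.0, np.sqrt(gam[component[nz]] * config.sigma_g2))
    for j, k in config.force_component.items():
        component[j] = k
        # planted at the component's RMS magnitude for reproducible size
        effect[j] = rng.choice([-1.0, 1.0]) * np.sqrt(gam[k] * config.sigma_g2) if k > 0 else 0.0

    genotypes = panel.to_genotypes()
    Z = _standardize(genotypes.dosage.astype(float))
    g = Z @ effect
    var_g = float(np.var(g))
    if var_g == 0.0:
        warnings.warn("all-zero genetic values; falling back to h2 = 0", stacklevel=2)
        noise_sd = 1.0
    else:
        noise_sd = np.sqrt(var_g * (1.0 - config.h2) / config.h2)

    cov = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "sex": rng.integers(0, 2, size=n),            # 0 female, 1 male
            "age": rng.normal(8.0, 2.5, size=n).round(1),
            "weight": rng.normal(35.0, 6.0, size=n).round(1),
            "neuter": (rng.random(n) < 0.75).astype(int),
        }
    )
    cov_term = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        x = cov[name].to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        cov_term += eff * x
    noise = rng.normal(0.0, noise_sd, size=n)
    liability = g + cov_term + noise
    threshold = float(np.quantile(liability, 1.0 - config.prevalence))
    case = (liability > threshold).astype(int)
    cov["case"] = case

    if config.missing_rate > 0:
        mask = rng.random(genotypes.dosage.shape) < config.missing_rate
        dosage = genotypes.dosage.copy()
        dosage[mask] = MISSING
        genotypes = GenotypeMatrix(genotypes.samples, genotypes.variants, dosage)

    h2_real = var_g / (var_g + noise_sd**2) if var_g > 0 else 0.0
    truth = TrueEffects(effect, component, liability, g, threshold, h2_real)
    return genotypes, cov, truth


def inject_sweep(
    panel: HaplotypePanel, case_ids: list[str], config: SimConfig
) -> HaplotypePanel:
    """Copy one donor haplotype into case haplotypes over the sweep span until
    it reaches the configured case frequency; controls are untouched."""
    sw = config.sweep
    if sw is None:
        raise ValueError("no sweep configured")
    v = panel.variants
    on_chrom = v["chrom"] == sw.chrom
    if not on_chrom.any():
        raise ValueError(f"sweep chromosome {sw.chrom} not in panel")
    chrom_len = int(v.loc[on_chrom, "pos"].max())
    half = sw.span_kb * 1000 / 2
    if sw.pos - half < 0 or sw.pos + half > chrom_len + config.snp_spacing_bp:
        raise ValueError(
            f"sweep span [{sw.pos - half:.0f}, {sw.pos + half:.0f}] outside "
            f"{sw.chrom} (length {chrom_len} bp)"
        )
    span = np.flatnonzero(on_chrom & (v["pos"] >= sw.pos - half) & (v["pos"] <= sw.pos + half))
    if span.size < 10:
        raise ValueError(f"sweep span contains only {span.size} SNPs (need >= 10)")

    case_idx = [panel.samples.index(s) for s in case_ids]
    hap_rows = np.array([r for i in case_idx for r in (2 * i, 2 * i + 1)])
    haps = panel.haplotypes.copy()
    donor = haps[hap_rows[0], span].copy()
    same = np.flatnonzero((haps[np.ix_(hap_rows, span)] == donor).all(axis=1))
    target = int(np.ceil(sw.case_freq * hap_rows.size))
    need = target - same.size
    if need > 0:
        rng = np.random.default_rng(config.seed + 3)
        others = np.setdiff1d(np.arange(hap_rows.size), same)
        pick = rng.choice(others, size=min(need, others.size), replace=False)
        haps[np.ix_(hap_rows[pick], span)] = donor
    return HaplotypePanel(list(panel.samples), panel.variants.copy(), haps, panel.ancestral.copy())


def simulate_cohort(config: SimConfig, flank_bp: int = _FLANK_BP):
    """Full cohort: haplotypes, annotation-derived classes, phenotypes, sweep.

    Returns (panel, genotypes, covariates, truth, genes, gene_lists, snp_class).
    """
    from .priors import assign_snps, build_gene_classes

    panel = simulate_haplotypes(config)
    genes, lists = simulate_annotation(config, panel.variants, flank_bp)
    classes = build_gene_classes(lists["deg_acl"], lists["deg_syn"], lists["lit"])
    genotypes0 = panel.to_genotypes()
    assignment = assign_snps(genotypes0, genes, classes, flank_bp=flank_bp)
    genotypes, cov, truth = simulate_phenotypes(panel, config, assignment.snp_class)
    if config.sweep is not None:
        case_ids = cov.loc[cov["case"] == 1, "sample_id"].tolist()
        panel = inject_sweep(panel, case_ids, config)
        genotypes = GenotypeMatrix(
            genotypes.samples, genotypes.variants, panel.to_genotypes().dosage
        )
    return panel, genotypes, cov, truth, genes, lists, assignment.snp_class


def write_cohort(out_dir: str, panel, genotypes, covariates, genes, gene_lists) -> dict[str, str]:
    """Write the standard cohort file set; returns {artifact: path}."""
    import os

    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "plink": os.path.join(out_dir, "cohort"),
        "covariates": os.path.join(out_dir, "covariates.tsv"),
        "annotation": os.path.join(out_dir, "genes.bed"),
        "deg_acl": os.path.join(out_dir, "deg_acl.txt"),
        "deg_syn": os.path.join(out_dir, "deg_syn.txt"),
        "lit": os.path.join(out_dir, "lit_genes.txt"),
    }
    _io.write_vcf(paths["vcf"], panel)
    _io.write_plink(paths["plink"], genotypes, covariates["case"].to_numpy())
    _io.write_covariates(paths["covariates"], covariates)
    _io.write_bed(paths["annotation"], genes)
    _io.write_gene_list(paths["deg_acl"], gene_lists["deg_acl"])
    _io.write_gene_list(paths["deg_syn"], gene_lists["deg_syn"])
    _io.write_gene_list(paths["lit"], gene_lists["lit"])
    return paths
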