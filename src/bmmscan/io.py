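"""Readers and writers for the cohort file formats.

Formats: phased VCF 4.2 (written as plain text, read through cyvcf2), the
PLINK .ped/.map text dialect, covariate TSV, BED3+name gene annotation and
one-symbol-per-line gene lists. Internally positions are 1-based inclusive;
BED is written 0-based half-open.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GenotypeMatrix, HaplotypePanel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------- VCF
def write_vcf(path: str, panel: HaplotypePanel) -> None:
    """Write a phased VCF 4.2; ancestral allele is carried in INFO/AA."""
    v = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in v.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 10_000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        h = panel.haplotypes
        for j in range(panel.n_variants):
            row = v.iloc[j]
            aa = row["ref"] if panel.ancestral[j] == 0 else row["alt"]
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_samples))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['chrom']}:{row['pos']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\tAA={aa}\tGT\t{gts}\n"
            )


def _scan_vcf(path: str):
    vcf = VCF(path)
    samples = list(vcf.samples)
    recs, dos_rows, hap_rows, anc = [], [], [], []
    n_skipped = 0
    phased_all = True
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = np.array(var.genotypes, dtype=np.int32)  # (n, 3): a0, a1, phased
        a = g[:, :2]
        if np.any((a > 1) & (a >= 0)):
            n_skipped += 1
            continue
        half = (a[:, 0] < 0) != (a[:, 1] < 0)
        if half.any():
            n_skipped += 1
            continue
        dos = np.where(a[:, 0] < 0, MISSING, a[:, 0] + a[:, 1]).astype(np.int8)
        phased_all &= bool(np.all(g[:, 2] == 1))
        aa = var.INFO.get("AA")
        anc.append(0 if aa is None or aa == var.REF else 1)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dos_rows.append(dos)
        hap_rows.append(a.astype(np.uint8, copy=False))
    if n_skipped:
        log.info("skipped %d non-biallelic or half-called VCF records", n_skipped)
    variants = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    return samples, variants, dos_rows, hap_rows, np.array(anc, dtype=np.uint8), phased_all


def read_vcf(path: str) -> GenotypeMatrix:
    samples, variants, dos_rows, _, _, _ = _scan_vcf(path)
    dosage = (
        np.array(dos_rows, dtype=np.int8).T
        if dos_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, dosage)


def read_vcf_haplotypes(path: str) -> HaplotypePanel:
    samples, variants, dos_rows, hap_rows, anc, phased = _scan_vcf(path)
    if not phased:
        raise ValueError(f"{path}: haplotype input requires fully phased genotypes")
    if any(np.any(r > 1) for r in hap_rows):
        raise ValueError(f"{path}: missing genotypes not allowed in a haplotype panel")
    m = len(hap_rows)
    haps = np.zeros((2 * len(samples), m), dtype=np.uint8)
    for j, a in enumerate(hap_rows):
        haps[0::2, j] = a[:, 0]
        haps[1::2, j] = a[:, 1]
    return HaplotypePanel(samples, variants, haps, anc)


# --------------------------------------------------------------- PLINK text
def write_plink(prefix: str, g: GenotypeMatrix, phenotype: np.ndarray | None = None) -> None:
    """Write .ped/.map; alleles are the variant ref/alt letters, missing = '0 0'."""
    v = g.variants
    with open(prefix + ".map", "w") as fh:
        for _, row in v.iterrows():
            chrom = str(row["chrom"]).removeprefix("chr")
            fh.write(f"{chrom}\t{row['chrom']}:{row['pos']}\t0\t{row['pos']}\n")
    ref = v["ref"].to_numpy()
    alt = v["alt"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(g.samples):
            pheno = 0 if phenotype is None else int(phenotype[i]) + 1  # plink 1/2 coding
            fields = [sid, sid, "0", "0", "0", str(pheno)]
            d = g.dosage[i]
            for j in range(g.n_variants):
                if d[j] == MISSING:
                    fields += ["0", "0"]
                elif d[j] == 0:
                    fields += [ref[j], ref[j]]
                elif d[j] == 1:
                    fields += [ref[j], alt[j]]
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    variants = pd.read_csv(
        prefix + ".map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str},
    )
    variants["chrom"] = [c if c.startswith("chr") else f"chr{c}" for c in variants["chrom"]]
    m = len(variants)
    samples, rows = [], []
    alleles: list[dict[str, int]] = [dict() for _ in range(m)]
    raw_pairs = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            samples.append(parts[1])
            pair = np.array(parts[6:], dtype="U1").reshape(m, 2)
            raw_pairs.append(pair)
            for j in range(m):
                for a in pair[j]:
                    if a != "0":
                        alleles[j].setdefault(a, len(alleles[j]))
    ref, alt = [], []
    for j in range(m):
        seen = sorted(alleles[j])
        if len(seen) > 2:
            raise ValueError(f"variant {j} has more than two alleles in {prefix}.ped")
        ref.append(seen[0] if seen else "A")
        alt.append(seen[1] if len(seen) > 1 else ".")
    # orient dosage as count of the lexicographically-later (alt) allele
    for pair in raw_pairs:
        d = np.full(m, MISSING, dtype=np.int8)
        called = pair[:, 0] != "0"
        d[called] = (pair[called, 0] == np.array(alt)[called]).astype(np.int8) + (
            pair[called, 1] == np.array(alt)[called]
        ).astype(np.int8)
        rows.append(d)
    variants = variants.rename(columns={"snp_id": "id"})[["chrom", "pos"]]
    variants["ref"] = ref
    variants["alt"] = alt
    dosage = np.array(rows, dtype=np.int8) if rows else np.zeros((0, m), dtype=np.int8)
    return GenotypeMatrix(samples, variants, dosage)


# ------------------------------------------------- haplotype-matrix TSV
def write_haplotype_tsv(path: str, panel: HaplotypePanel) -> None:
    """Plain haplotype matrix: chrom, pos, ancestral, then one 0/1 column per
    haplotype (two per sample, suffixed _a/_b)."""
    cols = {"chrom": panel.variants["chrom"], "pos": panel.variants["pos"],
            "ancestral": panel.ancestral}
    for i, sid in enumerate(panel.samples):
        cols[f"{sid}_a"] = panel.haplotypes[2 * i]
        cols[f"{sid}_b"] = panel.haplotypes[2 * i + 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path: str) -> HaplotypePanel:
    tab = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in tab.columns if c.endswith(("_a", "_b"))]
    samples = list(dict.fromkeys(c[:-2] for c in hap_cols))
    haps = np.empty((2 * len(samples), len(tab)), dtype=np.uint8)
    for i, sid in enumerate(samples):
        haps[2 * i] = tab[f"{sid}_a"].to_numpy()
        haps[2 * i + 1] = tab[f"{sid}_b"].to_numpy()
    variants = pd.DataFrame(
        {"chrom": tab["chrom"], "pos": tab["pos"], "ref": "A", "alt": "G"}
    )
    return HaplotypePanel(samples, variants, haps, tab["ancestral"].to_numpy(np.uint8))


# ------------------------------------------------------- covariates and BED
def write_covariates(path: str, covariates: pd.DataFrame) -> None:
    covariates.to_csv(path, sep="\t", index=False)


def read_covariates(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(path: str, genes: pd.DataFrame) -> None:
    """Genes (gene, chrom, start, end; 1-based inclusive) -> BED 0-based half-open."""
    out = genes[["chrom"]].copy()
    out["start"] = genes["start"] - 1
    out["end"] = genes["end"]
    out["name"] = genes["gene"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"])
    return pd.DataFrame(
        {
            "gene": bed["gene"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,  # back to 1-based inclusive
            "end": bed["end"],
        }
    )


def write_gene_list(path: str, genes: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + ("\n" if genes else ""))


def read_gene_list(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
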