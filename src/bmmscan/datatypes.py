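"""Core in-memory containers shared across the pipeline.

Conventions: genomic positions are 1-based inclusive internally; BED files are
read/written 0-based half-open. Dosages are alt-allele counts in {0, 1, 2} with
``MISSING`` (-1) allowed only before QC. Haplotype panels are binary matrices of
shape (2 * n_samples, m_variants); row ``2i`` and ``2i + 1`` are the two phased
haplotypes of sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical biological prior class labels, in precedence order
CLASS_LABELS = ("A&S", "ACL", "SYN", "LIT", "NA")

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


def _check_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for _, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("variant positions must be strictly increasing within chromosome")
    return variants.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages with variant and sample metadata."""

    samples: list[str]
    variants: pd.DataFrame  # columns chrom, pos, ref, alt
    dosage: np.ndarray      # (n_samples, m) int8, MISSING allowed pre-QC

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> np.ndarray:
        v = self.variants
        return (v["chrom"].astype(str) + ":" + v["pos"].astype(str)).to_numpy()

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        n_called = d.count(axis=0)
        with np.errstate(invalid="ignore"):
            p = d.sum(axis=0).filled(0) / np.maximum(2 * n_called, 1)
        p = np.where(n_called > 0, p, np.nan)
        return np.asarray(p, dtype=float)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (2n x m) with ancestral-allele orientation.

    ``ancestral[j]`` is the allele code (0 or 1) regarded as ancestral at
    variant j; the other allele is derived.
    """

    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray  # (2n, m) uint8 in {0, 1}
    ancestral: np.ndarray   # (m,) uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.variants = _check_variants(self.variants)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError("haplotype matrix must be (2*n_samples, n_variants)")
        if self.ancestral.shape != (len(self.variants),):
            raise ValueError("ancestral orientation must have one entry per variant")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def to_genotypes(self) -> GenotypeMatrix:
        dos = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeMatrix(list(self.samples), self.variants.copy(), dos)

    def subset_samples(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        hap_rows = np.empty(2 * len(idx), dtype=np.int64)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            haplotypes=self.haplotypes[hap_rows],
            ancestral=self.ancestral.copy(),
        )


@dataclass
class QCReport:
    """Per-filter removal accounting for sequential genotype QC."""

    n_input: int
    n_output: int
    removed: dict[str, int]
    thresholds: dict[str, float]
    per_snp: pd.DataFrame = field(repr=False, default=None)  # maf, call_rate, hwe_p

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "total", "removed": self.n_input - self.n_output})
        return pd.DataFrame(rows)


@dataclass
class PriorClassAssignment:
    """Per-SNP biological prior class plus the gene(s) that justified it."""

    snp_class: np.ndarray        # (m,) of CLASS_LABELS strings
    gene: np.ndarray             # (m,) gene symbol or "" for NA
    distance: np.ndarray         # (m,) bp to the justifying gene body, -1 for NA

    def counts(self) -> pd.DataFrame:
        lab, cnt = np.unique(self.snp_class, return_counts=True)
        table = pd.DataFrame({"class": list(CLASS_LABELS)})
        table["n_snps"] = [int(cnt[lab == c][0]) if c in lab else 0 for c in CLASS_LABELS]
        table["fraction"] = table["n_snps"] / table["n_snps"].sum()
        return table

    def class_index(self) -> tuple[np.ndarray, list[str]]:
        """Integer class codes for the sampler, NA last; only non-empty classes."""
        present = [c for c in CLASS_LABELS if (self.snp_class == c).any()]
        code = {c: i for i, c in enumerate(present)}
        return np.array([code[c] for c in self.snp_class], dtype=np.int32), present


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior means, averaged across replicate chains."""

    effects: np.ndarray            # (m,) posterior-mean SNP effect, standardized scale
    occupancy: np.ndarray          # (m, 4) mixture-component occupancy probabilities
    pi: np.ndarray                 # (C, 4) mixing-proportion means per class
    sigma_g2: float
    sigma_e2: float
    component_counts: np.ndarray   # (4,) mean number of SNPs per component
    fixed_effects: np.ndarray
    var_genetic: float = 0.0       # posterior mean of var(Z beta), the variance
                                   # the SNPs jointly explain
    class_labels: list[str] = field(default_factory=lambda: ["NA"])
    per_chain: list["PosteriorSummary"] = field(default_factory=list)
    max_residual_error: float = 0.0
    beta_trace: np.ndarray | None = None

    @property
    def h2(self) -> float:
        """Genomic heritability: variance explained by SNPs over total."""
        return self.var_genetic / (self.var_genetic + self.sigma_e2)

    def to_frame(self, variants: pd.DataFrame, snp_class: np.ndarray | None = None) -> pd.DataFrame:
        out = variants[["chrom", "pos"]].copy()
        out["class"] = snp_class if snp_class is not None else "NA"
        out["effect"] = self.effects
        for k in range(4):
            out[f"p_comp{k}"] = self.occupancy[:, k]
        return out
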