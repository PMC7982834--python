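"""Genotype QC, Hardy-Weinberg exact testing, GRM/PCA and imputation scoring.

QC filters run sequentially — minor allele frequency, genotyping call rate,
Hardy-Weinberg exact-test p-value, then removal of any SNP with remaining
missing genotypes (the mixture-model sampler does not tolerate missingness).
MAF and HWE use non-missing calls only.

The genomic relationship matrix is VanRaden-style on variance-standardized
genotypes: each column centered by twice the allele frequency and scaled to
unit variance, GRM = ZZ'/m. Principal-component scores are eigenvectors
scaled by the square root of their eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix, QCReport

log = logging.getLogger(__name__)


# ------------------------------------------------------------- HWE exact test
def hwe_het_distribution(n: int, rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given ``n`` diploid
    samples and ``rare`` copies of the rarer allele.

    Returns (possible heterozygote counts, their probabilities); the counts
    share the parity of ``rare``.
    """
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return hets, p


def hwe_exact_pvalues(n: int, rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided exact-test p-value for every possible heterozygote count
    given ``n`` samples and ``rare`` rare-allele copies."""
    hets, p = hwe_het_distribution(n, rare)
    # p-value = total probability of outcomes no more likely than the observed
    pvals = np.array([min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()) for p_obs in p])
    return hets, pvals


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test (sum of heterozygote-count
    probabilities not exceeding the observed one, conditional on allele
    counts). Returns 1.0 for monomorphic counts."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    hets, pvals = hwe_exact_pvalues(n, rare)
    return float(pvals[hets == n_Aa][0])


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    out = np.empty(dosage.shape[1])
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        col = col[col != MISSING]
        out[j] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    return out


# ------------------------------------------------------------------ QC filter
class QCFilter(BaseEstimator, TransformerMixin):
    """Sequential SNP-level QC as a transformer over a GenotypeMatrix.

    Parameters follow the standard case-control defaults: ``maf_min=0.01``,
    ``callrate_min=0.90``, ``hwe_alpha=1e-7``, ``drop_any_missing=True``.
    Fitted attributes: ``keep_``, ``report_``.
    """

    def __init__(self, maf_min=0.01, callrate_min=0.90, hwe_alpha=1e-7, drop_any_missing=True):
        self.maf_min = maf_min
        self.callrate_min = callrate_min
        self.hwe_alpha = hwe_alpha
        self.drop_any_missing = drop_any_missing

    def fit(self, g: GenotypeMatrix, y=None):
        for name in ("maf_min", "callrate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in [0, 1]")
        if g.n_variants == 0:
            raise ValueError("empty genotype matrix")
        d = g.dosage
        n = g.n_samples
        called = (d != MISSING).sum(axis=0)
        p = g.allele_freq()
        maf = np.minimum(p, 1.0 - p)

        keep = np.ones(g.n_variants, dtype=bool)
        removed: dict[str, int] = {}

        fail = keep & ~(maf >= self.maf_min)
        removed["maf"] = int(fail.sum())
        keep &= ~fail

        callrate = called / n
        fail = keep & (callrate < self.callrate_min)
        removed["call_rate"] = int(fail.sum())
        keep &= ~fail

        hwe_p = _hwe_pvalues(d)
        fail = keep & (hwe_p < self.hwe_alpha)
        removed["hwe"] = int(fail.sum())
        keep &= ~fail

        if self.drop_any_missing:
            fail = keep & (called < n)
            removed["any_missing"] = int(fail.sum())
            keep &= ~fail

        self.keep_ = keep
        self.report_ = QCReport(
            n_input=g.n_variants,
            n_output=int(keep.sum()),
            removed=removed,
            thresholds={
                "maf_min": self.maf_min,
                "callrate_min": self.callrate_min,
                "hwe_alpha": self.hwe_alpha,
                "drop_any_missing": float(self.drop_any_missing),
            },
            per_snp=pd.DataFrame({"maf": maf, "call_rate": callrate, "hwe_p": hwe_p}),
        )
        return self

    def transform(self, g: GenotypeMatrix) -> GenotypeMatrix:
        return g.take_variants(np.flatnonzero(self.keep_))


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.90,
    hwe_alpha: float = 1e-7,
    drop_any_missing: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    f = QCFilter(maf_min, callrate_min, hwe_alpha, drop_any_missing).fit(g)
    return f.transform(g), f.report_


# --------------------------------------------------------------------- GRM/PCA
def standardized_genotypes(dosage: np.ndarray) -> np.ndarray:
    """Center by 2p and scale to unit variance 1/sqrt(2p(1-p))."""
    d = np.asarray(dosage, dtype=float)
    if np.any(d == MISSING):
        raise ValueError("missing genotypes present; run QC first")
    p = d.mean(axis=0) / 2.0
    var = 2.0 * p * (1.0 - p)
    if np.any(var == 0):
        raise ValueError("zero-variance SNP present; run QC first")
    return (d - 2.0 * p) / np.sqrt(var)


class GRMPCA(BaseEstimator, TransformerMixin):
    """Variance-standardized GRM and its top principal components.

    ``fit`` computes ``grm_`` (n x n), ``eigenvalues_`` and ``scores_``
    (eigenvectors scaled by sqrt(eigenvalue), descending order).
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, g: GenotypeMatrix | np.ndarray, y=None):
        dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g)
        Z = standardized_genotypes(dosage)
        m = Z.shape[1]
        self.grm_ = Z @ Z.T / m
        w, v = np.linalg.eigh(self.grm_)
        order = np.argsort(w)[::-1][: self.n_components]
        self.eigenvalues_ = w[order]
        self.scores_ = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
        return self

    def transform(self, g=None) -> np.ndarray:
        return self.scores_


def compute_grm(g: GenotypeMatrix) -> np.ndarray:
    return GRMPCA(n_components=0).fit(g).grm_


def top_pcs(grm: np.ndarray, k: int = 5) -> np.ndarray:
    w, v = np.linalg.eigh(grm)
    order = np.argsort(w)[::-1][:k]
    return v[:, order] * np.sqrt(np.maximum(w[order], 0.0))


# --------------------------------------------------------------- concordance
def imputation_concordance(imputed: GenotypeMatrix, truth: GenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome imputation accuracy: genotypes counted correct only when
    the complete diploid genotype matches; comparison restricted to shared
    (chrom, pos) sites with non-missing truth."""
    if imputed.samples != truth.samples:
        raise ValueError("sample sets must match in order")
    key_i = pd.MultiIndex.from_frame(imputed.variants[["chrom", "pos"]])
    key_t = pd.MultiIndex.from_frame(truth.variants[["chrom", "pos"]])
    shared = key_i.intersection(key_t)
    if len(shared) == 0:
        raise ValueError("no shared variants between imputed and truth sets")
    ii = key_i.get_indexer(shared)
    ti = key_t.get_indexer(shared)
    di = imputed.dosage[:, ii]
    dt = truth.dosage[:, ti]
    valid = dt != MISSING
    correct = (di == dt) & valid
    chroms = imputed.variants["chrom"].to_numpy()[ii]
    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        n_cmp = int(valid[:, sel].sum())
        n_ok = int(correct[:, sel].sum())
        rows.append(
            {"chrom": chrom, "n_compared": n_cmp,
             "accuracy": n_ok / n_cmp if n_cmp else np.nan}
        )
    return pd.DataFrame(rows)
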