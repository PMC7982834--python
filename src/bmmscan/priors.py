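"""Biological prior classes for annotation-informed mixture-model GWAS.

Every SNP is assigned to exactly one class: A&S (differentially expressed in
both ligament and synovium), ACL (ligament only), SYN (synovium only), LIT
(literature candidate genes), or NA. A SNP belongs to a class if it lies
within a classed gene's body extended by a flank (default 25 kb, boundaries
inclusive on both sides). Overlap precedence is A&S > ACL > SYN > LIT — the
both-tissue class carries the least uncertainty — with ties within a class
resolved by the nearest gene. Gene symbols are matched case-insensitively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import CLASS_LABELS, GenotypeMatrix, PriorClassAssignment

log = logging.getLogger(__name__)

_PRECEDENCE = {c: i for i, c in enumerate(CLASS_LABELS)}  # A&S highest


def build_gene_classes(
    deg_acl: list[str], deg_syn: list[str], lit: list[str]
) -> dict[str, str]:
    """Map gene symbol (upper-cased) to prior class.

    Genes in both DEG lists are A&S; DEG membership takes precedence over the
    literature list (a both-listed gene keeps its expression-derived class).
    """
    acl = {g.upper() for g in deg_acl}
    syn = {g.upper() for g in deg_syn}
    lit_s = {g.upper() for g in lit}
    classes: dict[str, str] = {}
    for g in lit_s:
        classes[g] = "LIT"
    for g in acl | syn:
        if g in acl and g in syn:
            classes[g] = "A&S"
        elif g in acl:
            classes[g] = "ACL"
        else:
            classes[g] = "SYN"
    overlap = (acl | syn) & lit_s
    if overlap:
        log.info("%d gene(s) in both DEG and literature lists kept their DEG class", len(overlap))
    return classes


def _gene_arrays(annotation: pd.DataFrame, classes: dict[str, str]):
    ann = annotation.copy()
    ann["symbol"] = ann["gene"].str.upper()
    ann["class"] = ann["symbol"].map(classes)
    unmatched = ann["class"].isna() & ann["symbol"].notna()
    ann = ann[ann["class"].notna()]
    return ann, int(unmatched.sum())


def assign_snps(
    g: GenotypeMatrix,
    annotation: pd.DataFrame,
    classes: dict[str, str],
    flank_bp: int = 25_000,
) -> PriorClassAssignment:
    """Assign each variant to one prior class via gene-body +- flank overlap."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    m = g.n_variants
    snp_class = np.full(m, "NA", dtype=object)
    gene = np.full(m, "", dtype=object)
    distance = np.full(m, -1, dtype=np.int64)
    best_rank = np.full(m, len(CLASS_LABELS), dtype=np.int64)
    best_dist = np.full(m, np.iinfo(np.int64).max, dtype=np.int64)

    ann, n_unmatched = _gene_arrays(annotation, classes)
    chrom_col = g.variants["chrom"].to_numpy()
    pos_col = g.variants["pos"].to_numpy()
    for _, row in ann.iterrows():
        on = chrom_col == row["chrom"]
        lo, hi = row["start"] - flank_bp, row["end"] + flank_bp
        hit = np.flatnonzero(on & (pos_col >= lo) & (pos_col <= hi))
        if hit.size == 0:
            continue
        pos = pos_col[hit]
        dist = np.maximum(0, np.maximum(row["start"] - pos, pos - row["end"]))
        rank = _PRECEDENCE[row["class"]]
        better = (rank < best_rank[hit]) | ((rank == best_rank[hit]) & (dist < best_dist[hit]))
        upd = hit[better]
        snp_class[upd] = row["class"]
        gene[upd] = row["gene"]
        distance[upd] = dist[better]
        best_rank[upd] = rank
        best_dist[upd] = dist[better]
    return PriorClassAssignment(snp_class, gene, distance)


def effects_to_genes(
    effects: pd.DataFrame,
    annotation: pd.DataFrame,
    classes: dict[str, str] | None = None,
    flank_bp: int = 25_000,
    top_n: int = 50,
) -> pd.DataFrame:
    """Rank SNP effects by |effect| and attach the nearest gene within +-flank.

    ``effects`` needs columns chrom, pos, effect (and optionally class).
    Distance is 0 for SNPs inside the gene body. Ties in |effect| break by
    chromosome then position.
    """
    eff = effects.copy()
    eff["abs_effect"] = eff["effect"].abs()
    eff = eff.sort_values(
        ["abs_effect", "chrom", "pos"], ascending=[False, True, True]
    ).head(top_n)
    genes, dists = [], []
    ann = annotation
    for _, row in eff.iterrows():
        on = ann[ann["chrom"] == row["chrom"]]
        if len(on) == 0:
            genes.append(None)
            dists.append(None)
            continue
        d = np.maximum(0, np.maximum(on["start"] - row["pos"], row["pos"] - on["end"]))
        k = int(np.argmin(d.to_numpy()))
        if d.to_numpy()[k] <= flank_bp:
            genes.append(on["gene"].to_numpy()[k])
            dists.append(int(d.to_numpy()[k]))
        else:
            genes.append(None)
            dists.append(None)
    out = eff.drop(columns="abs_effect").reset_index(drop=True)
    out["gene"] = genes
    out["distance"] = dists
    out["locus"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    cols = ["locus"] + (["class"] if "class" in out.columns else []) + ["effect", "gene", "distance"]
    return out[cols]
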