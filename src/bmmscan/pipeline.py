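"""End-to-end orchestration: simulate -> QC -> PCA -> priors -> GWAS -> selection scan.

Every run writes a manifest (config snapshot, seeds, per-output SHA-256 digest
and row count); re-running with the same config reproduces every output
bit-for-bit because all randomness flows through recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import io as _io
from .bayesrc import build_model_data, run_bayesr_mode, run_replicates
from .config import SimConfig
from .priors import assign_snps, build_gene_classes, effects_to_genes
from .qc import GRMPCA, apply_qc
from .selection import classify_hits, haplotype_spans, xpehh_scan
from .simulate import simulate_cohort, write_cohort

DEFAULTS = {
    "flank_bp": 25_000,
    "qc": {"maf_min": 0.01, "callrate_min": 0.90, "hwe_alpha": 1e-7},
    "gwas": {"n_iter": 5_000, "burn_in": 2_500, "n_chains": 5, "seed": 0},
    "selscan": {"floor": 0.05, "candidate_p": 1e-5, "genomewide_p": 1e-8},
    "top_n": 50,
    "n_pcs": 5,
    "bayesr_mode": False,
}


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def overlap_report(
    gwas_top: pd.DataFrame, hits: pd.DataFrame, spans: dict[str, tuple[str, int, int]]
) -> pd.DataFrame:
    """Flag, per selection hit, whether any top GWAS SNP lies in its haplotype span.

    ``spans`` maps "chrom:pos" locus keys to (chrom, start, end) — the union of
    case/control, ancestral/derived spans.
    """
    if len(hits) == 0:
        return hits.assign(gwas_association=pd.Series(dtype=object))
    flags = []
    for _, hit in hits.iterrows():
        key = f"{hit['chrom']}:{hit['pos']}"
        chrom, lo, hi = spans[key]
        inside = (
            (gwas_top["chrom"] == chrom)
            & (gwas_top["pos"] >= lo)
            & (gwas_top["pos"] <= hi)
        )
        flags.append("Yes" if bool(inside.any()) else "No")
    out = hits.copy()
    out["gwas_association"] = flags
    return out


def run_pipeline(config: dict | None = None, out_dir: str = "bmmscan_run", stages=None) -> dict:
    """Run the full synthetic-cohort analysis; returns the manifest dict."""
    cfg = {**DEFAULTS, **(config or {})}
    for key in ("qc", "gwas", "selscan"):
        cfg[key] = {**DEFAULTS[key], **cfg.get(key, {})}
    os.makedirs(out_dir, exist_ok=True)
    stages = set(stages or ["simulate", "qc", "priors", "gwas", "selscan", "report"])
    from . import __version__

    manifest: dict = {"config": json.loads(json.dumps(cfg, default=str)),
                      "version": __version__, "outputs": {}}

    def record(name: str, path: str, rows: int) -> None:
        manifest["outputs"][name] = {"path": path, "sha256": _digest(path), "rows": rows}

    sim = SimConfig(**cfg.get("sim", {}))
    manifest["seeds"] = {"sim": sim.seed, "gwas": cfg["gwas"]["seed"]}

    panel, genotypes, covariates, truth, genes, gene_lists, _ = simulate_cohort(
        sim, flank_bp=cfg["flank_bp"]
    )
    if "simulate" in stages:
        paths = write_cohort(out_dir, panel, genotypes, covariates, genes, gene_lists)
        record("vcf", paths["vcf"], panel.n_variants)
        record("covariates", paths["covariates"], len(covariates))
        record("annotation", paths["annotation"], len(genes))

    qc_g, report = apply_qc(genotypes, **cfg["qc"])
    report.to_frame().to_csv(os.path.join(out_dir, "qc_report.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "qc_report.json"), "w") as fh:
        json.dump({"removed": report.removed, "n_input": report.n_input,
                   "n_output": report.n_output, "thresholds": report.thresholds}, fh, indent=1)
    record("qc_report", os.path.join(out_dir, "qc_report.tsv"), len(report.removed))

    pca = GRMPCA(n_components=cfg["n_pcs"]).fit(qc_g)
    pcs = pca.scores_

    classes = build_gene_classes(gene_lists["deg_acl"], gene_lists["deg_syn"], gene_lists["lit"])
    assignment = assign_snps(qc_g, genes, classes, flank_bp=cfg["flank_bp"])
    counts = assignment.counts()
    counts.to_csv(os.path.join(out_dir, "class_counts.tsv"), sep="\t", index=False)
    record("class_counts", os.path.join(out_dir, "class_counts.tsv"), len(counts))

    use_priors = "priors" in stages
    data = build_model_data(
        qc_g, covariates, pcs, assignment if use_priors else None
    )
    g = cfg["gwas"]
    posterior = run_replicates(
        data, n_chains=g["n_chains"], n_iter=g["n_iter"], burn_in=g["burn_in"], seed=g["seed"]
    ) if use_priors else run_bayesr_mode(
        data, n_chains=g["n_chains"], n_iter=g["n_iter"], burn_in=g["burn_in"], seed=g["seed"]
    )
    eff = posterior.to_frame(qc_g.variants, assignment.snp_class if use_priors else None)
    eff.to_csv(os.path.join(out_dir, "snp_effects.tsv"), sep="\t", index=False)
    record("snp_effects", os.path.join(out_dir, "snp_effects.tsv"), len(eff))
    top = effects_to_genes(eff, genes, flank_bp=cfg["flank_bp"], top_n=cfg["top_n"])
    top.to_csv(os.path.join(out_dir, "top_effects.tsv"), sep="\t", index=False)
    record("top_effects", os.path.join(out_dir, "top_effects.tsv"), len(top))

    hits = pd.DataFrame()
    spans: dict[str, tuple[str, int, int]] = {}
    if "selscan" in stages:
        case_mask = covariates["case"].to_numpy() == 1
        keep = np.flatnonzero(case_mask)
        drop = np.flatnonzero(~case_mask)
        case_panel = panel.subset_samples(keep)
        ctrl_panel = panel.subset_samples(drop)
        s = cfg["selscan"]
        scan = xpehh_scan(case_panel, ctrl_panel, floor=s["floor"],
                          candidate_p=s["candidate_p"], genomewide_p=s["genomewide_p"])
        scan.to_csv(os.path.join(out_dir, "xpehh_scan.tsv"), sep="\t", index=False)
        record("xpehh_scan", os.path.join(out_dir, "xpehh_scan.tsv"), len(scan))
        hits = classify_hits(scan, s["candidate_p"], s["genomewide_p"])
        for _, hit in hits.iterrows():
            core = int(
                np.flatnonzero(
                    (panel.variants["chrom"] == hit["chrom"])
                    & (panel.variants["pos"] == hit["pos"])
                )[0]
            )
            sp = haplotype_spans(case_panel, ctrl_panel, core, threshold=s["floor"])
            lo = int(np.nanmin(sp["start"])) if sp["start"].notna().any() else int(hit["pos"])
            hi = int(np.nanmax(sp["end"])) if sp["end"].notna().any() else int(hit["pos"])
            spans[f"{hit['chrom']}:{hit['pos']}"] = (hit["chrom"], lo, hi)

    if "report" in stages and len(hits):
        gwas_top = eff.reindex(eff["effect"].abs().sort_values(ascending=False).index).head(
            cfg["top_n"]
        )
        overlap = overlap_report(gwas_top, hits, spans)
        overlap.to_csv(os.path.join(out_dir, "selection_hits.tsv"), sep="\t", index=False)
        record("selection_hits", os.path.join(out_dir, "selection_hits.tsv"), len(overlap))

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
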