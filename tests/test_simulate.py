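"""Synthetic cohort generator: LD structure, mixture effects, sweep injection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, pearsonr

import bmmscan as bm
from bmmscan.config import GAMMA


def test_haplotype_panel_deterministic():
    cfg = bm.SimConfig(n_samples=40, n_snps=400, n_chroms=2, seed=9)
    a = bm.simulate_haplotypes(cfg)
    b = bm.simulate_haplotypes(cfg)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert a.variants.equals(b.variants)
    assert np.array_equal(a.ancestral, b.ancestral)


def test_single_founder_no_recomb_gives_identical_haplotypes():
    cfg = bm.SimConfig(n_samples=20, n_snps=100, n_chroms=1, n_founders=1,
                       recomb_between_blocks=0.0, maf_range=(0.05, 0.5), seed=0)
    panel = bm.simulate_haplotypes(cfg)
    assert (panel.haplotypes == panel.haplotypes[0]).all()


def test_allele_frequencies_within_configured_range():
    cfg = bm.SimConfig(n_samples=500, n_snps=2000, n_chroms=2, seed=3)
    panel = bm.simulate_haplotypes(cfg)
    p = panel.haplotypes.mean(axis=0)
    maf = np.minimum(p, 1 - p)
    lo, hi = cfg.maf_range
    # sampling noise around the founder frequencies allows a small overshoot
    assert np.mean((maf >= lo - 0.03) & (maf <= hi)) >= 0.95


def test_ld_higher_within_blocks_than_between():
    cfg = bm.SimConfig(n_samples=500, n_snps=10_000, n_chroms=2, seed=5)
    panel = bm.simulate_haplotypes(cfg)
    dos = panel.to_genotypes().dosage.astype(float)
    block = max(1, int(cfg.block_len_kb * 1000 / cfg.snp_spacing_bp))
    rng = np.random.default_rng(0)
    within, between = [], []
    for _ in range(300):
        b = rng.integers(0, cfg.n_snps // block - 2)
        j0 = b * block
        r_w = pearsonr(dos[:, j0], dos[:, j0 + block // 2])[0] ** 2
        r_b = pearsonr(dos[:, j0], dos[:, j0 + 3 * block])[0] ** 2
        within.append(r_w)
        between.append(r_b)
    assert np.mean(within) > np.mean(between)


def test_snp_remainder_goes_to_last_chromosome():
    cfg = bm.SimConfig(n_samples=10, n_snps=103, n_chroms=4, seed=0)
    counts = cfg.snps_per_chrom()
    assert counts == [25, 25, 25, 28]
    panel = bm.simulate_haplotypes(cfg)
    assert (panel.variants["chrom"] == "chr4").sum() == 28


def test_null_model_all_effects_zero():
    cfg = bm.SimConfig(
        n_samples=100, n_snps=300, n_chroms=1, seed=2,
        effect_mixture={"NA": (1.0, 0.0, 0.0, 0.0)}, class_fractions={},
    )
    panel = bm.simulate_haplotypes(cfg)
    with pytest.warns(UserWarning, match="h2 = 0"):
        _, cov, truth = bm.simulate_phenotypes(panel, cfg)
    assert np.all(truth.effect == 0.0)
    assert np.all(truth.component == 0)
    assert np.all(truth.genetic_value == 0.0)


def test_component_zero_snps_have_exactly_zero_effect(small_cohort):
    truth = small_cohort["truth"]
    assert np.all(truth.effect[truth.component == 0] == 0.0)
    assert np.all(truth.effect[truth.component > 0] != 0.0)


def test_realized_prevalence_near_configured():
    cfg = bm.SimConfig(n_samples=400, n_snps=1000, n_chroms=2, seed=8)
    panel = bm.simulate_haplotypes(cfg)
    _, cov, _ = bm.simulate_phenotypes(panel, cfg)
    assert abs(cov["case"].mean() - cfg.prevalence) <= 0.05


def test_forced_component3_snp_is_strongest_association():
    cfg = bm.SimConfig(n_samples=2000, n_snps=2000, n_chroms=2, seed=4,
                       force_component={777: 3})
    panel = bm.simulate_haplotypes(cfg)
    genotypes, cov, truth = bm.simulate_phenotypes(panel, cfg)
    assert truth.component[777] == 3
    assert abs(truth.effect[777]) == pytest.approx(np.sqrt(GAMMA[3] * cfg.sigma_g2))
    y = cov["case"].to_numpy(dtype=float)
    dos = genotypes.dosage.astype(float)
    ys = (y - y.mean()) / y.std()
    ds = (dos - dos.mean(0)) / dos.std(0)
    corr = np.abs(ds.T @ ys / len(y))
    # strongest point-biserial correlation lies in the forced SNP's LD block
    block = int(cfg.block_len_kb * 1000 / cfg.snp_spacing_bp)
    assert abs(int(np.argmax(corr)) - 777) <= block


def test_h2_controls_liability_regression_r2():
    cfg = bm.SimConfig(n_samples=2000, n_snps=2000, n_chroms=2, seed=6, h2=0.5,
                       covariate_effects={})
    panel = bm.simulate_haplotypes(cfg)
    _, _, truth = bm.simulate_phenotypes(panel, cfg)
    r2 = pearsonr(truth.liability, truth.genetic_value)[0] ** 2
    assert r2 == pytest.approx(0.5, abs=0.05)
    assert truth.h2_realized == pytest.approx(0.5, abs=1e-9)


def test_class_component_frequencies_match_configuration():
    cfg = bm.SimConfig(n_samples=30, n_snps=50_000, n_chroms=5, seed=7)
    panel = bm.simulate_haplotypes(cfg)
    genes, lists = bm.simulate_annotation(cfg, panel.variants)
    classes = bm.build_gene_classes(lists["deg_acl"], lists["deg_syn"], lists["lit"])
    assignment = bm.assign_snps(panel.to_genotypes(), genes, classes)
    _, _, truth = bm.simulate_phenotypes(panel, cfg, assignment.snp_class)
    for cls, probs in cfg.effect_mixture.items():
        idx = assignment.snp_class == cls
        if idx.sum() < 1000:
            continue
        observed = np.bincount(truth.component[idx], minlength=4)
        expected = np.asarray(probs) * idx.sum()
        keep = expected >= 5
        stat, p = chisquare(
            np.append(observed[keep], observed[~keep].sum()),
            np.append(expected[keep], expected[~keep].sum()),
        )
        assert p > 0.01, f"class {cls}: component frequencies off ({p=})"


class TestInjectSweep:
    def _cfg(self, case_freq, span_kb=200.0, pos=500_000):
        return bm.SimConfig(n_samples=80, n_snps=1000, n_chroms=1, seed=11,
                            sweep=bm.SweepConfig("chr1", pos, case_freq, span_kb))

    def test_full_fixation_makes_case_haplotypes_identical_in_span(self):
        cfg = self._cfg(1.0)
        panel = bm.simulate_haplotypes(cfg)
        cases = panel.samples[:40]
        swept = bm.inject_sweep(panel, cases, cfg)
        v = swept.variants
        span = (v["pos"] >= 400_000) & (v["pos"] <= 600_000)
        case_haps = swept.haplotypes[: 2 * 40, span.to_numpy()]
        assert (case_haps == case_haps[0]).all()
        # EHH of the shared core allele is 1 across the span
        core = int(np.argmin(np.abs(v["pos"].to_numpy() - 500_000)))
        sub = swept.subset_samples(np.arange(40))
        curve = bm.ehh(sub, core, int(swept.haplotypes[0, core]))
        inside = (curve.positions >= 400_000) & (curve.positions <= 600_000)
        assert np.all(curve.ehh[inside] == 1.0)

    def test_target_below_existing_frequency_is_noop(self):
        cfg = self._cfg(0.0)
        panel = bm.simulate_haplotypes(cfg)
        swept = bm.inject_sweep(panel, panel.samples[:40], cfg)
        assert np.array_equal(swept.haplotypes, panel.haplotypes)

    def test_span_outside_chromosome_errors_with_length(self):
        cfg = self._cfg(0.9, span_kb=400.0, pos=950_000)
        panel = bm.simulate_haplotypes(cfg)
        with pytest.raises(ValueError, match="length"):
            bm.inject_sweep(panel, panel.samples[:40], cfg)

    def test_span_with_too_few_snps_errors(self):
        cfg = self._cfg(0.9, span_kb=5.0)
        panel = bm.simulate_haplotypes(cfg)
        with pytest.raises(ValueError, match="SNPs"):
            bm.inject_sweep(panel, panel.samples[:40], cfg)

    def test_reaches_target_frequency(self):
        cfg = self._cfg(0.8)
        panel = bm.simulate_haplotypes(cfg)
        cases = panel.samples[:40]
        swept = bm.inject_sweep(panel, cases, cfg)
        v = swept.variants
        span = ((v["pos"] >= 400_000) & (v["pos"] <= 600_000)).to_numpy()
        case_haps = swept.haplotypes[: 2 * 40][:, span]
        donor = case_haps[0]
        freq = (case_haps == donor).all(axis=1).mean()
        assert freq >= 0.8


class TestCohortFiles:
    def test_vcf_round_trip_and_phase_bars(self, small_cohort, tmp_path):
        panel = small_cohort["panel"]
        path = str(tmp_path / "c.vcf")
        bm.io.write_vcf(path, panel)
        body = [l for l in open(path) if not l.startswith("#")]
        assert all("|" in l.split("\t", 9)[-1] and "/" not in l.split("\t", 9)[-1] for l in body)
        back = bm.io.read_vcf_haplotypes(path)
        assert np.array_equal(back.haplotypes, panel.haplotypes)
        assert np.array_equal(back.ancestral, panel.ancestral)
        g = bm.io.read_vcf(path)
        assert np.array_equal(g.dosage, panel.to_genotypes().dosage)

    def test_plink_round_trip(self, small_cohort, tmp_path):
        g = small_cohort["genotypes"]
        prefix = str(tmp_path / "c")
        bm.io.write_plink(prefix, g, small_cohort["covariates"]["case"].to_numpy())
        back = bm.io.read_plink(prefix)
        assert back.samples == g.samples
        assert np.array_equal(back.dosage, g.dosage)

    def test_bed_round_trip_restores_1based_inclusive_bounds(self, small_cohort, tmp_path):
        genes = small_cohort["genes"]
        path = str(tmp_path / "genes.bed")
        bm.io.write_bed(path, genes)
        first = open(path).readline().split("\t")
        assert int(first[1]) == genes["start"].iloc[0] - 1  # 0-based half-open on disk
        back = bm.io.read_bed(path)
        pd.testing.assert_frame_equal(
            back[["gene", "chrom", "start", "end"]],
            genes[["gene", "chrom", "start", "end"]],
        )

    def test_haplotype_tsv_round_trip(self, small_cohort, tmp_path):
        panel = small_cohort["panel"]
        path = str(tmp_path / "haps.tsv")
        bm.io.write_haplotype_tsv(path, panel)
        back = bm.io.read_haplotype_tsv(path)
        assert back.samples == panel.samples
        assert np.array_equal(back.haplotypes, panel.haplotypes)
        assert np.array_equal(back.ancestral, panel.ancestral)

    def test_write_cohort_round_trips_through_readers(self, small_cohort, tmp_path):
        paths = bm.write_cohort(
            str(tmp_path), small_cohort["panel"], small_cohort["genotypes"],
            small_cohort["covariates"], small_cohort["genes"], small_cohort["lists"],
        )
        g = bm.io.read_vcf(paths["vcf"])
        assert np.array_equal(g.dosage, small_cohort["genotypes"].dosage)
        cov = bm.io.read_covariates(paths["covariates"])
        pd.testing.assert_frame_equal(cov, small_cohort["covariates"])
        assert bm.io.read_gene_list(paths["deg_acl"]) == small_cohort["lists"]["deg_acl"]
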