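"""Tests of SNP-effect back-solving, windows, QTL selection and gene lookup."""

import numpy as np
import pandas as pd
import pytest

import boargp as bg
from boargp.gwas import WindowTable
from boargp.mixedmodel import BlupSolution, build_design

from conftest import qtl_window_frames, small_config


def fake_solution(animal_ids, u, vc, blend=0.0, kind="genomic_G"):
    q = len(u)
    return BlupSolution(
        animal_ids=np.asarray(animal_ids, dtype=object),
        mu_hat=0.0,
        day_levels=np.array([]),
        day_blups=np.array([]),
        u_hat=np.asarray(u, dtype=float),
        pev=np.zeros(q),
        reliability=np.ones(q),
        pev_matrix=np.zeros((q, q)),
        kind=kind,
        blend_weight=blend,
        vc=vc,
    )


class TestBacksolve:
    def test_zero_gebv_zero_effects(self, fullrank_gblup):
        f = fullrank_gblup
        sol0 = fake_solution(f["geno"].animal_ids, np.zeros(f["G"].n_animals),
                             f["vc"])
        eff = bg.backsolve_snp_effects(sol0, f["geno"], f["G"])
        assert np.allclose(eff["g_hat"], 0.0)

    def test_z_g_reconstructs_gebv(self, fullrank_gblup):
        f = fullrank_gblup
        eff = bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"])
        recon = f["Z"] @ eff["g_hat"].to_numpy()
        assert np.max(np.abs(recon - f["sol"].u_hat)) < 1e-6

    def test_equals_ridge_snp_blup(self):
        # direct ridge-regression SNP-BLUP with shrinkage d * lambda_a
        # more markers than animals so the supplied-frequency G is full rank
        cfg = small_config(n_founders=20, n_generations=0, n_snps=30,
                           n_chromosomes=2, n_qtl=5, seed=13)
        ped = bg.simulate_pedigree(cfg)
        geno, _ = bg.simulate_genotypes(ped, cfg)
        pheno, truth = bg.simulate_phenotypes(geno, cfg)
        p = 0.9 * bg.compute_maf(geno)["p"].to_numpy() + 0.05
        G = bg.build_G(geno, freq_source="supplied", freqs=p)
        spec = bg.ModelSpec(trait="and_log", include_day=False)
        vc = bg.VarianceComponents(*truth.true_variance_components)
        sol = bg.solve_blup(pheno, spec, G, vc, blend_weight=0.0)
        eff = bg.backsolve_snp_effects(sol, geno, G)

        y, _, W, _, _ = build_design(pheno, spec, G)
        Z = geno.gene_content - 2.0 * p
        Zr = W @ Z
        d = G.scale_denominator
        lam = vc.sigma2_e / (vc.sigma2_a / d)
        M = np.concatenate([np.ones((len(y), 1)), Zr], axis=1)
        LHS = M.T @ M
        LHS[1:, 1:] += lam * np.eye(Z.shape[1])
        g_ridge = np.linalg.solve(LHS, M.T @ y)[1:]
        assert np.max(np.abs(eff["g_hat"].to_numpy() - g_ridge)) < 1e-6

    def test_mismatched_animals_rejected(self, fullrank_gblup):
        f = fullrank_gblup
        bad = fake_solution([f"zz{i}" for i in range(f["G"].n_animals)],
                            np.zeros(f["G"].n_animals), f["vc"])
        with pytest.raises(ValueError, match="animal"):
            bg.backsolve_snp_effects(bad, f["geno"], f["G"])


class TestPvalues:
    @pytest.fixture()
    def completed(self, fullrank_gblup):
        f = fullrank_gblup
        eff = bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"])
        return bg.snp_pvalues(eff, f["sol"], f["geno"], f["G"])

    def test_table_contract(self, completed):
        assert ((completed["p_value"] > 0) & (completed["p_value"] <= 1)).all()
        assert np.allclose(completed["neg_log10_p"],
                           -np.log10(completed["p_value"]))
        assert (completed["sd_g_hat"] > 0).all()

    def test_zero_effect_p_one(self, fullrank_gblup):
        f = fullrank_gblup
        eff = bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"])
        eff.loc[0, "g_hat"] = 0.0
        out = bg.snp_pvalues(eff, f["sol"], f["geno"], f["G"])
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_phenotype_rescaling(self, fullrank_gblup):
        f = fullrank_gblup
        eff1 = bg.snp_pvalues(
            bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"]),
            f["sol"], f["geno"], f["G"])
        ph2 = f["pheno"].copy()
        ph2["and_log"] = 3.0 * ph2["and_log"]
        vc2 = bg.VarianceComponents(9 * f["vc"].sigma2_a, 9 * f["vc"].sigma2_day,
                                    9 * f["vc"].sigma2_e)
        sol2 = bg.solve_blup(ph2, f["spec"], f["G"], vc2, blend_weight=0.0)
        eff2 = bg.snp_pvalues(
            bg.backsolve_snp_effects(sol2, f["geno"], f["G"]),
            sol2, f["geno"], f["G"])
        assert np.allclose(eff1["p_value"], eff2["p_value"], atol=1e-8)


class TestBonferroni:
    def test_published_snp_count(self):
        assert bg.bonferroni_threshold(29844).neg_log10_display == 5.78

    def test_small_counts(self):
        assert bg.bonferroni_threshold(1).neg_log10_display == pytest.approx(1.30)
        assert bg.bonferroni_threshold(100).neg_log10_display == pytest.approx(3.30)

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            bg.bonferroni_threshold(0)


class TestWindows:
    def test_simple_geometry(self):
        snp_map = pd.DataFrame({
            "snp_id": ["s1", "s2", "s3"],
            "chrom": ["1", "1", "1"],
            "pos": [100_000, 300_000, 600_000],
        })
        wt = bg.make_windows(snp_map)
        assert len(wt.table) == 2
        assert wt.table["n_snps"].tolist() == [2, 1]
        assert wt.table["start_bp"].tolist() == [100_000, 500_000]
        assert np.array_equal(wt.assignment, [0, 0, 1])

    def test_snp_conservation(self, small_dataset):
        wt = bg.make_windows(small_dataset["map"])
        assert wt.table["n_snps"].sum() == small_dataset["geno"].n_snps
        assert len(np.unique(wt.assignment)) == len(wt.table)

    def test_unsorted_map_rejected(self):
        snp_map = pd.DataFrame({"snp_id": ["a", "b"], "chrom": ["1", "1"],
                                "pos": [500, 100]})
        with pytest.raises(ValueError, match="unsorted"):
            bg.make_windows(snp_map)

    def test_chip_density_window_count_matches_study_scale(self):
        # 29,844 SNPs on 18 x 90 Mb chromosomes tile into ~4040 windows
        cfg = small_config(n_founders=10, n_generations=0, n_chromosomes=18,
                           n_snps=29_844, chrom_length_bp=90_000_000, seed=2)
        ped = bg.simulate_pedigree(cfg)
        _, snp_map = bg.simulate_genotypes(ped, cfg)
        wt = bg.make_windows(snp_map)
        n = len(wt.table)
        coverage = 18 * 90_000_000 / 400_000
        assert abs(n - coverage) / coverage < 0.10
        assert abs(n - 4040) / 4040 < 0.10


class TestWindowVariance:
    def test_zero_effects_zero_percent(self, fullrank_gblup):
        f = fullrank_gblup
        eff = pd.DataFrame({"snp_id": f["geno"].snp_ids,
                            "g_hat": np.zeros(f["geno"].n_snps)})
        wt = bg.make_windows(f["map"])
        out = bg.window_variance(f["geno"], eff, wt, f["sol"], f["G"])
        assert np.allclose(out.table["pct_variance"], 0.0)

    def test_single_window_explains_everything(self, fullrank_gblup):
        f = fullrank_gblup
        eff = bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"])
        m = f["geno"].n_snps
        one = WindowTable(
            pd.DataFrame([{"window_id": "all", "chrom": "1", "start_bp": 0,
                           "end_bp": 10**9, "n_snps": m}]),
            np.zeros(m, dtype=np.intp), 10**9)
        out = bg.window_variance(f["geno"], eff, one, f["sol"], f["G"])
        assert out.table["pct_variance"].iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_linkage_equilibrium_additivity(self):
        # unlinked founder genotypes with many more animals than markers, so
        # finite-sample LD noise is small: window percentages sum to ~100.
        # Effects are taken as known so the property is about the window
        # bookkeeping itself, not the solver.
        cfg = small_config(n_founders=800, n_generations=0, n_snps=100,
                           n_qtl=50, seed=17)
        ped = bg.simulate_pedigree(cfg)
        geno, snp_map = bg.simulate_genotypes(ped, cfg)
        G = bg.build_G(geno)
        rng = np.random.default_rng(17)
        g = rng.normal(size=geno.n_snps)
        eff = pd.DataFrame({"snp_id": geno.snp_ids, "g_hat": g})
        Z = geno.gene_content - 2.0 * G.freqs
        vc = bg.VarianceComponents(1.0, 0.0, 1.0)
        sol = fake_solution(geno.animal_ids, Z @ g, vc)
        wt = bg.window_variance(geno, eff, bg.make_windows(snp_map), sol, G)
        assert wt.table["pct_variance"].sum() == pytest.approx(100.0, abs=5.0)


class TestQtlSelection:
    def test_published_regions_merge_to_eighteen(self):
        frames = qtl_window_frames()
        regions = bg.select_qtl(frames, threshold_pct=0.5)
        assert len(regions) == 18
        shared = [r for r in regions if len(r.traits) > 1]
        assert len(shared) == 4
        sums = {t: frames[t]["pct_variance"].sum() for t in frames}
        assert sums["and"] == pytest.approx(5.25)
        assert sums["ind"] == pytest.approx(5.50)
        assert sums["ska"] == pytest.approx(3.76)

    def test_threshold_is_inclusive(self):
        df = pd.DataFrame({"chrom": ["1", "1"], "start_bp": [0, 10**6],
                           "end_bp": [4 * 10**5, 14 * 10**5],
                           "pct_variance": [0.50, 0.49]})
        regions = bg.select_qtl({"t": df}, threshold_pct=0.5)
        assert len(regions) == 1
        assert regions[0].members["pct_variance"].iloc[0] == 0.50

    def test_no_window_above_threshold(self):
        df = pd.DataFrame({"chrom": ["1"], "start_bp": [0], "end_bp": [10],
                           "pct_variance": [0.1]})
        assert bg.select_qtl({"t": df}) == []

    def test_shared_with_bookkeeping(self):
        frames = qtl_window_frames()
        regions = bg.select_qtl(frames)
        ssc6 = [r for r in regions if r.chromosome == "6"]
        assert len(ssc6) == 2
        for r in ssc6:
            assert set(r.traits) == {"and", "ind"}
            assert r.shared_with["and"] == ("ind",)


class TestExpectedContribution:
    def test_study_scale_windows(self):
        expected, multiple = bg.expected_window_contribution(4040)
        assert round(expected, 3) == 0.025
        # the published derivation uses the rounded expectation
        assert 0.5 / round(expected, 3) == pytest.approx(20.0)
        assert multiple == pytest.approx(20.2)

    def test_simple_value(self):
        expected, multiple = bg.expected_window_contribution(100, threshold_pct=0.5)
        assert expected == pytest.approx(1.0)
        assert multiple == pytest.approx(0.5)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            bg.expected_window_contribution(0)


def toy_regions():
    df = pd.DataFrame({"chrom": ["1"], "start_bp": [900_000],
                       "end_bp": [1_300_000], "pct_variance": [0.9],
                       "lead_snp_bp": [1_000_000], "lead_snp": ["s1"]})
    return bg.select_qtl({"t": df})


class TestCandidateGenes:
    def annotation(self):
        return pd.DataFrame({
            "gene_id": ["g_in1", "g_in2", "g_boundary", "g_far", "g_otherchrom"],
            "symbol": ["G1", "G2", "GB", "GF", "GO"],
            "chrom": ["1", "1", "1", "1", "1"],
            "start_bp": [950_000, 1_150_000, 1_200_000, 2_000_000, 5_000_000],
            "end_bp": [960_000, 1_160_000, 1_250_000, 2_100_000, 5_100_000],
        })

    def test_empty_annotation_no_hits(self):
        hits = bg.candidate_genes(toy_regions(), self.annotation().iloc[0:0])
        assert len(hits) == 0

    def test_boundary_gene_included(self):
        # gene starting exactly at lead + flank is inside the closed interval
        ann = pd.DataFrame({"gene_id": ["edge"], "symbol": ["E"], "chrom": ["1"],
                            "start_bp": [1_200_000], "end_bp": [1_400_000]})
        hits = bg.candidate_genes(toy_regions(), ann, flank_bp=200_000)
        assert hits["gene_id"].tolist() == ["edge"]

    def test_brute_force_interval_scan(self):
        ann = self.annotation()
        hits = bg.candidate_genes(toy_regions(), ann, flank_bp=200_000)
        lead, flank = 1_000_000, 200_000
        expect = ann.loc[(ann["start_bp"] <= lead + flank)
                         & (ann["end_bp"] >= lead - flank), "gene_id"]
        assert sorted(hits["gene_id"]) == sorted(expect)
        # ordered by distance to the lead SNP
        assert hits["distance_bp"].is_monotonic_increasing

    def test_chromosome_mismatch_rejected(self):
        ann = self.annotation().assign(chrom="chr1")
        with pytest.raises(ValueError, match="chr|label"):
            bg.candidate_genes(toy_regions(), ann)

    def test_bed_dialect_converts_coordinates(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("1\t949999\t960000\tg_in1\n")
        ann = bg.read_gene_annotation(p, dialect="bed")
        assert ann["start_bp"].iloc[0] == 950_000
        assert ann["end_bp"].iloc[0] == 960_000


class TestManhattanExport:
    def test_rows_coordinates_and_metadata(self, tmp_path, fullrank_gblup):
        f = fullrank_gblup
        eff = bg.snp_pvalues(
            bg.backsolve_snp_effects(f["sol"], f["geno"], f["G"]),
            f["sol"], f["geno"], f["G"])
        thr = bg.bonferroni_threshold(f["geno"].n_snps)
        out = tmp_path / "man.tsv"
        df = bg.export_manhattan(eff, f["map"], thr, path=out)
        assert len(df) == f["geno"].n_snps
        assert np.all(np.diff(df["cum_bp"]) > 0)
        header = out.read_text().splitlines()[0]
        assert f"neg_log10={thr.neg_log10_display}" in header
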