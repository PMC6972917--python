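import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pescore import scoring
from pescore.genesets import CandidatePathway
from pescore.simulate import preset, simulate_study

from conftest import make_genotypes


def _sumstats_for(gm, pvals=None, betas=None, rng=None):
    rng = rng or np.random.default_rng(0)
    m = gm.n_variants
    return pd.DataFrame({
        "snp_id": gm.variants["snp_id"], "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"],
        "effect_allele": gm.variants["counted_allele"],
        "other_allele": gm.variants["other_allele"],
        "beta": betas if betas is not None else rng.normal(size=m),
        "pvalue": pvals if pvals is not None else rng.uniform(0.001, 1, m),
    })


def _correlated_genotypes(n=300, m=200, rho=0.9, seed=0, spacing=1000):
    """AR(1)-correlated hard calls with known positions."""
    rng = np.random.default_rng(seed)
    gm = make_genotypes(n=n, m=m, seed=seed)
    latent = np.empty((2, n, m))
    for h in range(2):
        eps = rng.standard_normal((n, m))
        latent[h, :, 0] = eps[:, 0]
        for t in range(1, m):
            latent[h, :, t] = rho * latent[h, :, t - 1] + np.sqrt(1 - rho ** 2) * eps[:, t]
    gm.dosages = ((latent[0] > 0).astype(float) + (latent[1] > 0).astype(float))
    gm.variants["pos"] = np.arange(1, m + 1) * spacing
    return gm


class TestLdClump:
    def test_stronger_snp_dominates_linked_neighbour(self):
        gm = _correlated_genotypes(n=500, m=2, rho=0.95, spacing=10_000)
        ss = _sumstats_for(gm, pvals=[1e-8, 1e-4])
        kept = scoring.ld_clump(ss, gm, r2=0.1, window_kb=250)
        assert kept == [gm.variants["snp_id"].iloc[0]]

    def test_linked_pair_outside_window_both_retained(self):
        gm = _correlated_genotypes(n=500, m=2, rho=0.99, spacing=300_000)
        ss = _sumstats_for(gm, pvals=[1e-8, 1e-4])
        kept = scoring.ld_clump(ss, gm, r2=0.1, window_kb=250)
        assert len(kept) == 2

    def test_postconditions_on_ar1_fixture(self):
        gm = _correlated_genotypes(n=400, m=200, rho=0.8, seed=3)
        ss = _sumstats_for(gm, rng=np.random.default_rng(4))
        kept = scoring.ld_clump(ss, gm, r2=0.1, window_kb=50)
        keep_set = set(kept)
        dos = gm.mean_imputed()
        r = np.corrcoef(dos, rowvar=False)
        ids = list(gm.variants["snp_id"])
        pos = gm.variants.set_index("snp_id")["pos"]
        pv = ss.set_index("snp_id")["pvalue"]
        window = 50 * 1000
        # no retained pair may violate the clumping rule
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j and a in keep_set and b in keep_set:
                    if abs(pos[a] - pos[b]) <= window:
                        assert r[i, j] ** 2 <= 0.1 + 1e-12
        # every removed SNP is linked to a retained, more significant index SNP
        for j, b in enumerate(ids):
            if b in keep_set:
                continue
            assert any(
                a in keep_set and abs(pos[a] - pos[b]) <= window
                and r[ids.index(a), j] ** 2 > 0.1
                and (pv[a], a) < (pv[b], b)
                for a in ids
            )

    def test_retained_set_invariant_to_row_order(self):
        gm = _correlated_genotypes(n=300, m=80, rho=0.8, seed=5)
        ss = _sumstats_for(gm, rng=np.random.default_rng(6))
        a = scoring.ld_clump(ss, gm, r2=0.1, window_kb=50)
        b = scoring.ld_clump(ss.sample(frac=1, random_state=7), gm, r2=0.1, window_kb=50)
        assert a == b


class TestComputeScore:
    def test_zero_dosages_give_zero_scores(self):
        gm = make_genotypes(n=5, m=3, seed=1)
        gm.dosages[:] = 0.0
        defn = scoring.ScoreDefinition("s", list(gm.variants["snp_id"]),
                                       np.array([0.5, -0.2, 1.0]), 1.0)
        assert np.allclose(scoring.compute_score(defn, gm), 0.0)

    def test_single_snp_score_is_beta_times_dosage(self):
        gm = make_genotypes(n=1, m=1, seed=2)
        gm.dosages[0, 0] = 2.0
        defn = scoring.ScoreDefinition("s", ["snp000"], np.array([np.log(2)]), 1.0)
        assert scoring.compute_score(defn, gm)[0] == pytest.approx(2 * np.log(2))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(8)
        gm = make_genotypes(n=50, m=200, seed=8)
        betas = rng.normal(size=200)
        defn = scoring.ScoreDefinition("s", list(gm.variants["snp_id"]), betas, 1.0)
        score = scoring.compute_score(defn, gm)
        for i in range(50):
            expect = sum(betas[j] * gm.dosages[i, j] for j in range(200))
            assert abs(score[i] - expect) < 1e-12

    def test_linear_in_dosages_and_order_invariant(self):
        rng = np.random.default_rng(9)
        gm = make_genotypes(n=20, m=30, seed=9)
        betas = rng.normal(size=30)
        ids = list(gm.variants["snp_id"])
        defn = scoring.ScoreDefinition("s", ids, betas, 1.0)
        perm = rng.permutation(30)
        defn_p = scoring.ScoreDefinition("s", [ids[k] for k in perm], betas[perm], 1.0)
        np.testing.assert_allclose(scoring.compute_score(defn, gm),
                                   scoring.compute_score(defn_p, gm), atol=1e-12)
        gm2 = make_genotypes(n=20, m=30, seed=10)
        gm_sum = make_genotypes(n=20, m=30, seed=9)
        gm_sum.dosages = np.clip(gm.dosages + gm2.dosages, 0, 2)
        # linearity on the raw sum (use unclipped arithmetic directly)
        s = scoring.compute_score(defn, gm) + scoring.compute_score(defn, gm2)
        expect = (gm.dosages + gm2.dosages) @ betas
        np.testing.assert_allclose(s, expect, atol=1e-10)

    def test_no_overlap_raises(self):
        gm = make_genotypes(n=5, m=3, seed=11)
        defn = scoring.ScoreDefinition("s", ["absent"], np.array([1.0]), 1.0)
        with pytest.raises(ValueError, match="no overlapping"):
            scoring.compute_score(defn, gm)


class TestBuildPesDefinitions:
    def _inputs(self, seed=12):
        gm = _correlated_genotypes(n=300, m=100, rho=0.7, seed=seed)
        ss = _sumstats_for(gm, rng=np.random.default_rng(seed))
        gene_map = {f"g{k}": list(gm.variants["snp_id"].iloc[k * 10:(k + 1) * 10])
                    for k in range(10)}
        return gm, ss, gene_map

    def test_one_definition_per_viable_candidate(self):
        gm, ss, gene_map = self._inputs()
        cands = [CandidatePathway(f"P{k}", 1.0, 1e-4, {f"g{k}"}) for k in range(8)]
        defs = scoring.build_pes_definitions(cands, ss, gene_map, gm)
        assert len(defs) == 8
        assert [d.pathway for d in defs] == [f"P{k}" for k in range(8)]

    def test_pathway_with_no_snp_below_threshold_skipped(self):
        gm, ss, gene_map = self._inputs()
        ss["pvalue"] = 0.5
        cands = [CandidatePathway("P", 0.005, 1e-4, {"g0"})]
        assert scoring.build_pes_definitions(cands, ss, gene_map, gm) == []

    def test_definitions_satisfy_mapping_threshold_and_clump_constraints(self):
        gm, ss, gene_map = self._inputs(seed=13)
        cands = [CandidatePathway("P0", 0.5, 1e-4, {"g0", "g1"}),
                 CandidatePathway("P1", 0.05, 1e-4, {"g5"})]
        defs = scoring.build_pes_definitions(cands, ss, gene_map, gm)
        pv = ss.set_index("snp_id")["pvalue"]
        for d, cand in zip(defs, cands):
            allowed = {s for g in cand.genes for s in gene_map[g]}
            assert set(d.snp_ids) <= allowed
            assert all(pv[s] < cand.p_threshold for s in d.snp_ids)
            clumped = scoring.ld_clump(ss.loc[ss["snp_id"].isin(allowed)
                                              & (ss["pvalue"] < cand.p_threshold)], gm)
            assert d.snp_ids == clumped

    def test_pes_equals_prs_restricted_to_pathway_snps(self):
        gm, ss, gene_map = self._inputs(seed=14)
        cand = CandidatePathway("P", 1.0, 1e-4, {"g2", "g3"})
        (defn,) = scoring.build_pes_definitions([cand], ss, gene_map, gm)
        genome = scoring.ld_clump(ss, gm)
        restriction = [s for s in defn.snp_ids if s in set(ss["snp_id"])]
        sub = ss.set_index("snp_id").loc[defn.snp_ids]
        prs_like = scoring.ScoreDefinition("prs_sub", list(sub.index),
                                           sub["beta"].to_numpy(), 1.0)
        np.testing.assert_allclose(scoring.compute_score(defn, gm),
                                   scoring.compute_score(prs_like, gm), atol=1e-12)


class TestNagelkerke:
    def test_no_improvement_gives_zero(self):
        assert scoring.nagelkerke_r2(-10.0, -10.0, 50) == 0.0

    def test_perfect_fit_attains_one(self):
        l0 = 2 * np.log(0.5)
        assert scoring.nagelkerke_r2(l0, 0.0, 2) == pytest.approx(1.0)

    def test_matches_deviance_based_formula_on_logistic_fits(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            n = 20
            x = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
            if y.min() == y.max():
                continue
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            r2 = scoring.nagelkerke_r2(fit.llnull, fit.llf, n)
            d0, d1 = -2 * fit.llnull, -2 * fit.llf  # deviance route
            expect = (1 - np.exp((d1 - d0) / n)) / (1 - np.exp(-d0 / n))
            assert r2 == pytest.approx(expect, abs=1e-10)

    def test_rejects_inconsistent_likelihoods(self):
        with pytest.raises(ValueError):
            scoring.nagelkerke_r2(-5.0, -6.0, 10)


class TestOptimiseTotalPrs:
    def test_singleton_grid_is_chosen(self, mini_study):
        res, defn = scoring.optimise_total_prs(
            mini_study.sumstats, mini_study.genotypes, mini_study.phenotypes,
            grid=(0.5,))
        assert res.chosen_p_threshold == 0.5
        assert defn.p_threshold == 0.5 and res.n_snps == len(defn.snp_ids)

    def test_null_phenotype_yields_negligible_r2(self):
        study = simulate_study(preset("null", seed=21))
        res, _ = scoring.optimise_total_prs(
            study.sumstats, study.genotypes, study.phenotypes,
            grid=(0.05, 0.5, 1.0))
        assert max(res.r2) < 0.05

    def test_concentrated_signal_prefers_stringent_thresholds(self):
        chosen = []
        for seed in range(4):
            study = simulate_study(preset("mini", seed=31 + seed, n_gwas=1500,
                                          enrichment_multiplier=60.0, h2=0.5))
            res, _ = scoring.optimise_total_prs(
                study.sumstats, study.genotypes, study.phenotypes)
            chosen.append(res.chosen_p_threshold)
        assert sum(c <= 0.05 for c in chosen) >= 3

    def test_single_class_phenotype_rejected(self, mini_study):
        pheno = mini_study.phenotypes.copy()
        pheno["case_status"] = 1
        with pytest.raises(ValueError, match="single class"):
            scoring.optimise_total_prs(mini_study.sumstats, mini_study.genotypes,
                                       pheno, grid=(1.0,))
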