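import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pescore import profiling


def _pheno(y, rng=None, n_cov=3):
    rng = rng or np.random.default_rng(0)
    n = len(y)
    data = {"case_status": y, "sex": rng.integers(0, 2, n)}
    for k in range(1, n_cov + 1):
        data[f"PC{k}"] = rng.standard_normal(n)
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n)])


class TestFlagPercentiles:
    def test_top_percentile_flags_exactly_one_of_hundred(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"a": rng.permutation(100).astype(float)})
        flags = profiling.flag_percentiles(scores, levels=(0.99,))
        assert flags.flags[0.99]["a"].sum() == 1
        assert flags.flags[0.99]["a"].idxmax() == scores["a"].idxmax()

    def test_cohort_of_676_flags_seven_per_column(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({f"PES_{k}": rng.permutation(676).astype(float)
                               for k in range(8)})
        flags = profiling.flag_percentiles(scores)
        assert (flags.flags[0.99].sum(axis=0) == 7).all()
        counts = flags.counts
        assert (counts["n99"] <= counts["n90"]).all()
        assert (counts["n90"] <= counts["n75"]).all()

    def test_boundary_ties_all_flagged(self):
        scores = pd.DataFrame({"a": [0.0] * 98 + [5.0, 5.0]})
        flags = profiling.flag_percentiles(scores, levels=(0.99,))
        assert flags.flags[0.99]["a"].sum() == 2

    def test_flags_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame({"a": rng.standard_normal(200)})
        f1 = profiling.flag_percentiles(scores)
        f2 = profiling.flag_percentiles(np.exp(scores * 2) + 3)
        for level in f1.flags:
            pd.testing.assert_frame_equal(f1.flags[level], f2.flags[level])

    def test_constant_column_flags_everyone_with_warning(self, caplog):
        scores = pd.DataFrame({"a": np.zeros(50)})
        with caplog.at_level("WARNING"):
            flags = profiling.flag_percentiles(scores, levels=(0.9,))
        assert flags.flags[0.9]["a"].all()
        assert "constant" in caplog.text


class TestAssociateWithCase:
    def test_two_by_two_design_recovers_odds_ratio(self):
        # cells (a, b, c, d) = (30, 20, 20, 30): OR = ad/bc = 2.25
        y = np.array([1] * 30 + [0] * 20 + [1] * 20 + [0] * 30)
        x = np.array([1] * 50 + [0] * 50)
        pheno = pd.DataFrame({"case_status": y}, index=range(100))
        res = profiling.associate_with_case(x, pheno, covariates=())
        assert res.odds_ratio == pytest.approx(2.25, abs=1e-6)
        assert res.ci95_low == pytest.approx(np.exp(res.beta - 1.96 * res.se))

    def test_constant_predictor_rejected(self):
        pheno = _pheno(np.array([0, 1] * 20))
        with pytest.raises(profiling.DegenerateDesignError):
            profiling.associate_with_case(np.ones(40), pheno)

    def test_null_wald_p_calibrated(self):
        rng = np.random.default_rng(4)
        n, reps, alpha = 150, 300, 0.05
        rej = 0
        for _ in range(reps):
            y = rng.integers(0, 2, n)
            pheno = _pheno(y, rng)
            rej += profiling.associate_with_case(rng.standard_normal(n), pheno).wald_p < alpha
        rate = rej / reps
        assert abs(rate - alpha) < 3.5 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_prs_adjustment_attenuates_prs_driven_signal(self):
        rng = np.random.default_rng(5)
        n = 400
        prs = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * prs))).astype(int)
        x = prs + 0.5 * rng.standard_normal(n)  # proxy of PRS
        pheno = _pheno(y, rng)
        raw = profiling.associate_with_case(x, pheno)
        adj = profiling.associate_with_case(x, pheno, adjust_prs=True, prs=prs)
        assert raw.wald_p < 0.01
        assert abs(adj.z) < abs(raw.z)


class TestGmm:
    def test_single_component_recovers_ml_moments(self):
        rng = np.random.default_rng(6)
        x = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]], size=300)
        best, table = profiling.fit_gmm(x, k_range=[1], families=[("full", "variable")])
        np.testing.assert_allclose(best.means[0], x.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(x, rowvar=False, bias=True)
        np.testing.assert_allclose(best.covariances[0], ml_cov, atol=1e-6)

    def test_bic_prefers_one_component_for_single_gaussian(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal((150, 2))
            best, _ = profiling.fit_gmm(x, k_range=range(1, 4), n_init=3, seed=seed)
            hits += best.k == 1
        assert hits >= 18

    def test_three_separated_clusters_recovered(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        labels = rng.integers(0, 3, 450)
        x = centers[labels] + rng.standard_normal((450, 2))
        best, table = profiling.fit_gmm(x, k_range=range(1, 6), n_init=5, seed=1)
        assert best.k == 3
        assert adjusted_rand_score(labels, best.assignments) >= 0.9
        # selected BIC dominates every fitted candidate
        assert best.bic >= table["bic"].max() - 1e-9

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.standard_normal((100, 2)),
                       rng.standard_normal((100, 2)) + 3])
        best, _ = profiling.fit_gmm(x, k_range=[2], families=[("full", "variable")],
                                    n_init=3, seed=2)
        hist = np.array(best.loglik_history)
        assert (np.diff(hist) >= -1e-7 * (1 + np.abs(hist[:-1]))).all()

    def test_loglik_agrees_with_sklearn_on_full_family(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(9)
        x = np.vstack([rng.standard_normal((120, 2)),
                       rng.standard_normal((120, 2)) + [4, 1]])
        best, _ = profiling.fit_gmm(x, k_range=[2], families=[("full", "variable")],
                                    n_init=10, seed=3)
        sk = GaussianMixture(2, covariance_type="full", n_init=10,
                             random_state=0, reg_covar=1e-9).fit(x)
        assert best.loglik / len(x) == pytest.approx(sk.score(x), abs=1e-3)

    def test_bic_penalty_counts_parameters_per_family(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((80, 2))
        best, table = profiling.fit_gmm(x, k_range=[2],
                                        families=[("spherical", "equal"),
                                                  ("full", "variable")],
                                        n_init=2, seed=4)
        sph = table.loc[table["model"] == "spherical-equal"].iloc[0]
        full = table.loc[table["model"] == "full-variable"].iloc[0]
        assert sph["n_params"] == (2 - 1) + 2 * 2 + 1
        assert full["n_params"] == (2 - 1) + 2 * 2 + 2 * 3
        for row in (sph, full):
            assert row["bic"] == pytest.approx(
                2 * row["loglik"] - row["n_params"] * np.log(80))


class TestClusterEnrichment:
    def test_two_clusters_match_binary_logistic(self):
        rng = np.random.default_rng(11)
        n = 200
        clusters = rng.integers(0, 2, n)
        carrier = rng.integers(0, 2, n)
        pheno = _pheno(rng.integers(0, 2, n), rng)
        res = profiling.cluster_enrichment(clusters, carrier, pheno)
        assert len(res) == 1
        # reference = larger cluster; binary logit of "being in the other one"
        ref = np.argmax(np.bincount(clusters))
        y = (clusters != ref).astype(float)
        covs = ["sex", "PC1", "PC2", "PC3"]
        x = np.column_stack([np.ones(n), carrier] + [pheno[c] for c in covs])
        fit = sm.Logit(y, x).fit(disp=0)
        assert res[0].beta == pytest.approx(fit.params[1], abs=1e-6)
        assert res[0].se == pytest.approx(fit.bse[1], abs=1e-6)

    def test_planted_carrier_concentration_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 300
            clusters = rng.choice([0, 1, 2], n, p=[0.3, 0.5, 0.2])
            p_carry = np.where(clusters == 0, 0.5, 0.1)
            carrier = (rng.random(n) < p_carry).astype(int)
            pheno = _pheno(rng.integers(0, 2, n), rng)
            res = profiling.cluster_enrichment(clusters, carrier, pheno)
            z0 = next(r.z for r in res if r.term.startswith("cluster_0"))
            hits += z0 > 0
        assert hits >= 9

    def test_small_clusters_dropped(self):
        rng = np.random.default_rng(12)
        clusters = np.array([0] * 100 + [1] * 80 + [2] * 3)
        carrier = rng.integers(0, 2, 183)
        pheno = _pheno(rng.integers(0, 2, 183), rng)
        res = profiling.cluster_enrichment(clusters, carrier, pheno)
        assert {r.term for r in res} == {"cluster_1_vs_0"}
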