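import numpy as np
import pytest
from scipy import stats

from helpers import correlated_genotypes
from pleioscan.errors import ValidationError
from pleioscan.io import LDMatrix
from pleioscan.simulate import (DESK_CLASS_COUNTS, FULL_CLASS_COUNTS,
                                BenchmarkDataset, LDModel, SimScenario,
                                build_benchmark_dataset, noncentrality,
                                read_benchmark, simulate_ld, simulate_region,
                                simulate_rg, write_benchmark)


class TestSimulateLd:
    def test_ar1_rho_zero_is_identity(self):
        ld, _ = simulate_ld(10, LDModel(kind="ar1", rho=0.0), seed=1)
        np.testing.assert_array_equal(ld.r, np.eye(10))

    def test_ar1_closed_form(self):
        ld, _ = simulate_ld(15, LDModel(kind="ar1", rho=0.9), seed=1)
        i, j = np.indices((15, 15))
        np.testing.assert_allclose(ld.r, 0.9 ** np.abs(i - j), atol=1e-15)

    def test_blockwise_psd_after_regularization(self):
        ld, _ = simulate_ld(120, LDModel(kind="blockwise", block_size=40),
                            seed=2)
        eig = np.linalg.eigvalsh(ld.regularize().r)
        assert eig.min() >= 0

    def test_maf_floor(self):
        _, maf = simulate_ld(500, LDModel(maf_range=(0.01, 0.5)), seed=3)
        assert np.all(maf > 0.01) and np.all(maf <= 0.5)

    def test_q_too_small(self):
        with pytest.raises(ValidationError):
            simulate_ld(1)


class TestSimScenario:
    def test_causal_count_must_match_truth(self):
        with pytest.raises(ValidationError):
            SimScenario(truth="Hn", Q=10, query_index=0,
                        causal_indices=(1,), causal_log_ors=(0.1,))
        with pytest.raises(ValidationError):
            SimScenario(truth="Hc2", Q=10, query_index=0,
                        causal_indices=(0,), causal_log_ors=(0.1,))

    def test_hc_requires_query_causal(self):
        with pytest.raises(ValidationError):
            SimScenario(truth="Hc", Q=10, query_index=0,
                        causal_indices=(3,), causal_log_ors=(0.1,))

    def test_ha_excludes_query(self):
        with pytest.raises(ValidationError):
            SimScenario(truth="Ha", Q=10, query_index=3,
                        causal_indices=(3,), causal_log_ors=(0.1,))

    def test_causal_index_range(self):
        with pytest.raises(ValidationError):
            SimScenario(truth="Ha", Q=10, query_index=0,
                        causal_indices=(12,), causal_log_ors=(0.1,))


class TestSimulateRegion:
    def test_hn_null_calibration(self):
        q, reps = 10, 2000
        ld, maf = simulate_ld(q, LDModel(kind="ar1", rho=0.6), seed=4)
        chol = np.linalg.cholesky(ld.regularize().r)
        scenario = SimScenario(truth="Hn", Q=q, query_index=0,
                               causal_indices=(), causal_log_ors=())
        rng = np.random.default_rng(5)
        zsum = np.zeros(q)
        for _ in range(reps):
            zsum += simulate_region(scenario, ld, maf, rng, chol=chol).z
        assert np.all(np.abs(zsum / reps) < 4 / np.sqrt(reps))

    def test_hc_identity_ld_expected_z_only_at_query(self):
        q = 8
        ld = LDMatrix([f"1_{1000+i}_A_G" for i in range(q)], np.eye(q))
        maf = np.full(q, 0.3)
        scenario = SimScenario(truth="Hc", Q=q, query_index=5,
                               causal_indices=(5,), causal_log_ors=(0.2,))
        lam = noncentrality(scenario, maf)
        assert np.count_nonzero(lam) == 1 and lam[5] != 0
        ez = ld.r @ lam
        assert np.count_nonzero(ez) == 1
        # empirical check
        rng = np.random.default_rng(6)
        chol = np.eye(q)
        zbar = np.mean([simulate_region(scenario, ld, maf, rng, chol=chol).z
                        for _ in range(800)], axis=0)
        off = np.delete(zbar, 5)
        assert np.all(np.abs(off) < 4 / np.sqrt(800))
        assert zbar[5] == pytest.approx(lam[5], abs=4 / np.sqrt(800))

    def test_ha_ld_leakage_matches_logistic_oracle(self):
        # causal SNP in LD r=0.8 with the query: the summary model predicts
        # E[z_query] = r * lambda_causal; check against individual-level
        # logistic regression on simulated genotypes
        import statsmodels.api as sm
        r, f, gamma, n_ind = 0.8, 0.3, 0.1, 40_000
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(24):
            g_causal, g_query = correlated_genotypes(n_ind, f, r, rng)
            eta = gamma * (g_causal - g_causal.mean())
            y = rng.random(n_ind) < 1 / (1 + np.exp(-eta))  # prevalence ~0.5
            fit = sm.Logit(y, sm.add_constant(g_query)).fit(disp=0)
            zs.append(fit.params[1] / fit.bse[1])
        s = np.mean(y)  # ~0.5
        lam_causal = gamma * np.sqrt(2 * f * (1 - f) * n_ind * s * (1 - s))
        expected = r * lam_causal
        assert np.mean(zs) == pytest.approx(expected, abs=0.8)

    def test_beta_se_relation(self):
        q = 6
        ld, maf = simulate_ld(q, seed=8)
        scenario = SimScenario(truth="Hn", Q=q, query_index=2,
                               causal_indices=(), causal_log_ors=(),
                               n_cases=10_000, n_controls=10_000)
        region = simulate_region(scenario, ld, maf, rng=9)
        expect_se = 1 / np.sqrt(2 * maf * (1 - maf) * 20_000 * 0.25)
        np.testing.assert_allclose(region.se, expect_se)
        np.testing.assert_allclose(region.z, region.beta / region.se)
        assert region.s == 0.5 and region.trait_type == "cc"


class TestBuildBenchmark:
    def test_small_counts_and_labels(self):
        counts = {"Hn": 100, "Ha": 10, "Ha2": 10, "Hc": 20, "Hc2": 20}
        ds = build_benchmark_dataset(counts, Q=30, seed=10)
        assert len(ds) == 160
        assert ds.truth["truth"].value_counts().to_dict() == counts
        # Hc truths have the query among their causal indices
        for row in ds.truth.itertuples():
            causal = ([int(v) for v in row.causal_indices.split(",")]
                      if row.causal_indices else [])
            if row.truth in ("Hc", "Hc2"):
                assert row.query_index in causal
            else:
                assert row.query_index not in causal

    def test_all_zero_counts_empty(self):
        ds = build_benchmark_dataset({c: 0 for c in DESK_CLASS_COUNTS},
                                     Q=10, seed=1)
        assert len(ds) == 0 and len(ds.truth) == 0

    def test_deterministic_given_seed(self):
        counts = {"Hn": 20, "Ha": 5, "Hc": 5}
        a = build_benchmark_dataset(counts, Q=25, seed=42)
        b = build_benchmark_dataset(counts, Q=25, seed=42)
        assert a.truth.equals(b.truth)
        for ra, rb in zip(a.regions, b.regions):
            np.testing.assert_array_equal(ra.beta, rb.beta)

    def test_class_count_proportions_preserved_at_desk_scale(self):
        full = sum(FULL_CLASS_COUNTS.values())
        desk = sum(DESK_CLASS_COUNTS.values())
        assert full == 110_000
        for cls_name in FULL_CLASS_COUNTS:
            assert DESK_CLASS_COUNTS[cls_name] == pytest.approx(
                FULL_CLASS_COUNTS[cls_name] / 10, abs=1)
        assert desk == pytest.approx(11_000, abs=2)

    def test_round_trip_through_directory(self, tmp_path):
        ds = build_benchmark_dataset({"Hn": 4, "Hc": 3}, Q=12, seed=3)
        write_benchmark(ds, str(tmp_path / "bench"))
        back = read_benchmark(str(tmp_path / "bench"))
        assert isinstance(back, BenchmarkDataset)
        assert len(back) == 7
        assert back.truth["truth"].tolist() == ds.truth["truth"].tolist()
        for ra, rb in zip(ds.regions, back.regions):
            np.testing.assert_array_equal(ra.beta, rb.beta)
            assert ra.query_index == rb.query_index
        np.testing.assert_allclose(back.ld.r, ds.ld.r, atol=1e-15)
        np.testing.assert_allclose(back.covariates.rg, ds.covariates.rg)


class TestSimulateRg:
    def test_hc_stochastically_higher(self):
        truths = ["Hc"] * 200 + ["Hc2"] * 200 + ["Hn"] * 200 + \
                 ["Ha"] * 200 + ["Ha2"] * 200
        cov = simulate_rg(truths, seed=11)
        hc = cov.rg[:400]
        rest = cov.rg[400:]
        assert hc.mean() > rest.mean() + 0.2

    def test_null_symmetric_about_zero(self):
        cov = simulate_rg(["Hn"] * 2000, seed=12)
        assert abs(cov.rg.mean()) < 3 * 0.25 / np.sqrt(2000)
        assert np.all(np.abs(cov.rg) <= 1)

    def test_deterministic(self):
        a = simulate_rg(["Hn", "Hc", "Ha"], seed=13)
        b = simulate_rg(["Hn", "Hc", "Ha"], seed=13)
        np.testing.assert_array_equal(a.rg, b.rg)


class TestDistributionalInvariants:
    def test_hn_pvalues_uniform(self):
        # marginal calibration: query p-values across independent Hn
        # replicates are Uniform(0,1)
        q, reps = 10, 5000
        ld, maf = simulate_ld(q, LDModel(kind="ar1", rho=0.5), seed=14)
        chol = np.linalg.cholesky(ld.regularize().r)
        scenario = SimScenario(truth="Hn", Q=q, query_index=0,
                               causal_indices=(), causal_log_ors=())
        rng = np.random.default_rng(15)
        pvals = [simulate_region(scenario, ld, maf, rng, chol=chol)
                 .pvalues()[0] for _ in range(reps)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_z_correlation_converges_to_ld(self):
        q, reps = 50, 5000
        ld, maf = simulate_ld(q, LDModel(kind="blockwise", block_size=25),
                              seed=16)
        chol = np.linalg.cholesky(ld.regularize().r)
        scenario = SimScenario(truth="Hn", Q=q, query_index=0,
                               causal_indices=(), causal_log_ors=())
        rng = np.random.default_rng(17)
        zmat = np.array([simulate_region(scenario, ld, maf, rng, chol=chol).z
                         for _ in range(reps)])
        emp = np.corrcoef(zmat.T)
        assert np.max(np.abs(emp - ld.r)) < 0.05
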