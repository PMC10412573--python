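import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pharmacoepimap import dmr_calling as dc


def ols_oracle(x, y):
    """Normal-equations OLS: coefficients, se, t and two-sided p for each
    column of the design (used as the independent reference)."""
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ x.T @ y
    resid = y - x @ coefs
    df = x.shape[0] - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = coefs / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return coefs, se, t, p, df


class TestEligibility:
    def test_inclusive_auc_bound(self):
        auc = pd.DataFrame({
            "hit": [0.6, 0.65, 0.69, 0.9, 0.95],
            "edge": [0.7, 0.7, 0.7, 0.9, 0.95],
            "miss": [0.75, 0.8, 0.9, 0.95, 0.99],
        })
        assert dc.eligible_drugs(auc) == ["hit", "edge"]

    def test_cancer_type_boundary(self):
        cov = pd.DataFrame({"cancer_type": ["A"] * 16 + ["B"] * 15})
        assert dc.eligible_cancer_types(cov) == ["A"]

    def test_empty_cohort(self):
        assert dc.eligible_cancer_types(pd.DataFrame()) == []


class TestMethylationPcs:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.random((20, 40)))
        scores = dc.methylation_pcs(x, 2).to_numpy()
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        for comp in range(2):
            v = evecs[:, -(comp + 1)]
            ref = xc @ v
            # sign-free comparison
            err = min(np.abs(scores[:, comp] - ref).max(),
                      np.abs(scores[:, comp] + ref).max())
            assert err < 1e-8

    def test_rank_one_matrix_has_no_second_component(self):
        rng = np.random.default_rng(1)
        u = rng.random(15)
        v = rng.random(30)
        x = pd.DataFrame(np.outer(u, v))
        scores = dc.methylation_pcs(x, 2)
        total = scores.to_numpy().var(axis=0).sum()
        assert scores["pc2"].var() < 1e-10 * total

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.random((12, 25)),
                         index=[f"s{i}" for i in range(12)])
        perm = rng.permutation(12)
        a = dc.methylation_pcs(x)
        b = dc.methylation_pcs(x.iloc[perm])
        np.testing.assert_allclose(a.to_numpy()[perm], b.to_numpy(),
                                   atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            dc.methylation_pcs(pd.DataFrame(np.ones((2, 5))))


class TestFitCpgModels:
    def _random_scan(self, rng, n=20, n_probes=5, with_missing=False):
        beta = pd.DataFrame(rng.random((n, n_probes)),
                            columns=[f"cg{j}" for j in range(n_probes)])
        if with_missing:
            beta.iloc[rng.integers(0, n, 3), 0] = np.nan
        y = pd.Series(rng.normal(0.7, 0.1, n))
        cov = pd.DataFrame({
            "medium": rng.choice(["A", "B"], n),
            "msi": rng.choice(["MSS", "MSI"], n)})
        pcs = pd.DataFrame(rng.normal(size=(n, 2)), columns=["pc1", "pc2"])
        return beta, y, cov, pcs

    def test_exact_linear_fit(self):
        rng = np.random.default_rng(3)
        m = rng.random(12)
        beta = pd.DataFrame({"cg0": m})
        y = pd.Series(2.0 * m)
        out = dc.fit_cpg_models(beta, y, pd.DataFrame(index=beta.index),
                                None, min_samples=8)
        assert out.loc["cg0", "beta1"] == pytest.approx(2.0, abs=1e-10)
        assert out.loc["cg0", "p_raw"] <= 1e-12

    @pytest.mark.parametrize("with_missing", [False, True])
    def test_matches_normal_equations_oracle(self, with_missing):
        rng = np.random.default_rng(4)
        for _ in range(25):
            beta, y, cov, pcs = self._random_scan(rng,
                                                  with_missing=with_missing)
            out = dc.fit_cpg_models(beta, y, cov, pcs, min_samples=8)
            design = dc.build_design(cov, pcs)
            for probe in out.index:
                m = beta[probe]
                keep = m.notna()
                x = np.column_stack([np.ones(keep.sum()), m[keep],
                                     design[keep].to_numpy(float)])
                coefs, se, t, p, _ = ols_oracle(x, y[keep].to_numpy())
                assert out.loc[probe, "beta1"] == pytest.approx(coefs[1],
                                                                abs=1e-8)
                assert out.loc[probe, "se"] == pytest.approx(se[1], abs=1e-8)
                assert out.loc[probe, "t_stat"] == pytest.approx(t[1],
                                                                 abs=1e-8)
                assert out.loc[probe, "p_raw"] == pytest.approx(p[1],
                                                                abs=1e-8)
                assert out.loc[probe, "intercept"] == pytest.approx(
                    coefs[0], abs=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        beta = pd.DataFrame(rng.random((40, 400)))
        y = pd.Series(rng.normal(0.7, 0.05, 40))
        out = dc.fit_cpg_models(beta, y, pd.DataFrame(index=beta.index),
                                None)
        assert stats.kstest(out["p_raw"], "uniform").pvalue > 0.01

    def test_constant_probe_skipped(self):
        beta = pd.DataFrame({"flat": np.full(12, 0.5),
                             "ok": np.random.default_rng(6).random(12)})
        y = pd.Series(np.random.default_rng(7).normal(size=12))
        out = dc.fit_cpg_models(beta, y, pd.DataFrame(index=beta.index),
                                None, min_samples=8)
        assert list(out.index) == ["ok"]

    def test_min_samples_enforced(self):
        rng = np.random.default_rng(8)
        beta = pd.DataFrame({"cg0": rng.random(6)})
        y = pd.Series(rng.normal(size=6))
        out = dc.fit_cpg_models(beta, y, pd.DataFrame(index=beta.index),
                                None, min_samples=8)
        assert out.empty


class TestEstimateAcf:
    def _assoc(self, z, pos):
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"p_raw": p, "t_stat": z,
                             "chromosome": "chr1", "pos0": pos})

    def test_iid_z_gives_near_zero_clipped_acf(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=500)
        pos = np.arange(500) * 100
        acf = dc.estimate_acf(self._assoc(z, pos))
        assert (acf.correlations >= 0).all()
        assert (acf.correlations < 0.15).all()

    def test_spatially_correlated_z_recovered(self):
        # correlation rho ** (d / 250) at 25 bp spacing
        rng = np.random.default_rng(10)
        rho, step = 0.7, 25
        phi = rho ** (step / 250)
        n = 2000
        z = np.empty(n)
        z[0] = rng.normal()
        innov = rng.normal(size=n - 1) * np.sqrt(1 - phi ** 2)
        for i in range(1, n):
            z[i] = phi * z[i - 1] + innov[i - 1]
        acf = dc.estimate_acf(self._assoc(z, np.arange(n) * step))
        assert 0.4 <= acf.correlations[0] <= 0.9

    def test_degenerate_constant_p_warns_and_zero(self):
        z = np.full(50, 1.3)
        with pytest.warns(UserWarning, match="degenerate"):
            acf = dc.estimate_acf(self._assoc(z, np.arange(50) * 50))
        assert (acf.correlations == 0).all()

    def test_no_pairs_warns(self):
        z = np.array([1.0, -0.5])
        with pytest.warns(UserWarning, match="no probe pairs"):
            acf = dc.estimate_acf(self._assoc(z, np.array([0, 100000])))
        assert (acf.correlations == 0).all()

    def test_lookup_step_function(self):
        acf = dc.ACFEstimate(bin_edges=[(0, 250), (250, 500)],
                             correlations=np.array([0.5, 0.2]),
                             pair_counts=np.array([100, 100]))
        np.testing.assert_allclose(
            acf.lookup(np.array([0, 1, 250, 251, 500, 501])),
            [1.0, 0.5, 0.5, 0.2, 0.2, 0.0])


class TestStoufferLiptak:
    def test_single_p_identity(self):
        assert dc.stouffer_liptak([0.37]) == pytest.approx(0.37, abs=1e-12)

    def test_independent_pair_closed_form(self):
        # 1 - Phi(2 * 1.6449 / sqrt(2)) ~= 0.0100
        got = dc.stouffer_liptak([0.05, 0.05], np.eye(2))
        want = stats.norm.sf(2 * stats.norm.isf(0.05) / np.sqrt(2))
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.0100, abs=2e-4)

    def test_fully_redundant_pair(self):
        got = dc.stouffer_liptak([0.05, 0.05], np.ones((2, 2)))
        assert got == pytest.approx(0.05, abs=1e-12)

    def test_equals_classic_stouffer_at_zero_correlation(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.001, 0.999, 6)
        got = dc.stouffer_liptak(p, np.eye(6))
        z = stats.norm.isf(p)
        assert got == pytest.approx(stats.norm.sf(z.sum() / np.sqrt(6)),
                                    abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=6),
           st.integers(0, 5), st.floats(1e-6, 0.5))
    def test_non_increasing_in_each_p(self, ps, idx, delta):
        idx = idx % len(ps)
        c = np.full((len(ps), len(ps)), 0.3)
        np.fill_diagonal(c, 1.0)
        base = dc.stouffer_liptak(ps, c)
        smaller = list(ps)
        smaller[idx] = max(1e-12, smaller[idx] - delta)
        assert dc.stouffer_liptak(smaller, c) <= base + 1e-12

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dc.stouffer_liptak([])


class TestSlkCorrectSites:
    def _acf(self, rho=0.0):
        return dc.ACFEstimate(bin_edges=[(0, 250), (250, 500), (500, 750),
                                         (750, 1000)],
                              correlations=np.full(4, rho),
                              pair_counts=np.full(4, 100))

    def test_isolated_site_keeps_raw_p(self):
        p = np.array([0.02, 0.5])
        out = dc.slk_correct_sites(p, np.array([0, 5000]), self._acf())
        np.testing.assert_allclose(out, p)

    def test_concordant_neighbours_strengthen(self):
        p = np.full(3, 0.01)
        out = dc.slk_correct_sites(p, np.array([0, 100, 200]), self._acf())
        assert (out < 0.01).all()

    def test_null_neighbours_weaken(self):
        p = np.array([1.0 - 1e-16, 0.5, 1.0 - 1e-16])
        out = dc.slk_correct_sites(p, np.array([0, 100, 200]), self._acf())
        assert out[1] >= 0.5


class TestExtractRegions:
    def test_hand_traced_example(self):
        p = np.array([0.5, 1e-8, 1e-8, 1e-8, 0.5])
        pos = np.array([0, 100, 200, 300, 1500])
        regions = dc.extract_regions(p, pos)
        assert len(regions) == 1
        np.testing.assert_array_equal(regions[0], [1, 2, 3])

    def test_merging_within_1000_bases(self):
        p = np.array([1e-8, 1e-8, 1e-8, 1e-8])
        pos = np.array([0, 50, 950, 1000])
        regions = dc.extract_regions(p, pos)
        assert len(regions) == 1 and regions[0].size == 4

    def test_far_clusters_stay_separate(self):
        p = np.array([1e-8, 1e-8, 1e-8, 1e-8])
        pos = np.array([0, 50, 1500, 1550])
        assert len(dc.extract_regions(p, pos)) == 2

    def test_no_seed_no_region(self):
        p = np.array([0.2, 0.3, 0.4])
        assert dc.extract_regions(p, np.array([0, 10, 20])) == []


class TestSidakAdjust:
    def test_identity_at_single_effective_test(self):
        assert dc.sidak_adjust(0.5, 10, 10) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form(self):
        got = dc.sidak_adjust(0.01, 7, 70)  # n_eff = 10
        assert got == pytest.approx(1 - 0.99 ** 10, abs=1e-12)
        assert got == pytest.approx(0.09562, abs=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(1e-10, 1.0), st.integers(1, 50), st.integers(1, 5000))
    def test_monotone_in_total_probes_and_never_smaller(self, p, n_region,
                                                        n_total):
        a = dc.sidak_adjust(p, n_region, n_total)
        b = dc.sidak_adjust(p, n_region, n_total + n_region)
        assert a >= p - 1e-12
        assert b >= a - 1e-12


class TestFilterAndScoreRegions:
    def _setup(self, p_raw, beta1, betas):
        n = len(p_raw)
        pos = np.arange(n) * 50
        assoc = pd.DataFrame({
            "probe_id": [f"cg{j}" for j in range(n)],
            "p_raw": p_raw, "beta1": beta1, "t_stat": np.sign(beta1),
            "pos0": pos})
        beta = pd.DataFrame(betas, columns=assoc["probe_id"])
        acf = dc.ACFEstimate(bin_edges=[(0, 250), (250, 500), (500, 750),
                                        (750, 1000)],
                             correlations=np.zeros(4),
                             pair_counts=np.full(4, 100))
        return assoc, beta, acf

    def test_aberrant_count_boundary(self):
        p = np.full(3, 1e-12)
        b1 = np.full(3, -0.2)
        # 30 hypo-methylated lines but only 3 hyper -> rejected
        betas = np.vstack([np.full((30, 3), 0.1), np.full((3, 3), 0.9)])
        assoc, beta, acf = self._setup(p, b1, betas)
        out = dc.filter_and_score_regions([np.arange(3)], assoc, beta, acf,
                                          100, "chr1", "d", "CT")
        assert out == []
        # one more hyper-methylated line -> accepted
        betas = np.vstack([np.full((30, 3), 0.1), np.full((4, 3), 0.9)])
        assoc, beta, acf = self._setup(p, b1, betas)
        out = dc.filter_and_score_regions([np.arange(3)], assoc, beta, acf,
                                          100, "chr1", "d", "CT")
        assert len(out) == 1 and out[0].n_hypo == 30 and out[0].n_hyper == 4

    def test_region_with_weak_probe_rejected(self):
        p = np.array([1e-12, 0.02, 1e-12])
        b1 = np.full(3, -0.2)
        betas = np.vstack([np.full((10, 3), 0.1), np.full((10, 3), 0.9)])
        assoc, beta, acf = self._setup(p, b1, betas)
        out = dc.filter_and_score_regions([np.arange(3)], assoc, beta, acf,
                                          100, "chr1", "d", "CT")
        assert out == []

    def test_effect_size_is_mean_slope(self):
        p = np.full(3, 1e-12)
        b1 = np.array([-0.1, -0.2, -0.3])
        betas = np.vstack([np.full((10, 3), 0.1), np.full((10, 3), 0.9)])
        assoc, beta, acf = self._setup(p, b1, betas)
        out = dc.filter_and_score_regions([np.arange(3)], assoc, beta, acf,
                                          100, "chr1", "d", "CT")
        assert out[0].effect_size == pytest.approx(-0.2, abs=1e-12)
        assert out[0].sidak_p >= out[0].region_p


class TestCallDdmrs:
    def test_deterministic_rerun(self, planted_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _ = dc.call_ddmrs(planted_sim.cohort, planted_sim.manifest)
            b, _ = dc.call_ddmrs(planted_sim.cohort, planted_sim.manifest)
        assert [vars(d) for d in a] == [vars(d) for d in b]
        assert len(a) >= 1

    def test_planted_region_recovered_with_negative_effect(self,
                                                           planted_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ddmrs, _ = dc.call_ddmrs(planted_sim.cohort,
                                     planted_sim.manifest)
        tr = planted_sim.truth["regions"][0]
        hits = [d for d in ddmrs if d.drug == tr["drug"]
                and d.start < tr["end"] and d.end > tr["start"]]
        assert hits and all(d.effect_size < 0 for d in hits)

    def test_requires_auc(self, planted_sim):
        import dataclasses
        cohort = dataclasses.replace(planted_sim.cohort, auc=None)
        with pytest.raises(ValueError, match="AUC"):
            dc.call_ddmrs(cohort, planted_sim.manifest)
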