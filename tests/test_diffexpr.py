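import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonbalance import (
    CountTable,
    ValidationError,
    adjust_bh,
    call_degs,
    estimate_dispersions,
    estimate_size_factors,
    nb_wald_test,
    pi_rank,
    pi_values,
    run_de,
)
from exonbalance import simulate as sim


def _median_of_ratios_oracle(mat):
    """Direct re-computation of median-of-ratios factors from the definition."""
    keep = (mat > 0).all(axis=1)
    geo = np.exp(np.log(mat[keep]).mean(axis=1))
    factors = np.array([np.median(mat[keep, j] / geo) for j in range(mat.shape[1])])
    return factors / np.exp(np.log(factors).mean())


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        mat = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
        sf = estimate_size_factors(CountTable(mat))
        np.testing.assert_allclose(sf, 1.0)

    def test_doubled_column_scale_equivariance(self):
        mat = pd.DataFrame(
            {"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz")
        )
        sf = estimate_size_factors(CountTable(mat))
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(1, 500, size=(20, 4))
        sf = estimate_size_factors(
            CountTable(pd.DataFrame(mat, index=[f"f{i}" for i in range(20)]))
        )
        np.testing.assert_allclose(sf, _median_of_ratios_oracle(mat.astype(float)))

    def test_fallback_when_no_common_feature(self):
        mat = pd.DataFrame({"a": [10, 0], "b": [0, 10]}, index=["x", "y"])
        with pytest.warns(UserWarning):
            sf = estimate_size_factors(CountTable(mat))
        np.testing.assert_allclose(sf, 1.0)


class TestDispersions:
    def _fit(self, phi_true, n, m=400, seed=0, shrink=0.0):
        spec = sim.DegSimSpec(
            n_features=m, n_per_group=n, dispersion=phi_true,
            mean_range=(100, 1000), library_size_cv=0.0, seed=seed,
        )
        counts, groups, _ = sim.simulate_deg_counts(spec)
        sf = estimate_size_factors(counts)
        return estimate_dispersions(counts, sf, groups, shrink_weight=shrink)

    def test_poisson_data_near_zero(self):
        disp = self._fit(0.0, n=100)
        assert disp.phi.median() <= 0.01

    def test_moment_recovery(self):
        disp = self._fit(0.2, n=100, seed=1)
        assert 0.15 <= disp.phi.mean() <= 0.25

    def test_constant_counts_zero(self):
        mat = pd.DataFrame(np.full((3, 6), 7), index=list("abc"),
                           columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=mat.columns)
        ct = CountTable(mat)
        sf = estimate_size_factors(ct)
        disp = estimate_dispersions(ct, sf, groups, shrink_weight=0.0)
        np.testing.assert_allclose(disp.phi, 0.0)


def _make_ct(mat, n1, n2):
    cols = [f"s{i}" for i in range(n1 + n2)]
    ct = CountTable(pd.DataFrame(mat, columns=cols,
                                 index=[f"f{i}" for i in range(mat.shape[0])]))
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=cols)
    return ct, groups


class TestWaldTest:
    def test_noiseless_fourfold_lfc_exact(self):
        mat = np.column_stack([np.full((5, 4), 25), np.full((5, 4), 100)])
        ct, groups = _make_ct(mat, 4, 4)
        sf = pd.Series(1.0, index=ct.sample_ids)
        disp = estimate_dispersions(ct, sf, groups, shrink_weight=0.0)
        res = nb_wald_test(ct, sf, disp, groups)
        np.testing.assert_allclose(res["log2fc"], 2.0)

    def test_null_large_counts(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(10_000, size=(50, 40))
        ct, groups = _make_ct(mat, 20, 20)
        res = run_de(ct, groups, shrink_weight=0.0)
        assert np.abs(res["log2fc"]).max() < 0.05
        assert (res["p"] > 0.01).mean() > 0.9

    def test_label_swap_antisymmetry(self, deg_fixture):
        counts, groups, _ = deg_fixture
        sf = estimate_size_factors(counts)
        disp = estimate_dispersions(counts, sf, groups)
        res = nb_wald_test(counts, sf, disp, groups)
        swapped_labels = groups.map({"g1": "g2", "g2": "g1"})
        # relabel so level order flips the contrast
        res_swap = nb_wald_test(counts, sf, disp, swapped_labels)
        np.testing.assert_allclose(res["log2fc"], -res_swap["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res["p"], res_swap["p"], atol=1e-12)

    def test_size_factor_invariance(self, deg_fixture):
        counts, groups, _ = deg_fixture
        res = run_de(counts, groups, shrink_weight=0.0)
        scaled = counts.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        res2 = run_de(CountTable(scaled), groups, shrink_weight=0.0)
        sf1 = estimate_size_factors(counts)
        sf2 = estimate_size_factors(CountTable(scaled))
        assert sf2.iloc[0] / sf1.iloc[0] == pytest.approx(
            4.0 / np.exp(np.log(4) / counts.shape[1]), rel=0.05
        )
        np.testing.assert_allclose(res["log2fc"], res2["log2fc"], atol=0.02)

    def test_all_zero_feature_untested(self):
        mat = np.vstack([np.zeros((1, 8), dtype=int), np.full((2, 8), 50)])
        ct, groups = _make_ct(mat, 4, 4)
        res = run_de(ct, groups)
        assert np.isnan(res.loc[0, "p"])
        assert res.loc[0, "direction"] == "NS"

    def test_poisson_glm_oracle_agreement(self):
        # in the phi -> 0 limit the NB Wald p matches an independent Poisson
        # GLM Wald oracle within 10% relative error
        import statsmodels.api as sm

        spec = sim.DegSimSpec(
            n_features=100, n_per_group=10, dispersion=0.0,
            library_size_cv=0.0, n_up=30, lfc_up=1.0, seed=11,
        )
        counts, groups, _ = sim.simulate_deg_counts(spec)
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersions(counts, sf, groups, shrink_weight=0.0)
        disp.phi[:] = 1e-8
        res = nb_wald_test(counts, sf, disp, groups)
        x = sm.add_constant((groups == "g2").astype(float).to_numpy())
        bad = 0
        for i, fid in enumerate(counts.feature_ids):
            y = counts.counts.loc[fid].to_numpy()
            fit = sm.GLM(y, x, family=sm.families.Poisson()).fit()
            p_oracle = fit.pvalues[1]
            p_ours = res.loc[i, "p"]
            denom = max(p_oracle, 1e-12)
            if abs(p_ours - p_oracle) / denom > 0.10:
                bad += 1
        assert bad == 0


def _bh_oracle(p):
    """Exhaustive step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 60))
        np.testing.assert_allclose(adjust_bh(p), _bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q_ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_bh(p), q_ref, atol=1e-12)

    def test_nan_passthrough(self):
        q = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], _bh_oracle(np.array([0.01, 0.04])))


class TestCallsAndPi:
    def test_direction_rules(self):
        res = pd.DataFrame(
            {"log2fc": [2.0, -2.0, 1.0, 0.5], "q": [0.01, 0.2, 0.049, 0.001]}
        )
        calls = call_degs(res)
        assert list(calls) == ["UP", "NS", "UP", "NS"]

    def test_pi_closed_form(self):
        res = pd.DataFrame(
            {"feature_id": list("abc"), "log2fc": [2.0, 0.0, -1.0],
             "q": [0.01, 0.001, 0.1]}
        )
        pi = pi_values(res)
        np.testing.assert_allclose(pi, [4.0, 0.0, -1.0])

    def test_pi_rank_descending_with_id_ties(self):
        res = pd.DataFrame(
            {"feature_id": ["b", "a", "c"], "log2fc": [1.0, 1.0, 2.0],
             "q": [0.1, 0.1, 0.1]}
        )
        ranked = pi_rank(res)
        assert list(ranked["feature_id"]) == ["c", "a", "b"]

    def test_q_zero_clamped(self):
        res = pd.DataFrame({"feature_id": ["a"], "log2fc": [1.0], "q": [0.0]})
        with pytest.warns(UserWarning):
            pi = pi_values(res)
        assert pi[0] == pytest.approx(300.0)


class TestAgainstDeseq2:
    def test_log2fc_agrees_with_deseq2(self, deg_fixture):
        # independent cross-check: the moment-based NB Wald pipeline should
        # rank and sign features like DESeq2 on well-expressed planted data
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, groups, truth = deg_fixture
        res = run_de(counts, groups)
        meta = pd.DataFrame({"condition": groups})
        dds = DeseqDataSet(
            counts=counts.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"]
        merged = res.set_index("feature_id").join(ref.rename("ref_lfc"))
        ok = merged.dropna()
        r = np.corrcoef(ok["log2fc"], ok["ref_lfc"])[0, 1]
        assert r > 0.95
        planted = truth.set_index("feature_id").loc[ok.index, "true_log2fc"]
        strong = planted != 0
        assert (np.sign(ok.loc[strong, "log2fc"]) == np.sign(planted[strong])).mean() > 0.95
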