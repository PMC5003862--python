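"""PLS fitting, bootstrap gene ranking and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hubgenes as hg
from hubgenes.pls import (
    _block_permutation,
    bootstrap_ranking,
    fit_pls,
    make_blocks,
    metric_correlations,
    permutation_test,
    spatial_calibration_check,
    variance_explained,
)


def planted_xy(rng, n=60, p=200, nsig=20, amp=2.0, noise=1.0):
    """Rank-2 planted construction: orthogonal gene supports, orthogonal
    regional patterns, clearly distinct component strengths (so the two
    components are identifiable by construction)."""
    pat1 = rng.standard_normal(n)
    pat2 = rng.standard_normal(n)
    pat2 -= pat1 * (pat1 @ pat2) / (pat1 @ pat1)
    w1 = np.zeros(p)
    w2 = np.zeros(p)
    w1[:nsig] = amp * 2.0
    w2[nsig : 2 * nsig] = amp * 0.75
    X = np.outer(w1, pat1) + np.outer(w2, pat2) + noise * rng.standard_normal((p, n))
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    T = pd.DataFrame(X, index=[f"g{i}" for i in range(p)], columns=[f"R{i}" for i in range(n)])
    C = pd.DataFrame(
        {"k_intra": pat1 + 0.1 * rng.standard_normal(n), "k_inter": pat2 + 0.1 * rng.standard_normal(n),
         "d": rng.standard_normal(n)},
        index=T.columns,
    )
    return T, C, w1, w2


class TestFitPLS:
    def test_noiseless_rank_one_exact_fit(self, rng):
        """When the single response column is an exact linear readout of
        mutually uncorrelated genes, component 1 captures >99% of the
        response variance (one-component exact-fit limit)."""
        Q, _ = np.linalg.qr(rng.standard_normal((60, 20)))
        X = Q.T  # 20 orthonormal gene rows over 60 regions
        v = np.zeros(20)
        v[:5] = rng.standard_normal(5)
        y = X.T @ v
        T = pd.DataFrame(X, columns=[f"R{i}" for i in range(60)])
        C = pd.DataFrame({"y": y}, index=T.columns)
        res = fit_pls(T, C, n_components=1)
        assert res.cumulative_pct_variance[0] > 99.0

    def test_component1_matches_svd_of_cross_covariance(self, rng):
        T, C, *_ = planted_xy(rng)
        res = fit_pls(T, C, n_components=1)
        X = T.to_numpy().T
        Y = C.to_numpy()
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        U, _, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
        cos = abs(float(res.weights.iloc[:, 0] @ U[:, 0]))
        assert cos > 0.999

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        T, C, *_ = planted_xy(rng, n=40, p=100)
        res = fit_pls(T, C, n_components=3)
        skl = PLSRegression(n_components=3, scale=True).fit(T.to_numpy().T, C.to_numpy())
        for c in range(3):
            cos = abs(float(res.weights.iloc[:, c] @ skl.x_weights_[:, c]))
            assert cos > 0.99

    def test_cumulative_variance_monotone_and_complete(self, rng):
        T, C, *_ = planted_xy(rng, n=12, p=30)
        res = fit_pls(T, C, n_components=11)
        cum = res.cumulative_pct_variance
        assert np.all(np.diff(cum) >= -1e-9)
        assert cum[-1] == pytest.approx(100.0, abs=1e-6)

    def test_constant_response_column_rejected(self, rng):
        T, C, *_ = planted_xy(rng)
        C["d"] = 1.0
        with pytest.raises(ValueError, match="d"):
            fit_pls(T, C, n_components=2)

    def test_planted_supports_recovered(self, rng):
        T, C, w1, w2 = planted_xy(rng, n=100, p=300, nsig=30)
        res = fit_pls(T, C, n_components=2)
        r11 = abs(np.corrcoef(res.weights.iloc[:, 0], w1)[0, 1])
        r22 = abs(np.corrcoef(res.weights.iloc[:, 1], w2)[0, 1])
        assert r11 > 0.9
        assert r22 > 0.9

    def test_pattern_sign_flip_flips_scores_not_magnitudes(self, rng):
        T, C, *_ = planted_xy(rng)
        res = fit_pls(T, C, n_components=2)
        C_flipped = C.copy()
        C_flipped["k_intra"] = -C_flipped["k_intra"]
        res_f = fit_pls(T, C_flipped, n_components=2)
        r = np.corrcoef(res.x_scores.iloc[:, 0], C["k_intra"])[0, 1]
        r_f = np.corrcoef(res_f.x_scores.iloc[:, 0], C_flipped["k_intra"])[0, 1]
        assert abs(abs(r) - abs(r_f)) < 1e-6


class TestMetricCorrelations:
    def test_scores_equal_metric_give_unit_r(self, rng):
        T, C, *_ = planted_xy(rng)
        res = fit_pls(T, C, n_components=1)
        metrics = pd.DataFrame(
            {
                "k": res.x_scores.iloc[:, 0],
                "PC": rng.standard_normal(len(C)),
                "k_intra": C["k_intra"],
                "k_inter": C["k_inter"],
                "d": C["d"],
            },
            index=C.index,
        )
        coords = rng.standard_normal((len(C), 3))
        table = metric_correlations(res, metrics, coords)
        assert table["r"].loc["PLS1", "k"] == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self, rng):
        T, C, *_ = planted_xy(rng)
        res = fit_pls(T, C, n_components=2)
        metrics = pd.DataFrame(
            {m: rng.standard_normal(len(C)) for m in ("k", "PC", "k_intra", "k_inter", "d")},
            index=C.index,
        )
        coords = rng.standard_normal((len(C), 3))
        table = metric_correlations(res, metrics, coords)
        t = res.x_scores["PLS2"].to_numpy()
        v = metrics["PC"].to_numpy()
        r_direct = ((t - t.mean()) @ (v - v.mean())) / (
            np.sqrt(((t - t.mean()) ** 2).sum()) * np.sqrt(((v - v.mean()) ** 2).sum())
        )
        assert table["r"].loc["PLS2", "PC"] == pytest.approx(r_direct, abs=1e-12)


class TestBootstrapRanking:
    def test_deterministic_under_seed(self, rng):
        T, C, *_ = planted_xy(rng, n=40, p=80, nsig=10)
        r1 = bootstrap_ranking(T, C, component=1, n_boot=100, seed=5)
        r2 = bootstrap_ranking(T, C, component=1, n_boot=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_signal_genes_top_ranked(self, rng):
        T, C, w1, w2 = planted_xy(rng, n=80, p=200, nsig=20)
        ranking = bootstrap_ranking(T, C, component=1, n_boot=150, seed=0)
        top = set(ranking.head(20)["gene"])
        signal = {f"g{i}" for i in np.flatnonzero(w1)}
        assert len(top & signal) >= 16

    def test_null_gene_z_centred(self):
        """Mean Z of a fixed noise gene over 50 simulation replicates is
        within +-0.3 of zero."""
        zs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            T, C, w1, _ = planted_xy(r, n=30, p=50, nsig=5)
            ranking = bootstrap_ranking(T, C, component=1, n_boot=100, seed=seed)
            noise_genes = [f"g{i}" for i in range(40, 50)]
            zs.append(ranking.set_index("gene").loc[noise_genes, "z"].mean())
        assert abs(np.mean(zs)) < 0.3

    def test_rank_is_permutation(self, rng):
        T, C, *_ = planted_xy(rng, n=30, p=40, nsig=5)
        ranking = bootstrap_ranking(T, C, component=1, n_boot=100, seed=1)
        assert sorted(ranking["rank"]) == list(range(1, 41))
        assert (ranking["se"] > 0).all()


class TestPermutationTest:
    def test_p_bounds_and_determinism(self, rng):
        T, C, *_ = planted_xy(rng, n=40, p=60)
        res = permutation_test(T, C, n_components=2, n_perm=99, seed=3)
        assert 1 / 100 <= res.p <= 1.0
        res2 = permutation_test(T, C, n_components=2, n_perm=99, seed=3)
        assert np.array_equal(res.null, res2.null)

    def test_planted_effect_detected(self, rng):
        T, C, *_ = planted_xy(rng, n=80, p=200, nsig=30)
        res = permutation_test(T, C, n_components=2, n_perm=199, seed=0)
        assert res.p == pytest.approx(1 / 200)

    def test_size_one_blocks_reduce_to_naive(self, rng):
        T, C, *_ = planted_xy(rng, n=30, p=50)
        blocks = np.arange(30)
        naive = permutation_test(T, C, n_components=2, n_perm=49, seed=7, scheme="naive")
        block = permutation_test(T, C, n_components=2, n_perm=49, seed=7, scheme="block", blocks=blocks)
        assert np.allclose(naive.null, block.null)

    def test_single_block_rejected(self, rng):
        T, C, *_ = planted_xy(rng, n=20, p=30)
        with pytest.raises(ValueError, match="block"):
            permutation_test(T, C, n_components=2, n_perm=9, scheme="block", blocks=np.zeros(20))

    def test_block_permutation_preserves_within_block_order(self, rng):
        blocks = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
        perm = _block_permutation(np.random.default_rng(0), blocks)
        assert sorted(perm.tolist()) == list(range(9))
        # each block's members stay adjacent and in order
        out_blocks = blocks[perm]
        changes = (np.diff(out_blocks) != 0).sum()
        assert changes == 2
        for b in range(3):
            members = perm[out_blocks == b]
            assert np.array_equal(members, np.sort(members))

    def test_make_blocks_contiguity(self, rng):
        coords = rng.uniform(-50, 50, size=(40, 3))
        blocks = make_blocks(coords, n_blocks=4, seed=0)
        assert len(np.unique(blocks)) >= 2
        assert len(blocks) == 40


class TestSpatialCalibration:
    def test_exchangeable_regions_both_calibrated(self):
        rep = spatial_calibration_check(n_sims=60, n_perm=99, rho=0.0, n_regions=40, n_genes=80, seed=4)
        half = 1.96 * np.sqrt(0.05 * 0.95 / 60)
        assert abs(rep["naive_rate"] - 0.05) <= half + 1e-9
        assert abs(rep["block_rate"] - 0.05) <= half + 1e-9
        assert not rep["naive_inflated"]

    def test_block_dependence_inflates_naive_only(self):
        rep = spatial_calibration_check(n_sims=60, n_perm=99, rho=0.7, n_regions=40, n_genes=80, seed=5)
        assert rep["naive_rate"] > rep["block_rate"]
        assert rep["naive_inflated"]
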