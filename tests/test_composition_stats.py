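"""Hellinger transform, PERMANOVA (with enumeration oracle and scikit-bio
cross-check), PCA, RDA and univariate permutation ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metadiet import (hellinger, pca, permanova, permutation_anova, rda)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no shared code with the package)


def oracle_one_way_f(X, labels):
    """One-way multivariate pseudo-F from group means, Euclidean geometry."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum()
    ssw = 0.0
    groups = np.unique(labels)
    for g in groups:
        sub = X[labels == g]
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    ssb = sst - ssw
    dfb, dfw = len(groups) - 1, len(X) - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / dfb) / (ssw / dfw)


def oracle_enumeration_p(X, labels):
    """Exact permutation p by complete enumeration of row orders."""
    X = np.asarray(X, float)
    f_obs = oracle_one_way_f(X, labels)
    count = total = 0
    for perm in itertools.permutations(range(len(X))):
        f = oracle_one_way_f(X[list(perm)], labels)
        total += 1
        if f >= f_obs - 1e-12 or (np.isinf(f_obs) and np.isinf(f)):
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestHellinger:
    def test_closed_form_square_roots(self):
        h = hellinger(pd.DataFrame([[0.25, 0.75]]))
        assert h.iloc[0, 0] == pytest.approx(0.5)
        assert h.iloc[0, 1] == pytest.approx(np.sqrt(0.75), abs=1e-4)

    def test_row_norms_are_one(self):
        rng = np.random.default_rng(2)
        h = hellinger(pd.DataFrame(rng.dirichlet(np.ones(5), size=8)))
        assert np.allclose(np.linalg.norm(h.to_numpy(), axis=1), 1.0)

    def test_distance_range(self):
        h = hellinger(pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]))
        d_max = np.linalg.norm(h.iloc[0] - h.iloc[1])
        d_zero = np.linalg.norm(h.iloc[0] - h.iloc[2])
        assert d_max == pytest.approx(np.sqrt(2.0))
        assert d_zero == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            hellinger(pd.DataFrame([[-0.1, 1.1]]))

    def test_renormalizes_unnormalized_rows(self):
        h1 = hellinger(pd.DataFrame([[1, 3]]))
        h2 = hellinger(pd.DataFrame([[0.25, 0.75]]))
        assert np.abs(h1.to_numpy() - h2.to_numpy()).max() < 1e-12


class TestPermanova:
    def test_separated_groups_exact_enumeration_p(self):
        # two tight groups, 3 + 3 identical rows each: orbit argument gives 1/10
        X = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], float)
        labels = ["a"] * 3 + ["b"] * 3
        assert oracle_enumeration_p(X, labels) == pytest.approx(0.1)
        res = permanova(X, pd.DataFrame({"g": labels}), terms=["g"],
                        n_perm=9999, seed=0)
        assert res.p_value["g"] == pytest.approx(0.1, abs=0.02)

    def test_monte_carlo_matches_enumeration_with_noise(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(6, 3))
        X[3:] += 1.0
        labels = ["a"] * 3 + ["b"] * 3
        p_exact = oracle_enumeration_p(X, labels)
        res = permanova(X, pd.DataFrame({"g": labels}), terms=["g"],
                        n_perm=9999, seed=1)
        sd = np.sqrt(p_exact * (1 - p_exact) / 9999)
        assert abs(res.p_value["g"] - p_exact) <= 3 * sd + 1e-4

    def test_pseudo_f_matches_oracle_and_skbio(self):
        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(4), size=12)
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(X, pd.DataFrame({"g": labels}), terms=["g"],
                        n_perm=99, seed=0)
        assert res.pseudo_f["g"] == pytest.approx(oracle_one_way_f(X, labels), rel=1e-9)
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        dm = skbio.DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(12)])
        sk = skbio.stats.distance.permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f["g"] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        design = pd.DataFrame({"a": ["x", "y"] * 10, "b": ["u"] * 10 + ["v"] * 10})
        res = permanova(X, design, terms=["a", "b", "a:b"], n_perm=49, seed=0)
        total = res.r2.sum() + res.residual_ss / res.total_ss
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_r2_invariant_to_level_relabelling(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 3))
        g1 = ["a", "b", "c"] * 4
        g2 = ["zz", "mm", "aa"] * 4  # same partition, different (reordered) names
        r1 = permanova(X, pd.DataFrame({"g": g1}), terms=["g"], n_perm=9, seed=0)
        r2 = permanova(X, pd.DataFrame({"g": g2}), terms=["g"], n_perm=9, seed=0)
        assert r1.r2["g"] == pytest.approx(r2.r2["g"], rel=1e-9)

    def test_single_level_term_rejected_by_name(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="g"):
            permanova(X, pd.DataFrame({"g": ["a"] * 6}), terms=["g"], n_perm=9)

    def test_degenerate_constant_matrix_flagged(self):
        X = np.ones((8, 3))
        res = permanova(X, pd.DataFrame({"g": ["a", "b"] * 4}), terms=["g"],
                        n_perm=9, seed=0)
        assert res.degenerate
        assert (res.p_value == 1.0).all()

    def test_strata_permutations_stay_within_blocks(self):
        # response differs only between strata: stratified test must be null
        X = np.vstack([np.zeros((6, 2)), np.ones((6, 2))])
        design = pd.DataFrame({"g": (["a", "b"] * 6),
                               "block": ["s1"] * 6 + ["s2"] * 6})
        res = permanova(X, design, terms=["g"], n_perm=199, seed=0, strata="block")
        assert res.p_value["g"] > 0.5

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        design = pd.DataFrame({"g": ["a", "b"] * 5})
        r1 = permanova(X, design, terms=["g"], n_perm=199, seed=42)
        r2 = permanova(X, design, terms=["g"], n_perm=199, seed=42)
        assert float(r1.p_value["g"]) == float(r2.p_value["g"])


class TestPca:
    def test_rank_one_data_single_axis(self):
        v = np.outer(np.arange(5.0), [1.0, 2.0])
        res = pca(v)
        assert res.percent_explained[0] == pytest.approx(100.0)
        assert len(res.eigenvalues) == 1

    def test_two_cluster_fixture_hand_eigenvalues(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        res = pca(X)
        # centered data: rows (+-0.5, -+0.5); covariance eigenvalues (2/3, 0)
        assert res.eigenvalues[0] == pytest.approx(2 / 3)
        s = res.site_scores.iloc[:, 0].to_numpy()
        assert np.sign(s[0]) == np.sign(s[1]) != np.sign(s[2])

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 6))
        res = pca(X)
        total = ((X - X.mean(0)) ** 2).sum() / (len(X) - 1)
        assert res.eigenvalues.sum() == pytest.approx(total)
        assert res.percent_explained.sum() == pytest.approx(100.0)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        res = pca(X)
        sk = sklearn.PCA().fit(X)
        assert np.allclose(res.eigenvalues, sk.explained_variance_[:len(res.eigenvalues)],
                           atol=1e-9)

    def test_constant_matrix_flagged(self):
        res = pca(np.ones((4, 3)))
        assert res.degenerate
        assert len(res.eigenvalues) == 0


class TestRda:
    def test_null_predictors_nonpositive_adjusted_r2(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        preds = pd.DataFrame({"g": ["a", "b"] * 6})
        # force orthogonality: remove the group-mean difference
        for g in ("a", "b"):
            mask = (preds["g"] == g).to_numpy()
            X[mask] -= X[mask].mean(axis=0)
        res = rda(X, preds, terms=["g"])
        assert res.r2 == pytest.approx(0.0, abs=1e-9)
        assert res.adjusted_r2 <= 0

    def test_saturated_two_level_factor(self):
        base = {"a": [1.0, 0.0, 0.0], "b": [0.0, 1.0, 0.0]}
        labels = ["a", "b"] * 4
        X = np.array([base[g] for g in labels])
        res = rda(X, pd.DataFrame({"g": labels}), terms=["g"])
        assert res.r2 == pytest.approx(1.0)
        assert res.percent_explained[0] == pytest.approx(100.0)

    def test_matches_regression_then_decomposition_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 3))
        labels = ["a", "a", "a", "b", "b", "b"]
        res = rda(X, pd.DataFrame({"g": labels}), terms=["g"])
        # oracle: explicit hat-matrix regression, then eigen-decomposition
        Xc = X - X.mean(axis=0)
        Z = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        H = Z @ np.linalg.pinv(Z.T @ Z) @ Z.T
        fitted = H @ Xc
        eig = np.linalg.eigvalsh(fitted.T @ fitted / 5)[::-1]
        eig = eig[eig > 1e-10]
        assert np.allclose(res.eigenvalues, eig, atol=1e-10)
        r2 = (fitted ** 2).sum() / (Xc ** 2).sum()
        assert res.r2 == pytest.approx(r2, rel=1e-12)
        assert res.adjusted_r2 == pytest.approx(1 - (1 - r2) * 5 / 4, rel=1e-12)

    def test_intercept_only_reproduces_pca(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(9, 4))
        res_rda = rda(X, pd.DataFrame({"g": ["a"] * 9}), terms=[])
        res_pca = pca(X)
        assert np.allclose(res_rda.eigenvalues, res_pca.eigenvalues)
        assert not res_rda.constrained

    def test_condition_partials_out_covariate(self):
        # X fully determined by the site covariate: nothing left for phase
        rng = np.random.default_rng(14)
        site = ["s1", "s2", "s3"] * 4
        site_effect = {"s1": 0.0, "s2": 3.0, "s3": -2.0}
        X = np.array([[site_effect[s]] * 3 for s in site])
        phase = ["p", "q"] * 6
        res = rda(X, pd.DataFrame({"phase": phase, "site": site}),
                  terms=["phase"], condition=["site"])
        assert res.r2 == pytest.approx(0.0, abs=1e-9) or np.isnan(res.r2)


class TestPermutationAnova:
    def test_constant_response_all_p_one(self):
        design = pd.DataFrame({"g": ["a", "b"] * 5})
        res = permutation_anova(np.ones(10), design, terms=["g"], n_perm=99, seed=0)
        assert res.degenerate
        assert (res.p_value == 1.0).all()

    def test_power_on_large_shift(self):
        rng = np.random.default_rng(15)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        design = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20})
        res = permutation_anova(y, design, terms=["g"], n_perm=999, seed=0)
        assert res.p_value["g"] <= 0.01

    def test_matches_classical_f_statistic(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=(18,))
        g = ["a", "b", "c"] * 6
        res = permutation_anova(y, pd.DataFrame({"g": g}), terms=["g"],
                                n_perm=9, seed=0)
        from scipy.stats import f_oneway
        groups = [y[np.asarray(g) == lv] for lv in "abc"]
        assert res.pseudo_f["g"] == pytest.approx(f_oneway(*groups).statistic, rel=1e-9)

    def test_residual_share_reported(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=12)
        res = permutation_anova(y, pd.DataFrame({"g": ["a", "b"] * 6}),
                                terms=["g"], n_perm=9, seed=0)
        assert 0 <= res.residual_ss / res.total_ss <= 1
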