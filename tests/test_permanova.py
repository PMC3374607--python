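"""Distance-matrix partition engine: oracles, classical limits, permutation
behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest

from permcomp.permanova import (
    DegenerateResponseError,
    DistanceMatrix,
    ModelTerm,
    RankDeficiencyError,
    encode_term,
    euclidean_distances,
    partition,
    permutation_test,
    scalar_distance,
    univariate_permutation_test,
)


def sequential_anova_oracle(y, blocks):
    """Classical sequential (Type-I) ANOVA/ANCOVA by direct regression.

    Independent of the distance-matrix path: fits nested OLS models in
    response space and returns per-term SS, F and the residual SS/df.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rank_prev = 1
    rss_prev = float(((y - y.mean()) ** 2).sum())
    ss_terms, df_terms = [], []
    for block in blocks:
        X = np.hstack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        ss_terms.append(rss_prev - rss)
        # term df is its rank increment (empty factor cells can make an
        # interaction block collinear with its parents)
        rank = np.linalg.matrix_rank(X)
        df_terms.append(rank - rank_prev)
        rank_prev = rank
        rss_prev = rss
    df_res = n - 1 - sum(df_terms)
    f = [
        (ss / df) / (rss_prev / df_res) for ss, df in zip(ss_terms, df_terms)
    ]
    return np.array(ss_terms), np.array(f), rss_prev, df_res


class TestEuclideanDistances:
    def test_identical_samples_have_zero_distance(self):
        comp = pd.DataFrame([[1.0, -1.0], [1.0, -1.0]], index=["a", "b"])
        d = euclidean_distances(comp)
        assert d.values[0, 1] == 0.0

    def test_hand_computed_pair(self):
        comp = pd.DataFrame([[0, 0, 0], [1, 0, -1]], index=["a", "b"], dtype=float)
        d = euclidean_distances(comp)
        assert d.values[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_loop(self, rng):
        comp = pd.DataFrame(rng.normal(size=(5, 6)))
        d = euclidean_distances(comp).values
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((comp.iloc[i] - comp.iloc[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestPartition:
    def test_classical_one_way_anova_by_hand(self):
        """y = (1,2,3,10,11,12) vs a 2-level factor: SS_between = 121.5,
        SS_within = 4, F = 121.5."""
        y = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        meta = pd.DataFrame({"g": list("AAABBB")}, index=[f"s{i}" for i in range(6)])
        d = scalar_distance(y, ids=meta.index)
        res = partition(d, [ModelTerm.main("g")], meta)
        assert res.table["ss"].iloc[0] == pytest.approx(121.5, abs=1e-10)
        assert res.residual_ss == pytest.approx(4.0, abs=1e-10)
        assert res.table["f"].iloc[0] == pytest.approx(121.5, abs=1e-10)

    def test_constant_response_is_degenerate(self, toy_metadata):
        d = scalar_distance(np.ones(6), ids=toy_metadata.index)
        with pytest.raises(DegenerateResponseError, match="degenerate"):
            partition(d, [ModelTerm.main("group")], toy_metadata)

    def test_term_order_conserves_total_and_residual(self, rng, toy_metadata):
        y = rng.normal(size=6)
        d = scalar_distance(y, ids=toy_metadata.index)
        terms = [ModelTerm.main("group"), ModelTerm.main("x")]
        a = partition(d, terms, toy_metadata)
        b = partition(d, terms[::-1], toy_metadata)
        assert a.total_ss == pytest.approx(b.total_ss, rel=1e-12)
        assert a.residual_ss == pytest.approx(b.residual_ss, rel=1e-10)

    def test_rank_deficient_term_is_named(self, toy_metadata):
        meta = toy_metadata.assign(g2=toy_metadata["group"])
        d = scalar_distance(np.arange(6.0), ids=meta.index)
        with pytest.raises(RankDeficiencyError, match="g2"):
            partition(d, [ModelTerm.main("group"), ModelTerm.main("g2")], meta)

    def test_classical_limit_on_random_designs(self, rng):
        """Univariate pseudo-F equals textbook sequential ANCOVA F to 1e-10
        on 20 random small designs mixing factors and covariates."""
        for _ in range(20):
            n = int(rng.integers(12, 25))
            meta = pd.DataFrame(
                {
                    "f1": rng.choice(list("ABC"), size=n),
                    "f2": rng.choice(["u", "v"], size=n),
                    "x": rng.normal(size=n),
                },
                index=[f"s{i}" for i in range(n)],
            )
            y = rng.normal(size=n)
            terms = [ModelTerm.main("f1"), ModelTerm.main("x"),
                     ModelTerm.interaction("f2", "x")]
            d = scalar_distance(y, ids=meta.index)
            res = partition(d, terms, meta)
            blocks = [encode_term(t, meta) for t in terms]
            ss_exp, f_exp, rss_exp, df_res_exp = sequential_anova_oracle(y, blocks)
            np.testing.assert_allclose(res.table["ss"], ss_exp, atol=1e-10)
            np.testing.assert_allclose(res.table["f"], f_exp, atol=1e-10)
            assert res.residual_ss == pytest.approx(rss_exp, abs=1e-10)
            assert res.residual_df == df_res_exp

    def test_matches_statsmodels_type1_anova(self, rng):
        """Independent library cross-check of the sequential partition."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        n = 30
        meta = pd.DataFrame(
            {
                "g": rng.choice(list("AB"), size=n),
                "x": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        y = rng.normal(size=n)
        frame = meta.assign(y=y)
        fit = smf.ols("y ~ C(g) + x", data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        d = scalar_distance(y, ids=meta.index)
        res = partition(d, [ModelTerm.main("g"), ModelTerm.main("x")], meta)
        np.testing.assert_allclose(
            res.table["ss"], anova["sum_sq"].iloc[:2], atol=1e-10
        )
        np.testing.assert_allclose(res.table["f"], anova["F"].iloc[:2], atol=1e-8)


class TestPermutationTest:
    def test_p_floor_when_observed_f_is_maximal(self):
        """A dominant effect with B = 999 gives p = 1/1000."""
        rng = np.random.default_rng(5)
        n = 24
        meta = pd.DataFrame(
            {"g": ["A"] * 12 + ["B"] * 12}, index=[f"s{i}" for i in range(n)]
        )
        y = np.r_[rng.normal(0, 0.1, 12), rng.normal(50, 0.1, 12)]
        res = univariate_permutation_test(
            y, [ModelTerm.main("g")], meta, n_permutations=999, seed=0
        )
        assert res.table["p"].iloc[0] == pytest.approx(0.001)

    def test_exhaustive_four_sample_case(self):
        """y = (1,2,3,4) with groups AABB: F = 8.0 and exactly 2 of the 6
        distinct labelings reach it, so the exhaustive p is 1/3."""
        meta = pd.DataFrame({"g": list("AABB")}, index=list("abcd"))
        res = univariate_permutation_test(
            np.array([1.0, 2, 3, 4]), [ModelTerm.main("g")], meta, exhaustive=True
        )
        assert res.table["f"].iloc[0] == pytest.approx(8.0, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(2 / 6, abs=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self):
        meta = pd.DataFrame({"g": list("AABB")}, index=list("abcd"))
        y = np.array([1.0, 2, 3, 4])
        mc = univariate_permutation_test(
            y, [ModelTerm.main("g")], meta, n_permutations=4999, seed=3
        )
        p_exact = 2 / 6
        se = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(mc.table["p"].iloc[0] - p_exact) < 3 * se

    def test_exhaustive_equals_enumeration_oracle(self, rng):
        """For n <= 7 the engine's exhaustive p equals a brute-force tail
        proportion computed by an independent regression-space loop."""
        n = 6
        meta = pd.DataFrame(
            {"g": ["A", "A", "B", "B", "C", "C"]}, index=[f"s{i}" for i in range(n)]
        )
        y = rng.normal(size=n)
        res = univariate_permutation_test(y, [ModelTerm.main("g")], meta, exhaustive=True)

        block = encode_term(ModelTerm.main("g"), meta)
        _, f_obs, _, _ = sequential_anova_oracle(y, [block])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            _, f_b, _, _ = sequential_anova_oracle(y[list(perm)], [block])
            count += f_b[0] >= f_obs[0] - 1e-12
            total += 1
        assert res.table["p"].iloc[0] == pytest.approx(count / total, abs=1e-9)

    def test_total_ss_invariant_under_permutation(self, rng, toy_metadata):
        """Permuting labels leaves the distance matrix — hence total SS —
        untouched; additivity holds on every evaluated permutation."""
        y = rng.normal(size=6)
        d = scalar_distance(y, ids=toy_metadata.index)
        res = permutation_test(d, [ModelTerm.main("group")], toy_metadata,
                               n_permutations=50, seed=1)
        res.check_additivity()
        perm = np.random.default_rng(0).permutation(6)
        d_perm = DistanceMatrix(ids=d.ids, values=d.values[np.ix_(perm, perm)])
        res_perm = partition(d_perm, [ModelTerm.main("group")],
                             toy_metadata.set_index(toy_metadata.index[perm]))
        assert res_perm.total_ss == pytest.approx(res.total_ss, rel=1e-12)

    def test_univariate_affine_invariance_and_determinism(self, rng):
        n = 20
        meta = pd.DataFrame(
            {"g": rng.choice(list("AB"), size=n), "x": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        y = rng.normal(size=n)
        terms = [ModelTerm.main("g"), ModelTerm.main("x")]
        a = univariate_permutation_test(y, terms, meta, n_permutations=199, seed=9)
        b = univariate_permutation_test(3.7 * y - 11.0, terms, meta,
                                        n_permutations=199, seed=9)
        np.testing.assert_allclose(a.table["f"], b.table["f"], rtol=1e-10)
        np.testing.assert_allclose(a.table["p"], b.table["p"], atol=0)
        c = univariate_permutation_test(y, terms, meta, n_permutations=199, seed=9)
        pd.testing.assert_frame_equal(a.table, c.table)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(ids=("a", "b"), values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(ids=("a", "b"), values=np.array([[1.0, 1.0], [1.0, 0.0]]))
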