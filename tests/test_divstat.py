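"""Beta diversity, ordination, and permutation-test behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from lichenbgc import divstat
from lichenbgc.divstat import DissimilarityMatrix


def brute_force_multisite(arr: np.ndarray):
    """Independent literal coding of the multiple-site Sorensen partition."""
    sites = [set(np.nonzero(row)[0]) for row in arr]
    S_i = [len(s) for s in sites]
    S_T = len(set().union(*sites))
    s_min = s_max = 0
    for a, b in itertools.combinations(sites, 2):
        bij, bji = len(a - b), len(b - a)
        s_min += min(bij, bji)
        s_max += max(bij, bji)
    excess = sum(S_i) - S_T
    if s_min + s_max == 0:
        return 0.0, 0.0, 0.0
    sim = s_min / (excess + s_min) if s_min else 0.0
    sor = (s_min + s_max) / (2 * excess + s_min + s_max)
    return sor, sim, sor - sim


class TestBetaPartition:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y", "z"}, {"x", "y", "z"}, (0.0, 0.0, 0.0)),
            ({1, 2, 3}, {1, 2}, (0.2, 0.0, 0.2)),
            ({1, 2}, {3, 4}, (1.0, 1.0, 0.0)),
        ],
    )
    def test_pairwise_examples(self, a, b, expected):
        res = divstat.beta_pairwise(a, b)
        assert (res.beta_sor, res.beta_sim, res.beta_sne) == pytest.approx(expected)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            divstat.beta_pairwise(set(), set())

    def test_identical_rows_give_zero(self):
        res = divstat.beta_multisite(np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0]]))
        assert res.beta_sor == res.beta_sim == res.beta_sne == 0.0

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError):
            divstat.beta_multisite(np.zeros((3, 4), dtype=int))

    def test_two_sites_reduce_to_pairwise(self, rng):
        for _ in range(25):
            m = rng.integers(0, 2, (2, 15))
            if not m.any():
                continue
            ms = divstat.beta_multisite(m)
            pw = divstat.beta_pairwise(
                set(np.nonzero(m[0])[0]), set(np.nonzero(m[1])[0])
            )
            assert ms.beta_sor == pytest.approx(pw.beta_sor, abs=1e-12)
            assert ms.beta_sim == pytest.approx(pw.beta_sim, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 8), st.integers(1, 30))
    def test_partition_identity_property(self, seed, n_sites, n_items):
        m = np.random.default_rng(seed).integers(0, 2, (n_sites, n_items))
        if not m.any():
            return
        res = divstat.beta_multisite(m)
        assert abs(res.beta_sor - res.beta_sim - res.beta_sne) < 1e-12
        for v in (res.beta_sor, res.beta_sim, res.beta_sne):
            assert -1e-12 <= v <= 1 + 1e-12
        oracle = brute_force_multisite(m)
        assert res.beta_sor == pytest.approx(oracle[0], abs=1e-12)
        assert res.beta_sim == pytest.approx(oracle[1], abs=1e-12)


class TestJaccard:
    def test_examples(self):
        pa = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [0, 0, 0]], index=list("abc"), columns=list("xyz")
        )
        with pytest.warns(UserWarning):
            d = divstat.jaccard_matrix(pa.iloc[[2, 2]])
        assert d.values[0, 1] == 0.0
        d = divstat.jaccard_matrix(pa.iloc[:2])
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            divstat.jaccard_matrix(np.array([[0, 2], [1, 0]]))


class TestPcoa:
    def test_euclidean_self_consistency(self, rng):
        pts = rng.normal(size=(9, 3))
        D = DissimilarityMatrix(squareform(pdist(pts)))
        res = divstat.pcoa(D)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rec - D.values).max() < 1e-8

    def test_two_points(self):
        res = divstat.pcoa(DissimilarityMatrix([[0, 1], [1, 0]]))
        coords = res.coordinates.to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-0.5, 0.5])

    def test_zero_matrix(self):
        res = divstat.pcoa(DissimilarityMatrix(np.zeros((4, 4))))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCophenetic:
    def test_path_sums(self):
        d = divstat.cophenetic_distances("((A:1,B:1):1,C:2);").to_frame()
        assert d.loc["A", "B"] == 2.0
        assert d.loc["A", "C"] == 4.0
        assert all(d.values.diagonal() == 0.0)

    def test_missing_branch_length_named(self):
        with pytest.raises(ValueError, match="branch length"):
            divstat.cophenetic_distances("((A:1,B),C:2);")


class TestMantel:
    def test_identical_matrices_give_r_one(self, rng):
        x = squareform(pdist(rng.normal(size=(8, 2))))
        D = DissimilarityMatrix(x)
        res = divstat.mantel(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        x = squareform(pdist(rng.normal(size=(5, 2))))
        y = squareform(pdist(rng.normal(size=(5, 2))))
        Dx, Dy = DissimilarityMatrix(x), DissimilarityMatrix(y)
        res = divstat.mantel(Dx, Dy, exact=True)
        iu = np.triu_indices(5, 1)

        def corr(b):
            av, bv = x[iu] - x[iu].mean(), b[iu] - b[iu].mean()
            return (av @ bv) / np.sqrt((av @ av) * (bv @ bv))

        r_obs = corr(y)
        hits = sum(
            corr(y[np.ix_(p, p)]) >= r_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.n_perm == 119
        assert res.p == pytest.approx(hits / 120, abs=1e-12)

    def test_label_mismatch_rejected(self, rng):
        x = squareform(pdist(rng.normal(size=(4, 2))))
        D1 = DissimilarityMatrix(x, list("abcd"))
        D2 = DissimilarityMatrix(x, list("abce"))
        with pytest.raises(ValueError):
            divstat.mantel(D1, D2)

    def test_too_small_rejected(self):
        D = DissimilarityMatrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            divstat.mantel(D, D)

    def test_seed_determinism(self, rng):
        x = squareform(pdist(rng.normal(size=(10, 2))))
        y = squareform(pdist(rng.normal(size=(10, 2))))
        a = divstat.mantel(DissimilarityMatrix(x), DissimilarityMatrix(y), seed=5)
        b = divstat.mantel(DissimilarityMatrix(x), DissimilarityMatrix(y), seed=5)
        assert a.p == b.p and a.r == b.r


class TestPhyloPCs:
    def test_rank_one_matrix(self):
        # collinear points on a line -> one axis explains everything
        pos = np.array([0.0, 1.0, 2.0, 3.5])
        D = DissimilarityMatrix(np.abs(pos[:, None] - pos[None, :]))
        res = divstat.phylo_pcs(D)
        assert res.k <= 2  # raw-row geometry of a line is essentially planar
        res_dc = divstat.phylo_pcs(D, double_center=True)
        assert res_dc.k == 1
        assert res_dc.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_threshold_zero_keeps_one(self, rng):
        D = DissimilarityMatrix(squareform(pdist(rng.normal(size=(6, 3)))))
        assert divstat.phylo_pcs(D, var_threshold=0.0).k == 1

    def test_variance_fractions_non_increasing(self, rng):
        D = DissimilarityMatrix(squareform(pdist(rng.normal(size=(8, 4)))))
        frac = divstat.phylo_pcs(D).variance_fractions
        assert np.all(np.diff(frac) <= 1e-12)


class TestPermanova:
    def test_univariate_equals_classical_regression(self, rng):
        n = 15
        x = rng.normal(size=n)
        y = 1.2 * x + rng.normal(size=n)
        D = DissimilarityMatrix(np.abs(y[:, None] - y[None, :]))
        cov = pd.DataFrame({"x": x}, index=D.labels)
        res = divstat.permanova(D, cov, n_perm=49, seed=0)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss1 = float(((y - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        f_cl = (rss0 - rss1) / (rss1 / (n - 2))
        assert res["x"].F == pytest.approx(f_cl, abs=1e-8)

    def test_r_squared_sums_to_one(self, rng):
        n = 12
        D = DissimilarityMatrix(squareform(pdist(rng.normal(size=(n, 3)))))
        cov = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)}, index=D.labels
        )
        res = divstat.permanova(D, cov, n_perm=49, seed=0)
        assert res.table["R2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_covariate_named(self, rng):
        n = 10
        D = DissimilarityMatrix(squareform(pdist(rng.normal(size=(n, 2)))))
        x = rng.normal(size=n)
        cov = pd.DataFrame({"a": x, "b": 2 * x}, index=D.labels)
        with pytest.raises(ValueError, match="'b'"):
            divstat.permanova(D, cov, n_perm=9, seed=0)


class TestPartialFTest:
    def test_matches_matrix_algebra_oracle(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        F, p, (q, dfd) = divstat.partial_f_test(y, x)
        X0 = np.ones((40, 1))
        X1 = np.column_stack([X0, x])
        r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
        oracle = ((r0 @ r0 - r1 @ r1) / 1) / ((r1 @ r1) / (40 - 2))
        assert F == pytest.approx(oracle, abs=1e-9)
        assert q == 1 and dfd == 38

    def test_exact_fit_reports_infinite_f(self):
        x = np.arange(10.0)
        F, p, _ = divstat.partial_f_test(2 * x, x)
        assert np.isinf(F) and p == 0.0

    def test_orthogonal_predictor_f_near_zero(self, rng):
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        x -= x @ y / (y @ y) * y  # orthogonalize against the response
        F, p, _ = divstat.partial_f_test(y, x)
        assert F < 1.5 and p > 0.2

    def test_singular_design_rejected(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            divstat.partial_f_test(np.arange(10.0), x)  # collinear with intercept
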