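import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from emtscape.genesets import GeneSet, GeneSetCollection
from emtscape.scoring import (
    ExpressionMatrix,
    ScoreTable,
    WalkParams,
    expression_statistic,
    random_walk_es,
    score_matrix,
    symmetric_rank,
)
from emtscape import synthetic_data as sd


def brute_force_scores(X, set_indices, tau=1.0, log=True):
    """Independent double-loop reference implementation of the KS walk."""
    X = np.asarray(X, float)
    if log:
        X = np.log2(X + 1.0)
    p, n = X.shape
    z = np.zeros((p, n))
    for i in range(p):
        h = X[i].std(ddof=1) / 4.0
        for j in range(n):
            if h > 0:
                z[i, j] = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(n)])
            else:
                z[i, j] = 0.5
    out = []
    m = len(set_indices)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))
        rt = {g: abs(p / 2.0 - (r + 1)) for r, g in enumerate(order)}
        denom = sum(rt[g] ** tau for g in set_indices)
        nu, c_in, c_out = [], 0.0, 0
        for g in order:
            if g in set_indices:
                c_in += rt[g] ** tau
            else:
                c_out += 1
            nu.append(c_in / denom - c_out / (p - m))
        out.append(max(0.0, max(nu)) + min(0.0, min(nu)))
    return np.array(out)


class TestExpressionStatistic:
    def test_monotone_in_expression(self):
        z = expression_statistic(np.array([[0.0, 10.0], [5.0, 1.0]]))
        assert z[0, 1] > z[0, 0]
        assert z[1, 0] > z[1, 1]

    def test_two_equal_values_sit_at_half(self):
        # kernel CDF evaluated at zero is exactly 1/2
        z = expression_statistic(np.array([[3.0, 3.0], [1.0, 2.0]]))
        assert z[0, 0] == pytest.approx(0.5)
        assert z[0, 1] == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        z = expression_statistic(X)
        for i in range(5):
            h = X[i].std(ddof=1) / 4.0
            for j in range(4):
                ref = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(4)])
                assert z[i, j] == pytest.approx(ref, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            expression_statistic(np.array([[1.0], [2.0]]))

    def test_rank_only_mode_uses_ecdf(self):
        z = expression_statistic(np.array([[1.0, 3.0, 2.0]]), kernel="none")
        assert np.allclose(z, [[1 / 3, 1.0, 2 / 3]])


class TestSymmetricRank:
    def test_folded_ranks_by_hand(self):
        # ranks (1, 2, 3, 4) by decreasing z -> |2 - r| = (1, 0, 1, 2)
        z = np.array([[4.0], [3.0], [2.0], [1.0]])
        r_tilde, ordering = symmetric_rank(z)
        assert np.allclose(r_tilde.ravel(), [1, 0, 1, 2])
        assert ordering.ravel().tolist() == [0, 1, 2, 3]

    def test_all_tied_is_still_a_bijection(self):
        r_tilde, ordering = symmetric_rank(np.ones((5, 3)))
        for j in range(3):
            assert sorted(ordering[:, j].tolist()) == [0, 1, 2, 3, 4]

    def test_reversed_statistic_reverses_ordering(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(7, 2))
        _, fwd = symmetric_rank(z)
        _, rev = symmetric_rank(-z)
        assert np.array_equal(rev, fwd[::-1, :])


class TestRandomWalk:
    def setup_method(self):
        # gene indices ordered by decreasing z; r_tilde per rank = (1, 0, 1, 2)
        self.ordering = np.array([0, 1, 2, 3])
        self.r_tilde = np.array([1.0, 0.0, 1.0, 2.0])

    def test_top_rank_member_walks_to_one(self):
        mask = np.array([True, False, False, False])
        es, nu = random_walk_es(self.ordering, self.r_tilde, mask)
        assert np.allclose(nu, [1.0, 2 / 3, 1 / 3, 0.0])
        assert es == pytest.approx(1.0)

    def test_bottom_rank_member_walks_to_minus_one(self):
        mask = np.array([False, False, False, True])
        es, nu = random_walk_es(self.ordering, self.r_tilde, mask)
        assert np.allclose(nu, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert es == pytest.approx(-1.0)

    def test_walk_always_returns_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.integers(5, 40)
            rt = rng.uniform(0.1, p / 2, size=p)
            mask = np.zeros(p, bool)
            mask[rng.choice(p, size=rng.integers(1, p - 1), replace=False)] = True
            _, nu = random_walk_es(np.arange(p), rt, mask)
            assert nu[-1] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="1 <= m < p"):
            random_walk_es(self.ordering, self.r_tilde, np.ones(4, bool))
        with pytest.raises(ValueError, match="degenerate"):
            random_walk_es(
                self.ordering, np.zeros(4), np.array([False, True, False, False])
            )


class TestScoreMatrix:
    def test_matches_bruteforce_oracle(self, small_matrix, small_sets):
        table = score_matrix(small_matrix, small_sets)
        ref = brute_force_scores(small_matrix.values.to_numpy(), set(range(3, 8)))
        assert np.allclose(table.scores["S"].to_numpy(), ref, atol=1e-12)
        assert (table.scores["S"].abs() <= 1.0).all()

    def test_sample_permutation_equivariance(self, small_matrix, small_sets):
        base = score_matrix(small_matrix, small_sets).scores
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = ExpressionMatrix(small_matrix.values.iloc[:, perm])
        out = score_matrix(shuffled, small_sets).scores
        assert np.allclose(out.to_numpy(), base.iloc[perm].to_numpy())

    def test_rank_invariance_under_monotone_transform(self, small_matrix, small_sets):
        params = WalkParams(kernel="none", log_transform=False)
        base = score_matrix(small_matrix, small_sets, params=params).scores
        cubed = ExpressionMatrix(small_matrix.values**3)
        out = score_matrix(cubed, small_sets, params=params).scores
        assert np.allclose(out.to_numpy(), base.to_numpy())

    def test_pinned_cohort_scores(self):
        """Regression pin: scores are cohort-dependent but reproducible."""
        m, _ = sd.generate_cohort(
            n_samples=40, n_e_genes=30, n_m_genes=25, n_background=40, seed=123
        )
        st = score_matrix(m, sd.signature_sets(30, 25))
        assert st.scores.loc["S00000", "E"] == pytest.approx(-0.135862785863, abs=1e-9)
        assert st.scores.loc["S00001", "E"] == pytest.approx(0.800759987676, abs=1e-9)
        assert st.scores.loc["S00002", "M"] == pytest.approx(0.774660531927, abs=1e-9)

    def test_sparse_set_rejected_by_name(self, small_matrix):
        sets = GeneSetCollection.from_sets(
            [GeneSet("TINY", frozenset({"g0", "nonexistent"}))]
        )
        with pytest.raises(ValueError, match="TINY"):
            score_matrix(small_matrix, sets)

    def test_agrees_with_external_gsva(self):
        """Cross-check against gseapy's GSVA; conventions differ at O(1/p)."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(11)
        p, n = 300, 12
        X = rng.gamma(2.0, 50.0, size=(p, n))
        genes = [f"g{i}" for i in range(p)]
        samples = [f"s{j}" for j in range(n)]
        gs = {"S1": genes[10:60], "S2": genes[100:140]}
        res = gseapy.gsva(
            data=pd.DataFrame(np.log2(X + 1), index=genes, columns=samples),
            gene_sets=gs, kcdf="Gaussian", mx_diff=True, tau=1,
            outdir=None, threads=1, min_size=1,
        )
        ext = res.res2d.pivot(index="Name", columns="Term", values="ES").astype(float)
        mat = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
        coll = GeneSetCollection.from_sets(
            GeneSet(k, frozenset(v)) for k, v in gs.items()
        )
        ours = score_matrix(mat, coll).scores
        diff = np.abs(ext.loc[samples, ["S1", "S2"]].to_numpy() - ours.to_numpy())
        assert diff.max() < 0.05


class TestScoreTable:
    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            ScoreTable(pd.DataFrame({"E": [0.2, 1.4]}))

    def test_round_trip(self, tmp_path):
        t = ScoreTable(pd.DataFrame({"E": [0.1, -0.5]}, index=["a", "b"]))
        p = tmp_path / "scores.tsv"
        t.write_delimited(p)
        back = ScoreTable.read_delimited(p)
        assert np.allclose(back.scores.to_numpy(), t.scores.to_numpy())
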