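import numpy as np
import pytest

from ncis import cocluster as cc
from ncis.evaluate import clustering_accuracy

from conftest import planted_blocks


def random_instance(rng, d=None, n=None, m=None, c=None):
    d = d or int(rng.integers(4, 31))
    n = n or int(rng.integers(4, 21))
    m = m or int(rng.integers(2, min(d, 6)))
    c = c or int(rng.integers(2, min(n, 6)))
    X = rng.normal(size=(d, n)) * rng.uniform(0.5, 3)
    w = rng.uniform(0, 2, size=d)
    F = rng.uniform(size=(n, c))
    F /= F.sum(1, keepdims=True)
    G = rng.uniform(size=(d, m))
    G /= G.sum(1, keepdims=True)
    return X, w, F, G


class TestObjective:
    def test_zero_on_exact_factorization(self):
        rng = np.random.default_rng(0)
        G = rng.uniform(size=(6, 2))
        S = rng.normal(size=(2, 3))
        F = rng.uniform(size=(5, 3))
        X = G @ S @ F.T
        assert cc.objective(X, rng.uniform(0.1, 1, 6), F, G, S) == pytest.approx(0.0, abs=1e-18)

    def test_zero_weights_give_zero(self):
        rng = np.random.default_rng(1)
        X, _, F, G = random_instance(rng, d=6, n=5, m=2, c=2)
        S = rng.normal(size=(2, 2))
        assert cc.objective(X, np.zeros(6), F, G, S) == 0.0

    def test_hand_evaluated_weighted_norm(self):
        # X = I2, identity factors reconstruct exactly; S = 0 leaves the
        # full rows, weighted 1 and 2.
        X = np.eye(2)
        w = np.array([1.0, 2.0])
        I = np.eye(2)
        assert cc.objective(X, w, I, I, I) == pytest.approx(0.0)
        assert cc.objective(X, w, I, I, np.zeros((2, 2))) == pytest.approx(3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            cc.objective(np.zeros((3, 2)), np.ones(3), np.zeros((2, 2)),
                         np.zeros((3, 2)), np.zeros((2, 3)))


class TestUpdateS:
    def test_block_means_oracle(self):
        X = np.array([[1.0, 1, 2, 2], [1, 1, 2, 2], [5, 5, 8, 8]])
        G = np.array([[1.0, 0], [1, 0], [0, 1]])
        F = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
        S = cc.update_S(X, np.ones(3), F, G)
        np.testing.assert_allclose(S, [[1, 2], [5, 8]], atol=1e-12)

    def test_single_block_grand_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 5))
        # m = c = 1 is outside fit's range but update_S itself handles it
        G = np.ones((4, 1))
        F = np.ones((5, 1))
        S = cc.update_S(X, np.ones(4), F, G)
        assert S[0, 0] == pytest.approx(X.mean())

    def test_weighted_block_mean(self):
        X = np.array([[0.0, 0], [4, 4], [9, 9]])
        G = np.array([[1.0, 0], [1, 0], [0, 1]])
        F = np.array([[1.0], [1]])
        S = cc.update_S(X, np.array([1.0, 3.0, 1.0]), F, G)
        assert S[0, 0] == pytest.approx(3.0)  # (0*1 + 4*3) / (1 + 3)

    def test_random_hard_partitions_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d, n = int(rng.integers(5, 15)), int(rng.integers(5, 15))
            m, c = int(rng.integers(2, 4)), int(rng.integers(2, 4))
            gl = rng.integers(0, m, d)
            sl = rng.integers(0, c, n)
            gl[:m] = np.arange(m)
            sl[:c] = np.arange(c)
            X = rng.normal(size=(d, n))
            w = rng.uniform(0.1, 2, d)
            G = np.eye(m)[gl]
            F = np.eye(c)[sl]
            S = cc.update_S(X, w, F, G)
            for k in range(m):
                for l in range(c):
                    block = X[np.ix_(gl == k, sl == l)]
                    wk = w[gl == k]
                    expected = (wk[:, None] * block).sum() / (wk.sum() * block.shape[1])
                    assert S[k, l] == pytest.approx(expected, rel=1e-10)

    def test_empty_cluster_raises(self):
        X = np.random.default_rng(4).normal(size=(4, 4))
        G = np.array([[1.0, 0], [1, 0], [1, 0], [1, 0]])  # cluster 2 empty
        F = np.eye(2)[[0, 0, 1, 1]]
        with pytest.raises(np.linalg.LinAlgError, match="gene cluster 2"):
            cc.update_S(X, np.ones(4), F, G)


class TestMultiplicativeUpdates:
    def test_exact_factorization_is_fixed_point(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            G = rng.uniform(0.1, 1, size=(7, 3))
            S = rng.normal(size=(3, 2))
            F = rng.uniform(0.1, 1, size=(6, 2))
            X = G @ S @ F.T
            w = rng.uniform(0.1, 1, 7)
            F2 = cc.update_F(X, w, G, S, F)
            G2 = cc.update_G(X, w, F, S, G)
            np.testing.assert_allclose(F2, F, rtol=1e-6)
            np.testing.assert_allclose(G2, G, rtol=1e-6)

    def test_zero_entry_stays_zero(self):
        rng = np.random.default_rng(6)
        X, w, F, G = random_instance(rng, d=8, n=6, m=3, c=2)
        F[2, 0] = 0.0
        S = cc.update_S(X, w, F, G)
        F2 = cc.update_F(X, w, G, S, F)
        assert F2[2, 0] == 0.0
        G[4, 1] = 0.0
        G2 = cc.update_G(X, w, F, S, G)
        assert G2[4, 1] == 0.0

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(7)
        X, w, F, G = random_instance(rng)
        S = cc.update_S(X, w, F, G)
        assert (cc.update_F(X, w, G, S, F) >= 0).all()
        assert (cc.update_G(X, w, F, S, G) >= 0).all()

    def test_zero_weight_gene_row_zeroes_out(self):
        rng = np.random.default_rng(8)
        X, w, F, G = random_instance(rng, d=8, n=6, m=3, c=2)
        w[3] = 0.0
        S = cc.update_S(X, w, F, G)
        G2 = cc.update_G(X, w, F, S, G)
        np.testing.assert_array_equal(G2[3], 0.0)

    def test_sweep_monotonicity_fuzz(self):
        """J never increases over an S -> F -> G sweep (relative slack 1e-9)."""
        rng = np.random.default_rng(9)
        for _ in range(300):
            X, w, F, G = random_instance(rng)
            for _ in range(3):
                S = cc.update_S(X, w, F, G)
                before = cc.objective(X, w, F, G, S)
                F = cc.update_F(X, w, G, S, F)
                G = cc.update_G(X, w, F, S, G)
                after = cc.objective(X, w, F, G, S)
                assert after <= before * (1 + 1e-9) + 1e-12

    def test_weight_scaling_leaves_iterates_unchanged(self):
        """Multiplying all weights by a constant rescales J but not F, G."""
        rng = np.random.default_rng(10)
        X, w, F, G = random_instance(rng, d=10, n=8, m=3, c=3)
        w = w + 0.05
        S1 = cc.update_S(X, w, F, G)
        S2 = cc.update_S(X, 7.3 * w, F, G)
        np.testing.assert_allclose(S1, S2, rtol=1e-10)
        np.testing.assert_allclose(
            cc.update_F(X, w, G, S1, F), cc.update_F(X, 7.3 * w, G, S2, F), rtol=1e-8)
        np.testing.assert_allclose(
            cc.update_G(X, w, F, S1, G), cc.update_G(X, 7.3 * w, F, S2, G), rtol=1e-8)


class TestHardAssignments:
    def test_argmax_is_one_based(self):
        assert cc.hard_assignments(np.array([[0.2, 0.7, 0.1]]))[0] == 2

    def test_tie_breaks_to_lowest_index(self):
        assert cc.hard_assignments(np.array([[0.5, 0.5]]))[0] == 1

    def test_indicator_matrix_round_trip(self):
        labels = np.array([2, 1, 3, 1])
        P = np.eye(3)[labels - 1]
        np.testing.assert_array_equal(cc.hard_assignments(P), labels)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            cc.hard_assignments(np.array([[-0.1, 0.2]]))


class TestFit:
    def test_planted_recovery(self, planted_2x2):
        X, gl, sl = planted_2x2
        model = cc.fit(X, np.ones(X.shape[0]), m=2, c=2, seed=0)
        assert clustering_accuracy(model.sample_labels, sl + 1) == 1.0
        assert clustering_accuracy(model.gene_labels, gl + 1) == 1.0

    def test_planted_recovery_rate_over_seeds(self, planted_2x2):
        """Noiseless distinct blocks are recovered for >= 95% of seeds."""
        X, gl, sl = planted_2x2
        hits = sum(
            clustering_accuracy(model.sample_labels, sl + 1) == 1.0
            and clustering_accuracy(model.gene_labels, gl + 1) == 1.0
            for model in (cc.fit(X, np.ones(X.shape[0]), m=2, c=2, seed=s)
                          for s in range(20))
        )
        assert hits >= 19

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 10)) + planted_blocks(
            np.array([[0.0, 3.0], [3.0, 0.0]]),
            np.repeat([0, 1], [8, 7]), np.repeat([0, 1], [5, 5]))
        model = cc.fit(X, rng.uniform(0.1, 1, 15), m=2, c=2, seed=3)
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) <= trace[:-1] * 1e-9 + 1e-12).all()

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 9))
        w = rng.uniform(0.1, 1, 12)
        a = cc.fit(X, w, m=3, c=2, seed=42)
        b = cc.fit(X, w, m=3, c=2, seed=42)
        assert (a.F == b.F).all() and (a.G == b.G).all() and (a.S == b.S).all()
        assert a.objective_trace == b.objective_trace

    def test_row_sums_of_returned_factors(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 9))
        model = cc.fit(X, rng.uniform(0.1, 1, 12), m=3, c=2, seed=0, n_init=2)
        np.testing.assert_allclose(model.F.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(model.G.sum(axis=1), 1.0, atol=1e-8)

    def test_zero_weight_genes_flagged_and_uniform(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 8))
        w = rng.uniform(0.5, 1, 10)
        w[[2, 5]] = 0.0
        model = cc.fit(X, w, m=2, c=2, seed=1, n_init=2)
        assert model.zero_weight_genes[[2, 5]].all()
        np.testing.assert_allclose(model.G[2], 0.5)
        np.testing.assert_allclose(model.G[5], 0.5)

    def test_parameter_validation(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError, match="c must"):
            cc.fit(X, np.ones(5), m=2, c=1)
        with pytest.raises(ValueError, match="m must"):
            cc.fit(X, np.ones(5), m=6, c=2)
        with pytest.raises(ValueError, match="weights are zero"):
            cc.fit(X, np.zeros(5), m=2, c=2)
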