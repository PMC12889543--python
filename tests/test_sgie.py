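import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from chiarep import Config, sgie
from conftest import toy_loop_window


class TestCoverageWeight:
    def test_zero_matrix_direct_substitution(self):
        out = sgie.coverage_weight(np.zeros((2, 2)), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(out, [[2, 3], [3, 4]])

    def test_zero_signal_identity(self):
        A = np.array([[0, 2.0], [2.0, 0]])
        np.testing.assert_array_equal(sgie.coverage_weight(A, np.zeros(2)), A)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(3)
        A = rng.poisson(2, (8, 8)).astype(float)
        A = A + A.T
        out = sgie.coverage_weight(A, rng.uniform(0, 5, 8))
        assert np.abs(out - out.T).max() == 0

    def test_support_mode_only_weights_existing_contacts(self):
        A = np.array([[0, 1.0], [1.0, 0]])
        out = sgie.coverage_weight(A, np.array([2.0, 3.0]), mode="support")
        np.testing.assert_array_equal(out, [[0, 6], [6, 0]])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            sgie.coverage_weight(np.zeros((3, 3)), np.zeros(2))


class TestMeanBlur:
    def test_constant_matrix_unchanged(self):
        np.testing.assert_allclose(sgie.mean_blur(np.full((5, 5), 3.0)),
                                   np.full((5, 5), 3.0))

    def test_degenerate_1x1(self):
        np.testing.assert_array_equal(sgie.mean_blur(np.array([[7.0]])), [[7.0]])

    def test_hand_convolution_with_edge_rule(self):
        A = np.zeros((3, 3))
        A[1, 1] = 9.0
        out = sgie.mean_blur(A)
        assert out[1, 1] == pytest.approx(1.0)      # 9 / 9 cells
        assert out[0, 0] == pytest.approx(9 / 4)    # corner: 4 in-bounds cells
        assert out[0, 1] == pytest.approx(9 / 6)    # edge: 6 in-bounds cells

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0, 1, (10, 10))
        A = A + A.T
        out = sgie.mean_blur(A)
        np.testing.assert_allclose(out, out.T, atol=1e-12)


class TestBuildKernel:
    def test_mu_zero_identity(self):
        K = sgie.build_kernel(np.array([[0, 5.0], [5.0, 0]]), 0)
        np.testing.assert_array_equal(K.K, np.eye(2))

    def test_two_node_swap(self):
        A = np.array([[0, 1.0], [1.0, 0]])
        np.testing.assert_allclose(sgie.build_kernel(A, 1).K, A)
        np.testing.assert_allclose(sgie.build_kernel(A, 2).K, np.eye(2))

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (30, 30))
        A = A + A.T
        for mu in (1, 3, 7):
            K = sgie.build_kernel(A, mu)
            np.testing.assert_allclose(K.K.sum(axis=0), np.ones(30), atol=1e-9)

    def test_isolated_node_gives_zero_column(self):
        A = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]])
        K = sgie.build_kernel(A, 1)
        np.testing.assert_array_equal(K.K[:, 2], np.zeros(3))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            sgie.build_kernel(np.array([[0, -1.0], [-1.0, 0]]), 1)

    def test_kernel_composition(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0, 1, (20, 20))
        A = A + A.T
        K5 = sgie.build_kernel(A, 5).K
        K2 = sgie.build_kernel(A, 2).K
        K3 = sgie.build_kernel(A, 3).K
        np.testing.assert_allclose(K5, K2 @ K3, atol=1e-9)


class TestNormalizeAndWalk:
    def test_normalization_examples(self):
        np.testing.assert_allclose(sgie.normalize_signal(np.array([2.0, 2.0])).values,
                                   [0.5, 0.5])
        np.testing.assert_allclose(sgie.normalize_signal(np.array([1.0, 3.0])).values,
                                   [0.25, 0.75])

    def test_zero_signal_degenerate(self):
        pi = sgie.normalize_signal(np.zeros(4))
        assert pi.degenerate

    def test_identity_kernel_leaves_signal(self):
        pi = sgie.normalize_signal(np.array([1.0, 3.0]))
        K = sgie.build_kernel(np.array([[0, 1.0], [1.0, 0]]), 0)
        np.testing.assert_array_equal(sgie.random_walk(pi, K).values, pi.values)

    def test_swap_kernel_moves_mass(self):
        pi = sgie.ProbabilitySignal(np.array([1.0, 0.0]))
        K = sgie.build_kernel(np.array([[0, 1.0], [1.0, 0]]), 1)
        np.testing.assert_allclose(sgie.random_walk(pi, K).values, [0.0, 1.0])

    def test_uniform_stationary_on_regular_graph(self):
        # 4-cycle: every node has degree 2, uniform is stationary
        A = np.zeros((4, 4))
        for i in range(4):
            A[i, (i + 1) % 4] = A[(i + 1) % 4, i] = 1.0
        pi = sgie.ProbabilitySignal(np.full(4, 0.25))
        for mu in (1, 2, 5):
            out = sgie.random_walk(pi, sgie.build_kernel(A, mu))
            np.testing.assert_allclose(out.values, np.full(4, 0.25), atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(float, (12,), elements=st.floats(0.1, 100.0)),
           st.integers(0, 10))
    def test_conservation_for_positive_signal(self, b, mu):
        # positive signal guarantees positive degrees after coverage weighting
        rng = np.random.default_rng(12)
        A = rng.poisson(1, (12, 12)).astype(float)
        A = A + A.T
        pi = sgie.process_window(A, b, Config(mu=mu))
        assert abs(pi.values.sum() - 1.0) < 1e-9
        assert not pi.degenerate

    def test_matrix_power_equals_iterated_steps(self):
        rng = np.random.default_rng(13)
        A = rng.uniform(0, 1, (50, 50))
        A = A + A.T
        b = rng.uniform(0.1, 10, 50)
        mu = 6
        pi0 = sgie.normalize_signal(b)
        direct = sgie.random_walk(pi0, sgie.build_kernel(A, mu)).values
        step = sgie.build_kernel(A, 1)
        iterated = pi0
        for _ in range(mu):
            iterated = sgie.random_walk(iterated, step)
        np.testing.assert_allclose(direct, iterated.values, atol=1e-9)

    def test_tv_distance_to_limit_nonincreasing(self):
        # connected aperiodic toy graph: walk converges monotonically to the
        # degree-proportional limiting distribution
        rng = np.random.default_rng(14)
        A = rng.uniform(0.05, 1, (10, 10))
        A = A + A.T
        deg = A.sum(axis=0)
        limit = deg / deg.sum()
        pi0 = sgie.normalize_signal(rng.uniform(0.1, 5, 10))
        tvs = []
        for mu in range(11):
            out = sgie.random_walk(pi0, sgie.build_kernel(A, mu))
            tvs.append(0.5 * np.abs(out.values - limit).sum())
        assert all(tvs[k + 1] <= tvs[k] + 1e-12 for k in range(10))


class TestProcessWindow:
    def test_mu_zero_zero_matrix_reduces_to_normalized_signal(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        pi = sgie.process_window(np.zeros((4, 4)), b, Config(mu=0))
        np.testing.assert_allclose(pi.values, b / b.sum())

    def test_determinism(self):
        rng = np.random.default_rng(15)
        A = rng.poisson(3, (30, 30)).astype(float)
        A = A + A.T
        b = rng.poisson(10, 30).astype(float)
        p1 = sgie.process_window(A, b, Config(mu=5))
        p2 = sgie.process_window(A, b, Config(mu=5))
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_loop_disperses_signal_to_partner_bin(self):
        # delta spike at one loop anchor: with growing mu, mass reaches the
        # loop partner faster than an equidistant-in-1D control bin
        A = toy_loop_window(n_bins=20, loop=(3, 16), loop_strength=50.0)
        b = np.zeros(20)
        b[3] = 100.0
        b += 1e-6  # keep degrees positive without altering the spike
        cfg = Config(mu=4, coverage_weight_mode="support")
        pi = sgie.process_window(A, b, cfg)
        partner, control = 16, 10  # both far from bin 3 along the genome
        assert pi.values[partner] > pi.values[control]
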