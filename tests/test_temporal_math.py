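"""Attention mathematics: damping matrix, alignment, decomposition.

Vectorized implementations are checked against explicit scalar-loop
oracles on small random instances.
"""

import numpy as np
import pytest

from attcrispr import temporal
from attcrispr.errors import NotFittedError


def random_seqs(n, length=21, seed=0):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


class TestDampingMatrix:
    def test_diagonal_symmetry_and_range(self):
        g = temporal.build_damping_matrix(21, 3.0)
        np.testing.assert_array_equal(np.diag(g), np.ones(21))
        np.testing.assert_array_equal(g, g.T)
        assert ((g >= 0) & (g <= 1)).all()

    def test_hard_cutoff_beyond_sigma(self):
        g = temporal.build_damping_matrix(21, 3.0)
        assert g[0, 5] == 0.0  # |i-j| = 5 > sigma = 3
        d = np.abs(np.subtract.outer(np.arange(21), np.arange(21)))
        assert (g[d > 3] == 0).all()
        assert (g[(d <= 3)] > 0).all()

    def test_closed_form_cell(self):
        g = temporal.build_damping_matrix(10, 2.0)
        # exp(-(1)^2 / (2*2)) — the Gaussian divides by 2*sigma, a length
        # threshold, not a variance
        assert g[3, 4] == pytest.approx(np.exp(-0.25), abs=1e-12)
        assert g[3, 4] == pytest.approx(0.77880, abs=1e-5)

    def test_monotone_decay_within_band(self):
        g = temporal.build_damping_matrix(15, 4.0)
        row = g[7]
        for d in range(1, 4):
            assert row[7 + d] < row[7 + d - 1]

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            temporal.build_damping_matrix(21, 0.0)
        with pytest.raises(ValueError):
            temporal.build_damping_matrix(21, -1.0)


class TestAlign:
    def test_rows_sum_to_one_without_damping(self):
        rng = np.random.default_rng(1)
        q, k = rng.normal(size=(2, 7, 4))
        b = temporal.align(q, k, np.ones((7, 7)))
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_scores_give_uniform_rows(self):
        k = np.zeros((6, 3))
        q = np.random.default_rng(2).normal(size=(6, 3))
        b = temporal.align(q, k, np.ones((6, 6)))
        np.testing.assert_allclose(b, 1.0 / 6, atol=1e-12)

    def test_band_structure_and_row_sums(self):
        rng = np.random.default_rng(3)
        g = temporal.build_damping_matrix(9, 2.0)
        q, k = rng.normal(size=(2, 9, 5))
        b = temporal.align(q, k, g)
        assert (b[g == 0] == 0).all()
        assert (b >= 0).all()
        assert (b.sum(axis=1) <= 1 + 1e-12).all()

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            q, k = rng.normal(size=(2, 5, 3))
            g = temporal.build_damping_matrix(5, float(rng.uniform(1, 4)))
            expected = np.zeros((5, 5))
            for i in range(5):
                scores = [sum(q[i][d] * k[j][d] for d in range(3)) for j in range(5)]
                exps = [np.exp(s) for s in scores]
                total = sum(exps)
                for j in range(5):
                    expected[i][j] = exps[j] / total * g[i][j]
            np.testing.assert_allclose(temporal.align(q, k, g), expected, atol=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            temporal.align(np.zeros((5, 3)), np.zeros((4, 3)), np.ones((5, 5)))


class TestFirstOrder:
    def test_identity_alignment_returns_values(self):
        v = np.random.default_rng(5).normal(size=(6, 4))
        np.testing.assert_allclose(temporal.first_order(np.eye(6), v), v, atol=0)

    def test_selector_row(self):
        v = np.random.default_rng(6).normal(size=(5, 3))
        b = np.zeros((5, 5))
        b[2, 4] = 1.0
        np.testing.assert_allclose(temporal.first_order(b, v)[2], v[4], atol=0)

    def test_matches_loop_oracle_with_projection(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            b = rng.uniform(0, 1, size=(5, 5))
            v = rng.normal(size=(5, 3))
            proj = rng.normal(size=(3, 4))
            expected = np.zeros((5, 4))
            for i in range(5):
                for d in range(4):
                    expected[i, d] = sum(
                        b[i, j] * v[j, h] * proj[h, d] for j in range(5) for h in range(3)
                    )
            np.testing.assert_allclose(temporal.first_order(b, v, proj), expected, atol=1e-10)


class TestPositionScores:
    def test_null_preference(self):
        ps = temporal.position_scores(np.zeros((21, 4)), np.ones((21, 4)), np.ones(21))
        np.testing.assert_array_equal(ps.values, 0.0)
        assert ps.baseline == 0.0

    def test_selector_weight(self):
        rng = np.random.default_rng(8)
        atilde, xe = rng.normal(size=(2, 21, 4))
        w = np.zeros(21)
        w[4] = 1.0
        ps = temporal.position_scores(atilde, xe, w)
        assert np.count_nonzero(ps.values) == 1
        assert ps.values[4] == pytest.approx(np.dot(atilde[4], xe[4]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            temporal.position_scores(np.zeros((3, 2)), np.zeros((3, 2)), np.array([1.0, -0.1, 0.2]))


class TestEncoderDecoder:
    def test_values_equal_keys_and_shapes(self):
        tp = temporal.init_temporal_params(seed=0)
        xe = np.random.default_rng(9).normal(size=(21, 32))
        k, q, v = temporal.encode_decode(xe, tp)
        np.testing.assert_array_equal(k, v)
        assert k.shape == (21, 64) and q.shape == (21, 64)

    def test_zero_parameter_network_gives_zero_states(self):
        tp = temporal.init_temporal_params(seed=0)
        for name, t in tp.params.items():
            t.data[...] = 0.0
        k, q, _ = temporal.encode_decode(np.ones((21, 32)), tp)
        np.testing.assert_array_equal(k, 0.0)
        np.testing.assert_array_equal(q, 0.0)


class TestForward:
    def test_output_range_and_determinism(self):
        tp = temporal.init_temporal_params(seed=1)
        seqs = random_seqs(20, seed=10)
        out1 = temporal.temporal_forward(seqs, tp)
        out2 = temporal.temporal_forward(seqs, tp)
        assert ((out1 > 0) & (out1 < 1)).all()
        np.testing.assert_array_equal(out1, out2)

    def test_not_fitted(self):
        empty = temporal.TemporalParams(params={})
        with pytest.raises(NotFittedError):
            temporal.temporal_forward("A" * 21, empty)

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_decomposition_ties_to_presigmoid(self, seed):
        """Sum of per-position scores equals the pre-sigmoid temporal output."""
        rng = np.random.default_rng(seed)
        cfg = temporal.TemporalConfig(hidden=int(rng.integers(2, 8)), m=int(rng.integers(2, 10)))
        tp = temporal.init_temporal_params(cfg, seed=seed)
        for s in random_seqs(10, seed=100 + seed):
            det = temporal.temporal_details(s, tp)
            assert det["position_scores"].sum() == pytest.approx(det["pre_sigmoid"], abs=1e-10)
            assert det["y"] == pytest.approx(1 / (1 + np.exp(-det["pre_sigmoid"])), abs=1e-12)

    def test_details_band_matches_damping(self):
        cfg = temporal.TemporalConfig(sigma=2.0)
        tp = temporal.init_temporal_params(cfg, seed=3)
        det = temporal.temporal_details(random_seqs(1, seed=11)[0], tp)
        g = tp.damping
        assert (det["B"][g == 0] == 0).all()
        # consistency of the graph with the public numpy operations
        b_np = temporal.align(det["Q"], det["K"], g)
        np.testing.assert_allclose(det["B"], b_np, atol=1e-10)
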