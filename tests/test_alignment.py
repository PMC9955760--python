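"""Givens angles, QR and Procrustes alignment, orientation recursion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import orthogonal_procrustes
from scipy.stats import special_ortho_group

from temporalign import (OrientationModel, align_series, angle_matrices,
                         givens_angles, givens_qr_alignment, orientation_step,
                         procrustes_alignment)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                   allow_infinity=False)


class TestGivensAngles:
    def test_b_zero_branch(self):
        assert givens_angles(5.0, 0.0) == (1.0, 0.0)
        assert givens_angles(0.0, 0.0) == (1.0, 0.0)
        assert givens_angles(-2.5, 0.0) == (1.0, 0.0)

    def test_three_four_hand_case(self):
        cos_a, cos_b = givens_angles(3.0, 4.0)
        assert cos_a == pytest.approx(-0.6, abs=1e-15)
        assert cos_b == pytest.approx(0.8, abs=1e-15)

    @given(finite, finite)
    def test_unit_norm_identity(self, a, b):
        cos_a, cos_b = givens_angles(a, b)
        assert cos_a ** 2 + cos_b ** 2 == pytest.approx(1.0, abs=1e-12)


class TestAngleMatrices:
    def test_zero_second_step(self):
        X = np.random.default_rng(0).random((4, 3))
        ang = angle_matrices(X, np.zeros_like(X))
        assert np.all(ang.theta_cos_alpha == 1.0)
        assert np.all(ang.theta_cos_beta == 0.0)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        Xt, Xt1 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        Xt1[2, 1] = 0.0  # exercise the b = 0 branch
        ang = angle_matrices(Xt, Xt1)
        for v in range(5):
            for i in range(3):
                ca, cb = givens_angles(Xt[v, i], Xt1[v, i])
                assert ang.theta_cos_alpha[v, i] == pytest.approx(ca, abs=1e-14)
                assert ang.theta_cos_beta[v, i] == pytest.approx(cb, abs=1e-14)

    def test_shapes_and_mismatch(self):
        rng = np.random.default_rng(2)
        ang = angle_matrices(rng.random((6, 4)), rng.random((6, 4)))
        assert ang.theta_cos_alpha.shape == (6, 4)
        with pytest.raises(ValueError, match="shape mismatch"):
            angle_matrices(rng.random((6, 4)), rng.random((5, 4)))


class TestGivensQR:
    def test_qr_of_identity(self):
        from temporalign.alignment import _qr_nonneg

        Q, R = _qr_nonneg(np.eye(3))
        assert np.allclose(Q, np.eye(3)) and np.allclose(R, np.eye(3))

    def test_orthogonal_on_equal_inputs(self):
        X = np.eye(3)
        op = givens_qr_alignment(X, X)
        assert np.allclose(op.Q.T @ op.Q, np.eye(3), atol=1e-12)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Xt, Xt1 = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
            op = givens_qr_alignment(Xt, Xt1)
            ang = angle_matrices(Xt, Xt1)
            C = ang.theta_cos_beta.T @ ang.theta_cos_alpha
            assert np.abs(op.Q @ op.R_upper - C).max() < 1e-8
            assert np.abs(op.Q.T @ op.Q - np.eye(4)).max() < 1e-8
            assert np.all(np.diag(op.R_upper) >= 0)

    def test_rank_deficient_still_orthogonal(self):
        # duplicate features make C rank-deficient
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 1))
        Xt = np.hstack([base, base, rng.normal(size=(6, 1))])
        Xt1 = np.hstack([base * 2, base * 2, rng.normal(size=(6, 1))])
        op = givens_qr_alignment(Xt, Xt1)
        assert np.abs(op.Q.T @ op.Q - np.eye(3)).max() < 1e-8

    def test_nonfinite_error(self):
        X = np.ones((3, 2))
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            givens_qr_alignment(X, bad)


def _residual(Xt, Xt1, Q):
    return np.linalg.norm(Xt1 @ Q - Xt)


class TestProcrustes:
    def test_identity_when_equal(self):
        X = np.random.default_rng(5).normal(size=(8, 3))
        op = procrustes_alignment(X, X)
        assert np.allclose(op.Q, np.eye(3), atol=1e-10)

    def test_recovers_planted_rotation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        R0 = special_ortho_group.rvs(5, random_state=7)
        op = procrustes_alignment(X, X @ R0)
        assert np.allclose(op.Q, R0.T, atol=1e-10)
        assert _residual(X, X @ R0, op.Q) < 1e-10

    def test_beats_random_orthogonal_candidates(self):
        rng = np.random.default_rng(8)
        Xt, Xt1 = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        op = procrustes_alignment(Xt, Xt1)
        res = _residual(Xt, Xt1, op.Q)
        assert res <= _residual(Xt, Xt1, np.eye(3))
        cands = special_ortho_group.rvs(3, size=100, random_state=9)
        for Qc in cands:
            assert res <= _residual(Xt, Xt1, Qc) + 1e-12

    def test_matches_scipy_closed_form(self):
        rng = np.random.default_rng(10)
        Xt, Xt1 = rng.normal(size=(15, 4)), rng.normal(size=(15, 4))
        op = procrustes_alignment(Xt, Xt1)
        Q_ref, _ = orthogonal_procrustes(Xt1, Xt)
        assert np.allclose(op.Q, Q_ref, atol=1e-10)

    def test_residual_rotation_invariant(self):
        rng = np.random.default_rng(11)
        Xt, Xt1 = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        S = special_ortho_group.rvs(4, random_state=12)
        r1 = _residual(Xt, Xt1, procrustes_alignment(Xt, Xt1).Q)
        r2 = _residual(Xt @ S, Xt1 @ S,
                       procrustes_alignment(Xt @ S, Xt1 @ S).Q)
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestAlignSeries:
    def test_equal_steps_give_identity(self, small_series):
        from temporalign import StaticEmbeddingSeries

        X = small_series.X[0]
        series = StaticEmbeddingSeries(X=[X, X.copy()])
        aligned, ops = align_series(series, "procrustes")
        assert len(ops) == 1
        assert np.allclose(ops[0].Q, np.eye(X.shape[1]), atol=1e-8)
        assert np.allclose(aligned.X[1], X, atol=1e-8)

    def test_operator_count(self, small_series):
        _, ops = align_series(small_series, "givens_qr")
        assert len(ops) == small_series.T - 1

    def test_procrustes_reduces_drift_on_constant_graph(self, constant_snapshots):
        """Same graph + fresh per-step weights: aligned consecutive steps
        are closer than unaligned ones."""
        from temporalign import DecayConfig, EmbedConfig, embed_series

        series = embed_series(constant_snapshots, EmbedConfig(d=10),
                              DecayConfig())
        aligned, _ = align_series(series, "procrustes")

        def drift(S):
            return np.mean([np.linalg.norm(S.X[t + 1] - S.X[t], axis=1).mean()
                            for t in range(S.T - 1)])

        assert drift(aligned) < drift(series)

    def test_unknown_method_errors(self, small_series):
        with pytest.raises(ValueError, match="unknown alignment"):
            align_series(small_series, "nope")


class TestOrientationStep:
    def test_zero_matrices_give_zero(self):
        model = OrientationModel(A=np.zeros((2, 2)), B=np.zeros((2, 2)))
        out = orientation_step(model, np.ones(2), np.ones(2), np.eye(2))
        assert np.array_equal(out, np.zeros(2))

    def test_elementwise_tanh_case(self):
        model = OrientationModel(A=np.random.default_rng(0).normal(size=(2, 2)),
                                 B=np.eye(2))
        out = orientation_step(model, np.zeros(2), np.array([0.1, -0.2]),
                               np.eye(2))
        assert out[0] == pytest.approx(0.099668, abs=1e-6)
        assert out[1] == pytest.approx(-0.197375, abs=1e-6)

    def test_output_strictly_inside_unit_box(self):
        rng = np.random.default_rng(13)
        model = OrientationModel.init(6, rng=1)
        out = orientation_step(model, rng.normal(size=6),
                               rng.normal(size=6))
        assert np.all(np.abs(out) < 1.0)

    def test_dimension_mismatch(self):
        model = OrientationModel.init(3, rng=0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            orientation_step(model, np.zeros(4), np.zeros(3))
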