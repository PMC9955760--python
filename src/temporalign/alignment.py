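"""Orthogonal alignment of consecutive embedding steps.

Because every step's embedding comes from an independent random projection,
consecutive latent-position matrices live in unrelated bases.  Two
alignment operators are provided:

* ``procrustes_alignment`` — the classical orthogonal Procrustes solution
  (SVD closed form) minimizing ||X_{t+1} Q - X_t||_F over orthogonal Q.
* ``givens_qr_alignment`` — a per-feature Givens-angle scheme: each
  (node, feature) pair of scalars across the two steps yields a rotation
  pair (cos a, cos b); the angle matrices are contracted into a d x d
  matrix C = Theta_cosb^T Theta_cosa whose QR factor Q serves as the
  alignment operator.

``align_series`` chains either operator along the series, and
``orientation_step`` applies the tanh orientation recursion
l_{t+1}(v) = tanh(A l_t(v) + B Q_t x_t(v)) whose A, B matrices are trained
jointly with the link predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .embedding import StaticEmbeddingSeries

__all__ = [
    "AngleMatrices",
    "AlignmentOperator",
    "OrientationModel",
    "givens_angles",
    "angle_matrices",
    "givens_qr_alignment",
    "procrustes_alignment",
    "align_series",
    "orientation_step",
]


@dataclass
class AngleMatrices:
    """Per-(node, feature) Givens rotation cosines; each pair is unit-norm."""

    theta_cos_alpha: np.ndarray
    theta_cos_beta: np.ndarray

    def __post_init__(self):
        norm = self.theta_cos_alpha ** 2 + self.theta_cos_beta ** 2
        if not np.allclose(norm, 1.0, atol=1e-10):
            raise ValueError("angle matrices violate cos^2 a + cos^2 b = 1")


@dataclass
class AlignmentOperator:
    """A d x d orthogonal operator relating steps (t, t+1)."""

    Q: np.ndarray
    method: str
    step: Tuple[int, int] = (0, 1)
    R_upper: Optional[np.ndarray] = None

    def __post_init__(self):
        d = self.Q.shape[0]
        err = np.abs(self.Q.T @ self.Q - np.eye(d)).max()
        if err > 1e-8:
            raise ValueError(f"Q is not orthogonal (max |Q^T Q - I| = {err:g})")


def givens_angles(a: float, b: float) -> Tuple[float, float]:
    """Rotation cosines for the scalar pair (x at t, x at t+1).

    Branches on which scalar dominates so the intermediate ratio stays in
    [-1, 1]; the b = 0 branch (including a = b = 0) returns (1, 0).  The
    pair always satisfies cos^2 a + cos^2 b = 1.
    """
    if b == 0:
        return 1.0, 0.0
    if abs(b) > abs(a):
        tmp = -a / b
        cos_b = 1.0 / np.sqrt(1.0 + tmp * tmp)
        cos_a = tmp * cos_b
    else:
        tmp = -b / a
        cos_a = 1.0 / np.sqrt(1.0 + tmp * tmp)
        cos_b = tmp * cos_a
    return float(cos_a), float(cos_b)


def angle_matrices(X_t: np.ndarray, X_t1: np.ndarray) -> AngleMatrices:
    """Vectorized entrywise `givens_angles` over two (n, d) matrices."""
    X_t = np.asarray(X_t, dtype=float)
    X_t1 = np.asarray(X_t1, dtype=float)
    if X_t.shape != X_t1.shape:
        raise ValueError(f"shape mismatch: {X_t.shape} vs {X_t1.shape}")
    a, b = X_t, X_t1
    cos_a = np.ones_like(a)
    cos_b = np.zeros_like(a)

    m1 = (b != 0) & (np.abs(b) > np.abs(a))          # t+1 dominates
    with np.errstate(divide="ignore", invalid="ignore"):
        tmp1 = -a / b
        cb = 1.0 / np.sqrt(1.0 + tmp1 * tmp1)
        cos_b = np.where(m1, cb, cos_b)
        cos_a = np.where(m1, tmp1 * cb, cos_a)

        m2 = (b != 0) & ~m1                           # t dominates (a != 0)
        tmp2 = -b / a
        ca = 1.0 / np.sqrt(1.0 + tmp2 * tmp2)
        cos_a = np.where(m2, ca, cos_a)
        cos_b = np.where(m2, tmp2 * ca, cos_b)
    return AngleMatrices(theta_cos_alpha=cos_a, theta_cos_beta=cos_b)


def _qr_nonneg(C: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """QR with the sign convention diag(R) >= 0 (makes Q unique)."""
    Q, R = np.linalg.qr(C)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    return Q * sign, sign[:, None] * R


def givens_qr_alignment(X_t: np.ndarray, X_t1: np.ndarray,
                        step: Tuple[int, int] = (0, 1)) -> AlignmentOperator:
    """Alignment operator from the per-feature angle matrices.

    C = Theta_cosb^T Theta_cosa summarizes how each feature's orientation
    rotated between the steps; its orthogonal QR factor (diag(R) >= 0) is
    returned as the operator.
    """
    if not (np.all(np.isfinite(X_t)) and np.all(np.isfinite(X_t1))):
        raise ValueError("embedding matrices contain non-finite entries")
    ang = angle_matrices(X_t, X_t1)
    C = ang.theta_cos_beta.T @ ang.theta_cos_alpha
    Q, R = _qr_nonneg(C)
    return AlignmentOperator(Q=Q, method="givens_qr", step=step, R_upper=R)


def procrustes_alignment(X_t: np.ndarray, X_t1: np.ndarray,
                         step: Tuple[int, int] = (0, 1)) -> AlignmentOperator:
    """Orthogonal Procrustes: Q = argmin ||X_{t+1} Q - X_t||_F, Q^T Q = I.

    Closed form Q = U V^T from the SVD of X_{t+1}^T X_t.
    """
    X_t = np.asarray(X_t, dtype=float)
    X_t1 = np.asarray(X_t1, dtype=float)
    if X_t.shape != X_t1.shape:
        raise ValueError(f"shape mismatch: {X_t.shape} vs {X_t1.shape}")
    if not (np.all(np.isfinite(X_t)) and np.all(np.isfinite(X_t1))):
        raise ValueError("embedding matrices contain non-finite entries")
    U, _, Vt = np.linalg.svd(X_t1.T @ X_t)
    return AlignmentOperator(Q=U @ Vt, method="procrustes", step=step)


def align_series(series: StaticEmbeddingSeries, method: str = "givens_qr"
                 ) -> Tuple[StaticEmbeddingSeries, List[AlignmentOperator]]:
    """Chain-align a series: X'_1 = X_1, X'_{t+1} = X_{t+1} Q_{t+1},
    where Q_{t+1} aligns X_{t+1} to the already-aligned X'_t.
    """
    if series.T < 2:
        raise ValueError("alignment needs at least two steps")
    if method == "none":
        return series, []
    fn = {"givens_qr": givens_qr_alignment,
          "procrustes": procrustes_alignment}.get(method)
    if fn is None:
        raise ValueError(f"unknown alignment method {method!r}")
    aligned = [series.X[0]]
    ops: List[AlignmentOperator] = []
    for t in range(1, series.T):
        op = fn(aligned[-1], series.X[t], step=(t - 1, t))
        aligned.append(series.X[t] @ op.Q)
        ops.append(op)
    out = StaticEmbeddingSeries(X=aligned, variant=series.variant,
                                provenance={**series.provenance,
                                            "alignment": method})
    return out, ops


@dataclass
class OrientationModel:
    """Learnable d x d matrices of the tanh orientation recursion.

    l_0(v) = 0; l_{t+1}(v) = tanh(A l_t(v) + B Q_t x_t(v)).  A and B are
    updated only by the link-prediction training loop.
    """

    A: np.ndarray
    B: np.ndarray

    @classmethod
    def init(cls, d: int, rng=None) -> "OrientationModel":
        rng = np.random.default_rng(rng)
        s = 1.0 / np.sqrt(d)
        return cls(A=rng.normal(0, s, (d, d)), B=rng.normal(0, s, (d, d)))


def orientation_step(model: OrientationModel, l_t: np.ndarray,
                     x_t: np.ndarray, Q_t: Optional[np.ndarray] = None
                     ) -> np.ndarray:
    """One orientation update for a single node (column-vector convention)."""
    l_t = np.asarray(l_t, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    d = model.A.shape[0]
    if l_t.shape[-1] != d or x_t.shape[-1] != model.B.shape[1]:
        raise ValueError(
            f"dimension mismatch: A {model.A.shape}, B {model.B.shape}, "
            f"l_t {l_t.shape}, x_t {x_t.shape}")
    rotated = x_t if Q_t is None else Q_t @ x_t
    return np.tanh(model.A @ l_t + model.B @ rotated)
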