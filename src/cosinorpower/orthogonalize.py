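"""Partitioned-regression orthogonalization (Frisch–Waugh–Lovell).

The reduction in sum of squares between the null model (nuisance block
``X1`` only) and the full model ``[X1 X2]`` is *not* the naive
quadratic form ``b2' X2'X2 b2`` unless ``X1'X2 = 0``: the nuisance
estimate changes between the nested fits whenever the rhythmic columns
are correlated with the nuisances.  Replacing ``X2`` by its residual
after projecting out ``X1``,

    Z2 = (I - X1 (X1'X1)^{-1} X1') X2,

makes the two blocks orthogonal without changing the column span, so

    SSE_null - SSE_full = b2_hat' Z2'Z2 b2_hat,

and the noncentrality parameter of the F-test under an alternative
``beta2`` is the population version of the same quadratic form,

    delta^2 = beta2' Z2'Z2 beta2 / sigma^2.

For the standard cosinor model (``X1`` = intercept) this machinery
collapses to column-centering of the cosine/sine block, but it holds
for any nuisance matrix — trends, blocks, batch indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankError, ValidationError

__all__ = ["Reparameterization", "orthogonalize", "general_ncp", "ss_reduction"]

#: Relative tolerance (scaled by ||X2||) for asserting X1'Z2 = 0.
ORTHOGONALITY_RTOL = 1e-8


@dataclass(frozen=True)
class Reparameterization:
    """The orthogonalized parameterization of a partitioned linear model.

    Attributes
    ----------
    Z2
        Rhythmic block with the projection onto ``X1`` removed;
        satisfies ``X1' Z2 = 0``.
    U
        Block upper-triangular change-of-basis matrix with
        ``X @ U = [X1 Z2]``; the rhythmic coefficients ``beta2`` are
        identical in both parameterizations.
    D
        Gram matrix of ``[X1 Z2]``; block-diagonal by construction.
    """

    X1: np.ndarray
    X2: np.ndarray
    Z2: np.ndarray
    U: np.ndarray
    D: np.ndarray

    def lambda_of(self, beta1: np.ndarray, beta2: np.ndarray) -> np.ndarray:
        """Reparameterized nuisance coefficients lambda = beta1 + (X1'X1)^{-1}X1'X2 beta2."""
        G = np.linalg.solve(self.X1.T @ self.X1, self.X1.T @ self.X2)
        return np.asarray(beta1, dtype=float) + G @ np.asarray(beta2, dtype=float)


def _solve_projection(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Coefficients G of the regression of each X2 column on X1, via QR."""
    Q, R = np.linalg.qr(X1)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or np.min(diag) <= np.max(diag, initial=0.0) * X1.shape[0] * np.finfo(float).eps:
        raise RankError("nuisance matrix X1 is rank deficient")
    return np.linalg.solve(R, Q.T @ X2)


def orthogonalize(X1: np.ndarray, X2: np.ndarray) -> Reparameterization:
    """Project ``X1`` out of ``X2`` and package the reparameterization.

    For ``X1`` a lone intercept column this is exactly column-centering
    of ``X2``.  The projector is applied through a QR factorization of
    ``X1`` rather than explicit normal equations.

    Raises
    ------
    RankError
        If ``X1`` is rank deficient, or if the computed ``Z2`` fails
        the orthogonality check ``X1'Z2 = 0`` at relative tolerance
        ``1e-8 * ||X2||``.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[0] != X2.shape[0]:
        raise ValidationError(f"X1 has {X1.shape[0]} rows, X2 has {X2.shape[0]}")
    G = _solve_projection(X1, X2)  # q x 2
    Z2 = X2 - X1 @ G
    scale = np.linalg.norm(X2)
    if np.abs(X1.T @ Z2).max() > ORTHOGONALITY_RTOL * max(scale, 1e-300):
        raise RankError("orthogonalization failed: X1'Z2 not numerically zero")
    q, k = X1.shape[1], X2.shape[1]
    U = np.block([
        [np.eye(q), -G],
        [np.zeros((k, q)), np.eye(k)],
    ])
    W = np.hstack([X1, Z2])
    return Reparameterization(X1=X1, X2=X2, Z2=Z2, U=U, D=W.T @ W)


def general_ncp(X1: np.ndarray, X2: np.ndarray, beta2, sigma: float) -> float:
    """Noncentrality parameter delta^2 = beta2' Z2'Z2 beta2 / sigma^2.

    Valid for any full-rank nuisance block ``X1``; with ``X1`` an
    intercept column it reduces to the standard cosinor closed form
    ``n * A^2 * sigma2_cosinor / sigma^2``.
    """
    if not sigma > 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    rep = orthogonalize(X1, X2)
    b2 = np.asarray(beta2, dtype=float).ravel()
    v = rep.Z2 @ b2
    return float(v @ v) / float(sigma) ** 2


def ss_reduction(y: np.ndarray, X1: np.ndarray, X2: np.ndarray) -> tuple[float, float]:
    """Reduction in SSE between nested fits, two ways.

    Returns ``(delta_ss, quadratic_form)`` where ``delta_ss`` is
    ``SSE_null - SSE_full`` from direct least-squares fits and
    ``quadratic_form`` is ``b2_hat' Z2'Z2 b2_hat``.  The two agree for
    every full-rank design; the naive ``b2_hat' X2'X2 b2_hat`` agrees
    only when ``X1'X2 = 0``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    X = np.hstack([X1, X2])
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= sv[0] * max(X.shape) * np.finfo(float).eps:
        raise RankError("[X1 X2] is rank deficient")
    beta_full, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    beta_null, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    sse_full = float(np.sum((y - X @ beta_full) ** 2))
    sse_null = float(np.sum((y - X1 @ beta_null) ** 2))
    rep = orthogonalize(X1, X2)
    b2 = beta_full[X1.shape[1]:]
    v = rep.Z2 @ b2
    return sse_null - sse_full, float(v @ v)
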