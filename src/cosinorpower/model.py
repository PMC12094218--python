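"""Cosinor design matrices, least-squares fitting and the F-test.

The standard cosinor model regresses a measured variable on an
intercept plus cosine and sine terms at a known period,

    y_i = m + a1*cos(w*t_i) + a2*sin(w*t_i) + eps_i,   eps_i ~ N(0, s^2),

with mesor ``m``, amplitude ``A = sqrt(a1^2 + a2^2)`` and acrophase
``phi = atan2(a2, a1)``.  Rhythm detection tests a1 = a2 = 0 with the
nested-model F statistic

    F = ((SSE_null - SSE_full)/(p - q)) / (SSE_full/(n - p)),

p = 3 and q = 1 for the standard model, which is central F(2, n-3)
under the null.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import SamplingDesign
from .errors import DesignFileError, InsufficientDataError, RankError, ValidationError

__all__ = [
    "CosinorEffect",
    "DesignMatrices",
    "CosinorFit",
    "TestDecision",
    "build_matrices",
    "fit_cosinor",
    "fit_cosinor_batch",
    "f_test",
    "read_measurements_csv",
    "ConditionNumberWarning",
]

#: Condition number above which a warning is issued for the full design
#: matrix; tightly clustered schedules are ill-conditioned by construction.
CONDITION_WARN = 1e8


class ConditionNumberWarning(UserWarning):
    """The design matrix is poorly conditioned; estimates may be unstable."""


@dataclass(frozen=True)
class CosinorEffect:
    """Effect size of a cosinor rhythm: (mesor, amplitude, acrophase, noise SD).

    The rectangular coefficients are ``a1 = A*cos(phi)`` and
    ``a2 = A*sin(phi)``; only the ratio ``A/sigma`` matters for the
    noncentrality parameter and hence power.
    """

    mesor: float
    amplitude: float
    phi: float
    sigma: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")

    @property
    def a1(self) -> float:
        return self.amplitude * math.cos(self.phi)

    @property
    def a2(self) -> float:
        return self.amplitude * math.sin(self.phi)

    @property
    def snr(self) -> float:
        """Amplitude-to-noise ratio A/sigma."""
        return self.amplitude / self.sigma

    @classmethod
    def from_rect(cls, mesor: float, a1: float, a2: float, sigma: float) -> "CosinorEffect":
        """Build from rectangular coefficients (a1, a2) instead of (A, phi)."""
        return cls(mesor=mesor, amplitude=math.hypot(a1, a2), phi=math.atan2(a2, a1), sigma=sigma)

    def signal(self, design: SamplingDesign) -> np.ndarray:
        """Noise-free mean response m + A*cos(w*t - phi) at the design times."""
        return self.mesor + self.amplitude * np.cos(design.phases() - self.phi)

    def peak_time(self) -> float:
        """Peak (acrophase) time in hours modulo the period — requires a period context.

        Provided for convenience as ``phi`` per radian; use
        ``phi / design.omega % design.period`` for a specific design.
        """
        return self.phi


@dataclass(frozen=True)
class DesignMatrices:
    """The partitioned cosinor design matrix X = [X1 | X2].

    ``X1`` holds the non-rhythmic columns (intercept, plus optional
    nuisance covariates such as trends or batch indicators); ``X2``
    holds the cosine and sine columns.  Standard cosinor: q = 1, p = 3.
    """

    X1: np.ndarray
    X2: np.ndarray

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.X1, self.X2])

    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def q(self) -> int:
        return self.X1.shape[1]

    @property
    def p(self) -> int:
        return self.q + self.X2.shape[1]


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares fit of the full and null cosinor models to one series."""

    beta_hat_full: np.ndarray  # (m_hat, a1_hat, a2_hat) for standard cosinor
    beta1_hat_null: np.ndarray  # null-model non-rhythmic coefficients
    sse_full: float
    sse_null: float
    F: float
    df: tuple[int, int]
    p_value: float

    @property
    def mesor_hat(self) -> float:
        return float(self.beta_hat_full[0])

    @property
    def a1_hat(self) -> float:
        return float(self.beta_hat_full[-2])

    @property
    def a2_hat(self) -> float:
        return float(self.beta_hat_full[-1])

    @property
    def amplitude_hat(self) -> float:
        return math.hypot(self.a1_hat, self.a2_hat)

    @property
    def phi_hat(self) -> float:
        """Acrophase estimate in (-pi, pi]; NaN when the amplitude estimate is 0."""
        if self.amplitude_hat == 0.0:
            return math.nan
        return math.atan2(self.a2_hat, self.a1_hat)


@dataclass(frozen=True)
class TestDecision:
    reject: bool
    critical_value: float
    alpha: float


def build_matrices(design: SamplingDesign, extra_x1: np.ndarray | None = None) -> DesignMatrices:
    """Assemble X1 = [1 | extra_x1] and X2 = [cos(wt), sin(wt)] for a design."""
    n = design.n
    ones = np.ones((n, 1))
    if extra_x1 is not None:
        extra = np.atleast_2d(np.asarray(extra_x1, dtype=float))
        if extra.shape[0] != n:
            if extra.shape == (1, n):  # accept a 1-D covariate
                extra = extra.T
            else:
                raise ValidationError(
                    f"extra_x1 has {extra.shape[0]} rows but the design has {n} times"
                )
        X1 = np.hstack([ones, extra])
    else:
        X1 = ones
    ph = design.phases()
    X2 = np.column_stack([np.cos(ph), np.sin(ph)])
    return DesignMatrices(X1=X1, X2=X2)


def _check_rank(X: np.ndarray, design: SamplingDesign | None = None) -> None:
    p = X.shape[1]
    sv = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * max(X.shape) * np.finfo(float).eps))
    if rank < p:
        hint = ""
        if design is not None:
            n_distinct = np.unique(np.round(np.mod(design.phases(), 2 * np.pi), 12)).size
            if n_distinct < 3:
                hint = (
                    f" ({n_distinct} distinct time(s) modulo the period; at least 3 are "
                    "needed to separate amplitude and phase from the mean)"
                )
        raise RankError(f"design matrix is rank deficient (rank {rank} < {p} columns){hint}")
    cond = sv[0] / sv[-1]
    if cond > CONDITION_WARN:
        warnings.warn(
            f"design matrix condition number {cond:.2e} exceeds {CONDITION_WARN:.0e}; "
            "estimates may be numerically unstable",
            ConditionNumberWarning,
            stacklevel=3,
        )


def _lstsq_sse(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares via SVD-backed lstsq; returns (coefficients, SSE per column)."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta, np.einsum("ij,ij->j", resid, resid)


def fit_cosinor(
    y: np.ndarray,
    design: SamplingDesign,
    extra_x1: np.ndarray | None = None,
) -> CosinorFit:
    """Fit the full and null cosinor models to one series and compute the F-test.

    Parameters
    ----------
    y
        Measurement vector of length ``design.n``.
    design
        Sampling design shared by the measurements.
    extra_x1
        Optional nuisance covariates (columns) appended to the intercept.

    Raises
    ------
    InsufficientDataError
        If ``n <= p`` so no residual degree of freedom remains.
    RankError
        If the design matrix is numerically rank-deficient (e.g. fewer
        than three distinct times modulo the period).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != design.n:
        raise ValidationError(f"y has length {y.size} but the design has {design.n} times")
    return fit_cosinor_batch(y[:, None], design, extra_x1=extra_x1)[0]


def fit_cosinor_batch(
    Y: np.ndarray,
    design: SamplingDesign,
    extra_x1: np.ndarray | None = None,
) -> list[CosinorFit]:
    """Fit many feature series sharing one design; one :class:`CosinorFit` per column.

    The design factorization is computed once and reused across
    columns, so fitting G features costs little more than one fit.  Raw
    p-values are returned; no multiplicity adjustment is applied.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mats = build_matrices(design, extra_x1=extra_x1)
    if Y.shape[0] != mats.n:
        raise ValidationError(f"Y has {Y.shape[0]} rows but the design has {mats.n} times")
    n, p, q = mats.n, mats.p, mats.q
    if n <= p:
        raise InsufficientDataError(
            f"need n > {p} observations for a residual degree of freedom, got n = {n}"
        )
    _check_rank(mats.X, design)
    beta_full, sse_full = _lstsq_sse(mats.X, Y)
    beta_null, sse_null = _lstsq_sse(mats.X1, Y)
    df1, df2 = p - q, n - p
    fits = []
    for g in range(Y.shape[1]):
        num = max(sse_null[g] - sse_full[g], 0.0)
        if sse_full[g] > 0:
            F = (num / df1) / (sse_full[g] / df2)
            p_value = float(stats.f.sf(F, df1, df2))
        else:  # perfect fit: infinite evidence against the null unless y is constant
            F = math.inf if num > 0 else 0.0
            p_value = 0.0 if num > 0 else 1.0
        fits.append(
            CosinorFit(
                beta_hat_full=beta_full[:, g].copy(),
                beta1_hat_null=beta_null[:, g].copy(),
                sse_full=float(sse_full[g]),
                sse_null=float(sse_null[g]),
                F=float(F),
                df=(df1, df2),
                p_value=p_value,
            )
        )
    return fits


def f_test(fit: CosinorFit, alpha: float = 0.05) -> TestDecision:
    """Size-alpha decision: reject rhythmicity iff F exceeds the central-F quantile."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    crit = float(stats.f.ppf(1.0 - alpha, *fit.df))
    return TestDecision(reject=bool(fit.F > crit), critical_value=crit, alpha=alpha)


def read_measurements_csv(
    path: Union[str, Path, io.TextIOBase], period: float | None = None
) -> tuple[SamplingDesign, pd.DataFrame]:
    """Read a wide-format measurement table: a ``time`` column plus feature columns.

    Returns the design (period from a ``# period=`` comment unless
    overridden) and the feature columns as a DataFrame aligned with it.
    """
    from .design import read_design_csv

    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    design = read_design_csv(io.StringIO(text), period=period)
    df = pd.read_csv(io.StringIO(text), comment="#")
    features = df.drop(columns=["time"])
    if features.shape[1] == 0:
        raise DesignFileError("measurement file has a 'time' column but no feature columns")
    return design, features
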