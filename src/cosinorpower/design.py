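"""Sampling designs for cosinor experiments and their rhythmic moments.

A sampling design is the set of measurement times together with the
assumed rhythm period.  Its geometry alone — through the means,
variances and covariance of the cosine and sine regressors evaluated at
the measurement times — determines the noncentrality parameter of the
cosinor F-test and hence the statistical power of rhythm detection.

Two special classes of design matter in practice:

* *centered*: the cosine and sine regressors both average to zero over
  the measurement times (``mu_cos == mu_sin == 0``).  Only for centered
  designs does the naive "sum of squared cosines" noncentrality formula
  agree with the correct one.
* *phase-invariant*: ``sigma2_cos == sigma2_sin`` and
  ``sigma_cossin == 0``, so power does not depend on the rhythm's
  acrophase.  Evenly spaced designs covering whole periods with at
  least three points per cycle are both centered and phase-invariant,
  with ``sigma2_cos == sigma2_sin == 1/2``.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DesignFileError, ValidationError

__all__ = [
    "SamplingDesign",
    "DesignMoments",
    "make_evenly_spaced",
    "make_uniform_grid",
    "rhythmic_moments",
    "cosinor_variance",
    "read_design_csv",
    "DEFAULT_FLAG_TOL",
]

#: Absolute tolerance for declaring the exact-zero properties
#: (centeredness, phase invariance) of ideal designs; floating-point
#: trigonometry needs some slack.
DEFAULT_FLAG_TOL = 1e-10


@dataclass(frozen=True)
class SamplingDesign:
    """Measurement times (hours) plus the assumed rhythm period.

    Parameters
    ----------
    times
        Measurement times in hours.  Arbitrary reals; repeats allowed.
        All moment computations are invariant to shifting every time by
        an integer number of periods.
    period
        Rhythm period ``T`` in hours (e.g. 24 for circadian), > 0.
    """

    times: np.ndarray
    period: float

    def __init__(self, times, period: float) -> None:
        t = np.atleast_1d(np.asarray(times, dtype=float)).ravel()
        if t.size < 1:
            raise ValidationError("a design needs at least one measurement time")
        if not np.all(np.isfinite(t)):
            raise ValidationError("measurement times must be finite")
        period = float(period)
        if not (period > 0 and math.isfinite(period)):
            raise ValidationError(f"period must be a positive finite number, got {period}")
        t = t.copy()
        t.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "period", period)

    @property
    def n(self) -> int:
        """Number of measurements."""
        return int(self.times.size)

    @property
    def omega(self) -> float:
        """Angular frequency ω = 2π/T in radians per hour."""
        return 2.0 * math.pi / self.period

    def phases(self) -> np.ndarray:
        """ω·tᵢ in radians, the arguments of the rhythmic regressors."""
        return self.omega * self.times

    def shifted(self, k_periods: int) -> "SamplingDesign":
        """The same design with every time moved by ``k_periods`` whole periods."""
        return SamplingDesign(self.times + k_periods * self.period, self.period)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SamplingDesign(n={self.n}, period={self.period})"


@dataclass(frozen=True)
class DesignMoments:
    """First and second population moments of the rhythmic regressors.

    All quantities use the population (divisor-``n``) convention.  The
    flags use an absolute tolerance because centeredness and phase
    invariance are exact-zero properties of ideal designs.
    """

    mu_cos: float
    mu_sin: float
    sigma2_cos: float
    sigma2_sin: float
    sigma_cossin: float
    centered: bool
    phase_invariant: bool
    tol: float = field(default=DEFAULT_FLAG_TOL, repr=False)


def make_evenly_spaced(
    n_per_cycle: int,
    n_cycles: int = 1,
    period: float = 24.0,
    replicates: int = 1,
    start: float = 0.0,
) -> SamplingDesign:
    """Evenly spaced design covering an integer number of periods.

    Constant spacing ``period / n_per_cycle`` between consecutive time
    points, including the wrap-around interval from the last point back
    to the first, with ``replicates`` measurements per time point.  Such
    designs are centered and phase-invariant whenever
    ``n_per_cycle >= 3``.

    Parameters
    ----------
    n_per_cycle
        Distinct time points per period, >= 1.
    n_cycles
        Number of whole periods spanned, >= 1.
    period
        Rhythm period in hours.
    replicates
        Measurements per time point, >= 1.
    start
        Time of the first measurement in hours.
    """
    for name, v in (("n_per_cycle", n_per_cycle), ("n_cycles", n_cycles), ("replicates", replicates)):
        if int(v) != v or v < 1:
            raise ValidationError(f"{name} must be a positive integer, got {v!r}")
    n_points = int(n_per_cycle) * int(n_cycles)
    spacing = float(period) / int(n_per_cycle)
    grid = start + spacing * np.arange(n_points)
    times = np.repeat(grid, int(replicates))
    return SamplingDesign(times, period)


def make_uniform_grid(t_start: float, t_end: float, n: int, period: float = 24.0) -> SamplingDesign:
    """``n`` equally spaced times on the closed interval [t_start, t_end].

    Both endpoints are included, so the spacing is
    ``(t_end - t_start) / (n - 1)`` for ``n >= 2`` (for ``n == 1`` the
    single point ``t_start`` is returned).  Unlike
    :func:`make_evenly_spaced`, the grid need not cover whole periods —
    this is the natural way to express clustered schedules such as 24
    samples squeezed between ZT 5 and ZT 7.
    """
    if int(n) != n or n < 1:
        raise ValidationError(f"n must be a positive integer, got {n!r}")
    if t_end < t_start:
        raise ValidationError(f"t_end ({t_end}) must be >= t_start ({t_start})")
    if n == 1:
        times = np.array([float(t_start)])
    else:
        times = np.linspace(float(t_start), float(t_end), int(n))
    return SamplingDesign(times, period)


def rhythmic_moments(design: SamplingDesign, tol: float = DEFAULT_FLAG_TOL) -> DesignMoments:
    """Population moments of cos(ωtᵢ) and sin(ωtᵢ) over the design.

    Returns means, variances and the covariance of the two rhythmic
    regressors (divisor ``n``), plus the ``centered`` and
    ``phase_invariant`` flags evaluated at absolute tolerance ``tol``.

    The moments satisfy the pointwise identity
    ``sigma2_cos + mu_cos**2 + sigma2_sin + mu_sin**2 == 1``
    because cos² + sin² = 1 at every time point.
    """
    ph = design.phases()
    c, s = np.cos(ph), np.sin(ph)
    mu_cos = float(c.mean())
    mu_sin = float(s.mean())
    sigma2_cos = float((c * c).mean() - mu_cos**2)
    sigma2_sin = float((s * s).mean() - mu_sin**2)
    sigma_cossin = float((c * s).mean() - mu_cos * mu_sin)
    centered = abs(mu_cos) < tol and abs(mu_sin) < tol
    phase_invariant = abs(sigma2_cos - sigma2_sin) < tol and abs(sigma_cossin) < tol
    return DesignMoments(
        mu_cos=mu_cos,
        mu_sin=mu_sin,
        sigma2_cos=max(sigma2_cos, 0.0),
        sigma2_sin=max(sigma2_sin, 0.0),
        sigma_cossin=sigma_cossin,
        centered=centered,
        phase_invariant=phase_invariant,
        tol=tol,
    )


def cosinor_variance(design: SamplingDesign, phi: float) -> tuple[float, float]:
    """Mean and population variance of cos(ωtᵢ − φ) over the design.

    ``sigma2_cosinor`` is the design-and-phase-dependent factor in the
    corrected noncentrality parameter δ² = n·(A/σ)²·σ²_cosinor.  It
    equals
    ``cos²φ·σ²_cos + sin²φ·σ²_sin + 2·cosφ·sinφ·σ_cos,sin``
    and is constant in φ exactly for phase-invariant designs.

    Returns
    -------
    (mu_cosinor, sigma2_cosinor)
    """
    x = np.cos(design.phases() - float(phi))
    mu = float(x.mean())
    var = float((x * x).mean() - mu**2)
    return mu, max(var, 0.0)


_PERIOD_RE = re.compile(r"#\s*period\s*=\s*([0-9eE+.\-]+)")


def read_design_csv(path: Union[str, Path, io.TextIOBase], period: float | None = None) -> SamplingDesign:
    """Read a sampling design from CSV.

    The file must contain a ``time`` column (hours).  The period may be
    given as a header comment ``# period=<hours>`` on any leading
    comment line; an explicit ``period`` argument wins over the file.

    Raises
    ------
    DesignFileError
        If the file is empty, lacks a ``time`` column, or specifies no
        period anywhere.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    file_period = None
    for i, line in enumerate(text.splitlines()):
        if not line.startswith("#"):
            break
        m = _PERIOD_RE.match(line)
        if m:
            try:
                file_period = float(m.group(1))
            except ValueError as exc:
                raise DesignFileError(f"line {i + 1}: unparsable period comment: {line!r}") from exc
    try:
        df = pd.read_csv(io.StringIO(text), comment="#")
    except pd.errors.EmptyDataError as exc:
        raise DesignFileError("design file is empty") from exc
    if "time" not in df.columns:
        raise DesignFileError(f"design file needs a 'time' column; found {list(df.columns)}")
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any():
        bad = int(df.index[times.isna()][0]) + 2  # +1 header, +1 one-based
        raise DesignFileError(f"line {bad}: missing or non-numeric time value")
    df["time"] = times
    eff_period = period if period is not None else file_period
    if eff_period is None:
        raise DesignFileError("no period given: add '# period=<hours>' to the file or pass period=")
    return SamplingDesign(df["time"].to_numpy(dtype=float), eff_period)
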