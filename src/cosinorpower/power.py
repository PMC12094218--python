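"""Analytic power of the cosinor F-test.

Under an alternative with amplitude ``A``, acrophase ``phi`` and noise
SD ``sigma``, the F statistic of the standard cosinor model follows a
noncentral F(2, n-3, delta^2) distribution with noncentrality

    delta^2 = n * (A/sigma)^2 * sigma2_cosinor(phi),

where ``sigma2_cosinor`` is the population (divisor-n) variance of
cos(w*t_i - phi) over the measurement times.  Note the convention:
``delta^2`` is the chi-square noncentrality itself, with no division by
the numerator degrees of freedom — some power tools divide by df1.

The historically used alternative replaces the population variance by
the raw mean of squares, i.e.

    delta2_naive = (A/sigma)^2 * sum_i cos^2(w*t_i - phi),

which is correct only for centered designs (mean of cos(w*t - phi)
equal to zero) and can overstate power dramatically otherwise; it is
provided here as :func:`ncp_zong_incorrect` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .design import SamplingDesign, cosinor_variance, make_evenly_spaced
from .errors import NotAchievableError, ValidationError

__all__ = [
    "PowerResult",
    "ncp_standard",
    "ncp_zong_incorrect",
    "power_from_ncp",
    "power_curve_vs_phase",
    "solve_sample_size",
]

FormulaTag = Literal["corrected", "zong_incorrect"]


@dataclass(frozen=True)
class PowerResult:
    """Noncentrality, degrees of freedom and power at a given test size."""

    delta2: float
    df1: int
    df2: int
    alpha: float
    power: float
    formula: FormulaTag = "corrected"


def _check_effect(A: float, sigma: float) -> None:
    if A < 0:
        raise ValidationError(f"amplitude must be >= 0, got {A}")
    if not sigma > 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")


def ncp_standard(design: SamplingDesign, A: float, sigma: float, phi: float) -> float:
    """Corrected noncentrality delta^2 = n*(A/sigma)^2 * sigma2_cosinor(phi)."""
    _check_effect(A, sigma)
    _, s2 = cosinor_variance(design, phi)
    return design.n * (A / sigma) ** 2 * s2


def ncp_zong_incorrect(design: SamplingDesign, A: float, sigma: float, phi: float) -> float:
    """Uncentered noncentrality (A/sigma)^2 * sum cos^2(w*t_i - phi).

    This is the quadratic form ``beta2' X2'X2 beta2 / sigma^2`` of the
    raw rhythmic block.  It coincides with :func:`ncp_standard` exactly
    when the mean of cos(w*t_i - phi) vanishes (in particular on
    centered designs) and strictly exceeds it otherwise.  Provided as a
    comparison baseline, not for use in design.
    """
    _check_effect(A, sigma)
    c = np.cos(design.phases() - float(phi))
    return (A / sigma) ** 2 * float(np.sum(c * c))


def power_from_ncp(
    delta2: float,
    n: int,
    alpha: float = 0.05,
    df1: int = 2,
    n_nuisance: int = 1,
    formula: FormulaTag = "corrected",
) -> PowerResult:
    """Power of the F-test given a noncentrality parameter.

    power = P[F' > q_{1-alpha}] with F' ~ noncentral F(df1, n - df1 -
    n_nuisance, delta2) and q the central-F quantile of the same
    degrees of freedom.  Standard cosinor: df1 = 2, df2 = n - 3.
    """
    if delta2 < 0:
        raise ValidationError(f"delta2 must be >= 0, got {delta2}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    df2 = int(n) - df1 - n_nuisance
    if df2 < 1:
        raise ValidationError(f"n = {n} leaves no residual degree of freedom (df2 = {df2})")
    q = stats.f.ppf(1.0 - alpha, df1, df2)
    if delta2 == 0.0:
        power = alpha  # central case, exactly
    else:
        power = float(stats.ncf.sf(q, df1, df2, delta2))
    return PowerResult(delta2=float(delta2), df1=df1, df2=df2, alpha=alpha, power=power, formula=formula)


def power_curve_vs_phase(
    design: SamplingDesign,
    A: float,
    sigma: float,
    alpha: float = 0.05,
    phi_grid: Sequence[float] | np.ndarray | None = None,
    formula: FormulaTag = "corrected",
) -> list[tuple[float, float, float]]:
    """Evaluate (phi, delta2, power) over a grid of acrophases.

    The curve is flat exactly for phase-invariant designs; for
    clustered schedules it exposes which rhythm phases the design can
    and cannot detect.
    """
    if phi_grid is None:
        phi_grid = np.linspace(-math.pi, math.pi, 73)
    phis = np.asarray(list(phi_grid), dtype=float)
    if phis.size == 0:
        raise ValidationError("phi_grid must be nonempty")
    ncp_fun = ncp_standard if formula == "corrected" else ncp_zong_incorrect
    out = []
    for phi in phis:
        d2 = ncp_fun(design, A, sigma, float(phi))
        res = power_from_ncp(d2, design.n, alpha, formula=formula)
        out.append((float(phi), d2, res.power))
    return out


def solve_sample_size(
    n_per_cycle: int,
    A: float,
    sigma: float,
    phi: float = 0.0,
    alpha: float = 0.05,
    target_power: float = 0.8,
    period: float = 24.0,
    start: float = 0.0,
    grow: Literal["replicates", "cycles"] = "replicates",
    max_multiplier: int = 10_000,
) -> tuple[int, PowerResult]:
    """Smallest multiplier of an evenly spaced per-cycle template reaching a power target.

    The template is ``n_per_cycle`` equally spaced points over one
    period; copies are added as replicates per time point (or as extra
    cycles), and the smallest count with power >= ``target_power`` is
    returned together with its :class:`PowerResult`.

    Raises
    ------
    NotAchievableError
        If the target cannot be reached within ``max_multiplier``
        copies (e.g. A = 0, or a phase at which the design carries no
        rhythmic variance).
    """
    if not alpha < target_power < 1.0:
        raise ValidationError(f"target_power must be in (alpha, 1), got {target_power}")
    _check_effect(A, sigma)

    def power_at(mult: int) -> PowerResult:
        kwargs = dict(replicates=mult) if grow == "replicates" else dict(n_cycles=mult)
        design = make_evenly_spaced(n_per_cycle, period=period, start=start, **kwargs)
        d2 = ncp_standard(design, A, sigma, phi)
        return power_from_ncp(d2, design.n, alpha)

    # bracket geometrically, then bisect on the integer multiplier
    lo, hi = 0, 1
    res_hi = None
    while hi <= max_multiplier:
        try:
            res_hi = power_at(hi)
        except ValidationError:  # too few points for df2 >= 1 yet
            lo, hi = hi, hi * 2
            continue
        if res_hi.power >= target_power:
            break
        lo, hi = hi, hi * 2
    else:
        raise NotAchievableError(
            f"power {target_power} not reachable within {max_multiplier} template copies "
            f"(A/sigma = {A / sigma:.3g}, phi = {phi:.3g})"
        )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        try:
            ok = power_at(mid).power >= target_power
        except ValidationError:
            ok = False
        if ok:
            hi = mid
        else:
            lo = mid
    return hi, power_at(hi)
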