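"""Monte Carlo validation of cosinor power analysis.

Generates synthetic measurement series from the cosinor model with
i.i.d. Gaussian noise,

    y_i = m + A*cos(w*t_i - phi) + eps_i,   eps_i ~ N(0, sigma^2),

and checks the analytic machinery against simulation: the type-I error
of the F-test should match its size alpha, the rejection rate under an
alternative should match the noncentral-F power, and the scaled
quadratic form ``b2_hat' Z2'Z2 b2_hat / sigma^2`` should follow a
noncentral chi-square with 2 degrees of freedom and noncentrality
delta^2.

Everything is driven by one integer seed for bit-exact
reproducibility; this module doubles as the test-fixture generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import SamplingDesign
from .errors import ValidationError
from .model import CosinorEffect, build_matrices, fit_cosinor_batch
from .orthogonalize import orthogonalize
from .power import ncp_standard, power_from_ncp

__all__ = [
    "SimulationSpec",
    "MonteCarloResult",
    "simulate_series",
    "noiseless_series",
    "mc_power",
    "mc_ncp_distribution",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to reproduce a simulation run bit-for-bit."""

    design: SamplingDesign
    effect: CosinorEffect
    n_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if int(self.n_reps) != self.n_reps or self.n_reps < 1:
            raise ValidationError(f"n_reps must be a positive integer, got {self.n_reps}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical rejection rate against the matched analytic power."""

    rejection_rate: float
    mc_se: float
    analytic_power: float
    n_reps: int

    @property
    def discrepancy_sigmas(self) -> float:
        """|empirical - analytic| in units of the binomial Monte Carlo SE."""
        if self.mc_se == 0:
            return 0.0 if self.rejection_rate == self.analytic_power else float("inf")
        return abs(self.rejection_rate - self.analytic_power) / self.mc_se


def _rng(spec: SimulationSpec) -> np.random.Generator:
    # one named generator; replicate rows are consecutive blocks of a
    # single deterministic stream, so spec + seed fixes every byte
    return np.random.default_rng(np.random.SeedSequence(spec.seed))


def simulate_series(spec: SimulationSpec) -> np.ndarray:
    """Simulate ``n_reps`` independent series; rows are replicates.

    Each row is the deterministic cosinor signal at the design times
    plus i.i.d. N(0, sigma^2) noise.  ``sigma`` must be positive; for
    exact noise-free signals use :func:`noiseless_series`.
    """
    d, e = spec.design, spec.effect
    signal = e.signal(d)
    noise = _rng(spec).normal(0.0, e.sigma, size=(spec.n_reps, d.n))
    return signal[None, :] + noise


def noiseless_series(design: SamplingDesign, effect_like) -> np.ndarray:
    """The exact mean response m + A*cos(w*t - phi), no random draw.

    Accepts a :class:`~cosinorpower.model.CosinorEffect` or any object
    with ``mesor``, ``amplitude`` and ``phi`` attributes; ``sigma`` is
    ignored so sigma = 0 fixtures are expressible.
    """
    return effect_like.mesor + effect_like.amplitude * np.cos(design.phases() - effect_like.phi)


def mc_power(spec: SimulationSpec) -> MonteCarloResult:
    """Empirical rejection rate of the cosinor F-test vs. analytic power.

    Simulates ``n_reps`` series, fits each, and counts p < alpha.  The
    matched analytic value uses the corrected noncentrality parameter;
    under the null (A = 0) it is alpha itself.
    """
    if spec.n_reps < 100:
        raise ValidationError("mc_power needs n_reps >= 100 for a meaningful rate")
    Y = simulate_series(spec).T  # columns = replicates, shared design factorization
    fits = fit_cosinor_batch(Y, spec.design)
    rejections = sum(f.p_value < spec.alpha for f in fits)
    rate = rejections / spec.n_reps
    d2 = ncp_standard(spec.design, spec.effect.amplitude, spec.effect.sigma, spec.effect.phi)
    analytic = power_from_ncp(d2, spec.design.n, spec.alpha).power
    se = float(np.sqrt(analytic * (1 - analytic) / spec.n_reps))
    return MonteCarloResult(
        rejection_rate=rate, mc_se=se, analytic_power=analytic, n_reps=spec.n_reps
    )


def mc_ncp_distribution(spec: SimulationSpec) -> np.ndarray:
    """Simulated values of ``b2_hat' Z2'Z2 b2_hat / sigma^2``.

    Under the model this quantity is noncentral chi-square with 2
    degrees of freedom and noncentrality delta^2, so its sample mean
    should approach ``2 + delta^2`` and its sample variance
    ``2*(2 + 2*delta^2)``.
    """
    if spec.n_reps < 1000:
        raise ValidationError("mc_ncp_distribution needs n_reps >= 1000")
    mats = build_matrices(spec.design)
    rep = orthogonalize(mats.X1, mats.X2)
    Y = simulate_series(spec).T
    fits = fit_cosinor_batch(Y, spec.design)
    B2 = np.array([[f.a1_hat, f.a2_hat] for f in fits])  # n_reps x 2
    V = B2 @ rep.Z2.T  # rows: Z2 @ b2_hat
    return np.einsum("ij,ij->i", V, V) / spec.effect.sigma**2


def write_fixture(spec: SimulationSpec, out_dir: str | Path, stem: str = "fixture") -> dict:
    """Write simulated series as CSV plus a JSON manifest; returns the manifest.

    The CSV has a ``time`` column and one ``rep<k>`` column per
    replicate; the manifest records the full spec and seed so the
    fixture can be regenerated exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Y = simulate_series(spec)
    import pandas as pd

    cols = {"time": spec.design.times}
    cols.update({f"rep{k}": Y[k] for k in range(spec.n_reps)})
    df = pd.DataFrame(cols)
    csv_path = out_dir / f"{stem}.csv"
    with open(csv_path, "w") as fh:
        fh.write(f"# period={spec.design.period}\n")
        df.to_csv(fh, index=False)
    manifest = {
        "times": [float(t) for t in spec.design.times],
        "period": spec.design.period,
        "mesor": spec.effect.mesor,
        "amplitude": spec.effect.amplitude,
        "phi": spec.effect.phi,
        "sigma": spec.effect.sigma,
        "n_reps": spec.n_reps,
        "seed": spec.seed,
        "alpha": spec.alpha,
        "csv": csv_path.name,
    }
    manifest_path = out_dir / f"{stem}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
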