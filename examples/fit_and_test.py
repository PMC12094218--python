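"""Simulate a rhythmic series and recover mesor, amplitude and acrophase.

Generates one noisy cosinor series on an hourly one-day schedule, fits
the model, and runs the F-test for rhythm detection.
"""

import math

from cosinorpower import (
    CosinorEffect,
    SimulationSpec,
    f_test,
    fit_cosinor,
    make_evenly_spaced,
    simulate_series,
)

design = make_evenly_spaced(n_per_cycle=24, period=24.0)
truth = CosinorEffect(mesor=10.0, amplitude=2.0, phi=2 * math.pi * 8 / 24, sigma=1.5)
spec = SimulationSpec(design=design, effect=truth, n_reps=1, seed=7)

y = simulate_series(spec)[0]
fit = fit_cosinor(y, design)
decision = f_test(fit, alpha=0.05)

peak_hours = fit.phi_hat / design.omega % design.period
print(f"truth:    mesor={truth.mesor}, A={truth.amplitude}, peak at ZT {truth.phi / design.omega:.1f}")
print(f"estimate: mesor={fit.mesor_hat:.2f}, A={fit.amplitude_hat:.2f}, peak at ZT {peak_hours:.1f}")
print(f"F({fit.df[0]}, {fit.df[1]}) = {fit.F:.2f}, p = {fit.p_value:.2e}, reject null: {decision.reject}")
print()
print("The fitted amplitude and peak time approximate the simulated truth;")
print("the small p-value detects the rhythm against the constant-mean null.")
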