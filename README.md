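# cosinorpower

Power analysis for detecting biological rhythms with the cosinor model,
correct for **any** sampling schedule — evenly spaced or not, centered or
not.

## The problem

Chronobiologists detect circadian (and other periodic) signals by fitting
the standard cosinor model to measurements `y_i` taken at times `t_i`:

    y_i = m + a1·cos(ω t_i) + a2·sin(ω t_i) + ε_i,   ε_i ~ N(0, σ²),

with angular frequency `ω = 2π/T` for a known period `T`, mesor `m`,
amplitude `A = √(a1² + a2²)` and acrophase `φ = atan2(a2, a1)`. Rhythm
detection tests `a1 = a2 = 0` with the nested-model F statistic, central
`F(2, n−3)` under the null. Planning such an experiment — how many time
points, where to place them, how many replicates — requires the power of
that test, which is governed by the noncentrality parameter δ² of the
noncentral `F(2, n−3, δ²)` distribution under the alternative.

A tempting shortcut takes the reduction in sum of squares to be the raw
quadratic form of the rhythmic block, giving

    δ²_naive = (A/σ)² · Σᵢ cos²(ω t_i − φ),

but this is wrong whenever the cosine/sine regressors do not average to
zero over the schedule (a *non-centered* design): the intercept estimate
then differs between the null and full models, and part of the apparent
rhythmic signal is absorbed by the mean. The correct noncentrality
parameter replaces the raw mean square by a **population variance**:

    δ² = n · (A/σ)² · σ²_cosinor,    σ²_cosinor = Var_n[ cos(ω t_i − φ) ],

obtained by orthogonalizing the rhythmic block against the nuisance block
(Frisch–Waugh–Lovell): with `Z2 = (I − X1(X1ᵀX1)⁻¹X1ᵀ)X2`,

    SSE_null − SSE_full = β̂2ᵀ Z2ᵀZ2 β̂2    and    δ² = β2ᵀ Z2ᵀZ2 β2 / σ².

The general form holds for any nuisance matrix `X1` (trends, blocks,
batches), not just the intercept. The difference matters: a schedule that
crowds all samples around the expected peak has a huge `Σ cos²` but a tiny
cosine *variance* — the naive formula promises near-certain detection
where the real power is barely above chance.

## Worked example

24 samples placed uniformly between ZT 5 and ZT 7 (period 24 h), rhythm
peaking at ZT 6, amplitude-to-noise ratio `A/σ = 3`
(`examples/clustered_design_pitfall.py`):

```python
import math
from cosinorpower import make_uniform_grid, ncp_standard, ncp_zong_incorrect, power_from_ncp

design = make_uniform_grid(5.0, 7.0, 24, period=24.0)
naive = ncp_zong_incorrect(design, A=3, sigma=1, phi=math.pi / 2)
corrected = ncp_standard(design, A=3, sigma=1, phi=math.pi / 2)
print(naive, power_from_ncp(naive, 24).power)
print(corrected, power_from_ncp(corrected, 24).power)
```

prints

```
naive delta^2     =  210.715  -> power 1.000
corrected delta^2 =    0.026  -> power 0.052
```

The naive δ² ≈ 210 would mean certain detection at size 0.05; the
corrected δ² ≈ 0.026 gives power 0.052 — essentially the false-positive
rate. Near its peak a cosine is nearly flat, so samples clustered there
are almost indistinguishable from a constant.

The same is available from the shell:

```
cosinorpower power design.csv --snr 3 --peak-zt 6
cosinorpower compare-formulas design.csv --snr 3 --peak-zt 6
cosinorpower design-check design.csv
cosinorpower sample-size --n-per-cycle 6 --snr 1 --target-power 0.8
cosinorpower simulate design.csv --snr 3 --peak-zt 6 --n-reps 10000 --seed 1
```

where `design.csv` has a `time` column and an optional `# period=24`
comment. See `examples/` for scripts covering design diagnostics, fitting
and testing measured series, sample-size planning, Monte Carlo
validation, and power with a trend nuisance.

## What's in the box

- `design` — schedule constructors (`make_evenly_spaced`,
  `make_uniform_grid`), CSV reading, rhythmic moments and the
  centered/phase-invariant diagnostics.
- `model` — cosinor design matrices, (batch) least-squares fitting, the
  F-test, amplitude/acrophase estimates.
- `orthogonalize` — the Frisch–Waugh–Lovell machinery: `Z2`, the
  transition matrix, the reduction-in-SS identity and the general δ² for
  arbitrary nuisance blocks.
- `power` — corrected and naive noncentrality parameters, noncentral-F
  power, phase-dependence curves, a sample-size solver.
- `simulate` — seeded synthetic cosinor data, Monte Carlo power and
  type-I-error validation, distributional checks, fixture writing.

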