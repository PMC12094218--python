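# Methods

## Model and test

The standard cosinor model for a measurement series at known period `T`
(angular frequency `ω = 2π/T`) is

    y_i = m + a1 cos(ω t_i) + a2 sin(ω t_i) + ε_i,   ε_i iid N(0, σ²),

equivalently `y_i = m + A cos(ω t_i − φ) + ε_i` with amplitude
`A = √(a1² + a2²)` and acrophase `φ = atan2(a2, a1)`. Collecting the
regressors into `X = [X1 | X2]` with `X1` the intercept column (plus any
nuisance covariates) and `X2` the cosine/sine columns, rhythm detection
compares the full model against the nuisance-only null with

    F = ((SSE_null − SSE_full)/(p−q)) / (SSE_full/(n−p)),

`p = 3`, `q = 1` for the standard model; `F ~ F(2, n−3)` under the null
and `F ~ F(2, n−3, δ²)` under an alternative `(a1, a2) ≠ 0`.

## The noncentrality parameter

The reduction in sum of squares is **not** `β̂2ᵀX2ᵀX2β̂2` in general,
because the nuisance estimate changes between the nested fits whenever
`X1ᵀX2 ≠ 0`. Orthogonalizing the rhythmic block against the nuisances
(Frisch–Waugh–Lovell), `Z2 = (I − X1(X1ᵀX1)⁻¹X1ᵀ)X2`, restores a clean
decomposition:

    SSE_null − SSE_full = β̂2ᵀ Z2ᵀZ2 β̂2,
    β̂2ᵀZ2ᵀZ2β̂2 / σ² ~ χ²(2, δ²),   δ² = β2ᵀ Z2ᵀZ2 β2 / σ².

For the intercept-only case `Z2` is the column-centered `X2` and the
quadratic form collapses to the closed form

    δ² = n (A/σ)² σ²_cosinor(φ),
    σ²_cosinor(φ) = (1/n)Σ cos²(ω t_i − φ) − ((1/n)Σ cos(ω t_i − φ))²,

a population (divisor-`n`) variance — the divisor-`n` convention is
forced by the definition of the moments and is used throughout, never
`n−1`. Equivalently `σ²_cosinor = cos²φ σ²_cos + sin²φ σ²_sin +
2 cosφ sinφ σ_cos,sin` in terms of the per-design cosine/sine moments.
The historically used uncentered form
`(A/σ)² Σ cos²(ω t_i − φ)` is kept as `ncp_zong_incorrect` purely as a
comparison baseline; it exceeds the correct value by
`n (A/σ)² μ²_cosinor ≥ 0`, with equality exactly when the mean of
`cos(ω t_i − φ)` vanishes.

Power at size α is `P[F' > q_{1−α}]` with `F' ~ noncentral F(2, n−3,
δ²)` and `q_{1−α}` the central-F quantile, evaluated with SciPy's
noncentral-F survival function (no Monte Carlo in the analytic path).
**Convention:** δ² here is the χ² noncentrality itself; some power
tools divide by the numerator degrees of freedom — divide by 2 before
transferring values to such tools.

## Design taxonomy

A design is *centered* when `μ_cos = μ_sin = 0` and *phase-invariant*
when additionally-or-independently `σ²_cos = σ²_sin` and
`σ_cos,sin = 0`, in which case δ² and power do not depend on φ. Evenly
spaced designs — constant spacing over whole periods including the
wrap-around interval, equal replication — are both, with
`σ²_cos = σ²_sin = 1/2` whenever there are at least 3 points per cycle.
These are exact-zero properties of ideal schedules, so the flags use an
absolute tolerance, default `1e-10` and user-overridable.

Times are accepted as arbitrary reals in hours (negative allowed) and
enter only through `cos(ωt)`/`sin(ωt)`; no modular reduction is
applied, so all moments are automatically invariant under whole-period
shifts. Replicated times simply contribute repeated rows.

The `make_uniform_grid` constructor places `n` points on a *closed*
interval (both endpoints included, spacing `(b−a)/(n−1)`). With this
convention the 24-point [ZT 5, ZT 7] schedule yields δ²_naive ≈ 210,
δ² ≈ 0.026 and power ≈ 0.052 at size 0.05 — the package's reference
illustration of the discrepancy, recomputed by `scripts/acceptance.py`
and asserted (at two significant figures) in the test suite.

## Numerical choices

- Least squares go through SVD-based `lstsq`, never normal equations.
  Before fitting, the singular values of `X` drive an explicit check:
  numerical rank loss raises a `RankError` naming the structural cause
  (e.g. fewer than three distinct times modulo the period); a condition
  number above `1e8` raises a `ConditionNumberWarning`, since clustered
  schedules are ill-conditioned by construction.
- The orthogonalization projector is applied through a QR factorization
  of `X1`; the resulting `X1ᵀZ2 = 0` is asserted at relative tolerance
  `1e-8·‖X2‖` (scale-free).
- Acrophase estimates are reported via `atan2` in `(−π, π]`; an exactly
  zero amplitude estimate leaves the acrophase undefined (NaN). Peak
  time in hours is `φ/ω mod T`.
- A perfect (zero-residual) fit maps to `p = 0` (or `p = 1` for a
  constant series); otherwise p-values are plain upper-tail
  probabilities with no finite-sample correction.
- `power_from_ncp(0, ·, α)` returns α exactly rather than evaluating
  the noncentral tail at zero noncentrality.
- Effect sizes may be given as `(A, σ)` or as the ratio `A/σ` with
  `σ = 1`; only the ratio enters δ².
- The sample-size solver brackets the integer template multiplier
  geometrically and bisects; power is monotone in the multiplier
  because δ² scales linearly with `n` while `df2` grows.

## Simulation harness

`simulate_series` draws `m + A cos(ω t_i − φ) + ε_i` with a single
`numpy` PCG64 generator seeded from the spec's integer seed; the whole
replicate matrix comes from one draw, so spec + seed fixes every byte.
(Per-replicate substreams were considered and dropped: nothing here
executes replicates in parallel, and a single stream keeps the
reproducibility contract trivially auditable.) Noise-free fixtures
bypass the Gaussian draw entirely (`noiseless_series`), so σ = 0 is
expressible without violating the σ > 0 contract of the stochastic
path.

Monte Carlo checks compare empirical rejection rates against analytic
power with acceptance bands of 4 binomial standard errors (false-alarm
probability ≈ 1/16,000 per check); distributional checks compare the
sample mean and variance of `β̂2ᵀZ2ᵀZ2β̂2/σ²` with the noncentral-χ²(2,
δ²) moments `2 + δ²` and `2(2 + 2δ²)`, with the variance band derived
from the exact kurtosis. Default replicate counts are 10,000 for the
type-I calibration and 20,000 for the clustered-design power check in
the deep tests (4,000–8,000 in the quicker per-module tests); at these
sizes the full suite runs in well under a minute.

What the simulations emulate — and what they do not: i.i.d. Gaussian
noise with constant variance, a single known period, no
within-subject correlation, no missingness, no non-sinusoidal wave
shape. Passing tests therefore validate the distribution theory under
the model's own assumptions; they say nothing about robustness to
autocorrelated or heteroscedastic noise, unknown periods, or
omics-scale multiple testing, all of which are out of scope (batch
fitting returns raw p-values with no multiplicity adjustment).

## Design choices

- The library is the primary interface (`examples/` contains one
  narrative script per capability); the `cosinorpower` CLI is a thin
  `click` layer over it for shell users, with JSON/TSV output, config
  embedded in every report for auditability, and logging to stderr.
- Design CSVs carry the period as a `# period=<hours>` comment; an
  explicit flag/argument wins over the file. Default period is 24 h.
- The CLI accepts the acrophase either in radians (`--phi`) or as a
  peak time in hours (`--peak-zt`, converted via `φ = ω t_peak`) —
  hours are the chronobiology-facing form.

## Known limitations

- Single-harmonic cosinor only; no multi-component or non-sinusoidal
  models.
- Period is a known input; no period estimation or scanning.
- Gaussian, homoscedastic, independent errors; no GLS/weights.
- The sample-size solver grows an evenly spaced template; it does not
  optimize placement of irregular schedules (use
  `power_curve_vs_phase` to audit a given irregular design instead).
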