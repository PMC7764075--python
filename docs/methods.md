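# Methods

## Model

Multifractional Brownian motion (MFBM) is the centred Gaussian process
with covariance kernel

    Cov(B_H(t)(t), B_H(s)(s)) = D(H(t), H(s)) (t^h + s^h − |t−s|^h),
    h = H(t) + H(s),
    D(x, y) = σ² √(Γ(2x+1)Γ(2y+1) sin(πx) sin(πy)) / (2 Γ(x+y+1) sin(π(x+y)/2)),

for a continuous `H: [0,T] → (0,1)` and variance level `σ² > 0`.  The
process starts at 0, has variance `σ² t^{2H(t)}`, non-stationary
increments, and reduces to fractional Brownian motion for constant `H`
(`D(H,H) = σ²/2`) and to Brownian motion for `H ≡ 1/2`.  `H(t)` acts as a
local regularity index: small values give rough, anti-persistent motion
(subdiffusion), large values smooth, persistent motion (superdiffusion).

`H(t)` must stay **strictly** inside `(0,1)`: at 0 or 1 the factor
`sin(πH)` in `D` vanishes and the kernel degenerates.  Validation
therefore combines grid evaluation with family-specific analytic extrema
(linear: endpoints; periodic: `b ± |a|`, attained since the horizon spans
two full periods; logistic: the asymptotic levels `min(b,c)`/`max(b,c)`,
a closure bound that is marginally conservative near the boundary;
tabulated: knot extrema).  Grid-only checks could miss excursions between
samples — the sine peak at `T/8`, for instance, never lies on an integer
grid when `T` is a multiple of 16.

Jump-type (non-continuous) regime switching is out of scope: the kernel
requires Hölder-continuous `H`.  The Hölder exponent itself is never used
quantitatively, so the package checks continuity and range only.

### Reference parameterizations

Three presets, chosen so each has mean `H ≈ 0.45` and range `[0.3, 0.6]`
on `[0, T]` (default `T = 1000`):

| preset | formula | interpretation |
|---|---|---|
| linear | `H(t) = (0.3/T)·t + 0.3` | steady drift from short- to long-range dependence |
| logistic | `H(t) = 0.3/(1+e^{−100(t−T/2)/T}) + 0.3` | rapid but smooth switch between two levels |
| periodic | `H(t) = 0.15 sin(4πt/T) + 0.45` | gradual, repetitive regime changes |

## Simulation

On the uniform grid `t_i = i·Δt`, `i = 1..N` (defaults `Δt = 1`,
`N = 1000`, `σ² = 1`), the process is an `N`-variate Gaussian, so sampling
is exact: factor `Σ = L Lᵀ` and draw `L z` with `z` standard normal.
`t = 0` is excluded from `Σ` (its row/column is identically zero and
would make the matrix singular) but can be prepended to ensembles as a
deterministic zero for MSD anchoring.  Cholesky is attempted first; if
floating-point round-off makes `Σ` indefinite, a jitter of
`10⁻¹² · mean(diag)` escalating tenfold up to `10⁻⁶ · mean(diag)` is
added, with a final fallback to a symmetric eigendecomposition with
negative eigenvalues clipped at zero.  Matrix assembly uses log-gamma
arithmetic for `D` and enforces symmetry and positive semidefiniteness
(minimum eigenvalue ≥ `−10⁻¹⁰ · λ_max`).

Reproducibility: one integer seed determines an ensemble; each
trajectory draws from its own `SeedSequence`-spawned substream, so the
first `k` paths do not change when the ensemble grows, and power-grid
cells derive per-cell seeds from `(seed, cell index)`.

Approximate fast synthesizers (circulant embedding, wavelet synthesis)
are deliberately not offered: the test's null distribution is exact only
under the exact finite-dimensional law.

## Test statistic and null distribution

The statistic is the lag-τ autocovariance **without mean subtraction**
`ACVF_N(τ) = (1/(N−τ)) Σ X(i+τ)X(i) = Xᵀ A(τ) X` with `A(0) = I/N` and,
for `τ ≥ 1`, entries `1/(2(N−τ))` on the two `τ`-th subdiagonals.  For
`X ~ N(0, Σ)` it is exactly `Σ λᵢ Zᵢ²` with `λᵢ` the eigenvalues of
`Σ^{1/2} A(τ) Σ^{1/2}` — no stationarity needed.  The eigenvalues are
computed from the symmetric form `S A S` (`S` the symmetric PSD square
root of `Σ`), which shares its spectrum with `Σ A` by similarity but
guarantees real eigenvalues in floating point.  `Σ λᵢ = trace(Σ A(τ))`
is verified to `10⁻⁸` relative.

The default lag is `τ = 1`; larger lags average fewer products and carry
less information, degrading power.  `τ` remains a parameter for
exploration.

### Generalized chi-square evaluation

`A(τ ≥ 1)` is indefinite, so the weight vector is mixed-sign and
positive-weight series methods do not apply.  The CDF is computed by
Imhof-type inversion of the characteristic function:

    P(Q ≤ q) = 1/2 − (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,
    θ(u) = ½ Σ arctan(λᵢu) − qu/2,   ρ(u) = Π (1 + λᵢ²u²)^{1/4}.

Numerical choices:

- weights with `|λ| < 10⁻¹² max|λ|` are dropped; if all retained weights
  are equal the law is exactly a scaled chi-square and the closed form is
  used; an all-zero vector yields the unit step at 0;
- the integral is truncated where the post-correction tail bound falls
  below the tolerance, integrated by adaptive quadrature (absolute
  tolerance `10⁻⁹`), and the oscillatory tail beyond the cutoff is added
  analytically via two orders of integration by parts — this keeps the
  evaluation accurate (≈`10⁻¹³` against closed forms) even for very few
  weights, where the integrand decays slowly;
- far in either tail, where the integrand oscillates wildly, a Chernoff
  bound from the exact cumulant generating function pins the CDF to 0 or
  1 within tolerance without quadrature;
- quantiles come from bracketed Brent root-finding started at
  `mean ± 10·sd` of the distribution;
- optional top-k eigenvalue truncation is **off** by default; saddlepoint
  or moment-matching approximations are used only as cross-checks in
  tests, never as the CDF path.

### Decision rule

The rejection region is **two-sided with equal tails**: accept iff the
statistic lies in `[F⁻¹(α/2), F⁻¹(1−α/2)]`.  Sidedness is this package's
choice (the statistic can deviate in either direction — alternatives
rougher than the null shrink it, smoother ones inflate it); type-I
calibration tests validate it.  The reported p-value is the matching
equal-tail value `2·min(F, 1−F)`, clipped to `[0,1]`, coherent with the
interval decision.

## Power studies

Power surfaces sweep two parameters of an alternative family — `(a, b)`
for linear and periodic, `(b, c)` for logistic with `d` and `t₀` held at
the null's values — simulate `n_reps` trajectories per cell from the
alternative, and record the fraction rejected by the null's (cached)
acceptance interval.  Cells whose `H(t)` leaves `(0,1)` per the analytic
extrema check are masked and never simulated.  The cell at the null's
own parameters estimates the type-I error.  Reference scale is
`N = 1000`, `n_reps = 1000`, `α = 0.05`, `τ = 1`; the test suite runs
scaled-down grids (`N = 200`, `n_reps = 200`, 9×9) chosen so a full
three-family sweep completes in well under a minute.

Because the power under any Gaussian alternative is itself a generalized
chi-square tail probability (the alternative's spectrum against the
null's interval), the Monte Carlo engine is cross-validated against that
exact computation in the test suite.

**Approximate symmetries.**  Two qualitative regularities of the
surfaces deserve care.  (i) *Periodic sign flip*: replacing `a` by `−a`
time-shifts `H(t)` by a quarter period; since MFBM is not shift
invariant, the power at `(a, b)` and `(−a, b)` is close but **not**
equal — at `N = 200`, `b = 0.45` the exact powers are 0.28 vs 0.45 for
`a = ±0.35`.  Heat maps look mirror-symmetric, but the symmetry fails a
3-standard-error comparison at moderate amplitudes.  (ii) *Logistic
level swap*: `(b, c)` and `(c, b)` give similar power (the test weights
all times equally), again only approximately.  The test suite asserts
the exact-power cross-check rather than strict symmetry.

## MSD estimators and ergodicity diagnostics

Given `n` trajectories of `N` points: the ensemble-averaged MSD
`EAMSD(τ) = (1/n) Σ_k (X_k(t₁+τ) − X_k(t₁))²`; the per-trajectory
time-averaged `TAMSD(τ=mΔt, k) = (1/(N−m)) Σ_j (X_k(t_{j+m}) − X_k(t_j))²`;
and their ensemble mean `EATAMSD`.  Anchoring choices:

- EAMSD is anchored at the deterministic origin `X(0) = 0` by default, so
  it equals the empirical variance of `X(τ)` and tracks `σ² τ^{2H(τ)}`;
  anchoring at the first observed point is available via a flag;
- the 95% band around EATAMSD is the pointwise empirical 2.5/97.5%
  quantile of per-trajectory TAMSDs (a cross-trajectory spread band, not
  a standard-error band; its width does not shrink with `n`).

For drifting `H(t)` (linear, logistic) the ensemble average exits the
band over most lags below `N/4` — weak ergodicity breaking — while the
periodic `H(t)` keeps it inside.  The discriminating summary used in
tests is the fraction of lags `≤ N/4` at which EAMSD lies inside the
band (at `N = 500`, `n = 400`: ≈0.2–0.4 linear, ≈0.01 logistic, ≈1.0
periodic); at larger lags the band widens so much that the signature
washes out.  These thresholds are package-level choices for a
qualitative phenomenon.

## Problem sizes in the test suite

Unit tests run at `N = 50–100`; end-to-end validation uses
`N = 1000`/1000 trajectories for type-I calibration of the linear null
(`N = 200`/500 for the other two), `10⁶` Monte Carlo draws for the CDF
cross-check at `N = 200`, `n = 10⁴` ensembles for moment checks, and
9×9 power grids at `N = 200` with 200 replicates per cell.  The whole
suite completes in about a minute on one CPU.

## Known limitations

- Exact simulation is `O(N³)` per covariance factorization and `O(nN²)`
  per ensemble; grids much beyond `N ≈ 5000` become slow.
- The test requires the null's `H(t)` and `σ²` to be fully specified;
  estimating `H(t)` from data is out of scope.
- Masked (invalid-`H`) cells depend on the conservative logistic closure
  bound; a logistic family touching 0 or 1 only asymptotically is
  rejected even though its finite-horizon values are interior.
- The tabulated family uses linear interpolation; exotic interpolants
  (splines) would change validity analytics.
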