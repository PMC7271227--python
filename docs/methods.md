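# Methods

## Model

`biasfront` computes the asymptotic speed of a population front whose
dynamics follow the *cohabitation* integro-difference equation: in each
generation of length `T` (yr) the density field is first convolved with a
dispersal kernel and then reproduced logistically, so that children appear at
their parents' post-dispersal location,

    N(x, y, t + T) = R_T[ ∬ N(x − Δx, y − Δy, t) φ(Δx, Δy) dΔx dΔy ],

with the exact one-generation logistic flow

    R_T(N) = e^{aT} K N / (K + (e^{aT} − 1) N),

`a` the initial growth rate (1/yr) and `K` the carrying capacity.  The order
of dispersal and reproduction does not change the front speed, but the
cohabitation form (reproduce after moving) is the appropriate one for humans,
where newborns stay with their parents.

The kernel is assumed separable, `φ = Ψ(Δ) Φ(θ)`, with

* a **radial histogram** `Ψ`: distances `r_i` (km) with probabilities `p_i`
  (ethnographic mobility data are reported exactly in this form), and
* an **angular density** `Φ(θ)` on [−π, π], with θ = 0 the local direction of
  front propagation.  Three anisotropic families are provided:
  - *model 1* (step): probability `p` of moving forward (|θ| ≤ π/2), `1 − p`
    backward; admissible `p ∈ [0.5, 1]`;
  - *model 2* (cosine): `Φ = [1 + (2p − 1) cos θ] / (2π)`; `p ∈ [0.5, 1]`
    (beyond 1 the density would go negative);
  - *model 3* (Gaussian): `Φ = A e^{−q²θ²}` with `q = 20p − 10` and
    `A = q / (√π erf(πq))`; `p ≥ 0.5` with no upper bound.
  `p = 0.5` is isotropic in every family.  The `delta` variant represents the
  exact `p → ∞` limit of model 3 (all migration along θ = 0) and the
  `isotropic` variant the uniform density; both are kept as distinct exact
  variants rather than numerical limits.

## Front-speed selection

Linearizing at the leading edge with the ansatz `N ≈ N₀ e^{−λ(x − ct)}` gives
the characteristic relation

    c(λ) = [ aT + ln Σ_i p_i B(λ r_i) ] / (λ T),
    B(s) = ∫ e^{s cos θ} Φ(θ) dθ,

and the realized (pulled-front) speed is `c = min_{λ>0} c(λ)`.  `B` has
closed forms `I₀(s) + (2p − 1) L₀(s)` (model 1, modified Struve `L₀`),
`I₀(s) + (2p − 1) I₁(s)` (model 2), `I₀(s)` (isotropic) and `e^s` (delta);
model 3 is evaluated by adaptive quadrature with the interval split at θ = 0,
where the integrand concentrates (absolute tolerance 1e−12, relative 1e−10).

Numerical choices:

* **Log-space evaluation.**  The scan reaches `λ r_max` of several thousand,
  where `e^s` overflows.  All angular factors are computed as `ln B(s)` using
  exponentially scaled Bessel functions (`i0e`, `i1e`), and the sum over
  radial bins uses log-sum-exp.  The scaled Struve term `e^{−s} L₀(s)` uses a
  series head `2s/π` below `s = 1e−6`, the direct product up to `s = 500`,
  and `i0e` beyond, where `I₀ − L₀ ~ 2/(πs)` is below double-precision
  resolution of the scaled value.
* **Minimization.**  `c(λ)` is sampled on a 300-point log grid over
  `λ ∈ [1e−4, 50]` /km; the bracketed interior minimum is refined by bounded
  scalar minimization.  If the objective is still decreasing at the upper
  edge (possible for e.g. a single-bin kernel with delta bias, where
  `c(λ) = r/T + a/λ`), the infimum `r_max/T` is not attained; the solver
  reports `attained = False` with `c = boundary_speed = r_max/T` instead of
  silently returning the scan edge.
* **Degenerate inputs.**  `a ≤ 0` is rejected (no pulled front; the
  linearization is meaningless), as are backward bias `p < 0.5`, `λ ≤ 0` and
  negative densities.

## Simulation oracle

For a planar front the 2-D convolution with a separable kernel is exactly a
1-D convolution with the marginal law of `Δx = r cos θ`.  The simulator
discretizes this marginal (θ sampled with ≥ 721 nodes per radial bin —
midpoint rule on each constant piece for model 1, trapezoid otherwise — and
mass deposited on the `Δx` grid by linear cloud-in-cell splitting; the delta
variant lands each bin's mass in the single cell containing `+r_i`), iterates
convolution + logistic growth on a lattice, and fits the front position
(largest `x` with `N ≥ K/2`, linearly interpolated) against time by ordinary
least squares, reporting `R²`.

Defaults: grid spacing 0.25 km (herder kernel; its smallest bin is 0.5 km)
or 0.5 km (farmer), domain 8000 km, **100 generations with a 50-generation
burn-in**, threshold `K/2`.  Pulled fronts converge algebraically — the front
position carries a `−(3/(2λ*)) ln t`-type correction — and with the
case-study decay rates `λ* ≈ 0.035–0.044` /km a 60-generation run still
undershoots the asymptotic speed by ≈ 2–2.6 %; at 100/50 every case-study
combination agrees with the analytic speed within 1.4 %, which is why the
longer window is the default.  Halving the grid spacing moves measured speeds
by well under 0.5 %.

The simulator is deterministic and one-dimensional by construction: it
validates the analytic speeds for homogeneous planar fronts and says nothing
about landscape heterogeneity, coastlines, stochasticity of small
populations, or curvature effects of strongly curved fronts.

## Case studies and derived quantities

Two built-in cases share the demographic ranges `a ∈ [0.023, 0.033]` /yr and
`T ∈ [29, 35]` yr:

* **khoikhoi** — herder kernel `r = {0.5, 3, 7.5, 15, 25, 35, 95}` km,
  `p = {0.67, 0.05, 0.04, 0.07, 0.08, 0.04, 0.05}`; observed front speed
  1.4–3.3 km/yr;
* **bantu** — farmer kernel `r = {2.4, 14.5, 36.2, 60.4}` km,
  `p = {0.40, 0.17, 0.17, 0.26}`; observed 1.5–2.3 km/yr.

The "fast" curve uses `(a, T) = (0.033, 29)`, the "slow" curve
`(0.023, 35)`; the predicted band for a given bias `p` is the range between
them.  Derived quantities:

* **bias effect** `= 100 (c(p) − c(0.5)) / c(p)` at a fixed demographic
  extreme — the share of the front speed attributable to anisotropy;
* **consistency threshold** — the smallest grid value of `p` (step 0.01 for
  model 3, 0.1 for models 1–2, starting at 0.5) whose fast-curve speed
  reaches the observed lower bound, i.e. where the predicted band first
  overlaps the observed interval.  If even the family's maximal bias (p = 1,
  or the delta limit for model 3) stays below the bound the case is reported
  inconsistent;
* **effect range** — (min, max) of the bias effect over the consistency
  p-range and both demographic extremes, rounded to the nearest integer
  percent.  The two extremes are the only demographic combinations
  evaluated, matching the two curves a speed-band figure actually shows;
  scanning the full (a, T) rectangle would be a different (and unplotted)
  summary.  For model 3 the effect is monotone in `p` and saturates at the
  delta limit, so the scan evaluates the threshold point, a few intermediate
  values and the saturation.

Model-3 speed curves can be computed either on an explicit `p` grid
(`speed_vs_bias_curve`) or directly at saturation via the `delta` variant;
the saturation row is appended to model-3 tables because the family has no
finite maximal bias.

## Known limitations

* Only histogram radial kernels are supported; parametric continuous kernels
  (exponential, gamma) are out of scope.
* Persistence (correlated successive jump directions) is not modelled: the
  bias is defined relative to the front orientation, not the previous step.
* The angular families are not defined for backward bias `p < 0.5`; such
  inputs are rejected.
* Observed speed intervals are taken as given constants; the package does
  not re-derive them from site-date regressions.
* The effect-range minima are sensitive to exactly where the consistency
  range starts: evaluating at the first 0.01-grid point at or above the
  crossing (as done here) can differ by a few integer percent from reading a
  plotted effect curve at the continuous crossing point.
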