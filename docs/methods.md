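# Methods

## Model

The simulator implements a two-variable membrane-binding oscillator for the
teneurin protein: cytoplasmic monomer `x` is synthesized at a constant rate
`k1` and taken up into the membrane-bound dimer pool `y` at rate
`k2·x·y^γ` (cooperative: uptake is promoted where dimers already sit; two
monomers are consumed per dimer, hence the factor 2 in the `x` equation);
the dimer is degraded cooperatively at rate `k3·y^m`:

    dx/dt = k1 − 2 k2 x y^γ
    dy/dt = k2 x y^γ − k3 y^m

The uptake term is the numerator of a Hill law `x·y^γ/(L + y^γ)`; dropping
the denominator keeps every threshold closed-form. The full saturating form
is available behind `KineticParams(saturating_uptake=True, L=...)` for
robustness experiments only — all analytic results assume the numerator-only
default (the saturating variant with L = 1 is linearly stable everywhere in
the parameter ranges used here and supports neither oscillation nor
patterning, so it is not a drop-in replacement).

### Linear analysis

The unique positive steady state is `y* = (k1/(2k3))^(1/m)`,
`x* = k1/(2 k2 y*^γ)`. The Jacobian there has

    a = −2 k2 y*^γ           b = −2 k2 x* γ y*^(γ−1)
    c = k2 y*^γ              d = k2 γ x* y*^(γ−1) − k3 m y*^(m−1)

with determinant `det = k1 k2 m (k1/(2k3))^((γ−1)/m) > 0` always, so local
stability is decided by the trace alone. `trace > 0` requires `γ > m` and

    k3 > k3c = (k1/2) · η^(m/(γ+1)),   η = 4 k2/(k1 (γ − m)).

Near the bifurcation the period is `Tp = 2π/√det`, i.e.
`Tp = 2π (m k1 k2)^(−1/2) η^((γ−1)/(2(γ+1)))`; the η exponent is 1/6 at
γ = 2, so protocols that hold η constant leave the period governed by the
front factor, `Tp ∝ k2^(−1/2)`. `period_fold_change` implements exactly
this front-factor scaling; the residual drift from the rising `m` inside
the front factor (bounded by `√(γ/m_start)`) is deliberately neglected, as
in the closed-form protocol analysis. The full simulation of the protocol
(below) independently reproduces the ten-fold slow-down within 15%, because
the strongly relaxational late cycles run slower than the linear estimate,
compensating the front-factor drift.

With diffusion (fast cytoplasmic `D_x`, slow membrane-bound `D_y`) the
critical wavenumber is `κ_T² = (a D_y + d D_x)/(2 D_x D_y)`, reducing to
`κ_T² ≈ d/(2 D_y) = (k1/(4 D_y))(γ−m)(2k3/k1)^(1/m)` when the monomer term
is subdominant. The two agree to 5% when `r = |a| D_y/(d D_x) ≤ 0.09`
(κ ratio = (1−r)^(−1/2)); a large `D_x/D_y` contrast promotes but does not
guarantee this. The fastest-growing mode of the dispersion relation
`Re λ(κ)` of `J − diag(D_x κ², D_y κ²)` sits below the marginal κ_T
(≈ 13% below it for the stripe-regime preset); wavelength checks are
therefore made against the dispersion argmax, at 15%.

## Numerical choices

* **ODE integration**: `scipy.solve_ivp` with LSODA, rtol 1e−8 / atol
  1e−10 — period measurement needs phase accuracy. Concentrations are
  clipped at zero inside the right-hand side so fractional powers never see
  negative round-off.
* **Peak detection**: maxima of `y` count as cycle peaks when their
  prominence exceeds both 5% of the local peak-to-trough amplitude (robust
  to the drifting mean during schedules) and 1% of the mean level of `y`
  (rejects the numerically resolved decaying wiggles of a stable focus).
  A run is "sustained" only if a surviving peak lies in the final quarter
  of the window. Peak times are quantized to one output sample.
* **Slow-down protocol**: `k2` interpolates exponentially in time
  (constant fold-change per unit time, matching the exponential character
  of a decaying morphogen signal; linear interpolation is a config option).
  Under the default hold-η policy, `m(t) = γ − 4 k2(t)/(k1 η0)`, and
  `k3(t) = 1.05 · k3c(t)` tracks the instantaneous threshold so the clock
  stays mildly super-critical throughout. Schedules that would drive
  `m ≥ γ` or `k2 ≤ 0` are rejected at construction.
* **Reaction–diffusion solver**: method of lines, second-order central
  differences, no-flux boundaries by default (closed tissue ends; periodic
  available for spectral tests). State is interleaved `(x_0, y_0, x_1, …)`
  so LSODA's banded Jacobian mode applies (bandwidth 2), which makes the
  default runs take seconds. Default domain: 10 predicted wavelengths at
  ≥ 20 grid points per wavelength; default initial condition: homogeneous
  steady state with 1% multiplicative uniform noise (seed 1729), optionally
  biased with a cosine of chosen wavelength to probe mode selection.
* **Pattern classification** (final 20% of the run): "stationary_pattern"
  if the final spatial profile's std exceeds 5% of the mean level and the
  space-mean's temporal std is < 20% of it; "homogeneous_oscillation" in
  the mirrored case; both small → "homogeneous_steady"; otherwise "mixed".
  The dominant wavelength is the domain length divided by the peak index of
  the final profile's power spectrum; flat profiles have no wavelength.
* **Growth scenario**: cells are discrete unit-length oscillator
  compartments appended at rate `v`; each inherits the posterior clock's
  state at birth (the posterior clock is spun up for 15 periods first so
  every segment reflects the asymptotic cycle) and then runs autonomously
  with `k2` set by its current distance from the posterior (exponential
  gradient by default, mirroring posterior-confined transcription plus
  first-order decay), with `m` and `k3` co-varying under the hold-η rule.
  There is no cell–cell coupling during growth; diffusion enters only at
  the transition.
* **Phase freezing**: the bistable latch that fixes the slowed clock is
  represented by a stand-in rule, not by explicit bistable dynamics: a
  cell's phase is latched when it crosses the determination front
  (distance > `psm_length`; default) or when its instantaneous linear
  period exceeds a threshold. Phase is the angle of `(x−x*, y−y*)` around
  the local steady state; because the relaxational cycle crowds wrapped
  angles near the slow branch, boundary calling uses each cell's
  *cumulative* phase (posterior phase at birth plus the unwrapped winding
  over its life, sampled at ≥ 80 points per period) and lays a boundary at
  every multiple of 2π, interpolated between cells.
* **Transition**: the frozen pattern is handed to the reaction–diffusion
  phase as a small bias — cos(frozen phase) at 3% amplitude around the new
  homogeneous steady state, plus 0.2% noise — and the pre/post wavelength
  ratio is reported (undefined when no stationary pattern forms).

## What the simulations show — and one thing they do not

The stripe-regime preset (k2=0.2, γ=2.4, m=1.6, k3=0.475, Dx=1.45,
Dy=0.09; k3c=0.50) behaves exactly as the linear analysis predicts: below
threshold and with `D_x ≫ D_y`, stationary stripes at wavelength ≈ λ_T grow
from 1% noise, while equal diffusivities give a quiescent field below
threshold and a spatially uniform limit cycle above it.

Raising `k3` above 0.50 makes the homogeneous mode unstable too, and one
might expect the uniform oscillation to displace the stripes somewhere
shortly above threshold. It does not, anywhere in `k3 ∈ [0.50, 0.56]` (or
indeed up to 0.90): the Turing band's growth rate (0.08–0.13) exceeds the
homogeneous Hopf growth rate (trace/2 ≤ 0.046) several-fold throughout, the
developed stripe state is stable against uniform perturbations, and even an
established homogeneous limit cycle is invaded by stripes within ~200 time
units (slowest near k3 ≈ 0.54). This was cross-checked with two independent
integrators, finer grids, longer runs (t = 4000), larger noise, displaced
initial states, and limit-cycle initial conditions. The acceptance scan
(`scripts/acceptance.py`, target `t5`) therefore honestly reports no
homogeneous-oscillation onset in the scan window under this protocol: with
these diffusivities the 1-D model selects stationary stripes, and a
homogeneous oscillation can only win when the diffusion contrast is reduced
(e.g. `D_y ≳ 0.2` at `k3 = 0.55`).

## Scope of the synthetic scenarios

The growth scenario is a 1-D caricature: discrete cells of fixed unit size,
no division, no cell–cell coupling in the PSM, a stationary exponential
gradient in the frame of the posterior, and a phase-latch stand-in for the
bistable switch. Passing tests show the clock-and-wavefront bookkeeping
(segment length = v·T to 5%), the slow-down physics, and pattern
inheritance through the sequential→simultaneous transition; they do not
validate synchronization dynamics, noise robustness across cells, or any
explicit Notch/Wnt/FGF pathway structure. Lengths and times are model
units; no calibration to embryonic micrometres or minutes is attempted.

## Known limitations

* Far above threshold with weak degradation cooperativity (m near 1) the
  limit cycle can collapse to the degenerate `y = 0` state (uptake
  `∝ y^γ` loses the race against degradation `∝ y^m` once `y` is driven
  low, and `x` grows only linearly). The oscillator's operating regime is
  mild super-criticality with m well above 1, as used in all protocols;
  the onset property tests sample that regime.
* The period formula is a linear (Hopf-point) estimate; measured periods
  run a few percent long already at `k3 = 1.05·k3c` and the gap widens with
  super-criticality as the cycle becomes relaxational.
* One-dimensional fields only; no apical/basal membrane geometry.
* The period-doubled (pair-rule) variant of the clock is out of scope.
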