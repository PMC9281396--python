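# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package. Units are reduced throughout: `k_B = 1`, mass
1, so energies divided by `k_B T` are thermal units and `beta = 1/T`.

## Model potentials

`DoubleWell` is a tilted quartic `U(x) = 0.3125 (x^2 - 4)^2 + 0.1 x` with
two minima near x = -2 and x = +2 inside the bias interval [-3, 3], a
unique global minimum on the left, and a barrier (saddle minus global
minimum) of 5.20 energy units — about 10 k_B T at the benchmark
temperature T = 0.5. The coefficients were chosen once so that the
landscape has exactly these printed properties and moderate energies
(~16 kT) at the interval edges, which a uniform target distribution must
fill; they are not otherwise special.

`WolfeQuapp` is the canonical quartic
`U = x^4 + y^4 - 2x^2 - 4y^2 + xy + 0.3x + 0.1y`: two dominant minima
separated by a high barrier along y (a third, shallow minimum sits
2.6 k_BT above the global one and belongs to the y < 0 state for
region-based free-energy differences). The rotated variant applies a
rotation by `theta = -0.15 pi` and an energy scale factor 2; both constants
live in `potentials.py` and nowhere else. Biasing only x on the rotated
surface is the standard suboptimal-CV stress test: the orthogonal slow
mode (y) is missing from the bias.

Reference free-energy surfaces come from quadrature: `F = U` up to a
constant when the CVs are the coordinates, and
`F(x) = -(1/beta) log Int dy e^{-beta U}` (trapezoidal rule, >= 2001
points, default marginal domain [-3, 3]) for the marginalized case. A
warning reports the boundary Boltzmann weight if the integrand has not
decayed at the marginalization edge.

The one-sided harmonic wall `kappa (x - x0)^2` applies only beyond `x0` on
the restrained side (its purpose is to cap dissociation, not to restrain
association) and is continuous with continuous first derivative at `x0`.

## Basis sets

All families share one convention: the user-facing size is the TOTAL
number of functions including one constant function, so "22 basis
functions" means the same expansion length for every family and sizes are
comparable across the benchmark.

* **Symlets (SymN, N = 4..12).** Scaling filters are hardcoded from the
  published coefficient tables and validated at import (sum sqrt(2),
  double-shift orthogonality <= 1e-10); the wavelet filter follows from
  the quadrature-mirror relation. phi and phi' are tabulated by the vector
  cascade algorithm: eigenvector of the two-scale matrix at eigenvalue 1
  (values) and 1/2 (derivatives, normalized by `sum_k k phi'(k) = -1` —
  the derivative table is NOT a finite difference of the value table),
  refined dyadically to 2^11 points per unit of support, linear
  interpolation in between. The basis is a single level of father-wavelet
  translates; the dilation is found by bisection on the interval length in
  shift units so that, after the 1% relative-maximum cutoff, exactly
  size-1 translates remain (if the retained count jumps past the target,
  the error reports both achievable neighbors rather than silently
  choosing). The 1% threshold compares each translate against its own
  global maximum; for pure translates this equals the basis-wide maximum.
  Functions carry the standard normalization `Int phi = 1` (peak ~1.19);
  no per-scale amplitude factor is applied, since the linear coefficients
  absorb any fixed rescaling.
* **Gaussians** `exp(-(x-mu_i)^2 / 2 sigma^2)` and **cubic B-splines**
  (peak-normalized piecewise cubic, support `|x - mu| < 2 sigma`) sit on
  centers `mu_i = a + i d`, `d = (b-a)/N`, `i = -1..N` — one center beyond
  the left boundary, N+2 localized functions, N+3 with the constant.
  Gaussian width defaults to `sigma = 0.75 d` (user-settable); the spline
  width is fixed at `sigma = d`. For the coverage flags a Gaussian's
  footprint is `4 sigma` (value 3.4e-4 of peak) — Gaussians are nowhere
  zero, so a cutoff is needed for masking to be meaningful.
* **Chebyshev / Legendre** polynomials of degree 0..order on the affinely
  mapped interval; evaluation delegates to numpy.polynomial (the standard
  three-term recursions); the closed forms `T_n(cos t) = cos(n t)` and
  `P_n(1) = 1` serve as test oracles.
* **Tensor products** give 2D bases as all pairwise products with
  product-rule derivatives; index (i, j) flattens to `i * size2 + j`.

Outside the bias interval every non-constant function evaluates to zero
with zero derivative, so the bias force vanishes there by construction.

## Dynamics

Velocity Verlet wrapped in half-step Ornstein-Uhlenbeck velocity updates
(`c1 = exp(-friction dt / 2)`, noise amplitude `sqrt((1-c1^2)/(beta m))`).
The discrete stationary position variance for a harmonic well at the
benchmark parameters was computed exactly from the map's Lyapunov equation
(0.500003 vs 0.5 at dt = 0.005, friction 10): the sampling bias of the
scheme is negligible against statistical error. Model-system defaults:
dt = 0.005, friction 10, mass 1. Initial velocities are Maxwell-Boltzmann
at the run temperature; initial positions default to the potential's
global minimum (dense grid search plus local refinement). Each walker owns
an RNG stream spawned from the master seed, so multi-walker runs are
reproducible and independent of execution order, and splitting a segment
does not perturb the stream.

## VES engine

Per iteration each walker advances one stride (500 MD steps for the model
benchmarks) under the current averaged bias; all walkers' samples pool
into one batch. Batch means of `f_i` and `f_i^2` give the gradient
`-(<f_i>_V - <f_i>_p)` and diagonal Hessian `beta Var[f_i]` (clamped at
zero against round-off); entries of functions with no sample in their
support are masked to zero before the update. The averaged-SGD recursion
updates the instantaneous coefficients with fixed step `mu` (energy
units), and the bias uses the uniform running mean of all instantaneous
iterates from iteration 1 — no burn-in discard. Adam (eta = 0.005,
standard moment defaults) is available for the suboptimal-CV benchmark and
maintains the same running-mean convention for the bias.

Target-distribution averages use trapezoidal quadrature on a grid over the
basis interval (1000 points per dimension in 1D, 301 in 2D; the tensor
structure reduces 2D target averages to two matrix products). Well-tempered
targets bootstrap from uniform and refresh every `update_stride` bias
updates from the current FES estimate, `p ~ exp(-beta F / gamma)`, using
the averaged coefficients.

During MD the engine does not sum basis functions at every step: after
each coefficient update the bias energy/force is retabulated on a dense
grid (4096 points in 1D; bilinear 201^2 in 2D via the tensor factorization)
and linearly interpolated, with the analytic potential force tabulated on
an extended domain and evaluated exactly outside it. The wavelet basis is
itself a linear-interpolation table at finer spacing, so this adds no new
approximation order; `BiasState.energy_force` performs the exact summation
and is the tested contract.

## FES estimation and metrics

Direct route: `F = -V - (1/beta) log p + C` on a grid, minimum shifted to
zero. Reweighting route: samples weighted by `e^{+beta V}` enter a binned
Gaussian kernel density estimate (cloud-in-cell deposition, separable
convolution, 5-sigma kernel truncation); each sample's kernel is
renormalized by its in-interval mass, the least-surprising boundary
treatment for CVs confined to an interval. An initial transient can be
discarded; zero-density grid points are capped.

The RMS error metric shifts both surfaces by their quadrature mean over
`Gamma = {F_ref <= 4 kT}` and averages the squared difference over
`{F_ref <= 8 kT}`, normalized by that region's measure so values read
directly in energy units. Free-energy differences integrate Boltzmann
weights over region predicates (half-spaces for the model benchmarks).

## Scales used in the shipped tests

The test suite runs the scaled-down protocol the package ships as explicit
`*_quick` presets: 5 runs x 5x10^5 steps (1000 bias iterations) for the
double-well comparison, a 25-walker pooled run (4000 iterations, stride
100) to produce a well-converged frozen bias, and 5x10^5 frozen-bias steps
across 10 walkers for the estimator-consistency checks. Full-scale presets
(20 runs x 5x10^6 steps) match the printed protocols and run in roughly
15 s per 1D run on one core.

What the model benchmarks do and do not show: they exercise every piece of
the method (bases, optimizer, masking, targets, reweighting, metrics) on
landscapes with known references, but a single Langevin particle has no
molecular noise structure — no multiple time scales from orthogonal
degrees of freedom beyond the constructed ones, no CV discretization
artifacts, no force-field error. Conclusions about basis-set robustness
transfer; absolute convergence rates do not.

## Known limitations

* The averaged coefficients converge with an O(1/t) tail fed by the
  initial filling transient; at 1000 iterations the double-well RMS error
  fluctuates around ~0.5 kT between runs (0.17-0.23 kT after 4000-10000
  iterations). Multi-walker pooling reduces the gradient noise but not the
  1/t tail itself.
* Only the father-wavelet level is implemented; multiresolution refinement
  with mother wavelets is validated (psi tabulation) but not used in the
  bias.
* Periodic CVs are not supported; all benchmarks use interval CVs.
* The well-tempered target refresh assumes the averaged bias is the best
  current FES estimate; no reweighted refresh is implemented.
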