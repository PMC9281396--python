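# localves

Variationally enhanced sampling (VES) with localized basis sets — symlet
wavelets, Gaussians and cubic B-splines — benchmarked against Chebyshev and
Legendre polynomial expansions on analytic model potentials.

## Who this is for

Researchers in molecular simulation who want a self-contained, desk-scale
engine for studying how the basis-set choice affects the convergence of the
VES bias potential, without a full MD stack: single-particle Langevin
dynamics on model landscapes stands in for the molecular system, and every
other ingredient (basis construction, stochastic optimization, target
distributions, free-energy estimation, performance metrics) is the real
method.

## The method

For collective variables `s` with free energy surface
`F(s) = -(1/beta) log P(s) + C`, VES constructs a bias potential `V(s)` by
minimizing the convex functional

    Omega[V] = (1/beta) log [ Int ds e^{-beta(F(s)+V(s))} / Int ds e^{-beta F(s)} ]
               + Int ds p(s) V(s),

whose minimizer satisfies `V = -F - (1/beta) log p`, so the biased system
samples the chosen target distribution `p(s)` (uniform, or well-tempered
`p ~ P^{1/gamma}`). In practice `V(s; alpha) = sum_i alpha_i f_i(s)` is a
linear expansion in basis functions; the gradient and diagonal Hessian of
`Omega(alpha)`,

    grad_i = -< f_i >_{V} + < f_i >_{p},      hess_ii = beta Var_V[f_i],

are estimated from short sampling batches and fed to averaged stochastic
gradient descent (the bias always uses the running mean of the coefficient
iterates) or to Adam. For localized bases, gradient/Hessian entries of
functions whose support saw no sample in a batch are masked to zero.

The distinguishing ingredient is the basis: orthonormal least-asymmetric
Daubechies scaling functions (symlets, SymN). They have no closed form, so
phi and its derivative are tabulated by the vector cascade algorithm —
values at the integers are the eigenvector of the two-scale matrix
`T[i,j] = sqrt(2) h_{2i-j}` at eigenvalue 1 (eigenvalue 1/2 for the
derivative), then the refinement relation doubles the resolution exactly to
a dyadic grid (2^11 points per unit of support, linear interpolation
between). A SymN basis reproduces polynomials up to degree N-1 exactly,
while each function is effectively localized; the dilation is chosen so
that, after discarding translates with less than 1% of the maximum function
value inside the bias interval, exactly the requested number remains.

FESs are obtained two ways: directly from the bias via the stationary-point
relation, and by reweighting trajectories with weights `e^{+beta V}`
(weighted kernel density estimate with boundary renormalization).
Performance is measured by a shift-invariant RMS error against a quadrature
reference, restricted to the region below `nu = 8 kT`, and by free-energy
differences `Delta F_AB` between CV-space regions.

## Worked example

The scaled-down double-well benchmark (a tilted quartic with a barrier of
about 10 kT at T = 0.5, biased on [-3, 3] with 22 Sym8 wavelet functions,
5 independent runs of 5x10^5 steps):

```python
import numpy as np
from localves.experiments import run_suite, suite_from_preset

suite = suite_from_preset("double_well_wavelet_quick", outdir="out")
result = run_suite(suite)

kT = 0.5  # T = 0.5, k_B = 1
print("final RMS error per run (kT):",
      np.round(result.rms.per_run[:, -1] / kT, 3))
print(f"mean +- sem (kT): {result.rms.mean[-1]/kT:.3f}"
      f" +- {result.rms.sem[-1]/kT:.3f}")
```

prints

```
final RMS error per run (kT): [0.524 0.836 0.435 0.543 0.242]
mean +- sem (kT): 0.516 +- 0.096
```

i.e. after 1000 bias updates the wavelet FES is converged to about half a
kT on average (the matched Legendre runs give 1.32 +- 0.24 kT — localized
bases converge faster and more robustly, which is the point of the
comparison). Per-run and aggregate metric series, the reference FES and the
final FES of every run are written to `out/` as plain-text files.

The same presets run from the shell:

```sh
localves list-presets
localves describe double_well_wavelet          # full-scale parameters
localves run --preset double_well_wavelet_quick -o out
localves basis-dump --kind wavelet --size 22 --out basis.dat
localves analyze out/fes_run0.dat out/reference_fes.dat -T 0.5 --split-at 0
```

Full-scale presets (`double_well_*`, `wolfe_quapp_*`,
`wolfe_quapp_rotated_*`: 20 runs x 5x10^6 steps) reproduce the complete
benchmark protocols; the `*_quick` variants declare their reduced scale
explicitly in the configuration.

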