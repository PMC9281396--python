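"""Variationally enhanced sampling: functional machinery and optimizers.

The bias potential is a linear expansion ``V(s; alpha) = sum_i alpha_i
f_i(s)`` whose coefficients minimize the convex VES functional

    Omega[V] = (1/beta) log [ int ds e^{-beta(F + V)} / int ds e^{-beta F} ]
               + int ds p(s) V(s),

with gradient ``-<f_i>_V + <f_i>_p`` (biased-ensemble average minus
target-distribution average) and diagonal Hessian ``beta Var_V[f_i] >= 0``.
At the minimum ``V = -F - (1/beta) log p`` and the CVs sample the target
distribution p(s).

Minimization is stochastic: each iteration the walkers advance one stride,
the per-batch sampled averages estimate the gradient/Hessian, elements of
basis functions whose support saw no sample are masked to zero (localized
bases only change where sampling occurs), and the optimizer updates the
instantaneous coefficients alpha.  The bias itself always uses the running
mean alpha_bar of the instantaneous iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .basis import BasisSet, TensorBasis
from .dynamics import DynamicsConfig, WalkerState, make_walker, run_segment
from .grid import FESGrid, regular_grid
from .potentials import PotentialSurface

__all__ = [
    "BiasState",
    "TargetDistribution",
    "AveragedSGD",
    "Adam",
    "SampledAverages",
    "bias_energy_force",
    "bias_on_grid",
    "sampled_averages",
    "target_averages",
    "gradient_hessian",
    "mask_uncovered",
    "averaged_sgd_step",
    "adam_step",
    "update_well_tempered_target",
    "uniform_target",
    "VESConfig",
    "VESResult",
    "run_ves",
]


# ---------------------------------------------------------------------------
# bias state

@dataclass
class BiasState:
    """Instantaneous and averaged expansion coefficients of the bias."""

    basis: BasisSet
    alpha: np.ndarray = None
    alpha_bar: np.ndarray = None
    iteration: int = 0

    def __post_init__(self):
        if self.alpha is None:
            self.alpha = np.zeros(self.basis.size)
        if self.alpha_bar is None:
            self.alpha_bar = np.zeros(self.basis.size)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.alpha_bar = np.asarray(self.alpha_bar, dtype=float)
        if len(self.alpha) != self.basis.size:
            raise ValueError("alpha length must equal basis size")
        if len(self.alpha_bar) != self.basis.size:
            raise ValueError("alpha_bar length must equal basis size")

    def energy_force(self, point):
        """Bias energy and force at one point, from the averaged parameters."""
        return bias_energy_force(self, point)


def _inside(basis: BasisSet, p: np.ndarray) -> bool:
    for (a, b), c in zip(basis.intervals, p):
        if c < a or c > b:
            return False
    return True


def bias_energy_force(bias: BiasState, point):
    """``V = sum_i alpha_bar_i f_i`` and ``-grad V`` at a point.

    Both are identically zero outside the basis interval: the bias does not
    act there by design.
    """
    p = np.atleast_1d(np.asarray(point, dtype=float))
    if not _inside(bias.basis, p):
        return 0.0, np.zeros(len(p))
    vals, ders, _ = bias.basis.evaluate(p)
    energy = float(vals @ bias.alpha_bar)
    force = -(bias.alpha_bar @ ders.reshape(bias.basis.size, -1))
    return energy, force


def bias_on_grid(bias: BiasState, axes, derivatives: bool = False):
    """Bias energy (and force components) tabulated on a regular grid.

    Exploits the tensor structure for 2D bases: with per-axis value and
    derivative matrices G (nx, M1), H (ny, M2) and coefficients A (M1, M2),
    the energy grid is ``G A H^T``.  Returns ``V`` of shape
    ``(n1, ..., nd)`` and, when requested, a list of force grids.
    """
    basis = bias.basis
    if isinstance(basis, TensorBasis):
        b1, b2 = basis.factors
        v1, d1, _ = b1.evaluate_batch(axes[0], derivatives=True)
        v2, d2, _ = b2.evaluate_batch(axes[1], derivatives=True)
        A = bias.alpha_bar.reshape(b1.size, b2.size)
        V = v1 @ A @ v2.T
        if not derivatives:
            return V
        Fx = -(d1[:, :, 0] @ A @ v2.T)
        Fy = -(v1 @ A @ d2[:, :, 0].T)
        return V, [Fx, Fy]
    if basis.dim != 1:
        raise ValueError("bias_on_grid supports 1D and tensor bases")
    vals, ders, _ = basis.evaluate_batch(axes[0], derivatives=True)
    V = vals @ bias.alpha_bar
    if not derivatives:
        return V
    F = -(ders[:, :, 0] @ bias.alpha_bar)
    return V, [F]


# ---------------------------------------------------------------------------
# target distributions

@dataclass
class TargetDistribution:
    """Normalized CV-space distribution p(s) on a quadrature grid."""

    kind: str                       # "uniform" | "well_tempered"
    grid: FESGrid                   # grid.values holds p
    gamma: float | None = None      # bias factor (well-tempered only)
    update_stride: int = 0          # bias updates between target refreshes

    def __post_init__(self):
        if self.kind not in ("uniform", "well_tempered"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "well_tempered":
            if self.gamma is None or self.gamma <= 1.0:
                raise ValueError(
                    "well-tempered target requires bias factor gamma > 1"
                )
        p = np.asarray(self.grid.values, dtype=float)
        if np.any(p < 0):
            raise ValueError("target distribution must be non-negative")
        total = float((p * self.grid.trapezoid_weights()).sum())
        if abs(total - 1.0) > 1e-8:
            p = p / total
        self.grid.values = p

    def normalization_defect(self) -> float:
        p = np.asarray(self.grid.values)
        return abs(float((p * self.grid.trapezoid_weights()).sum()) - 1.0)


def uniform_target(
    intervals, bins: int | list[int] = 1000, **kwargs
) -> TargetDistribution:
    """Uniform target distribution on the basis interval(s)."""
    grid = regular_grid(intervals, bins)
    vol = float(np.prod([b - a for a, b in intervals]))
    grid.values = np.full(grid.shape, 1.0 / vol)
    return TargetDistribution(kind="uniform", grid=grid, **kwargs)


def well_tempered_target(
    intervals, gamma: float, bins: int | list[int] = 1000,
    update_stride: int = 100,
) -> TargetDistribution:
    """Well-tempered target, bootstrapped from a uniform distribution.

    The first target is uniform; after each refresh stride it becomes
    ``p ~ exp(-beta F / gamma)`` for the current FES estimate (see
    :func:`update_well_tempered_target`).
    """
    t = uniform_target(intervals, bins)
    return TargetDistribution(
        kind="well_tempered", grid=t.grid, gamma=gamma,
        update_stride=update_stride,
    )


def update_well_tempered_target(
    target: TargetDistribution, bias: BiasState, beta: float
) -> TargetDistribution:
    """Refresh a well-tempered target from the current FES estimate.

    The FES implied by the current bias and target (``F = -V - (1/beta)
    log p``) gives the new target ``p ~ exp(-beta F / gamma)``, normalized
    on the target grid.  Uniform targets are returned unchanged.
    """
    if target.kind == "uniform":
        return target
    gamma = target.gamma
    if gamma is None or gamma <= 1.0:
        raise ValueError("bias factor gamma must exceed 1")
    from .fes import fes_from_bias  # deferred: fes depends on engine types

    fes = fes_from_bias(bias, target, beta, grid=target.grid)
    logp = -beta * np.asarray(fes.values) / gamma
    logp -= logp.max()
    p = np.exp(logp)
    p /= (p * target.grid.trapezoid_weights()).sum()
    new_grid = FESGrid(
        axes=[ax.copy() for ax in target.grid.axes],
        values=p,
        units=target.grid.units,
        fields=list(target.grid.fields),
    )
    return replace(target, grid=new_grid)


# ---------------------------------------------------------------------------
# sampled and target averages, gradient, Hessian, masking

class SampledAverages(NamedTuple):
    mean_f: np.ndarray        # per-function batch mean of f_i
    mean_ff_diag: np.ndarray  # per-function batch mean of f_i^2
    coverage: np.ndarray      # bool: support contained >= 1 sample


def sampled_averages(cv_samples, basis: BasisSet) -> SampledAverages:
    """Batch means of f_i and f_i^2 plus per-function coverage flags."""
    samples = np.asarray(cv_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample batch")
    if basis.dim == 1:
        samples = samples.reshape(-1)
    else:
        samples = samples.reshape(-1, basis.dim)
    vals, _, act = basis.evaluate_batch(samples, derivatives=False)
    return SampledAverages(
        mean_f=vals.mean(axis=0),
        mean_ff_diag=(vals * vals).mean(axis=0),
        coverage=act.any(axis=0),
    )


def target_averages(
    target: TargetDistribution, basis: BasisSet
) -> np.ndarray:
    """``<f_i>_p`` by quadrature of f_i * p over the target grid."""
    for (a, b), ax in zip(basis.intervals, target.grid.axes):
        if ax[0] > a + 1e-12 or ax[-1] < b - 1e-12:
            raise ValueError(
                "target grid does not cover the basis interval"
            )
    if isinstance(basis, TensorBasis):
        b1, b2 = basis.factors
        v1, _, _ = b1.evaluate_batch(target.grid.axes[0], derivatives=False)
        v2, _, _ = b2.evaluate_batch(target.grid.axes[1], derivatives=False)
        W = target.grid.trapezoid_weights() * np.asarray(target.grid.values)
        return (v1.T @ W @ v2).reshape(-1)
    pts = target.grid.points
    vals, _, _ = basis.evaluate_batch(
        pts if basis.dim > 1 else pts[:, 0], derivatives=False
    )
    w = (
        target.grid.trapezoid_weights() * np.asarray(target.grid.values)
    ).reshape(-1, order="F")
    return vals.T @ w


def gradient_hessian(
    sampled: SampledAverages, target_means: np.ndarray, beta: float
):
    """VES gradient and diagonal Hessian from batch estimates.

    ``grad_i = -(<f_i>_V - <f_i>_p)`` and ``hess_i = beta * Var_V[f_i]``,
    clamped at zero against round-off on tiny batches.
    """
    target_means = np.asarray(target_means, dtype=float)
    if len(target_means) != len(sampled.mean_f):
        raise ValueError("sampled and target averages have mismatched length")
    grad = -(sampled.mean_f - target_means)
    hess = beta * (sampled.mean_ff_diag - sampled.mean_f**2)
    return grad, np.maximum(hess, 0.0)


def mask_uncovered(grad, hess_diag, coverage):
    """Zero gradient/Hessian elements of functions with no sampling.

    Localized basis functions whose support contained no sample this
    iteration must not be updated: their gradient would otherwise be
    driven purely by the target-distribution term.
    """
    grad = np.asarray(grad, dtype=float)
    hess_diag = np.asarray(hess_diag, dtype=float)
    coverage = np.asarray(coverage, dtype=bool)
    if not (len(grad) == len(hess_diag) == len(coverage)):
        raise ValueError("masking inputs have mismatched lengths")
    keep = coverage.astype(float)
    return grad * keep, hess_diag * keep


# ---------------------------------------------------------------------------
# optimizers

def _update_running_mean(bias: BiasState, new_alpha: np.ndarray) -> None:
    bias.alpha = new_alpha
    bias.iteration += 1
    bias.alpha_bar = (
        bias.alpha_bar + (new_alpha - bias.alpha_bar) / bias.iteration
    )


@dataclass
class AveragedSGD:
    """Averaged stochastic gradient descent (the plain VES optimizer).

    Update of the instantaneous parameters with fixed step size mu
    (units of energy):

        alpha <- alpha - mu * [grad(alpha_bar)
                               + hess_diag(alpha_bar) * (alpha - alpha_bar)]

    The bias uses the uniform running mean alpha_bar of all instantaneous
    iterates.
    """

    mu: float = 0.5
    kind: str = field(default="averaged_sgd", init=False)

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("step size mu must be positive")

    def step(self, bias: BiasState, grad, hess_diag) -> BiasState:
        new_alpha = bias.alpha - self.mu * (
            grad + hess_diag * (bias.alpha - bias.alpha_bar)
        )
        _update_running_mean(bias, new_alpha)
        return bias


@dataclass
class Adam:
    """Adam with bias-corrected moments; alpha_bar kept as running mean.

    The curvature information comes from the second-moment accumulator, so
    the diagonal Hessian of the VES functional is not used.
    """

    eta: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    kind: str = field(default="adam", init=False)
    m: np.ndarray | None = field(default=None, repr=False)
    v: np.ndarray | None = field(default=None, repr=False)
    t: int = field(default=0, repr=False)

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("step size eta must be positive")

    def step(self, bias: BiasState, grad, hess_diag=None) -> BiasState:
        grad = np.asarray(grad, dtype=float)
        if self.m is None:
            self.m = np.zeros_like(grad)
            self.v = np.zeros_like(grad)
        self.t += 1
        self.m = self.beta1 * self.m + (1.0 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1.0 - self.beta2) * grad * grad
        mhat = self.m / (1.0 - self.beta1**self.t)
        vhat = self.v / (1.0 - self.beta2**self.t)
        new_alpha = bias.alpha - self.eta * mhat / (np.sqrt(vhat) + self.epsilon)
        _update_running_mean(bias, new_alpha)
        return bias


def averaged_sgd_step(opt: AveragedSGD, bias, grad, hess_diag, mu=None):
    """Functional form of the averaged-SGD update (see :class:`AveragedSGD`)."""
    if opt.kind != "averaged_sgd":
        raise ValueError("optimizer is not averaged SGD")
    if mu is not None:
        opt = replace(opt, mu=mu)
    return opt.step(bias, np.asarray(grad, float), np.asarray(hess_diag, float))


def adam_step(opt: Adam, bias, grad, eta=None):
    """Functional form of the Adam update (see :class:`Adam`)."""
    if opt.kind != "adam":
        raise ValueError("optimizer is not Adam")
    if eta is not None:
        opt.eta = float(eta)
    return opt.step(bias, np.asarray(grad, float))


# ---------------------------------------------------------------------------
# run orchestration

@dataclass
class VESConfig:
    """Complete definition of one VES run on a model potential."""

    potential: PotentialSurface
    basis: BasisSet
    dynamics: DynamicsConfig
    target: TargetDistribution
    optimizer: AveragedSGD | Adam
    n_steps: int
    stride: int = 500               # MD steps per walker between updates
    fes_stride: int = 50_000        # MD steps between bias snapshots
    n_walkers: int = 1
    seed: int = 0
    start_position: np.ndarray | None = None
    record_samples: bool = True
    bias_table_points: int = 4096   # per dimension (1D); 201 used for 2D
    colvar_path: str | None = None

    def __post_init__(self):
        if self.n_steps < self.stride:
            raise ValueError("n_steps must be at least one stride")
        if self.fes_stride % self.stride:
            raise ValueError("fes_stride must be a multiple of stride")


@dataclass
class VESResult:
    """Outputs of one VES run."""

    bias: BiasState
    #: per-snapshot coefficient history: (iteration, alpha, alpha_bar)
    snapshots: list[tuple[int, np.ndarray, np.ndarray]]
    cv_samples: np.ndarray | None
    target: TargetDistribution
    config: VESConfig
    masked_fraction: np.ndarray               # per-iteration diagnostics
    n_iterations: int


def _default_start(potential: PotentialSurface) -> np.ndarray:
    """Global minimum of the potential by dense grid search + refinement."""
    from scipy.optimize import minimize

    grids = [np.linspace(a, b, 201) for a, b in potential.domain]
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    u = potential.energy(pts if potential.dim > 1 else pts[:, 0])
    x0 = pts[np.argmin(u)]
    res = minimize(
        lambda p: float(
            potential.energy(p if potential.dim > 1 else p[0])
        ),
        x0,
    )
    return np.atleast_1d(res.x)


class _ExtendedForceTable1D:
    """Combined potential+bias force on a dense grid, linearly interpolated.

    The potential part is tabulated once over an extended domain (the
    walker may leave the bias interval); the bias part is refreshed after
    every coefficient update.  Outside the extended domain the exact
    potential force is evaluated directly.
    """

    def __init__(self, potential, basis, n_points: int):
        a, b = basis.intervals[0]
        ext = 0.5 * (b - a)
        self.x0 = a - ext
        self.x1 = b + ext
        self.n = int(n_points * 2)
        self.dx = (self.x1 - self.x0) / (self.n - 1)
        self.inv_dx = 1.0 / self.dx
        xs = np.linspace(self.x0, self.x1, self.n)
        self.pot_force = -potential.gradient(xs)
        self.exact = lambda x: float(-potential.gradient(np.array([x]))[0])
        vals, ders, _ = basis.evaluate_batch(xs, derivatives=True)
        self._dmat = ders[:, :, 0]
        self.table = self.pot_force.copy()

    def refresh(self, alpha_bar: np.ndarray) -> None:
        self.table = self.pot_force - self._dmat @ alpha_bar

    def __call__(self, x: float) -> float:
        t = (x - self.x0) * self.inv_dx
        if t < 0.0 or t >= self.n - 1:
            return self.exact(x)
        i = int(t)
        frac = t - i
        tab = self.table
        return tab[i] * (1.0 - frac) + tab[i + 1] * frac


class _PartialBiasForce:
    """Full-dimensional potential force plus a lower-dimensional bias.

    Used when only a subset of the coordinates is biased (suboptimal-CV
    benchmarks): the bias force from a 1D basis acts on the first
    coordinate only.
    """

    def __init__(self, potential, basis, n_points: int):
        self.potential = potential
        a, b = basis.intervals[0]
        self.a, self.b = a, b
        self.n = int(n_points)
        self.inv_dx = (self.n - 1) / (b - a)
        xs = np.linspace(a, b, self.n)
        _, ders, _ = basis.evaluate_batch(xs, derivatives=True)
        self._dmat = ders[:, :, 0]
        self.table = np.zeros(self.n)

    def refresh(self, alpha_bar: np.ndarray) -> None:
        self.table = -(self._dmat @ alpha_bar)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        f = -self.potential.gradient(x)
        t = (x[0] - self.a) * self.inv_dx
        if 0.0 <= t < self.n - 1:
            i = int(t)
            frac = t - i
            f[0] += self.table[i] * (1.0 - frac) + self.table[i + 1] * frac
        return f


class _ExtendedForceTable2D:
    """Analytic potential force plus bilinearly interpolated bias force."""

    def __init__(self, potential, bias: BiasState, n_points: int = 201):
        self.potential = potential
        self.basis = bias.basis
        self.axes = [
            np.linspace(a, b, n_points) for a, b in self.basis.intervals
        ]
        self.bias_ref = bias
        self.Fx = np.zeros((n_points, n_points))
        self.Fy = np.zeros((n_points, n_points))
        (a1, b1), (a2, b2) = self.basis.intervals
        self._o = np.array([a1, a2])
        self._inv = np.array(
            [(n_points - 1) / (b1 - a1), (n_points - 1) / (b2 - a2)]
        )
        self._nm1 = n_points - 1

    def refresh(self, alpha_bar: np.ndarray) -> None:
        bias = BiasState(self.basis, alpha_bar, alpha_bar)
        _, (self.Fx, self.Fy) = bias_on_grid(bias, self.axes, derivatives=True)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        f = -self.potential.gradient(x)
        t = (x - self._o) * self._inv
        if np.all(t >= 0.0) and np.all(t < self._nm1):
            i, j = int(t[0]), int(t[1])
            fx, fy = t[0] - i, t[1] - j
            w00 = (1 - fx) * (1 - fy)
            w10 = fx * (1 - fy)
            w01 = (1 - fx) * fy
            w11 = fx * fy
            f[0] += (
                w00 * self.Fx[i, j] + w10 * self.Fx[i + 1, j]
                + w01 * self.Fx[i, j + 1] + w11 * self.Fx[i + 1, j + 1]
            )
            f[1] += (
                w00 * self.Fy[i, j] + w10 * self.Fy[i + 1, j]
                + w01 * self.Fy[i, j + 1] + w11 * self.Fy[i + 1, j + 1]
            )
        return f


def run_ves(config: VESConfig) -> VESResult:
    """Run one VES optimization: walkers, pooled updates, snapshots.

    Each iteration every walker advances ``stride`` MD steps under the
    current averaged bias; the pooled samples of all walkers form one batch
    for the gradient/Hessian estimate; uncovered elements are masked; the
    optimizer updates the coefficients.  Every ``fes_stride`` MD steps the
    averaged coefficients are snapshotted.  Fully deterministic given the
    master seed.
    """
    potential, basis = config.potential, config.basis
    dyn = config.dynamics
    beta = dyn.beta
    bias = BiasState(basis)
    target = config.target
    optimizer = config.optimizer

    start = (
        np.atleast_1d(np.asarray(config.start_position, dtype=float))
        if config.start_position is not None
        else _default_start(potential)
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_walkers)
    walkers = [make_walker(start, dyn, s) for s in seeds]

    if basis.dim == potential.dim == 1:
        table = _ExtendedForceTable1D(potential, basis, config.bias_table_points)
    elif basis.dim == potential.dim == 2:
        table = _ExtendedForceTable2D(potential, bias)
    elif basis.dim == 1 and potential.dim == 2:
        table = _PartialBiasForce(potential, basis, config.bias_table_points)
    else:
        raise ValueError("unsupported potential/basis dimensionality")
    table.refresh(bias.alpha_bar)

    n_iter = config.n_steps // config.stride
    snap_every = max(1, config.fes_stride // config.stride)
    tmeans = target_averages(target, basis)

    all_samples = [] if config.record_samples else None
    snapshots: list[tuple[int, np.ndarray, np.ndarray]] = []
    masked_frac = np.empty(n_iter)
    colvar = open(config.colvar_path, "w") if config.colvar_path else None
    if colvar:
        names = " ".join(f"cv{i+1}" for i in range(basis.dim))
        colvar.write(f"# FIELDS time {names} bias\n")

    try:
        for it in range(n_iter):
            batch = []
            for w in walkers:
                _, samples = run_segment(w, table, dyn, config.stride)
                batch.append(samples)
            batch = np.concatenate(batch)
            # biased CVs are the first basis.dim coordinates of the walker
            if batch.ndim == 2 and basis.dim < batch.shape[1]:
                cv_batch = batch[:, : basis.dim]
            else:
                cv_batch = batch
            if config.record_samples:
                all_samples.append(batch)
            if colvar:
                _write_colvar(colvar, bias, cv_batch, it, config, dyn)

            sampled = sampled_averages(cv_batch, basis)
            grad, hess = gradient_hessian(sampled, tmeans, beta)
            grad, hess = mask_uncovered(grad, hess, sampled.coverage)
            masked_frac[it] = 1.0 - sampled.coverage.mean()
            optimizer.step(bias, grad, hess)
            table.refresh(bias.alpha_bar)

            if (
                target.kind == "well_tempered"
                and target.update_stride > 0
                and (it + 1) % target.update_stride == 0
            ):
                target = update_well_tempered_target(target, bias, beta)
                tmeans = target_averages(target, basis)

            if (it + 1) % snap_every == 0:
                snapshots.append(
                    (bias.iteration, bias.alpha.copy(), bias.alpha_bar.copy())
                )
    finally:
        if colvar:
            colvar.close()

    samples_arr = (
        np.concatenate(all_samples) if config.record_samples else None
    )
    return VESResult(
        bias=bias,
        snapshots=snapshots,
        cv_samples=samples_arr,
        target=target,
        config=config,
        masked_fraction=masked_frac,
        n_iterations=n_iter,
    )


def sample_with_frozen_bias(
    potential: PotentialSurface,
    bias: BiasState,
    dynamics: DynamicsConfig,
    n_steps: int,
    seed: int,
    n_walkers: int = 1,
    start_position=None,
    table_points: int = 4096,
) -> np.ndarray:
    """Sample a fixed (frozen) bias: the input to reweighting checks.

    Runs ``n_walkers`` independent walkers for ``n_steps`` each under the
    frozen averaged bias and returns the pooled CV samples (one row per
    step).  Estimating the FES both directly from the bias and by
    reweighting such a trajectory — and comparing — is standard good
    practice.
    """
    basis = bias.basis
    if basis.dim == potential.dim == 1:
        table = _ExtendedForceTable1D(potential, basis, table_points)
    elif basis.dim == potential.dim == 2:
        table = _ExtendedForceTable2D(potential, bias)
    elif basis.dim == 1 and potential.dim == 2:
        table = _PartialBiasForce(potential, basis, table_points)
    else:
        raise ValueError("unsupported potential/basis dimensionality")
    table.refresh(bias.alpha_bar)
    start = (
        np.atleast_1d(np.asarray(start_position, dtype=float))
        if start_position is not None
        else _default_start(potential)
    )
    seeds = np.random.SeedSequence(seed).spawn(n_walkers)
    out = []
    for s in seeds:
        w = make_walker(start, dynamics, s)
        _, samples = run_segment(w, table, dynamics, n_steps)
        out.append(samples)
    return np.concatenate(out)


def _write_colvar(fh, bias, batch, it, config, dyn):
    batch2 = batch.reshape(len(batch), -1)
    t0 = it * config.stride * dyn.dt * config.n_walkers
    for i, p in enumerate(batch2):
        v, _ = bias_energy_force(bias, p)
        cols = " ".join(f"{c:.8g}" for c in p)
        fh.write(f"{t0 + (i + 1) * dyn.dt:.6g} {cols} {v:.8g}\n")
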