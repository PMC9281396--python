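"""Single-particle Langevin dynamics: the sampling engine of the benchmarks.

Velocity Verlet with the stochastic friction/noise splitting of the
Bussi-Parrinello Langevin thermostat: an Ornstein-Uhlenbeck half-step on
the velocity before and after a plain velocity-Verlet step.  With zero
friction the integrator reduces to symplectic velocity Verlet; the
stationary distribution at friction > 0 is the Boltzmann distribution of
the (biased) potential.

Reduced units throughout: k_B = 1, default mass 1.  Reproducibility is
bit-for-bit: a walker owns its RNG stream, and splitting a run into
segments does not change the stream (noise is drawn in the same order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicsConfig",
    "WalkerState",
    "langevin_step",
    "run_segment",
    "make_walker",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Integrator and thermostat parameters (model-system defaults)."""

    dt: float = 0.005
    friction: float = 10.0
    beta: float = 2.0          # inverse temperature; T = 0.5 by default
    mass: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def temperature(self) -> float:
        return 1.0 / self.beta


@dataclass
class WalkerState:
    """Position, velocity and RNG stream of one Langevin walker."""

    position: np.ndarray
    velocity: np.ndarray
    rng: np.random.Generator
    step_count: int = 0

    def __post_init__(self):
        self.position = np.atleast_1d(np.asarray(self.position, dtype=float))
        self.velocity = np.atleast_1d(np.asarray(self.velocity, dtype=float))

    @property
    def dim(self) -> int:
        return len(self.position)


def make_walker(
    position,
    config: DynamicsConfig,
    seed_seq: np.random.SeedSequence | int,
) -> WalkerState:
    """Walker at ``position`` with Maxwell-Boltzmann initial velocities."""
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(int(seed_seq))
    rng = np.random.default_rng(seed_seq)
    position = np.atleast_1d(np.asarray(position, dtype=float))
    sigma_v = math.sqrt(1.0 / (config.beta * config.mass))
    velocity = rng.standard_normal(len(position)) * sigma_v
    return WalkerState(position=position, velocity=velocity, rng=rng)


class TrajectoryError(RuntimeError):
    """Raised when a walker produces a non-finite force or position."""


def _thermostat_constants(config: DynamicsConfig, zero_noise: bool):
    c1 = math.exp(-config.friction * config.dt / 2.0)
    if zero_noise or config.friction == 0.0:
        c2 = 0.0
    else:
        c2 = math.sqrt((1.0 - c1 * c1) / (config.beta * config.mass))
    return c1, c2


def run_segment(
    state: WalkerState,
    force,
    config: DynamicsConfig,
    steps: int,
    record: bool = True,
    zero_noise: bool = False,
):
    """Advance a walker ``steps`` steps; return ``(state, cv_samples)``.

    ``force`` maps position to total deterministic force -grad(U) - grad(V):
    for 1D walkers it is called with and must return a plain float; for
    higher dimensions it takes/returns arrays of shape (dim,).  The state is
    advanced in place (and returned); CV samples are recorded after every
    step when ``record`` is true.

    ``zero_noise`` disables the stochastic part (used to exercise the
    symplectic velocity-Verlet core in tests).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    c1, c2 = _thermostat_constants(config, zero_noise)
    dt = config.dt
    half_dt_m = dt / (2.0 * config.mass)
    dim = state.dim
    if c2 > 0.0:
        noise = state.rng.standard_normal((steps, 2, dim))
    else:
        noise = np.zeros((steps, 2, dim))

    if dim == 1:
        return _segment_1d(
            state, force, steps, record, c1, c2, dt, half_dt_m, noise
        )

    x = state.position.copy()
    v = state.velocity.copy()
    samples = np.empty((steps, dim)) if record else None
    f = np.asarray(force(x), dtype=float)
    for i in range(steps):
        v = c1 * v + c2 * noise[i, 0]
        v = v + half_dt_m * f
        x = x + dt * v
        f = np.asarray(force(x), dtype=float)
        if not np.all(np.isfinite(f)):
            raise TrajectoryError(
                f"non-finite force at step {state.step_count + i + 1}, "
                f"position {x}"
            )
        v = v + half_dt_m * f
        v = c1 * v + c2 * noise[i, 1]
        if record:
            samples[i] = x
    state.position = x
    state.velocity = v
    state.step_count += steps
    return state, samples


def _segment_1d(state, force, steps, record, c1, c2, dt, half_dt_m, noise):
    # scalar fast path: ~1 microsecond per step
    x = float(state.position[0])
    v = float(state.velocity[0])
    samples = np.empty(steps) if record else None
    n1 = noise[:, 0, 0]
    n2 = noise[:, 1, 0]
    f = force(x)
    isfinite = math.isfinite
    for i in range(steps):
        v = c1 * v + c2 * n1[i]
        v += half_dt_m * f
        x += dt * v
        f = force(x)
        if not isfinite(f):
            raise TrajectoryError(
                f"non-finite force at step {state.step_count + i + 1}, "
                f"position {x}"
            )
        v += half_dt_m * f
        v = c1 * v + c2 * n2[i]
        if record:
            samples[i] = x
    state.position = np.array([x])
    state.velocity = np.array([v])
    state.step_count += steps
    return state, samples


def langevin_step(
    state: WalkerState, force, config: DynamicsConfig, zero_noise=False
) -> WalkerState:
    """One integration step (velocity Verlet + stochastic thermostat)."""
    new_state, _ = run_segment(
        state, force, config, steps=1, record=False, zero_noise=zero_noise
    )
    return new_state
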