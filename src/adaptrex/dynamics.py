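"""Langevin and self-guided Langevin (SGLD) integrators.

The SGLD equation of motion adds a guiding force lambda * gamma * <p>_L to
plain Langevin dynamics, where <p>_L is a moving local average of the
momentum over averaging time t_L.  Discretization is a BAOAB splitting with
the guiding force folded into the deterministic (B) half-kicks; with
lambda = 0 the integrator is exactly plain Langevin, and with gamma = 0 it
reduces to velocity Verlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, NumericalBlowupError
from .exchange import WalkerLabel

__all__ = [
    "ReplicaState",
    "DynamicsParams",
    "SegmentResult",
    "update_momentum_average",
    "guiding_force",
    "sgld_step",
    "langevin_step",
    "run_segment",
]


@dataclass
class ReplicaState:
    """Dynamic state of one replica (or a stacked batch of replicas).

    ``x``, ``p`` and ``p_avg`` share a common shape: ``(dim,)`` for a single
    replica or ``(n_replicas, dim)`` for a batch stepped in lockstep.
    """

    x: np.ndarray
    p: np.ndarray
    p_avg: np.ndarray = None
    window: int = 0
    label: WalkerLabel = WalkerLabel.UNLABELED

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p_avg is None:
            self.p_avg = np.zeros_like(self.p)
        self.p_avg = np.asarray(self.p_avg, dtype=float)
        if self.p.shape != self.x.shape or self.p_avg.shape != self.x.shape:
            raise InvalidArgumentError("x, p, p_avg must share one shape")


@dataclass(frozen=True)
class DynamicsParams:
    """Integrator parameters.

    Physical-mode defaults mirror a 2 fs time step with friction 1/ps,
    guiding factor 1 and averaging time 1 ps; reduced-unit toy runs override
    them freely.  ``masses`` broadcasts against the coordinate shape.
    """

    dt: float = 0.002
    gamma: float = 1.0
    lam: float = 1.0
    t_l: float = 1.0
    masses: float | np.ndarray = 1.0
    kb: float = 1.0

    def __post_init__(self):
        if self.dt <= 0.0:
            raise InvalidArgumentError("dt must be positive")
        if self.gamma < 0.0:
            raise InvalidArgumentError("gamma must be nonnegative")
        if self.t_l < self.dt:
            raise InvalidArgumentError("t_l must be >= dt")
        if np.any(np.asarray(self.masses) <= 0.0):
            raise InvalidArgumentError("masses must be positive")


@dataclass(frozen=True)
class SegmentResult:
    final_energy: float | np.ndarray
    mean_energy: float | np.ndarray


def update_momentum_average(p_avg, p, dt: float, t_l: float):
    """One step of the recursive exponential local momentum average.

    p_avg <- (1 - dt/t_l) * p_avg + (dt/t_l) * p, i.e. an exponential moving
    average with window L = t_l / dt steps.
    """
    if t_l < dt:
        raise InvalidArgumentError("t_l must be >= dt")
    a = dt / t_l
    return (1.0 - a) * np.asarray(p_avg, dtype=float) + a * np.asarray(p, dtype=float)


def guiding_force(p_avg, gamma: float, lam: float):
    """Guiding force lambda * gamma * <p>_L."""
    return lam * gamma * np.asarray(p_avg, dtype=float)


def _force(model, x: np.ndarray) -> np.ndarray:
    """Systematic force -dE/dx, batched when x is 2-D."""
    if x.ndim == 2:
        f = -model.gradient_batch(x)
    else:
        f = -model.gradient(x)
    # NaN/inf propagate through the sum, so one scalar check suffices
    if not np.isfinite(f.sum()):
        bad = np.argwhere(~np.isfinite(f))[0]
        raise NumericalBlowupError(
            f"non-finite force at coordinate index {tuple(int(b) for b in bad)}"
        )
    return f


def _col(temp, x: np.ndarray):
    """Broadcast a per-replica temperature array against batched coordinates."""
    t = np.asarray(temp, dtype=float)
    if x.ndim == 2 and t.ndim == 1:
        return t[:, None]
    return t


def _baoab(state, model, temp, params, rng, lam: float) -> ReplicaState:
    m = np.asarray(params.masses, dtype=float)
    dt = params.dt
    gamma = params.gamma
    x, p, p_avg = state.x, state.p, state.p_avg
    t = _col(temp, x)

    f = _force(model, x) + lam * gamma * p_avg
    p = p + 0.5 * dt * f
    x = x + 0.5 * dt * p / m
    c1 = np.exp(-gamma * dt)
    sigma = np.sqrt((1.0 - c1 * c1) * m * params.kb * t)
    p = c1 * p + sigma * rng.standard_normal(p.shape)
    x = x + 0.5 * dt * p / m
    f = _force(model, x) + lam * gamma * p_avg
    p = p + 0.5 * dt * f

    a = dt / params.t_l
    p_avg = (1.0 - a) * p_avg + a * p
    # bypass dataclass validation in the hot loop; arrays are fresh and shaped
    new = ReplicaState.__new__(ReplicaState)
    new.x, new.p, new.p_avg = x, p, p_avg
    new.window, new.label = state.window, state.label
    return new


def sgld_step(
    state: ReplicaState,
    model,
    temp,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> ReplicaState:
    """One SGLD step at the given window temperature(s).

    The random kick satisfies fluctuation-dissipation at ``temp``; the
    momentum memory is refreshed once per step from the post-step momentum.
    With ``params.lam == 0`` the step is bit-identical to ``langevin_step``
    given the same noise stream.
    """
    if np.any(np.asarray(temp) <= 0.0):
        raise InvalidArgumentError("temperature must be positive")
    return _baoab(state, model, temp, params, rng, params.lam)


def langevin_step(
    state: ReplicaState,
    model,
    temp,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> ReplicaState:
    """One plain (unguided) BAOAB Langevin step."""
    if np.any(np.asarray(temp) <= 0.0):
        raise InvalidArgumentError("temperature must be positive")
    return _baoab(state, model, temp, params, rng, 0.0)


def run_segment(
    state: ReplicaState,
    model,
    temp,
    params: DynamicsParams,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[ReplicaState, SegmentResult]:
    """Integrate ``n_steps`` SGLD steps between swap attempts.

    Returns the final state and the instantaneous potential energy of the
    final configuration (the quantity entering the Metropolis swap test),
    along with the segment-mean potential energy.
    """
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    if np.any(np.asarray(temp) <= 0.0):
        raise InvalidArgumentError("temperature must be positive")
    batched = state.x.ndim == 2
    acc = 0.0
    for _ in range(n_steps):
        state = _baoab(state, model, temp, params, rng, params.lam)
        acc = acc + (model.energy_batch(state.x) if batched else model.energy(state.x))
    final = model.energy_batch(state.x) if batched else model.energy(state.x)
    return state, SegmentResult(final_energy=final, mean_energy=acc / n_steps)
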