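"""Perturbed-equilibrium initialization and fixed-step Euler integration.

Simulations start from the uniform equilibrium with a small multiplicative
fluctuation (default 1%) on every field value, and advance with the explicit
Euler scheme at a fixed time step (default dt = 0.001) under periodic
boundaries inherited from the lattice. Integration stops at ``max_time`` or
as soon as the largest time-derivative falls below ``steady_tol``.

Euler preserves linear invariants exactly, so total-auxin conservation in
the degradation-free models holds to rounding error; this is recorded as a
per-snapshot diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import Lattice
from .models import ModelSpec, Params, State, rhs
from .regulation import DomainError

__all__ = ["SimConfig", "Trajectory", "IntegrationBlowupError",
           "perturb", "integrate", "total_auxin"]


class IntegrationBlowupError(RuntimeError):
    """A field became non-finite or negative: the time step is too large."""


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt           Euler time step (time units).
    max_time     simulation horizon.
    steady_tol   early stop when max |d(field)/dt| < steady_tol.
    record_every record a snapshot every this many steps (0: endpoints only).
    seed         RNG seed for the initial fluctuation.
    fluctuation  relative amplitude of the initial fluctuation.
    distribution "uniform" (default) or "gaussian" fluctuation shape.
    check_every  blowup/steady check stride in steps.
    """

    dt: float = 0.001
    max_time: float = 1000.0
    steady_tol: float = 1e-8
    record_every: int = 0
    seed: int | None = None
    fluctuation: float = 0.01
    distribution: str = "uniform"
    check_every: int = 25

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.fluctuation < 1:
            raise ValueError("fluctuation must be in [0, 1)")
        if not self.steady_tol > 0:
            raise ValueError("steady_tol must be > 0")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError("distribution must be 'uniform' or 'gaussian'")


@dataclass
class Trajectory:
    """Result of one integration run."""

    times: list[float]
    snapshots: list[State]
    final: State
    stop_reason: str            # "steady" | "max_time"
    n_steps: int
    max_rate: float             # max |rhs| at the final state
    diagnostics: dict = field(default_factory=dict)


def perturb(state: State, fluctuation: float, seed: int | None = None,
            distribution: str = "uniform") -> State:
    """Multiply every field value by (1 + u), u ~ U(-fluctuation, fluctuation)
    (or N(0, fluctuation) for the gaussian option), independently per entry.

    Deterministic given ``seed``; field order (a, p, a_apo, x, x_apo) is part
    of the contract so identical seeds give bit-identical states.
    """
    if not 0 <= fluctuation < 1:
        raise ValueError("fluctuation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = state.copy()
    for name, v in out.fields():
        if fluctuation == 0:
            continue
        if distribution == "uniform":
            u = rng.uniform(-fluctuation, fluctuation, size=v.shape)
        else:
            u = rng.normal(0.0, fluctuation, size=v.shape)
        setattr(out, name, v * (1.0 + u))
    return out


def total_auxin(spec: ModelSpec, params: Params, state: State) -> float:
    """Total auxin mass: sum_i a_i plus V * sum_edges a'_ij where apoplast
    compartments exist (the 1/V bookkeeping makes this the conserved total
    when synthesis/degradation are switched off)."""
    total = float(state.a.sum())
    if spec.has_apoplast:
        total += params.V * float(state.a_apo.sum())
    return total


def _max_rate(deriv: State) -> float:
    return max(float(np.max(np.abs(v))) for _, v in deriv.fields())


def _check_finite(state: State, t: float) -> None:
    for name, v in state.fields():
        if not np.all(np.isfinite(v)):
            raise IntegrationBlowupError(
                f"field {name!r} became non-finite at t={t:.6g} "
                "(time step too large)")
        if name != "p" and np.any(v < 0):
            raise IntegrationBlowupError(
                f"field {name!r} became negative at t={t:.6g} "
                "(time step too large)")


def integrate(spec: ModelSpec, params: Params, lattice: Lattice,
              state0: State, cfg: SimConfig) -> Trajectory:
    """Explicit Euler integration of ``rhs`` from ``state0``.

    Returns the trajectory with recorded snapshots (stride
    ``cfg.record_every``; the initial state is always snapshot 0),
    the final state, and the stop reason. Raises
    :class:`IntegrationBlowupError` if any concentration becomes negative or
    non-finite, naming the offending field and time.
    """
    params.validate(spec)
    state = state0.copy()
    _check_finite(state, 0.0)
    n_steps_max = int(round(cfg.max_time / cfg.dt))
    times = [0.0]
    snapshots = [state.copy()]
    masses = [total_auxin(spec, params, state)]
    stop_reason = "max_time"
    step = 0
    max_rate = np.inf
    while step < n_steps_max:
        try:
            deriv = rhs(spec, params, lattice, state)
        except DomainError as err:
            # a concentration went negative between finite-checks
            raise IntegrationBlowupError(
                f"state left the model domain at t={step * cfg.dt:.6g} "
                f"(time step too large): {err}") from err
        state.axpy(cfg.dt, deriv)
        step += 1
        t = step * cfg.dt
        if cfg.record_every and step % cfg.record_every == 0:
            times.append(t)
            snapshots.append(state.copy())
            masses.append(total_auxin(spec, params, state))
        if step % cfg.check_every == 0 or step == n_steps_max:
            _check_finite(state, t)
            max_rate = _max_rate(deriv)
            if max_rate < cfg.steady_tol:
                stop_reason = "steady"
                break
    final_deriv = rhs(spec, params, lattice, state)
    max_rate = _max_rate(final_deriv)
    t = step * cfg.dt
    if times[-1] != t:
        times.append(t)
        snapshots.append(state.copy())
        masses.append(total_auxin(spec, params, state))
    return Trajectory(
        times=times,
        snapshots=snapshots,
        final=state,
        stop_reason=stop_reason,
        n_steps=step,
        max_rate=max_rate,
        diagnostics={"total_auxin": masses},
    )
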