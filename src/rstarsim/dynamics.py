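"""Discrete-time dynamics of two consumers on one flowing resource.

Deterministic update (synchronous, from time-t values)::

    N_i(t+1) = N_i(t) + mu_i*N_i(t)*R(t)/(K_i + R(t)) - D*N_i(t)
    R(t+1)   = R(t) + D*(I - R(t)) - sum_i Q_i * mu_i*N_i(t)*R(t)/(K_i + R(t))

Stochastic (demographic) update replaces the growth and mortality terms by
Poisson draws around the deterministic expectations::

    N_i(t+1) = N_i(t) + pois(G_i) - min(pois(M_i), N_i(t))
    G_i = mu_i*N_i(t)*R(t)/(K_i + R(t)),   M_i = D*N_i(t)

Resource uptake equals quota times realised births and is never allowed to
exceed the resource available at the start of the step; when the drawn
births would overdraw the resource, total births are reduced to
``floor(R/Q)`` and split between the species proportionally to their drawn
births (largest-remainder rounding, rng coin flip on an exact tie).  With the
canonical parameters (I = 10, Q = 1e-6) this cap essentially never binds.

Populations are extinct once N < 1 (i.e. N == 0 in the integer stochastic
mode); extinction is absorbing in both modes.  Mortality does not return
resource to the pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .parameter_space import RegimeParameters

__all__ = [
    "SystemState",
    "StepIncrements",
    "TrajectoryResult",
    "monod_term",
    "deterministic_step",
    "stochastic_step",
    "run_trajectory",
]

Mode = Literal["deterministic", "stochastic"]


@dataclass(frozen=True)
class SystemState:
    """Populations (per litre), resource concentration (umol/L) and time step.

    Populations are non-negative; they are integers in stochastic mode and
    continuous in deterministic mode.
    """

    n_a: float
    n_b: float
    resource: float
    t: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("populations must be non-negative")
        if self.resource < 0:
            raise ValueError("resource concentration must be non-negative")
        if self.t < 0:
            raise ValueError("time step must be non-negative")


@dataclass(frozen=True)
class StepIncrements:
    """Expected and realised per-step birth/death increments and uptake.

    ``growth_*``/``mortality_*`` are the Poisson expectations G and M;
    the ``realized_*`` fields are the drawn integers (None in deterministic
    mode, where expectation and realisation coincide).
    """

    growth_a: float
    growth_b: float
    mortality_a: float
    mortality_b: float
    uptake: float
    realized_births_a: Optional[int] = None
    realized_births_b: Optional[int] = None
    realized_deaths_a: Optional[int] = None
    realized_deaths_b: Optional[int] = None


@dataclass(frozen=True)
class TrajectoryResult:
    """Final state at the horizon plus first-passage extinction times.

    ``extinction_time_a/b`` is the first step at which the population hit 0,
    or None if it survived.  ``trajectory`` (optional) is an array with
    columns (t, n_a, n_b, resource), thinned by the recording stride.
    """

    final: SystemState
    extinction_time_a: Optional[int]
    extinction_time_b: Optional[int]
    trajectory: Optional[np.ndarray] = None


def monod_term(mu: float, k: float, r: float) -> float:
    """Per-capita Monod growth rate mu*r/(k + r)."""
    if r < 0:
        raise ValueError("resource concentration must be non-negative")
    if k <= 0:
        raise ValueError("half-saturation constant must be positive")
    return mu * r / (k + r)


def _deterministic_update(n_a, n_b, r, p: RegimeParameters):
    """One synchronous deterministic step on raw scalars."""
    g_a = p.mu_a * n_a * r / (p.k_a + r) if n_a > 0 else 0.0
    g_b = p.mu_b * n_b * r / (p.k_b + r) if n_b > 0 else 0.0
    m_a = p.dilution * n_a
    m_b = p.dilution * n_b
    na1 = n_a + g_a - m_a
    nb1 = n_b + g_b - m_b
    if na1 < 1.0:
        na1 = 0.0
    if nb1 < 1.0:
        nb1 = 0.0
    uptake = p.quota_a * g_a + p.quota_b * g_b
    r1 = r + p.dilution * (p.inflow - r) - uptake
    if r1 < 0.0:
        r1 = 0.0
    return na1, nb1, r1, g_a, g_b, m_a, m_b, uptake


def _stochastic_update(n_a, n_b, r, p: RegimeParameters, rng: np.random.Generator):
    """One synchronous stochastic step on raw scalars.

    Returns (n_a', n_b', r', G_a, G_b, M_a, M_b, b_a, b_b, d_a, d_b, uptake).
    """
    poisson = rng.poisson
    if n_a > 0:
        g_a = p.mu_a * n_a * r / (p.k_a + r)
        m_a = p.dilution * n_a
        b_a = int(poisson(g_a))
        d_a = int(poisson(m_a))
        if d_a > n_a:
            d_a = int(n_a)
    else:
        g_a = m_a = 0.0
        b_a = d_a = 0
    if n_b > 0:
        g_b = p.mu_b * n_b * r / (p.k_b + r)
        m_b = p.dilution * n_b
        b_b = int(poisson(g_b))
        d_b = int(poisson(m_b))
        if d_b > n_b:
            d_b = int(n_b)
    else:
        g_b = m_b = 0.0
        b_b = d_b = 0

    uptake = p.quota_a * b_a + p.quota_b * b_b
    if uptake > r:
        b_a, b_b = _ration_births(b_a, b_b, r, p.quota_a, p.quota_b, rng)
        uptake = p.quota_a * b_a + p.quota_b * b_b

    na1 = n_a + b_a - d_a
    nb1 = n_b + b_b - d_b
    if na1 < 1:
        na1 = 0
    if nb1 < 1:
        nb1 = 0
    r1 = r + p.dilution * (p.inflow - r) - uptake
    if r1 < 0.0:
        r1 = 0.0
    return na1, nb1, r1, g_a, g_b, m_a, m_b, b_a, b_b, d_a, d_b, uptake


def _ration_births(b_a, b_b, r, q_a, q_b, rng):
    """Reduce drawn births so uptake fits in the available resource.

    Common-quota case: cap total births at floor(r/q) and allocate by
    largest-remainder rounding of each species' proportional share, breaking
    a single-birth tie with an rng coin flip.  Unequal quotas (not used by
    the canonical experiment) fall back to proportional down-scaling.
    """
    total_drawn = b_a + b_b
    if total_drawn == 0:
        return 0, 0
    if q_a != q_b:
        scale = r / (q_a * b_a + q_b * b_b)
        return int(b_a * scale), int(b_b * scale)
    allowed = int(r // q_a)
    if allowed >= total_drawn:
        return b_a, b_b
    share_a = allowed * b_a / total_drawn
    share_b = allowed * b_b / total_drawn
    fa = math.floor(share_a)
    fb = math.floor(share_b)
    if fa + fb < allowed:  # one unallocated birth remains
        frac_a = share_a - fa
        frac_b = share_b - fb
        if frac_a > frac_b:
            fa += 1
        elif frac_b > frac_a:
            fb += 1
        elif rng.integers(2) == 0:
            fa += 1
        else:
            fb += 1
    return fa, fb


def _require_integer_pops(state: SystemState) -> None:
    if float(state.n_a) != int(state.n_a) or float(state.n_b) != int(state.n_b):
        raise ValueError(
            "stochastic mode requires integer populations, got "
            f"({state.n_a}, {state.n_b})"
        )


def deterministic_step(state: SystemState, params: RegimeParameters) -> SystemState:
    """Advance one deterministic step; populations below 1 are zeroed."""
    na1, nb1, r1, *_ = _deterministic_update(
        state.n_a, state.n_b, state.resource, params
    )
    return SystemState(n_a=na1, n_b=nb1, resource=r1, t=state.t + 1)


def stochastic_step(
    state: SystemState, params: RegimeParameters, rng: np.random.Generator
) -> tuple[SystemState, StepIncrements]:
    """Advance one stochastic step; returns the new state and the increments."""
    _require_integer_pops(state)
    na1, nb1, r1, g_a, g_b, m_a, m_b, b_a, b_b, d_a, d_b, uptake = _stochastic_update(
        int(state.n_a), int(state.n_b), state.resource, params, rng
    )
    inc = StepIncrements(
        growth_a=g_a,
        growth_b=g_b,
        mortality_a=m_a,
        mortality_b=m_b,
        uptake=uptake,
        realized_births_a=b_a,
        realized_births_b=b_b,
        realized_deaths_a=d_a,
        realized_deaths_b=d_b,
    )
    return SystemState(n_a=na1, n_b=nb1, resource=r1, t=state.t + 1), inc


def run_trajectory(
    initial: SystemState,
    params: RegimeParameters,
    horizon: int,
    mode: Mode = "stochastic",
    rng: Optional[np.random.Generator] = None,
    record: bool = False,
    record_stride: int = 1,
) -> TrajectoryResult:
    """Iterate the chosen stepper for ``horizon`` steps.

    Records the first step at which each population hit zero.  Once both
    populations are extinct the loop exits early (the resource can no longer
    affect the outcome); the final state is reported with t = horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        _require_integer_pops(initial)
        n_a, n_b = int(initial.n_a), int(initial.n_b)
    else:
        n_a, n_b = float(initial.n_a), float(initial.n_b)
    r = float(initial.resource)
    t0 = initial.t
    ext_a = 0 if n_a == 0 else None
    ext_b = 0 if n_b == 0 else None
    traj = [(t0, n_a, n_b, r)] if record else None

    p = params
    stochastic = mode == "stochastic"
    for step in range(1, horizon + 1):
        if stochastic:
            n_a, n_b, r = _stochastic_update(n_a, n_b, r, p, rng)[:3]
        else:
            n_a, n_b, r = _deterministic_update(n_a, n_b, r, p)[:3]
        if ext_a is None and n_a == 0:
            ext_a = t0 + step
        if ext_b is None and n_b == 0:
            ext_b = t0 + step
        if record and (step % record_stride == 0 or step == horizon):
            traj.append((t0 + step, n_a, n_b, r))
        if n_a == 0 and n_b == 0:
            break

    final = SystemState(n_a=n_a, n_b=n_b, resource=r, t=t0 + horizon)
    trajectory = np.asarray(traj, dtype=float) if record else None
    return TrajectoryResult(
        final=final,
        extinction_time_a=ext_a,
        extinction_time_b=ext_b,
        trajectory=trajectory,
    )
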