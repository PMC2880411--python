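"""Deterministic pair-approximation reduction of the exit-entry dynamics.

Under weak selection (omega << 1) the local pair frequencies relax on a fast
timescale while the global type-A fraction p = P_A drifts slowly.  On the
fast manifold the conditional neighbour frequency takes the standard
pair-approximation form

    q_A|A = p + (1 - p) / (k - 1),

i.e. a type-A cell sees an excess 1/(k-1) of its own type over the global
frequency (local clustering generated by the birth process).  The slow
dynamics of p is

    dp/dt = rate_scale * omega * p (1 - p) * g(p),

with g the sign polynomial of :mod:`macronet.stability`.  Only the sign
structure (equilibria, stability, direction of flow) is anchored by theory;
the overall positive prefactor sets an arbitrary time unit, controlled by
``rate_scale`` (default 1), so time courses should not be read as calibrated
to simulation generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .payoffs import InteractionMatrix
from . import stability

__all__ = [
    "OdeConfig",
    "OdeTrajectory",
    "PhaseLine",
    "qAA_fast_equilibrium",
    "pA_rate",
    "integrate",
    "phase_line",
]


@dataclass(frozen=True)
class OdeConfig:
    """Configuration of one deterministic slow-manifold integration."""

    payoff: InteractionMatrix
    k: int
    omega: float
    p0: float
    t_max: float = 1e5
    rate_scale: float = 1.0
    n_eval: int = 400

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class OdeTrajectory:
    """Deterministic time course of p_A with its slaved pair frequency."""

    t: np.ndarray
    p_A: np.ndarray
    q_A_given_A: np.ndarray
    config: OdeConfig

    @property
    def final_p(self) -> float:
        return float(self.p_A[-1])


@dataclass
class PhaseLine:
    """Sampled evolutionary rate of p_A over [0, 1] with annotated roots."""

    p: np.ndarray
    rate: np.ndarray
    roots: list[float] = field(default_factory=list)


def qAA_fast_equilibrium(p_A: float | np.ndarray, k: int):
    """Fast-manifold equilibrium of the conditional frequency q_A|A.

    Valid for k >= 2; at k -> infinity the local excess vanishes and
    q_A|A -> p_A (well-mixed limit).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    return p_A + (1.0 - p_A) / (k - 1)


def pA_rate(
    p_A: float | np.ndarray,
    I: InteractionMatrix,
    k: int,
    omega: float,
    rate_scale: float = 1.0,
):
    """Slow-manifold rate of change of the global type-A fraction.

    rate = rate_scale * omega * p (1 - p) * (c0 + c1 p + c2 p^2); exactly
    zero at the absorbing boundaries p = 0 and p = 1.
    """
    c0, c1, c2 = stability.coefficients(I, k)
    p = np.asarray(p_A, dtype=float) if isinstance(p_A, np.ndarray) else p_A
    g = c0 + p * (c1 + p * c2)
    return rate_scale * omega * p * (1.0 - p) * g


def integrate(cfg: OdeConfig) -> OdeTrajectory:
    """Integrate the slow manifold with q_A|A slaved to its fast equilibrium.

    Uses adaptive explicit Runge-Kutta (RK45, rtol 1e-8) and clips
    machine-epsilon excursions of p back into [0, 1].
    """
    c0, c1, c2 = stability.coefficients(cfg.payoff, cfg.k)
    scale = cfg.rate_scale * cfg.omega

    def rhs(t, y):
        p = min(1.0, max(0.0, y[0]))
        return [scale * p * (1.0 - p) * (c0 + p * (c1 + p * c2))]

    t_eval = np.linspace(0.0, cfg.t_max, cfg.n_eval)
    sol = solve_ivp(
        rhs, (0.0, cfg.t_max), [cfg.p0],
        method="RK45", rtol=1e-8, atol=1e-10, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    p = np.clip(sol.y[0], 0.0, 1.0)
    q = p + (1.0 - p) / (cfg.k - 1)
    return OdeTrajectory(t=sol.t, p_A=p, q_A_given_A=q, config=cfg)


def phase_line(
    I: InteractionMatrix, k: int, omega: float,
    n_grid: int = 201, rate_scale: float = 1.0,
) -> PhaseLine:
    """Sample the rate on a uniform grid over [0, 1] and annotate the roots.

    Roots come from the analytic equilibrium set (0, 1, and the interior
    root c0/c2 when it lies inside the unit interval), not from numerical
    sign-change hunting.
    """
    if n_grid < 3:
        raise ValueError(f"n_grid must be >= 3, got {n_grid}")
    p = np.linspace(0.0, 1.0, n_grid)
    rate = pA_rate(p, I, k, omega, rate_scale)
    roots = [eq.p for eq in stability.equilibria(I, k)]
    return PhaseLine(p=p, rate=np.asarray(rate), roots=roots)
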