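"""Equilibria and stability of the pair-approximated exit-entry dynamics.

Under weak selection the global type-A fraction p = P_A obeys a slow-manifold
equation whose sign structure is carried entirely by the quadratic

    g(p) = c0 + c1 p + c2 p**2,

with coefficients determined by the interaction matrix (a, b, c, d) and the
degree k:

    c0 = (k+1) a + (k^2 - k - 1) b - c - (k^2 - 1) d
    c1 = (k+1)(k-3) a - (2k^2 - 2k - 3) b - (k^2 - k - 3) c + (2k^2 - k - 3) d
    c2 = -(k+1)(k-2)(a - b - c + d)

These follow from expanding the expected per-event change of P_A to first
order in omega with the pair frequencies on their fast manifold (neighbour
types drawn from the conditional frequencies q, each neighbour's energy
summed over its k links including the vacated vertex); the expansion is
rederived symbolically in the test suite and validated against the
stochastic simulator.  The derived per-event drift is proportional to
omega p (1 - p) (c0 - c2 p) (k-2)/(k(k-1)), an exact mirror-symmetric form:
relabeling the two types (a<->d, b<->c, p -> 1-p) negates it.  The
quadratic g(p) = (1 - p)(c0 - c2 p) used throughout carries the same sign
structure on (0, 1), so equilibria, stability and classification coincide.

The identity c0 + c1 + c2 = 0 holds for every (a, b, c, d, k), so g factors
as g(p) = c2 (p - 1)(p - c0/c2): p = 1 is always a root of g, and the only
possible interior equilibrium of the full rate p (1 - p) g(p) is
p* = c0 / c2.  Classification of the long-run behaviour from (matrix, k, p0)
is then exact sign analysis of g on the interval between the initial
frequency p0 and each candidate limit:

* A dominates (limit 1) when g > 0 throughout (p0, 1);
* C dominates (limit 0) when g < 0 throughout (0, p0);
* stable coexistence at p* when c2 > 0 and p* is interior (g > 0 below p*,
  g < 0 above);
* a bistable threshold at p* when c2 < 0 and p* is interior: the population
  fixes at 1 if p0 > p*, at 0 if p0 < p*, and is undecided exactly at p*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

from .payoffs import InteractionMatrix

__all__ = [
    "StabilityReport",
    "Equilibrium",
    "coefficients",
    "g_poly",
    "equilibria",
    "classify",
]

_SIGN_TOL = 1e-12


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium of the slow dynamics with its stability label."""

    p: float
    stability: str  # 'stable' | 'unstable' | 'semi-stable' | 'degenerate'


@dataclass(frozen=True)
class StabilityReport:
    """Full analytic characterisation of one (matrix, k, p0) configuration."""

    c0: float
    c1: float
    c2: float
    equilibria: tuple[Equilibrium, ...]
    interior_root: Optional[float]
    case_label: str  # 'A_dominates' | 'C_dominates' | 'stable_coexistence'
    #                 | 'bistable_threshold' | 'neutral'
    predicted_limit: Optional[float]
    basin_boundary: Optional[float] = None
    undecided: bool = False
    inputs: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def coefficients(I: InteractionMatrix, k: int) -> tuple[float, float, float]:
    """Coefficients (c0, c1, c2) of the sign polynomial g(p) = c0 + c1 p + c2 p^2."""
    if k < 2:
        raise ValueError(f"degree k must be >= 2, got {k}")
    a, b, c, d = I.as_tuple()
    c0 = (k + 1) * a + (k * k - k - 1) * b - c - (k * k - 1) * d
    c1 = (
        (k + 1) * (k - 3) * a
        - (2 * k * k - 2 * k - 3) * b
        - (k * k - k - 3) * c
        + (2 * k * k - k - 3) * d
    )
    c2 = -(k + 1) * (k - 2) * (a - b - c + d)
    return c0, c1, c2


def g_poly(p: float, I: InteractionMatrix, k: int) -> float:
    """Evaluate the sign polynomial g(p)."""
    c0, c1, c2 = coefficients(I, k)
    return c0 + p * (c1 + p * c2)


def _interior_root(c0: float, c2: float) -> Optional[float]:
    """c0/c2 when c2 != 0 and the quotient lies strictly inside (0, 1)."""
    if abs(c2) < _SIGN_TOL:
        return None
    r = c0 / c2
    if _SIGN_TOL < r < 1.0 - _SIGN_TOL:
        return r
    return None


def equilibria(I: InteractionMatrix, k: int) -> list[Equilibrium]:
    """Equilibria {0, 1, and c0/c2 when interior} with stability labels.

    Labels follow the sign of the full rate f(p) = p (1 - p) g(p) on each
    side of each equilibrium: 'stable' if f pushes toward it from both sides,
    'unstable' if away from both, 'semi-stable' if mixed, 'degenerate' when
    g vanishes identically (payoff-indifferent dynamics).
    """
    c0, c1, c2 = coefficients(I, k)
    if abs(c0) < _SIGN_TOL and abs(c1) < _SIGN_TOL and abs(c2) < _SIGN_TOL:
        return [
            Equilibrium(0.0, "degenerate"),
            Equilibrium(1.0, "degenerate"),
        ]
    root = _interior_root(c0, c2)
    points = [0.0] + ([root] if root is not None else []) + [1.0]

    def g(p: float) -> float:
        return c0 + p * (c1 + p * c2)

    out: list[Equilibrium] = []
    for i, p_star in enumerate(points):
        lo = points[i - 1] if i > 0 else None
        hi = points[i + 1] if i < len(points) - 1 else None
        # sign of the rate f = p(1-p) g just left / right of p_star;
        # outside [0,1] the dynamics is undefined, treat boundary one-sided
        left = g((lo + p_star) / 2.0) if lo is not None else None
        right = g((p_star + hi) / 2.0) if hi is not None else None
        # f has the sign of g inside (0,1)
        toward_left = left is not None and left > _SIGN_TOL  # flow up toward p_star
        away_left = left is not None and left < -_SIGN_TOL
        toward_right = right is not None and right < -_SIGN_TOL  # flow down toward
        away_right = right is not None and right > _SIGN_TOL
        n_sides = (left is not None) + (right is not None)
        n_toward = toward_left + toward_right
        n_away = away_left + away_right
        if n_toward == n_sides:
            label = "stable"
        elif n_away == n_sides:
            label = "unstable"
        elif n_toward + n_away < n_sides:
            label = "degenerate"  # g vanishes on an adjacent interval midpoint
        else:
            label = "semi-stable"
        out.append(Equilibrium(p_star, label))
    return out


def classify(I: InteractionMatrix, k: int, p0: float) -> StabilityReport:
    """Predict the long-run fate of the type-A fraction from (matrix, k, p0).

    Returns a :class:`StabilityReport` with the coefficients, the labelled
    equilibrium set, a case label, and the predicted limit of P_A.  Initial
    frequencies p0 in {0, 1} are absorbing and returned as such.  When the
    dynamics is bistable and p0 sits exactly on the threshold the report is
    flagged ``undecided`` rather than silently assigned to a basin.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    c0, c1, c2 = coefficients(I, k)
    eqs = tuple(equilibria(I, k))
    root = _interior_root(c0, c2)
    inputs = {"a": I.a, "b": I.b, "c": I.c, "d": I.d, "k": k, "p0": p0}

    def report(case: str, limit: Optional[float], *, basin=None, undecided=False):
        return StabilityReport(
            c0=c0, c1=c1, c2=c2, equilibria=eqs, interior_root=root,
            case_label=case, predicted_limit=limit, basin_boundary=basin,
            undecided=undecided, inputs=inputs,
        )

    degenerate = abs(c0) < _SIGN_TOL and abs(c1) < _SIGN_TOL and abs(c2) < _SIGN_TOL
    if degenerate:
        # payoff-indifferent: every p is an equilibrium of the slow dynamics
        return report("neutral", p0)

    if p0 == 0.0 or p0 == 1.0:
        return report(_boundary_case(c0, c2, root), p0)

    if root is not None:
        if c2 > 0:
            # g > 0 below the root, g < 0 above: globally attracting interior
            return report("stable_coexistence", root)
        # c2 < 0: interior root repels; basins split at the root
        if p0 > root + _SIGN_TOL:
            return report("bistable_threshold", 1.0, basin=root)
        if p0 < root - _SIGN_TOL:
            return report("bistable_threshold", 0.0, basin=root)
        return report("bistable_threshold", None, basin=root, undecided=True)

    # no interior root: g keeps one sign on (0, 1); sample midpoint
    mid = c0 + 0.5 * (c1 + 0.5 * c2)
    if mid > _SIGN_TOL:
        return report("A_dominates", 1.0)
    if mid < -_SIGN_TOL:
        return report("C_dominates", 0.0)
    # g not identically zero but vanishing at the midpoint: razor's-edge
    return report("neutral", p0, undecided=True)


def _boundary_case(c0: float, c2: float, root: Optional[float]) -> str:
    if root is not None:
        return "stable_coexistence" if c2 > 0 else "bistable_threshold"
    mid = c0 + 0.5 * (-c0 - c2 + 0.5 * c2)  # g(1/2) using c1 = -c0 - c2
    return "A_dominates" if mid > 0 else "C_dominates"
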