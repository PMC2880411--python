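"""Interaction matrix, group fitness and the exit-entry replacement rule.

Two cell types are tracked, A (alternatively activated, pro-repair) and C
(classically activated, pro-inflammatory).  A 2x2 interaction matrix gives
the energy a cell of one type confers on a linked cell of each type:

              to A   to C
    from A  [  a      b  ]
    from C  [  c      d  ]

Equivalently, in game-theoretic terms, a type-A cell playing against an A
neighbour collects payoff ``a`` and against a C neighbour payoff ``b``; a
type-C cell collects ``c`` against A and ``d`` against C.  A cell's energy
``eps`` is the sum of these payoffs over its links, and its fitness is the
weak-selection blend ``F = 1 - omega + omega * eps``.

When a randomly chosen cell exits the network, the vacated vertex is refilled
by type A with probability ``F_A / (F_A + F_C)``, where ``F_A`` and ``F_C``
aggregate the fitness of the type-A and type-C neighbours of the vacated
vertex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "InteractionMatrix",
    "SelectionConfig",
    "NeighborTally",
    "FitnessPair",
    "group_fitness",
    "replacement_probability",
    "validate_selection",
    "WEAK_SELECTION_WARN_THRESHOLD",
]

#: omega above this is outside the weak-selection regime the reduction assumes.
WEAK_SELECTION_WARN_THRESHOLD = 0.1


@dataclass(frozen=True)
class InteractionMatrix:
    """Interaction strengths between type-A and type-C cells.

    Entries are dimensionless and may be negative (inhibitory interaction).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        import math

        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"interaction entry {name!r} must be finite, got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def swapped(self) -> "InteractionMatrix":
        """The matrix under the relabeling A <-> C (a<->d, b<->c)."""
        return InteractionMatrix(self.d, self.c, self.b, self.a)


@dataclass(frozen=True)
class SelectionConfig:
    """Selection intensity omega in [0, 1).

    omega = 0 is neutral drift; omega << 1 is the weak-selection regime in
    which the pair-approximation reduction is valid.  Values above
    ``WEAK_SELECTION_WARN_THRESHOLD`` trigger a warning (recorded in run
    metadata by callers) but are not rejected.
    """

    omega: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega < 1.0):
            raise ValueError(f"omega must be in [0, 1), got {self.omega}")
        if self.omega > WEAK_SELECTION_WARN_THRESHOLD:
            warnings.warn(
                f"omega={self.omega} exceeds the weak-selection threshold "
                f"{WEAK_SELECTION_WARN_THRESHOLD}; the pair-approximation "
                "reduction may be inaccurate",
                stacklevel=3,
            )

    @property
    def is_weak(self) -> bool:
        return self.omega <= WEAK_SELECTION_WARN_THRESHOLD


@dataclass(frozen=True)
class NeighborTally:
    """Neighbourhood bookkeeping around a vacated vertex of degree k.

    ``K_A`` and ``K_C`` count the type-A and type-C neighbours of the vacated
    vertex.  ``edges_A_to_A`` / ``edges_A_to_C`` aggregate, over all K_A
    type-A neighbours, how many of their own links point at A cells and at C
    cells; ``edges_C_to_A`` / ``edges_C_to_C`` do the same for the K_C type-C
    neighbours.  Whether the link back to the vacated vertex is included in a
    neighbour's tally is a convention set where the tally is built (see
    ``abm.step``); with it included every neighbour contributes exactly k
    links, so edges_A_to_A + edges_A_to_C == K_A * k.
    """

    K_A: int
    K_C: int
    edges_A_to_A: int = 0
    edges_A_to_C: int = 0
    edges_C_to_A: int = 0
    edges_C_to_C: int = 0

    def __post_init__(self) -> None:
        fields = (
            self.K_A, self.K_C,
            self.edges_A_to_A, self.edges_A_to_C,
            self.edges_C_to_A, self.edges_C_to_C,
        )
        if any(v < 0 for v in fields):
            raise ValueError(f"neighbor tallies must be non-negative, got {self}")

    @property
    def k(self) -> int:
        """Degree of the vacated vertex."""
        return self.K_A + self.K_C


@dataclass(frozen=True)
class FitnessPair:
    """Aggregate fitness of the type-A and type-C neighbour groups."""

    F_A: float
    F_C: float


def group_fitness(
    tally: NeighborTally, I: InteractionMatrix, sel: SelectionConfig
) -> FitnessPair:
    """Aggregate fitness of the neighbour groups around a vacated vertex.

    Each neighbour contributes ``(1 - omega) + omega * eps`` where ``eps`` is
    its energy, i.e. the payoff summed over its tallied links.  Summed over a
    group of K same-type neighbours:

        F_A = K_A (1 - omega) + omega (edges_A_to_A * a + edges_A_to_C * b)
        F_C = K_C (1 - omega) + omega (edges_C_to_A * c + edges_C_to_C * d)

    An empty group has fitness exactly 0.
    """
    w = sel.omega
    F_A = tally.K_A * (1.0 - w) + w * (
        tally.edges_A_to_A * I.a + tally.edges_A_to_C * I.b
    )
    F_C = tally.K_C * (1.0 - w) + w * (
        tally.edges_C_to_A * I.c + tally.edges_C_to_C * I.d
    )
    return FitnessPair(F_A=F_A, F_C=F_C)


def replacement_probability(F: FitnessPair) -> float:
    """Probability that the vacated vertex is refilled by a type-A cell.

    Returns ``F_A / (F_A + F_C)``.  Raises ``ValueError`` on the degenerate
    configuration F_A + F_C == 0 (cannot arise on a k>=2 regular graph once
    ``validate_selection`` has passed).
    """
    total = F.F_A + F.F_C
    if total <= 0.0:
        raise ValueError(
            f"degenerate fitness configuration: F_A={F.F_A}, F_C={F.F_C}; "
            "total group fitness must be positive"
        )
    p = F.F_A / total
    # guard against rounding excursions
    return min(1.0, max(0.0, p))


def validate_selection(
    I: InteractionMatrix, k: int, sel: SelectionConfig
) -> None:
    """Reject configurations whose negative payoffs can produce non-positive fitness.

    With negative interaction entries a neighbour's fitness
    ``(1 - omega) + omega * eps`` can go non-positive, which would break the
    replacement rule.  The worst attainable energy of a single type-A
    neighbour of degree k is ``k * min(a, b)`` (all links at the least
    favourable type), so the minimal attainable group fitness over group
    sizes K in 1..k is ``K * [(1 - omega) + omega * k * min(row)]``, whose
    sign is that of the bracket.  Raises ``ValueError`` if either type's
    bound is non-positive.
    """
    if k < 2:
        raise ValueError(f"degree k must be >= 2, got {k}")
    w = sel.omega
    for label, row_min in (("A", min(I.a, I.b)), ("C", min(I.c, I.d))):
        worst = (1.0 - w) + w * k * row_min
        if worst <= 0.0:
            raise ValueError(
                f"selection too strong for payoff range: a type-{label} "
                f"neighbour can attain fitness {worst:.6g} <= 0 "
                f"(omega={w}, k={k}, worst row entry {row_min}); "
                "reduce omega or the magnitude of negative entries"
            )
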