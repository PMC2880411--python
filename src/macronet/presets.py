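"""Preset experiments: the six figure-scale single-run configurations and
the degree/entry sweep.

All presets share the published study conditions: N = 10000 cells on a
random 4-regular graph, selection intensity omega = 0.01, and initial
counts drawn from the post-infarct macrophage estimates (9900/100 at day 3;
4000/6000 and 2000/8000 for the initial-status comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

from .abm import RunConfig
from .network import NetworkConfig
from .payoffs import InteractionMatrix, SelectionConfig

__all__ = ["ExperimentPreset", "PRESETS", "SWEEP_PRESETS", "get_preset"]


@dataclass(frozen=True)
class ExperimentPreset:
    """One named single-run experiment with its expected qualitative outcome."""

    name: str
    payoff: InteractionMatrix
    n_A_initial: int
    expected: str  # qualitative long-run outcome of P_A
    max_generations: int = 3_000

    def run_config(self, seed: int = 0) -> RunConfig:
        return RunConfig(
            network=NetworkConfig(N=10_000, k=4, seed=seed),
            payoff=self.payoff,
            sel=SelectionConfig(0.01),
            n_A_initial=self.n_A_initial,
            max_generations=self.max_generations,
            generation_unit="sweep",
            record_every=10,
            seed=seed,
        )

    @property
    def p0(self) -> float:
        return self.n_A_initial / 10_000


PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in (
        ExperimentPreset("fig2", InteractionMatrix(1, 0, 0, 1), 9_900,
                         "type A dominates (P_A -> 1)"),
        ExperimentPreset("fig3", InteractionMatrix(0, -0.5, 1, 0), 9_900,
                         "type C dominates (P_A -> 0)"),
        ExperimentPreset("fig4", InteractionMatrix(0, 1, 1, 0), 9_900,
                         "stable coexistence (P_A -> 0.5)"),
        ExperimentPreset("fig5", InteractionMatrix(0, 1, 1, 0), 4_000,
                         "stable coexistence (P_A -> 0.5)"),
        ExperimentPreset("fig6", InteractionMatrix(0, -1, -2, 0), 9_900,
                         "bistable: above threshold 0.3, type A fixes (P_A -> 1)"),
        ExperimentPreset("fig7", InteractionMatrix(0, -1, -2, 0), 2_000,
                         "bistable: below threshold 0.3, type A exits (P_A -> 0)"),
    )
}

#: Degree/entry sweep (the two-panel grid experiment): mean type-C count
#: after 5 generations, varying b in [0 b; 1 0] or d in [1 0; 0 d]
#: for k in {4, 5, 6}, initial 100 type-C cells of 10000.
SWEEP_PRESETS: dict[str, dict] = {
    "fig8": dict(
        entries=("b", "d"),
        values=(-1.0, 0.0, 1.0, 2.0),
        ks=(4, 5, 6),
        N=10_000,
        n_C_initial=100,
        omega=0.01,
        readout_generation=5,
    ),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
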