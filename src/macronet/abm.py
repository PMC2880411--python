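"""Stochastic exit-entry (death-birth) simulation on k-regular graphs.

One elementary event: a uniformly random cell exits; the vacated vertex is
refilled by type A with probability F_A / (F_A + F_C) computed from the
fitness of the vertex's neighbour groups (see :mod:`macronet.payoffs`),
otherwise by type C.  The population size is conserved and the homogeneous
states n_A in {0, N} are absorbing.

Two generation units are supported: ``'event'`` (one generation = one
exit-entry event) and ``'sweep'`` (one generation = N events, the scale on
which figure-style population curves are drawn; the default).  Both
semantics are recorded in the trajectory metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .network import (
    GraphState,
    NetworkConfig,
    StateSummary,
    assign_types,
    build_regular_graph,
    neighbor_array,
    summary_from_counts,
)
from .payoffs import (
    FitnessPair,
    InteractionMatrix,
    NeighborTally,
    SelectionConfig,
    group_fitness,
    replacement_probability,
    validate_selection,
)

__all__ = [
    "RunConfig",
    "EventRecord",
    "Trajectory",
    "EnsembleSummary",
    "step",
    "build_tally",
    "run",
    "ensemble",
    "sweep_entry",
    "quasi_stationary_mean",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one stochastic run."""

    network: NetworkConfig
    payoff: InteractionMatrix
    sel: SelectionConfig
    n_A_initial: int
    max_generations: int
    generation_unit: Literal["event", "sweep"] = "sweep"
    record_every: int = 1
    seed: int = 0
    count_vacated_link: bool = True

    def __post_init__(self) -> None:
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if not (0 <= self.n_A_initial <= self.network.N):
            raise ValueError(
                f"n_A_initial must be in [0, {self.network.N}], "
                f"got {self.n_A_initial}"
            )
        if self.generation_unit not in ("event", "sweep"):
            raise ValueError(f"unknown generation_unit {self.generation_unit!r}")
        validate_selection(self.payoff, self.network.k, self.sel)

    @property
    def events_per_generation(self) -> int:
        return self.network.N if self.generation_unit == "sweep" else 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class EventRecord:
    """Bookkeeping for a single exit-entry event."""

    exited_vertex: int
    exited_type: str
    entered_type: str
    prob_enter_A: float


@dataclass
class Trajectory:
    """Per-generation record of one run.

    ``generations`` and ``n_A`` are aligned arrays (generation in the unit
    named by the config); pair counts are kept so full
    :class:`~macronet.network.StateSummary` records can be reconstructed
    without rescanning the graph.
    """

    generations: np.ndarray
    n_A: np.ndarray
    m_AA: np.ndarray
    m_AC: np.ndarray
    m_CC: np.ndarray
    absorbed: bool
    absorption_generation: Optional[float]
    config: RunConfig

    @property
    def N(self) -> int:
        return self.config.network.N

    @property
    def final_n_A(self) -> int:
        return int(self.n_A[-1])

    def summary_at(self, i: int) -> StateSummary:
        return summary_from_counts(
            self.N, self.config.network.k, int(self.n_A[i]),
            int(self.m_AA[i]), int(self.m_AC[i]), int(self.m_CC[i]),
        )

    @property
    def records(self) -> Iterator[tuple[float, int, StateSummary]]:
        for i, g in enumerate(self.generations):
            yield float(g), int(self.n_A[i]), self.summary_at(i)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with the standard CSV columns."""
        rows = []
        for g, n_A, s in self.records:
            rows.append(
                dict(generation=g, n_A=n_A, P_A=s.P_A, P_AA=s.P_AA,
                     P_AC=s.P_AC, P_CC=s.P_CC, q_A_given_A=s.q_A_given_A)
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnsembleSummary:
    """Aggregate of n_runs independent trajectories under one config.

    Absorbed runs hold their absorbing value for all later recorded
    generations (constant extension) when averaging.
    """

    n_runs: int
    generations: np.ndarray
    mean_n_A: np.ndarray
    std_n_A: np.ndarray
    final_n_A: np.ndarray
    absorption_generations: np.ndarray  # NaN where not absorbed
    fixation_fraction_A: float
    fixation_fraction_C: float
    seeds: list[int]
    config: RunConfig

    def to_json(self, **kwargs) -> str:
        payload = {
            "config": self.config.to_dict(),
            "n_runs": self.n_runs,
            "seeds": self.seeds,
            "generations": self.generations.tolist(),
            "mean_n_A": self.mean_n_A.tolist(),
            "std_n_A": self.std_n_A.tolist(),
            "final_n_A": self.final_n_A.tolist(),
            "absorption_generations": [
                None if np.isnan(g) else float(g)
                for g in self.absorption_generations
            ],
            "fixation_fraction_A": self.fixation_fraction_A,
            "fixation_fraction_C": self.fixation_fraction_C,
        }
        return json.dumps(payload, **kwargs)


def build_tally(
    state: GraphState, v: int, count_vacated_link: bool = True
) -> NeighborTally:
    """Neighbour tally around vertex v, with v treated as just having exited.

    By the vacated-link convention each neighbour's energy sums over all k of
    its links, the link back to v contributing with the exiting cell's type;
    with ``count_vacated_link=False`` that link is skipped.
    """
    K_A = K_C = 0
    eAA = eAC = eCA = eCC = 0
    t = state.types
    for u in state.graph.neighbors(v):
        to_A = to_C = 0
        for w in state.graph.neighbors(u):
            if w == v and not count_vacated_link:
                continue
            if t[w] == 1:
                to_A += 1
            else:
                to_C += 1
        if t[u] == 1:
            K_A += 1
            eAA += to_A
            eAC += to_C
        else:
            K_C += 1
            eCA += to_A
            eCC += to_C
    return NeighborTally(
        K_A=K_A, K_C=K_C,
        edges_A_to_A=eAA, edges_A_to_C=eAC,
        edges_C_to_A=eCA, edges_C_to_C=eCC,
    )


def step(
    state: GraphState,
    I: InteractionMatrix,
    sel: SelectionConfig,
    rng: np.random.Generator,
    count_vacated_link: bool = True,
) -> EventRecord:
    """One exit-entry event, mutating ``state`` in place.

    Draw order: exiting vertex first, then the replacement Bernoulli.
    Raises ``ValueError`` on an absorbed state (n_A in {0, N}), which the
    dynamics cannot leave.
    """
    n_A = state.n_A
    if n_A == 0 or n_A == state.N:
        raise ValueError("cannot step an absorbed state (n_A in {0, N})")
    v = int(rng.integers(state.N))
    exited = int(state.types[v])
    tally = build_tally(state, v, count_vacated_link)
    F = group_fitness(tally, I, sel)
    p_A = replacement_probability(F)
    entered = 1 if rng.random() < p_A else 0
    state.types[v] = entered
    return EventRecord(
        exited_vertex=v,
        exited_type="A" if exited == 1 else "C",
        entered_type="A" if entered == 1 else "C",
        prob_enter_A=p_A,
    )


def run(cfg: RunConfig) -> Trajectory:
    """One full stochastic run: iterate events until absorption or the horizon.

    The graph, the initial type assignment and the event sequence are all
    deterministic functions of the seeds in ``cfg``.
    """
    graph = build_regular_graph(cfg.network)
    state = assign_types(graph, cfg.n_A_initial, cfg.network.seed + 1,
                         k=cfg.network.k)
    nbrs = neighbor_array(graph, cfg.network.k)

    epg = cfg.events_per_generation
    max_events = cfg.max_generations * epg
    stride = cfg.record_every * epg
    n_slots = max_events // stride + 3
    rec_event = np.zeros(n_slots, dtype=np.int64)
    rec_nA = np.zeros(n_slots, dtype=np.int64)
    rec_mAA = np.zeros(n_slots, dtype=np.int64)
    rec_mAC = np.zeros(n_slots, dtype=np.int64)
    rec_mCC = np.zeros(n_slots, dtype=np.int64)

    a, b, c, d = cfg.payoff.as_tuple()
    n_rec, absorbed, absorption_event, _ = _kernel.run_events(
        nbrs, state.types, a, b, c, d, cfg.sel.omega,
        cfg.count_vacated_link,
        max_events, stride, cfg.seed % _SEED_MOD,
        rec_event, rec_nA, rec_mAA, rec_mAC, rec_mCC,
    )
    gens = rec_event[:n_rec] / epg
    return Trajectory(
        generations=gens,
        n_A=rec_nA[:n_rec].copy(),
        m_AA=rec_mAA[:n_rec].copy(),
        m_AC=rec_mAC[:n_rec].copy(),
        m_CC=rec_mCC[:n_rec].copy(),
        absorbed=bool(absorbed),
        absorption_generation=(absorption_event / epg) if absorbed else None,
        config=cfg,
    )


def ensemble(cfg: RunConfig, n_runs: int, base_seed: int) -> EnsembleSummary:
    """n_runs independent runs with seeds base_seed, base_seed+1, ...

    Graphs and initial assignments are redrawn per run (the network seed is
    offset by the run index), so ensemble spread includes structural
    variability, not just event noise.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    grid = np.arange(0, cfg.max_generations + 1, cfg.record_every, dtype=float)
    all_nA = np.empty((n_runs, grid.size))
    final = np.empty(n_runs, dtype=np.int64)
    absorb = np.full(n_runs, np.nan)
    seeds = []
    for i in range(n_runs):
        seed_i = (base_seed + i) % _SEED_MOD
        seeds.append(seed_i)
        cfg_i = dataclasses.replace(
            cfg,
            seed=seed_i,
            network=dataclasses.replace(cfg.network, seed=seed_i),
        )
        traj = run(cfg_i)
        # constant extension onto the common grid
        all_nA[i] = _extend_onto_grid(traj, grid)
        final[i] = traj.final_n_A
        if traj.absorbed:
            absorb[i] = traj.absorption_generation
    N = cfg.network.N
    fix_A = float(np.mean(final == N))
    fix_C = float(np.mean(final == 0))
    return EnsembleSummary(
        n_runs=n_runs,
        generations=grid,
        mean_n_A=all_nA.mean(axis=0),
        std_n_A=all_nA.std(axis=0, ddof=1) if n_runs > 1
        else np.zeros(grid.size),
        final_n_A=final,
        absorption_generations=absorb,
        fixation_fraction_A=fix_A,
        fixation_fraction_C=fix_C,
        seeds=seeds,
        config=cfg,
    )


def _extend_onto_grid(traj: Trajectory, grid: np.ndarray) -> np.ndarray:
    """Sample a trajectory on a generation grid, holding the last value."""
    idx = np.searchsorted(traj.generations, grid, side="right") - 1
    idx = np.clip(idx, 0, traj.generations.size - 1)
    return traj.n_A[idx].astype(float)


def quasi_stationary_mean(traj: Trajectory, window: int) -> float:
    """Mean n_A over the final ``window`` recorded generations."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return float(traj.n_A[-window:].mean())


def sweep_entry(
    entry: Literal["b", "d"],
    values: Sequence[float],
    ks: Sequence[int],
    *,
    N: int = 10_000,
    n_C_initial: int = 100,
    omega: float = 0.01,
    readout_generation: int = 5,
    n_runs: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Grid experiment: mean type-C population at a fixed readout generation.

    Varies one payoff entry over ``values`` for each degree in ``ks``:
    ``entry='b'`` uses matrices [0 b; 1 0] and ``entry='d'`` uses
    [1 0; 0 d].  Each grid point is averaged over ``n_runs`` replicates;
    replicate i uses seed base_seed + i at every grid point (common random
    numbers), so comparisons along the grid are paired.
    """
    if entry not in ("b", "d"):
        raise ValueError("entry must be 'b' or 'd'")
    rows = []
    for k in ks:
        for val in values:
            I = (InteractionMatrix(0.0, val, 1.0, 0.0) if entry == "b"
                 else InteractionMatrix(1.0, 0.0, 0.0, val))
            cfg = RunConfig(
                network=NetworkConfig(N=N, k=k),
                payoff=I,
                sel=SelectionConfig(omega),
                n_A_initial=N - n_C_initial,
                max_generations=readout_generation,
                generation_unit="sweep",
                record_every=readout_generation,
                seed=0,
            )
            summ = ensemble(cfg, n_runs, base_seed)
            n_C_final = N - summ.mean_n_A[-1]
            rows.append(
                dict(entry=entry, value=val, k=k,
                     mean_n_C=float(n_C_final),
                     sem_n_C=float(summ.std_n_A[-1] / np.sqrt(n_runs)),
                     n_runs=n_runs)
            )
    return pd.DataFrame(rows)
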