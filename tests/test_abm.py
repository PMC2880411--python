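import dataclasses

import numpy as np
import pytest

from macronet import _kernel
from macronet.abm import (
    RunConfig,
    build_tally,
    ensemble,
    quasi_stationary_mean,
    run,
    step,
    sweep_entry,
)
from macronet.network import (
    NetworkConfig,
    assign_types,
    build_regular_graph,
    neighbor_array,
    summarize_state,
)
from macronet.payoffs import (
    InteractionMatrix,
    SelectionConfig,
    group_fitness,
    replacement_probability,
)
from macronet.pair_approx import qAA_fast_equilibrium

from conftest import random_state


class _ForcedRng:
    """Generator stand-in that exits a chosen vertex, then draws uniform u."""

    def __init__(self, vertex: int, u: float):
        self._v, self._u = vertex, u

    def integers(self, n):
        return self._v

    def random(self):
        return self._u


def _small_cfg(**overrides) -> RunConfig:
    base = dict(
        network=NetworkConfig(N=30, k=4, seed=2),
        payoff=InteractionMatrix(0, 1, 1, 0),
        sel=SelectionConfig(0.01),
        n_A_initial=15,
        max_generations=50,
        generation_unit="sweep",
        record_every=1,
        seed=2,
    )
    base.update(overrides)
    return RunConfig(**base)


class TestStep:
    def test_unanimous_neighborhood_forces_type(self):
        # every neighbour of the exiting cell is type A -> F_C = 0 -> enter A
        state = random_state(N=20, k=4, p=0.0, seed=1)
        state.types[:] = 1
        state.types[3] = 0  # lone C cell; its neighbours are all A
        rec = step(state, InteractionMatrix(0, 1, 1, 0), SelectionConfig(0.01),
                   _ForcedRng(3, 0.999999))
        assert rec.exited_type == "C" and rec.entered_type == "A"
        assert rec.prob_enter_A == 1.0

    def test_population_is_conserved(self, rng):
        state = random_state(N=30, k=4, p=0.5, seed=4)
        for _ in range(200):
            if state.n_A in (0, state.N):
                break
            step(state, InteractionMatrix(0, 1, 1, 0), SelectionConfig(0.01), rng)
            assert state.n_A + state.n_C == 30

    def test_absorbed_state_refuses_to_step(self, rng):
        state = random_state(N=20, k=4, p=0.0, seed=1)
        with pytest.raises(ValueError, match="absorbed"):
            step(state, InteractionMatrix(0, 1, 1, 0), SelectionConfig(0.01), rng)

    def test_neutral_probability_is_local_frequency(self):
        """At omega=0 the replacement probability is exactly K_A / k."""
        state = random_state(N=40, k=5, p=0.4, seed=6)
        sel = SelectionConfig(0.0)
        I = InteractionMatrix(3, -1, 2, 0.5)
        for v in range(state.N):
            tally = build_tally(state, v)
            p = replacement_probability(group_fitness(tally, I, sel))
            assert p == pytest.approx(tally.K_A / 5)

    def test_tally_edge_conservation(self):
        # with the vacated link counted, each neighbour contributes all k links
        state = random_state(N=40, k=4, p=0.5, seed=8)
        for v in range(0, 40, 7):
            t = build_tally(state, v, count_vacated_link=True)
            assert t.edges_A_to_A + t.edges_A_to_C == t.K_A * 4
            assert t.edges_C_to_A + t.edges_C_to_C == t.K_C * 4
            t2 = build_tally(state, v, count_vacated_link=False)
            assert t2.edges_A_to_A + t2.edges_A_to_C == t2.K_A * 4 - t2.K_A


class TestKernelEquivalence:
    @pytest.mark.parametrize("cvl", [True, False])
    def test_replacement_probability_matches_python_path(self, cvl):
        """The compiled kernel and the pure-Python payoff pipeline give the
        same replacement probability at every vertex."""
        state = random_state(N=36, k=4, p=0.45, seed=3)
        nbrs = neighbor_array(state.graph, 4)
        I = InteractionMatrix(0.7, -0.4, 1.2, 0.1)
        sel = SelectionConfig(0.05)
        for v in range(state.N):
            p_py = replacement_probability(
                group_fitness(build_tally(state, v, cvl), I, sel))
            p_kn = _kernel.replacement_prob_kernel(
                nbrs, state.types, v, I.a, I.b, I.c, I.d, sel.omega, cvl)
            assert p_kn == pytest.approx(p_py, abs=1e-12)

    def test_incremental_edge_counts_match_rescan(self):
        """Edge-type counters maintained across many flips agree with a
        from-scratch recount of the final state."""
        state = random_state(N=50, k=4, p=0.5, seed=5)
        nbrs = neighbor_array(state.graph, 4)
        n_slots = 10_000 // 100 + 3
        rec = [np.zeros(n_slots, dtype=np.int64) for _ in range(5)]
        n_rec, absorbed, _, _ = _kernel.run_events(
            nbrs, state.types, 0.0, 1.0, 1.0, 0.0, 0.01, True,
            10_000, 100, 99, *rec)
        m_AA, m_AC, m_CC = _kernel.edge_type_counts(nbrs, state.types)
        assert (rec[2][n_rec - 1], rec[3][n_rec - 1], rec[4][n_rec - 1]) == \
            (m_AA, m_AC, m_CC)
        assert rec[1][n_rec - 1] == state.types.sum()
        s = summarize_state(state)
        assert s.P_AA == pytest.approx(2 * m_AA / (50 * 4))


class TestRun:
    def test_bit_reproducible_given_seed(self):
        t1, t2 = run(_small_cfg()), run(_small_cfg())
        assert np.array_equal(t1.n_A, t2.n_A)
        assert np.array_equal(t1.generations, t2.generations)

    def test_single_event_unit(self):
        cfg = _small_cfg(max_generations=1, generation_unit="event")
        traj = run(cfg)
        assert traj.generations.tolist() == [0.0, 1.0]
        assert abs(int(traj.n_A[1]) - int(traj.n_A[0])) <= 1

    def test_trajectory_invariants(self):
        traj = run(_small_cfg(max_generations=200))
        assert np.all(np.diff(traj.generations) > 0)
        assert np.all((traj.n_A >= 0) & (traj.n_A <= 30))
        if traj.absorbed:
            assert traj.n_A[-1] in (0, 30)
            assert traj.generations[-1] == pytest.approx(
                traj.absorption_generation)

    def test_zero_max_generations_rejected(self):
        with pytest.raises(ValueError):
            _small_cfg(max_generations=0)

    def test_frame_has_standard_columns(self):
        df = run(_small_cfg(max_generations=5)).to_frame()
        assert list(df.columns) == [
            "generation", "n_A", "P_A", "P_AA", "P_AC", "P_CC", "q_A_given_A"]
        assert df["P_A"].iloc[0] == pytest.approx(0.5)


class TestEnsemble:
    def test_single_run_reduces_to_trajectory(self):
        cfg = _small_cfg(max_generations=20)
        summ = ensemble(cfg, n_runs=1, base_seed=77)
        cfg77 = dataclasses.replace(
            cfg, seed=77, network=dataclasses.replace(cfg.network, seed=77))
        traj = run(cfg77)
        assert summ.final_n_A[0] == traj.final_n_A
        assert summ.mean_n_A[-1] == traj.n_A[-1]
        assert summ.fixation_fraction_A in (0.0, 1.0)

    def test_absorbed_runs_extend_constantly(self):
        # strong A-favouring matrix on a tiny graph absorbs fast; the mean
        # curve must stay at N afterwards
        cfg = _small_cfg(payoff=InteractionMatrix(2, 2, 0, 0),
                         n_A_initial=25, max_generations=300)
        summ = ensemble(cfg, n_runs=5, base_seed=1)
        absorbed_at_N = summ.final_n_A == 30
        assert absorbed_at_N.any()
        assert summ.mean_n_A[-1] == pytest.approx(np.mean(summ.final_n_A))

    def test_neutral_fixation_probability_matches_initial_frequency(self):
        """omega=0: the type-A fixation probability equals its initial
        frequency (martingale property of neutral drift)."""
        cfg = RunConfig(
            network=NetworkConfig(N=30, k=4, seed=0),
            payoff=InteractionMatrix(1, 1, 1, 1),
            sel=SelectionConfig(0.0),
            n_A_initial=9,  # p0 = 0.3
            max_generations=4_000,
            generation_unit="sweep",
            record_every=1_000,
            seed=0,
        )
        summ = ensemble(cfg, n_runs=600, base_seed=10)
        assert np.isfinite(summ.absorption_generations).all()
        # 3-sigma binomial band around 0.3
        sigma = np.sqrt(0.3 * 0.7 / 600)
        assert abs(summ.fixation_fraction_A - 0.3) < 3 * sigma

    def test_relabeling_symmetry_distributional(self):
        """Swapping types, payoff entries and the initial frequency mirrors
        the ensemble mean within stochastic tolerance."""
        N = 200
        base = dict(max_generations=30, generation_unit="sweep",
                    record_every=30)
        cfg_f = RunConfig(network=NetworkConfig(N=N, k=4, seed=0),
                          payoff=InteractionMatrix(0, -0.5, 1, 0),
                          sel=SelectionConfig(0.01), n_A_initial=60,
                          seed=0, **base)
        cfg_m = RunConfig(network=NetworkConfig(N=N, k=4, seed=0),
                          payoff=InteractionMatrix(0, 1, -0.5, 0),
                          sel=SelectionConfig(0.01), n_A_initial=140,
                          seed=0, **base)
        s_f = ensemble(cfg_f, 150, base_seed=5)
        s_m = ensemble(cfg_m, 150, base_seed=5)
        se = np.hypot(s_f.std_n_A[-1], s_m.std_n_A[-1]) / np.sqrt(150)
        assert s_f.mean_n_A[-1] == pytest.approx(N - s_m.mean_n_A[-1],
                                                 abs=4 * se)


class TestQuasiStationaryAgreement:
    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_local_pairing_matches_fast_manifold(self, k):
        """Long-run ABM q_A|A at quasi-stationarity agrees with the
        pair-approximation fast equilibrium within 0.03."""
        cfg = RunConfig(
            network=NetworkConfig(N=2_000, k=k, seed=3),
            payoff=InteractionMatrix(0, 1, 1, 0),
            sel=SelectionConfig(0.01),
            n_A_initial=1_000,
            max_generations=400,
            record_every=1,
            seed=3,
        )
        traj = run(cfg)
        tail = range(traj.n_A.size // 2, traj.n_A.size)
        qs = [traj.summary_at(i).q_A_given_A for i in tail]
        ps = [traj.summary_at(i).P_A for i in tail]
        assert np.mean(qs) == pytest.approx(
            qAA_fast_equilibrium(float(np.mean(ps)), k), abs=0.03)


def test_quasi_stationary_mean_window():
    traj = run(_small_cfg(max_generations=20))
    assert quasi_stationary_mean(traj, 5) == pytest.approx(
        traj.n_A[-5:].mean())
    with pytest.raises(ValueError):
        quasi_stationary_mean(traj, 0)


def test_sweep_entry_shape_and_pairing():
    df = sweep_entry("b", [0.0, 1.0], [4], N=100, n_C_initial=10,
                     readout_generation=3, n_runs=5, base_seed=1)
    assert len(df) == 2
    assert set(df["entry"]) == {"b"}
    assert (df["n_runs"] == 5).all()
    with pytest.raises(ValueError):
        sweep_entry("a", [0.0], [4], N=100, n_runs=2)
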