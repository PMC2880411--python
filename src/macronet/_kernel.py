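"""Numba-compiled inner loop of the exit-entry simulator.

The event loop is hot (figure-scale experiments run 10^8-10^9 elementary
events), so it operates on flat arrays: an (N, k) int32 neighbour table and
an int8 type vector (1 = type A, 0 = type C).  Undirected edge-type counts
(m_AA, m_AC, m_CC) are maintained incrementally — O(k) per flip — so pair
frequencies can be recorded without rescanning the graph.

RNG discipline: ``np.random.seed(seed)`` once per run; each event draws the
exiting vertex first, then the replacement Bernoulli, unconditionally, so
trajectories are bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["replacement_prob_kernel", "edge_type_counts", "run_events"]


@njit(cache=True)
def replacement_prob_kernel(
    neighbors, types, v,
    a, b, c, d, omega, count_vacated_link,
):
    """P(vacated vertex v is refilled by type A), from the current state.

    ``types[v]`` must still hold the exiting cell's label: by convention its
    link contributes to each neighbour's energy with the exited type (skipped
    entirely when ``count_vacated_link`` is false).
    """
    k = neighbors.shape[1]
    F_A = 0.0
    F_C = 0.0
    for i in range(k):
        u = neighbors[v, i]
        tu = types[u]
        eps = 0.0
        for j in range(k):
            w = neighbors[u, j]
            if w == v and not count_vacated_link:
                continue
            tw = types[w]
            if tu == 1:
                eps += a if tw == 1 else b
            else:
                eps += c if tw == 1 else d
        f = (1.0 - omega) + omega * eps
        if tu == 1:
            F_A += f
        else:
            F_C += f
    return F_A / (F_A + F_C)


@njit(cache=True)
def edge_type_counts(neighbors, types):
    """Undirected edge counts (m_AA, m_AC, m_CC)."""
    N, k = neighbors.shape
    m_AA = 0
    m_AC = 0
    m_CC = 0
    for v in range(N):
        for i in range(k):
            u = neighbors[v, i]
            if u > v:
                s = types[v] + types[u]
                if s == 2:
                    m_AA += 1
                elif s == 1:
                    m_AC += 1
                else:
                    m_CC += 1
    return m_AA, m_AC, m_CC


@njit(cache=True)
def run_events(
    neighbors, types,
    a, b, c, d, omega, count_vacated_link,
    max_events, record_stride, seed,
    rec_event, rec_nA, rec_mAA, rec_mAC, rec_mCC,
):
    """Run up to ``max_events`` exit-entry events, mutating ``types`` in place.

    State is recorded into the ``rec_*`` arrays at event 0, every
    ``record_stride`` events, and at the final event (absorption or horizon).
    Returns (n_records, absorbed, absorption_event, n_events_run).
    """
    np.random.seed(seed)
    N, k = neighbors.shape
    n_A = 0
    for v in range(N):
        n_A += types[v]
    m_AA, m_AC, m_CC = edge_type_counts(neighbors, types)

    n_rec = 0
    rec_event[n_rec] = 0
    rec_nA[n_rec] = n_A
    rec_mAA[n_rec] = m_AA
    rec_mAC[n_rec] = m_AC
    rec_mCC[n_rec] = m_CC
    n_rec += 1

    absorbed = n_A == 0 or n_A == N
    absorption_event = 0 if absorbed else -1
    ev = 0
    while ev < max_events and not absorbed:
        ev += 1
        v = np.random.randint(0, N)
        p_A = replacement_prob_kernel(
            neighbors, types, v, a, b, c, d, omega, count_vacated_link
        )
        r = np.random.random()
        new = 1 if r < p_A else 0
        old = types[v]
        if new != old:
            # update incremental edge-type counts over v's k links
            for i in range(k):
                tu = types[neighbors[v, i]]
                if old == 1:
                    if tu == 1:
                        m_AA -= 1
                        m_AC += 1
                    else:
                        m_AC -= 1
                        m_CC += 1
                else:
                    if tu == 1:
                        m_AA += 1
                        m_AC -= 1
                    else:
                        m_AC += 1
                        m_CC -= 1
            types[v] = new
            n_A += new - old
            if n_A == 0 or n_A == N:
                absorbed = True
                absorption_event = ev
        if (ev % record_stride == 0) or absorbed or ev == max_events:
            rec_event[n_rec] = ev
            rec_nA[n_rec] = n_A
            rec_mAA[n_rec] = m_AA
            rec_mAC[n_rec] = m_AC
            rec_mCC[n_rec] = m_CC
            n_rec += 1
    return n_rec, absorbed, absorption_event, ev
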