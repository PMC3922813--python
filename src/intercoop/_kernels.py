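"""Numba event-loop kernel for the co-evolution simulator.

The kernel owns the hot loop only; all setup, validation and recording
semantics live in :mod:`intercoop.abm`.  State layout: node groups and
strategies as int8 arrays (group 0/1, strategy 0=C, 1=D), the edge list
as an (L, 2) int64 array, plus a dense adjacency byte matrix (populations
here are a few hundred nodes, so O(N^2) memory is trivial and gives O(1)
membership tests and O(N) neighbor scans).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel", "link_type_index"]

_MAX_REJECTION_TRIES = 64


@njit(cache=True, inline="always")
def link_type_index(su, gu, sv, gv):
    """Canonical index 0..9 of the link type with endpoint labels (s, g).

    Order: intra-1 (CC, CD, DD), intra-2 (CC, CD, DD), inter
    (C1C2, C1D2, D1C2, D1D2); groups are 0-based here.
    """
    if gu == gv:
        return 3 * gu + su + sv
    if gu < gv:
        return 6 + 2 * su + sv
    return 6 + 2 * sv + su


@njit(cache=True)
def _payoff(node, strat, adj, M, N):
    total = 0.0
    s = strat[node]
    row = adj[node]
    for j in range(N):
        if row[j]:
            total += M[s, strat[j]]
    return total


@njit(cache=True)
def _nth_neighbor(node, adj, N, idx):
    seen = 0
    row = adj[node]
    for j in range(N):
        if row[j]:
            if seen == idx:
                return j
            seen += 1
    return -1  # unreachable when idx < degree


@njit(cache=True)
def simulate_kernel(
    group,
    strat,
    edges,
    adj,
    deg,
    type_counts,
    g_nodes,
    g_offsets,
    M,
    kvec,
    p,
    W,
    w,
    horizon,
    sample_every,
    seed,
    stop_when_monomorphic,
    focal_replaces_neighbor,
    imitation_mode,
    rec_x1,
    rec_x2,
    rec_counts,
):
    """Run ``horizon`` events in place; fill the preallocated records.

    Each event is a strategy update with probability W (uniform focal
    player, uniform neighbor, Fermi acceptance on accumulated payoffs)
    and a link event otherwise (uniform link; break with the type's
    probability; uniform retained endpoint rewires with intra-group bias
    p to a uniform eligible non-neighbor).  Events that find no neighbor
    or no eligible partner are consumed as no-ops.  Returns the number
    of events actually executed (less than ``horizon`` only when
    ``stop_when_monomorphic`` triggers).
    """
    np.random.seed(seed)
    N = strat.shape[0]
    L = edges.shape[0]
    n_c = 0
    for i in range(N):
        if strat[i] == 0:
            n_c += 1
    rec_idx = 0
    t = -1
    for t in range(horizon):
        if t % sample_every == 0:
            _record(rec_idx, strat, group, type_counts, N, rec_x1, rec_x2, rec_counts)
            rec_idx += 1
        if np.random.random() < W:
            # ---- strategy update ----------------------------------------
            # mode 0: uniform focal, uniform neighbor (focal's strategy
            #         tries to replace the neighbor's)
            # mode 1: pairwise comparison along a uniform link, fair coin
            #         for who is focal
            # mode 2: uniform target, model player drawn from the target's
            #         own group with probability p, the other otherwise
            #         (the bias-weighted comparison of the mean-field
            #         transition probabilities)
            if imitation_mode == 1:
                if L == 0:
                    continue
                e = np.random.randint(L)
                if np.random.random() < 0.5:
                    i, j = edges[e, 0], edges[e, 1]
                else:
                    i, j = edges[e, 1], edges[e, 0]
            elif imitation_mode == 2:
                j = np.random.randint(N)
                g_m = group[j] if np.random.random() < p else 1 - group[j]
                lo, hi = g_offsets[g_m], g_offsets[g_m + 1]
                i = j
                while i == j:
                    i = g_nodes[lo + np.random.randint(hi - lo)]
            else:
                i = np.random.randint(N)
                if deg[i] == 0:
                    continue
                j = _nth_neighbor(i, adj, N, np.random.randint(deg[i]))
            if strat[i] == strat[j]:
                continue
            pi_i = _payoff(i, strat, adj, M, N)
            pi_j = _payoff(j, strat, adj, M, N)
            if focal_replaces_neighbor or imitation_mode == 2:
                target, new_s, delta = j, strat[i], pi_i - pi_j
            else:
                target, new_s, delta = i, strat[j], pi_j - pi_i
            z = w * delta
            if z < -700.0:
                accept = 0.0
            else:
                accept = 1.0 / (1.0 + np.exp(-z))
            if np.random.random() < accept:
                old_s = strat[target]
                gt = group[target]
                row = adj[target]
                for m in range(N):
                    if row[m]:
                        type_counts[
                            link_type_index(old_s, gt, strat[m], group[m])
                        ] -= 1
                        type_counts[
                            link_type_index(new_s, gt, strat[m], group[m])
                        ] += 1
                strat[target] = new_s
                n_c += 1 if new_s == 0 else -1
                if stop_when_monomorphic and (n_c == 0 or n_c == N):
                    break
        else:
            # ---- link event ---------------------------------------------
            if L == 0:
                continue
            e = np.random.randint(L)
            u, v = edges[e, 0], edges[e, 1]
            ty = link_type_index(strat[u], group[u], strat[v], group[v])
            if np.random.random() >= kvec[ty]:
                continue
            retained = u if np.random.random() < 0.5 else v
            g_r = group[retained]
            g_t = g_r if np.random.random() < p else 1 - g_r
            lo, hi = g_offsets[g_t], g_offsets[g_t + 1]
            n_t = hi - lo
            # delete first, so reconnecting to the old partner is allowed
            adj[u, v] = 0
            adj[v, u] = 0
            deg[u] -= 1
            deg[v] -= 1
            type_counts[ty] -= 1
            partner = -1
            for _ in range(_MAX_REJECTION_TRIES):
                cand = g_nodes[lo + np.random.randint(n_t)]
                if cand != retained and adj[retained, cand] == 0:
                    partner = cand
                    break
            if partner < 0:
                # exact fallback: count eligible, then pick uniformly
                n_elig = 0
                for q in range(lo, hi):
                    cand = g_nodes[q]
                    if cand != retained and adj[retained, cand] == 0:
                        n_elig += 1
                if n_elig > 0:
                    pick = np.random.randint(n_elig)
                    seen = 0
                    for q in range(lo, hi):
                        cand = g_nodes[q]
                        if cand != retained and adj[retained, cand] == 0:
                            if seen == pick:
                                partner = cand
                                break
                            seen += 1
            if partner < 0:
                # no eligible partner on the chosen side: restore the link
                adj[u, v] = 1
                adj[v, u] = 1
                deg[u] += 1
                deg[v] += 1
                type_counts[ty] += 1
                continue
            adj[retained, partner] = 1
            adj[partner, retained] = 1
            deg[retained] += 1
            deg[partner] += 1
            edges[e, 0] = retained
            edges[e, 1] = partner
            type_counts[
                link_type_index(
                    strat[retained], group[retained], strat[partner], group[partner]
                )
            ] += 1
    # fill the remaining sample slots with the final state
    while rec_idx < rec_x1.shape[0]:
        _record(rec_idx, strat, group, type_counts, N, rec_x1, rec_x2, rec_counts)
        rec_idx += 1
    return t + 1


@njit(cache=True, inline="always")
def _record(rec_idx, strat, group, type_counts, N, rec_x1, rec_x2, rec_counts):
    n1 = 0
    c1 = 0
    c2 = 0
    for i in range(N):
        if group[i] == 0:
            n1 += 1
            if strat[i] == 0:
                c1 += 1
        elif strat[i] == 0:
            c2 += 1
    rec_x1[rec_idx] = c1 / n1
    rec_x2[rec_idx] = c2 / (N - n1)
    for q in range(10):
        rec_counts[rec_idx, q] = type_counts[q]
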