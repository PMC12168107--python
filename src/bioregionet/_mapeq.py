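"""Numba kernel for greedy two-level map-equation minimization.

The optimizer works on a (possibly aggregated) weighted graph in normalized
flow units: each directed arc carries flow ``phi`` (edge weight / 2E), each
node a visit rate ``node_p`` and an internal flow ``node_self`` (flow that an
aggregated super-node keeps inside itself). With module visit rate
``p_i = sum node_p``, internal flow ``int_i`` and exit rate
``q_i = p_i - int_i``, the two-level description length is

    L = plogp(q) - 2 sum_i plogp(q_i) + sum_i plogp(q_i + p_i)
        - sum_alpha plogp(p_alpha),        plogp(x) = x log2 x.

The last sum runs over the *original* nodes and is partition-independent, so
the kernel only tracks the first three terms; moving whole super-nodes is
therefore exact for L. The driver (bionet.infomap_cluster) alternates local
node moves with Louvain-style aggregation, which realizes module merges.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["optimize_level"]


@njit(cache=True)
def _plogp(x):
    if x <= 0.0:
        return 0.0
    return x * np.log2(x)


@njit(cache=True)
def optimize_level(indptr, indices, phi, node_p, node_self, seed, max_passes=64):
    """One level of greedy node moves from a singleton start.

    Returns (modules, core_L) where core_L omits the partition-independent
    node-rate term. Moves are accepted only if they strictly lower L
    (tolerance 1e-12), with node order reshuffled every pass; ties are thus
    broken by first-found under the seeded order.
    """
    n = node_p.size
    np.random.seed(seed)

    modules = np.arange(n)
    mod_p = node_p.copy()
    mod_int = node_self.copy()
    mod_size = np.ones(n, dtype=np.int64)

    q_tot = 0.0
    s2 = 0.0
    s3 = 0.0
    for i in range(n):
        qi = mod_p[i] - mod_int[i]
        q_tot += qi
        s2 += _plogp(qi)
        s3 += _plogp(qi + mod_p[i])

    free = np.empty(n, dtype=np.int64)
    n_free = 0

    touched = np.empty(n, dtype=np.int64)
    link_w = np.zeros(n, dtype=np.float64)
    mark = np.full(n, -1, dtype=np.int64)
    order = np.arange(n)
    stamp = 0

    for _ in range(max_passes):
        improved = False
        # Fisher-Yates reshuffle
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp

        for oi in range(n):
            v = order[oi]
            a = modules[v]
            stamp += 1
            nt = 0
            k_a = 0.0
            for e in range(indptr[v], indptr[v + 1]):
                mu = modules[indices[e]]
                f = phi[e]
                if mu == a:
                    k_a += f
                else:
                    if mark[mu] != stamp:
                        mark[mu] = stamp
                        touched[nt] = mu
                        nt += 1
                        link_w[mu] = 0.0
                    link_w[mu] += f

            q_a_old = mod_p[a] - mod_int[a]
            p_a2 = mod_p[a] - node_p[v]
            int_a2 = mod_int[a] - 2.0 * k_a - node_self[v]
            q_a2 = p_a2 - int_a2
            base_dq = q_a2 - q_a_old
            base_ds2 = _plogp(q_a2) - _plogp(q_a_old)
            base_ds3 = _plogp(q_a2 + p_a2) - _plogp(q_a_old + mod_p[a])

            best_dl = -1e-12
            best_b = -1
            best_dq = 0.0
            best_ds2 = 0.0
            best_ds3 = 0.0
            best_kb = 0.0

            n_cand = nt + 1  # neighbour modules plus a fresh singleton
            for ci in range(n_cand):
                if ci < nt:
                    b = touched[ci]
                    k_b = link_w[b]
                    q_b_old = mod_p[b] - mod_int[b]
                    p_b_old = mod_p[b]
                    int_b_old = mod_int[b]
                else:
                    if mod_size[a] == 1 or n_free == 0:
                        continue
                    b = free[n_free - 1]
                    k_b = 0.0
                    q_b_old = 0.0
                    p_b_old = 0.0
                    int_b_old = 0.0
                p_b2 = p_b_old + node_p[v]
                int_b2 = int_b_old + 2.0 * k_b + node_self[v]
                q_b2 = p_b2 - int_b2
                dq = base_dq + q_b2 - q_b_old
                ds2 = base_ds2 + _plogp(q_b2) - _plogp(q_b_old)
                ds3 = base_ds3 + _plogp(q_b2 + p_b2) - _plogp(q_b_old + p_b_old)
                dl = (_plogp(q_tot + dq) - _plogp(q_tot)) - 2.0 * ds2 + ds3
                if dl < best_dl:
                    best_dl = dl
                    best_b = b
                    best_dq = dq
                    best_ds2 = ds2
                    best_ds3 = ds3
                    best_kb = k_b

            if best_b >= 0 and best_b != a:
                b = best_b
                if mod_size[b] == 0:  # taking a free slot
                    n_free -= 1
                mod_p[a] -= node_p[v]
                mod_int[a] -= 2.0 * k_a + node_self[v]
                mod_size[a] -= 1
                if mod_size[a] == 0:
                    free[n_free] = a
                    n_free += 1
                    mod_p[a] = 0.0
                    mod_int[a] = 0.0
                mod_p[b] += node_p[v]
                mod_int[b] += 2.0 * best_kb + node_self[v]
                mod_size[b] += 1
                modules[v] = b
                q_tot += best_dq
                s2 += best_ds2
                s3 += best_ds3
                improved = True

        if not improved:
            break

    core_l = _plogp(q_tot) - 2.0 * s2 + s3
    return modules, core_l
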