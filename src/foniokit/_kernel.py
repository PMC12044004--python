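"""Numba-compiled coalescent kernel for site-frequency-spectrum expectations.

The kernel runs the standard n-coalescent with piecewise-constant population
sizes, population joins (splits viewed backward in time), and accumulates,
for every pair of sampled populations, the expected branch length carrying
each joint derived-allele count class.  Under the infinite-sites model the
probability that a segregating site falls in class (i, j) is proportional
to that branch length, which is what the composite-likelihood machinery
needs.  A mutation-dropping mode draws Poisson mutation counts per class
per genealogy instead (higher variance, available as a cross-check).
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_JOIN = 0
EV_SIZE = 1


@njit(cache=True)
def sim_joint_branch_weights(
    n_pops: int,
    samples: np.ndarray,
    sizes0: np.ndarray,
    ev_time: np.ndarray,
    ev_kind: np.ndarray,
    ev_a: np.ndarray,
    ev_b: np.ndarray,
    n_sims: int,
    seed: int,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    W: np.ndarray,
    theta_per_class: float,
    mutation_mode: bool,
):
    """Accumulate joint-SFS class weights over ``n_sims`` genealogies.

    W has shape (n_pairs, max_a + 1, max_b + 1) and receives branch lengths
    (generations) in branch mode, or Poisson mutation counts when
    ``mutation_mode`` (with per-branch rate ``theta_per_class`` * length).
    Returns the summed total tree length over simulations.
    """
    np.random.seed(seed)
    n_slots = sizes0.shape[0]
    n_tot = 0
    for p in range(n_pops):
        n_tot += samples[p]
    n_pairs = pair_i.shape[0]
    counts = np.zeros((n_tot, n_pops), dtype=np.int64)
    pop = np.zeros(n_tot, dtype=np.int64)
    sizes = np.zeros(n_slots, dtype=np.float64)
    kpop = np.zeros(n_slots, dtype=np.int64)
    Wsim = np.zeros_like(W)
    n_ev = ev_time.shape[0]
    t_total = 0.0
    for _s in range(n_sims):
        k = 0
        for p in range(n_pops):
            for _ in range(samples[p]):
                for q in range(n_pops):
                    counts[k, q] = 0
                counts[k, p] = 1
                pop[k] = p
                k += 1
        for p in range(n_slots):
            sizes[p] = sizes0[p]
        if mutation_mode:
            Wsim[:] = 0.0
        t = 0.0
        iev = 0
        n_act = k
        tlen = 0.0
        while n_act > 1:
            for p in range(n_slots):
                kpop[p] = 0
            for l in range(n_act):
                kpop[pop[l]] += 1
            rate = 0.0
            for p in range(n_slots):
                if kpop[p] > 1:
                    rate += kpop[p] * (kpop[p] - 1) / 2.0 / (2.0 * sizes[p])
            if rate > 0.0:
                dt = np.random.exponential(1.0 / rate)
            else:
                dt = np.inf
            if iev < n_ev and t + dt > ev_time[iev]:
                d = ev_time[iev] - t
                if d > 0.0:
                    for l in range(n_act):
                        for pr in range(n_pairs):
                            a = counts[l, pair_i[pr]]
                            b = counts[l, pair_j[pr]]
                            if mutation_mode:
                                Wsim[pr, a, b] += d
                            else:
                                W[pr, a, b] += d
                    tlen += n_act * d
                t = ev_time[iev]
                if ev_kind[iev] == EV_JOIN:
                    a0 = ev_a[iev]
                    b0 = int(ev_b[iev])
                    for l in range(n_act):
                        if pop[l] == a0:
                            pop[l] = b0
                else:
                    sizes[ev_a[iev]] = ev_b[iev]
                iev += 1
                continue
            if not np.isfinite(dt):
                # lineages can never coalesce under this event table
                return -1.0
            for l in range(n_act):
                for pr in range(n_pairs):
                    a = counts[l, pair_i[pr]]
                    b = counts[l, pair_j[pr]]
                    if mutation_mode:
                        Wsim[pr, a, b] += dt
                    else:
                        W[pr, a, b] += dt
            tlen += n_act * dt
            t += dt
            u = np.random.random() * rate
            acc = 0.0
            cpop = -1
            for p in range(n_slots):
                if kpop[p] > 1:
                    acc += kpop[p] * (kpop[p] - 1) / 2.0 / (2.0 * sizes[p])
                    if u <= acc:
                        cpop = p
                        break
            if cpop < 0:
                for p in range(n_slots - 1, -1, -1):
                    if kpop[p] > 1:
                        cpop = p
                        break
            kp = kpop[cpop]
            i1 = np.random.randint(kp)
            i2 = np.random.randint(kp - 1)
            if i2 >= i1:
                i2 += 1
            li1 = -1
            li2 = -1
            c = 0
            for l in range(n_act):
                if pop[l] == cpop:
                    if c == i1:
                        li1 = l
                    if c == i2:
                        li2 = l
                    c += 1
            for q in range(n_pops):
                counts[li1, q] += counts[li2, q]
            n_act -= 1
            if li2 != n_act:
                for q in range(n_pops):
                    counts[li2, q] = counts[n_act, q]
                pop[li2] = pop[n_act]
        if mutation_mode:
            for pr in range(n_pairs):
                for a in range(W.shape[1]):
                    for b in range(W.shape[2]):
                        lam = theta_per_class * Wsim[pr, a, b]
                        if lam > 0.0:
                            W[pr, a, b] += np.random.poisson(lam)
        t_total += tlen
    return t_total
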