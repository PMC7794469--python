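"""Numba kernels for sequential chain growth and contact counting.

One kernel serves every sampler in the package. A chain is grown bead by
bead; at each step K trial directions are drawn uniformly on the bond
sphere, each trial is scored by

    L = [valid] * tether_factor * prod_over_targets(contact_factor)

where ``valid`` means inside the confinement sphere and not overlapping
any previously placed bead, the tether factor is an optional Gaussian
pull toward a per-bead center (used only by synthetic fixtures), and the
contact factors are optional per-pair Bernoulli terms that bias growth
toward satisfying Hi-C-derived contact probabilities. The chosen trial
is sampled proportionally to L and the chain's log-weight accrues
``log(sum(L) / K)`` — the Rosenbluth correction that makes the weighted
ensemble target the prior-times-likelihood distribution. With no tether
and no targets this reduces exactly to uniform sampling of confined
self-avoiding chains.

All kernels seed numpy's (numba-internal) MT state explicitly, so every
chain is reproducible from its 31-bit seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEAD = -1.0e300  # log-weight of a chain that ran out of valid moves


@njit(cache=True)
def _uniform_in_sphere(radius):
    while True:
        x = (2.0 * np.random.random() - 1.0) * radius
        y = (2.0 * np.random.random() - 1.0) * radius
        z = (2.0 * np.random.random() - 1.0) * radius
        if x * x + y * y + z * z <= radius * radius:
            return x, y, z


@njit(cache=True)
def _unit_vector():
    # Gaussian triple, normalized; re-draw the (measure-zero) zero vector
    while True:
        x = np.random.normal(0.0, 1.0)
        y = np.random.normal(0.0, 1.0)
        z = np.random.normal(0.0, 1.0)
        s = np.sqrt(x * x + y * y + z * z)
        if s > 1e-12:
            return x / s, y / s, z / s


@njit(cache=True)
def grow_segment(coords, t0, t1, bond, radius, n_trials, d_c,
                 q_indptr, q_idx, q_val,
                 tether_c, tether_s2, use_tether, seed):
    """Grow beads [t0, t1) of one chain in place.

    ``coords`` is (n, 3) with beads [0, t0) already placed. The pairwise
    target terms are CSR-by-column: for bead t, ``q_idx[q_indptr[t]:
    q_indptr[t+1]]`` lists partners j < t with effective contact
    probability ``q_val[...]``. Returns (t_reached, delta_log_weight);
    ``t_reached < t1`` with DEAD log-weight means the chain died.
    """
    np.random.seed(seed)
    bond2 = bond * bond
    r2 = radius * radius
    dc2 = d_c * d_c
    dlogw = 0.0
    tx = np.empty(n_trials)
    ty = np.empty(n_trials)
    tz = np.empty(n_trials)
    lw = np.empty(n_trials)
    for t in range(t0, t1):
        for i in range(n_trials):
            if t == 0:
                x, y, z = _uniform_in_sphere(radius)
                valid = True
            else:
                ux, uy, uz = _unit_vector()
                x = coords[t - 1, 0] + bond * ux
                y = coords[t - 1, 1] + bond * uy
                z = coords[t - 1, 2] + bond * uz
                valid = (x * x + y * y + z * z) <= r2
                if valid:
                    for j in range(t - 1):
                        dx = x - coords[j, 0]
                        dy = y - coords[j, 1]
                        dz = z - coords[j, 2]
                        if dx * dx + dy * dy + dz * dz < bond2:
                            valid = False
                            break
            if not valid:
                lw[i] = 0.0
                tx[i] = x
                ty[i] = y
                tz[i] = z
                continue
            L = 1.0
            if use_tether:
                dx = x - tether_c[t, 0]
                dy = y - tether_c[t, 1]
                dz = z - tether_c[t, 2]
                L *= np.exp(-(dx * dx + dy * dy + dz * dz) / (2.0 * tether_s2[t]))
            for p in range(q_indptr[t], q_indptr[t + 1]):
                j = q_idx[p]
                q = q_val[p]
                dx = x - coords[j, 0]
                dy = y - coords[j, 1]
                dz = z - coords[j, 2]
                # Bernoulli factor with separate clips: the contact side is
                # capped at 1, the miss side floored at 1e-3 so calibration
                # can push geometrically hard targets without killing chains
                if dx * dx + dy * dy + dz * dz < dc2:
                    L *= min(q, 1.0)
                else:
                    nc = 1.0 - q
                    L *= nc if nc > 1e-3 else 1e-3
            lw[i] = L
            tx[i] = x
            ty[i] = y
            tz[i] = z
        total = 0.0
        for i in range(n_trials):
            total += lw[i]
        if total <= 0.0:
            return t, DEAD
        u = np.random.random() * total
        acc = 0.0
        pick = n_trials - 1
        for i in range(n_trials):
            acc += lw[i]
            if u <= acc:
                pick = i
                break
        coords[t, 0] = tx[pick]
        coords[t, 1] = ty[pick]
        coords[t, 2] = tz[pick]
        dlogw += np.log(total / n_trials)
    return t1, dlogw


@njit(cache=True)
def grow_population_segment(coords, lengths, logw, t1, bond, radius, n_trials,
                            d_c, q_indptr, q_idx, q_val,
                            tether_c, tether_s2, use_tether, seeds):
    """Advance every live chain of a population to length t1 in place."""
    n_chains = coords.shape[0]
    for k in range(n_chains):
        if logw[k] <= DEAD:
            continue
        t_reached, dlw = grow_segment(coords[k], lengths[k], t1, bond, radius,
                                      n_trials, d_c, q_indptr, q_idx, q_val,
                                      tether_c, tether_s2, use_tether, seeds[k])
        lengths[k] = t_reached
        if dlw <= DEAD:
            logw[k] = DEAD
        else:
            logw[k] += dlw


@njit(cache=True)
def rejection_sample_chains(n_chains, n_beads, bond, radius, seed):
    """Naive oracle: uniform random walks, rejected on any violation.

    Draws bead 0 uniform in the sphere and each subsequent direction
    uniform on the bond sphere; a proposal is discarded as soon as a bead
    leaves the confinement or overlaps a previous bead. Exact but slow —
    used as an independent reference for the weighted sampler.
    """
    np.random.seed(seed)
    out = np.empty((n_chains, n_beads, 3))
    bond2 = bond * bond
    r2 = radius * radius
    chain = np.empty((n_beads, 3))
    k = 0
    while k < n_chains:
        x, y, z = _uniform_in_sphere(radius)
        chain[0, 0] = x
        chain[0, 1] = y
        chain[0, 2] = z
        ok = True
        for t in range(1, n_beads):
            ux, uy, uz = _unit_vector()
            x = chain[t - 1, 0] + bond * ux
            y = chain[t - 1, 1] + bond * uy
            z = chain[t - 1, 2] + bond * uz
            if x * x + y * y + z * z > r2:
                ok = False
                break
            for j in range(t - 1):
                dx = x - chain[j, 0]
                dy = y - chain[j, 1]
                dz = z - chain[j, 2]
                if dx * dx + dy * dy + dz * dz < bond2:
                    ok = False
                    break
            if not ok:
                break
            chain[t, 0] = x
            chain[t, 1] = y
            chain[t, 2] = z
        if ok:
            out[k] = chain
            k += 1
    return out


@njit(cache=True)
def weighted_contact_map(coords, weights, d_c):
    """Weighted fraction of chains with bead pair within d_c; (n, n) map."""
    n_chains, n, _ = coords.shape
    dc2 = d_c * d_c
    acc = np.zeros((n, n))
    wtot = 0.0
    for k in range(n_chains):
        w = weights[k]
        wtot += w
        for i in range(n):
            for j in range(i + 1, n):
                dx = coords[k, i, 0] - coords[k, j, 0]
                dy = coords[k, i, 1] - coords[k, j, 1]
                dz = coords[k, i, 2] - coords[k, j, 2]
                if dx * dx + dy * dy + dz * dz < dc2:
                    acc[i, j] += w
    p = acc / wtot
    for i in range(n):
        for j in range(i + 1, n):
            p[j, i] = p[i, j]
        p[i, i] = 1.0
    return p


@njit(cache=True)
def blb_weighted_means(ind, members, cw, out):
    """Replicate means: out[m, p] = sum_k cw[m,k] * ind[members[m,k], p] / sum_k cw[m,k].

    ``ind`` is the per-chain contact-indicator matrix (int8); one row of
    ``members``/``cw`` describes one bootstrap replicate's chains and
    count-times-importance weights.
    """
    M, b = members.shape
    P = ind.shape[1]
    for m in range(M):
        tot = 0.0
        for k in range(b):
            tot += cw[m, k]
        for k in range(b):
            c = cw[m, k] / tot
            if c == 0.0:
                continue
            row = members[m, k]
            for p in range(P):
                if ind[row, p] != 0:
                    out[m, p] += c
    return out


@njit(cache=True)
def contact_indicators(coords, pair_i, pair_j, d_c):
    """Per-chain contact indicator matrix over a list of pairs, (N, n_pairs)."""
    n_chains = coords.shape[0]
    n_pairs = pair_i.shape[0]
    dc2 = d_c * d_c
    out = np.zeros((n_chains, n_pairs))
    for k in range(n_chains):
        for p in range(n_pairs):
            i = pair_i[p]
            j = pair_j[p]
            dx = coords[k, i, 0] - coords[k, j, 0]
            dy = coords[k, i, 1] - coords[k, j, 1]
            dz = coords[k, i, 2] - coords[k, j, 2]
            if dx * dx + dy * dy + dz * dz < dc2:
                out[k, p] = 1.0
    return out
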