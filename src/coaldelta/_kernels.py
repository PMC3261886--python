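"""Numba kernels: pruning likelihood and MSC log density on flat arrays.

The sequence likelihood uses Felsenstein pruning under K80 (JC69 is the
kappa=1 special case, mirroring the deliberately simple likelihood model
of the original Bayesian program).  With equal base frequencies the
per-branch transition probabilities collapse to three numbers, stored as
A = p_same - p_tv, B = p_ti - p_tv, C = p_tv for the branch above each
node, so a child's contribution to state x is
``A*L[x] + B*L[ti(x)] + C*sum(L)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TI = np.array([2, 3, 0, 1], dtype=np.int64)


def abc_coeffs(d: float, kappa: float):
    """Branch coefficients (A, B, C) for distance d under K80."""
    e2 = math.exp(-4.0 * d / (kappa + 2.0))
    e1 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    return 0.5 * (e2 + e1), 0.5 * (e2 - e1), 0.25 * (1.0 - e2)


@njit(cache=True)
def pruning_update(nodes, child0, child1, n_tips, codes, A, B, C, part):
    """Recompute conditional likelihoods for ``nodes`` (postorder order)."""
    P = codes.shape[1]
    ti0, ti1, ti2, ti3 = 2, 3, 0, 1
    for ii in range(nodes.shape[0]):
        v = nodes[ii]
        c0 = child0[v]
        c1 = child1[v]
        a0, b0, cc0 = A[c0], B[c0], C[c0]
        a1, b1, cc1 = A[c1], B[c1], C[c1]
        for p in range(P):
            if c0 < n_tips:
                k = codes[c0, p]
                f00 = cc0
                f01 = cc0
                f02 = cc0
                f03 = cc0
                if k == 0:
                    f00 += a0
                    f02 += b0
                elif k == 1:
                    f01 += a0
                    f03 += b0
                elif k == 2:
                    f02 += a0
                    f00 += b0
                else:
                    f03 += a0
                    f01 += b0
            else:
                l0 = part[c0, p, 0]
                l1 = part[c0, p, 1]
                l2 = part[c0, p, 2]
                l3 = part[c0, p, 3]
                s = (l0 + l1 + l2 + l3) * cc0
                f00 = a0 * l0 + b0 * l2 + s
                f01 = a0 * l1 + b0 * l3 + s
                f02 = a0 * l2 + b0 * l0 + s
                f03 = a0 * l3 + b0 * l1 + s
            if c1 < n_tips:
                k = codes[c1, p]
                f10 = cc1
                f11 = cc1
                f12 = cc1
                f13 = cc1
                if k == 0:
                    f10 += a1
                    f12 += b1
                elif k == 1:
                    f11 += a1
                    f13 += b1
                elif k == 2:
                    f12 += a1
                    f10 += b1
                else:
                    f13 += a1
                    f11 += b1
            else:
                l0 = part[c1, p, 0]
                l1 = part[c1, p, 1]
                l2 = part[c1, p, 2]
                l3 = part[c1, p, 3]
                s = (l0 + l1 + l2 + l3) * cc1
                f10 = a1 * l0 + b1 * l2 + s
                f11 = a1 * l1 + b1 * l3 + s
                f12 = a1 * l2 + b1 * l0 + s
                f13 = a1 * l3 + b1 * l1 + s
            part[v, p, 0] = f00 * f10
            part[v, p, 1] = f01 * f11
            part[v, p, 2] = f02 * f12
            part[v, p, 3] = f03 * f13


@njit(cache=True)
def root_loglik(part, root, w):
    P = w.shape[0]
    ll = 0.0
    for p in range(P):
        s = part[root, p, 0] + part[root, p, 1] \
            + part[root, p, 2] + part[root, p, 3]
        if s <= 0.0:
            return -np.inf
        ll += w[p] * math.log(0.25 * s)
    return ll


@njit(cache=True, inline="always")
def _abc_scalar(d, kappa):
    e2 = math.exp(-4.0 * d / (kappa + 2.0))
    e1 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    return 0.5 * (e2 + e1), 0.5 * (e2 - e1), 0.25 * (1.0 - e2)


@njit(cache=True)
def gene_age_sweep(n_moves, seed, parent, child0, child1, age, mask,
                   n_tips, post_int, codes, w, A, B, C, part, r, kappa,
                   lik_scale, root_step,
                   sp_parent, sp_age, sp_mask, sp_theta, n_species,
                   tip_counts, h, ll_in, dens_in):
    """Batch of single-node age moves on one locus's gene tree.

    Mutates age/A/B/C/part in place; returns (ll, dens, accepted, tried).
    """
    np.random.seed(seed)
    ll = ll_in
    dens = dens_in
    n_int = post_int.shape[0]
    root = post_int[n_int - 1]
    P = codes.shape[1]
    acc = 0
    tot = 0
    path = np.empty(n_int, dtype=np.int64)
    save_part = np.empty((n_int, P, 4))
    upd = np.empty(1, dtype=np.int64)
    for m in range(n_moves):
        v = post_int[np.random.randint(0, n_int)]
        c0 = child0[v]
        c1 = child1[v]
        lb = age[c0] if age[c0] > age[c1] else age[c1]
        mm = mask[v]
        i = 0
        while ((mm >> i) & 1) == 0:
            i += 1
        p = i
        while (mm & ~sp_mask[p]) != 0:
            p = sp_parent[p]
        if sp_age[p] > lb:
            lb = sp_age[p]
        pv = parent[v]
        old_age = age[v]
        if pv < 0:
            ex = old_age - lb
            if ex <= 0.0:
                ex = 1e-12
            new_ex = ex * math.exp(root_step * (np.random.random() - 0.5))
            new_age = lb + new_ex
            hast = math.log(new_ex / ex)
        else:
            ub = age[pv]
            if ub <= lb:
                continue
            new_age = lb + np.random.random() * (ub - lb)
            hast = 0.0
        tot += 1
        # path v -> root
        np_ = 0
        u = v
        while u >= 0:
            path[np_] = u
            np_ += 1
            u = parent[u]
        a_v, b_v, cc_v = A[v], B[v], C[v]
        a_0, b_0, cc_0 = A[c0], B[c0], C[c0]
        a_1, b_1, cc_1 = A[c1], B[c1], C[c1]
        if lik_scale != 0.0:
            for k in range(np_):
                u = path[k]
                for pp in range(P):
                    for x in range(4):
                        save_part[k, pp, x] = part[u, pp, x]
        age[v] = new_age
        if pv >= 0:
            A[v], B[v], C[v] = _abc_scalar((age[pv] - new_age) * r, kappa)
        A[c0], B[c0], C[c0] = _abc_scalar(
            max((new_age - age[c0]) * r, 0.0), kappa)
        A[c1], B[c1], C[c1] = _abc_scalar(
            max((new_age - age[c1]) * r, 0.0), kappa)
        new_ll = 0.0
        if lik_scale != 0.0:
            pruning_update(path[:np_], child0, child1, n_tips, codes,
                           A, B, C, part)
            new_ll = lik_scale * root_loglik(part, root, w)
        new_dens = msc_logdens(sp_parent, sp_age, sp_mask, sp_theta,
                               n_species, age, mask, n_tips, tip_counts, h)
        logr = (new_dens - dens) + (new_ll - ll) + hast
        if math.log(np.random.random() + 1e-300) < logr:
            ll = new_ll
            dens = new_dens
            acc += 1
        else:
            age[v] = old_age
            A[v], B[v], C[v] = a_v, b_v, cc_v
            A[c0], B[c0], C[c0] = a_0, b_0, cc_0
            A[c1], B[c1], C[c1] = a_1, b_1, cc_1
            if lik_scale != 0.0:
                for k in range(np_):
                    u = path[k]
                    for pp in range(P):
                        for x in range(4):
                            part[u, pp, x] = save_part[k, pp, x]
    return ll, dens, acc, tot


@njit(cache=True)
def spr_attach(seed, parent, age, tip_species, n_tips, active, t0, mask_c,
               sp_parent, sp_age, sp_mask, sp_theta, h):
    """Re-coalesce a pruned lineage into the remaining genealogy.

    Samples the attachment (branch, time) from the conditional MSC
    density of one extra lineage entering at ``t0`` with species
    composition ``mask_c``, given the remaining tree (nodes with
    ``active`` set; the pruned subtree and its old parent are inactive).
    Returns (target_node, t_star).
    """
    np.random.seed(seed)
    nn = age.shape[0]
    # species composition of remaining branches, bottom-up by age
    rem_mask = np.zeros(nn, dtype=np.int64)
    order = np.argsort(age)
    for ii in range(nn):
        v = order[ii]
        if not active[v]:
            continue
        if v < n_tips:
            rem_mask[v] = np.int64(1) << tip_species[v]
        pv = parent[v]
        if pv >= 0:
            rem_mask[pv] |= rem_mask[v]
    # candidate (branch, interval) overlaps with the moving lineage
    npop = sp_age.shape[0]
    max_c = nn * npop
    cv = np.empty(max_c, dtype=np.int64)
    clo = np.empty(max_c)
    chi = np.empty(max_c)
    cth = np.empty(max_c)
    nc = 0
    for v in range(nn):
        if not active[v]:
            continue
        pv = parent[v]
        b_v = np.inf if pv < 0 else age[pv]
        if b_v <= t0:
            continue
        # walk populations from the branch's species MRCA to the root
        m = rem_mask[v]
        i = 0
        while ((m >> i) & 1) == 0:
            i += 1
        q = i
        while (m & ~sp_mask[q]) != 0:
            q = sp_parent[q]
        while True:
            q_end = np.inf if sp_parent[q] == -1 else sp_age[sp_parent[q]]
            if (mask_c & ~sp_mask[q]) == 0:  # moving lineage shares pop q
                lo = max(max(age[v], sp_age[q]), t0)
                hi = min(b_v, q_end)
                if hi > lo:
                    cv[nc] = v
                    clo[nc] = lo
                    chi[nc] = hi
                    cth[nc] = h * sp_theta[q]
                    nc += 1
            if sp_parent[q] == -1:
                break
            q = sp_parent[q]
    # segment sweep with piecewise-constant rate
    pts = np.empty(2 * nc)
    npts = 0
    for k in range(nc):
        if clo[k] > t0:
            pts[npts] = clo[k]
            npts += 1
        if chi[k] < np.inf:
            pts[npts] = chi[k]
            npts += 1
    seg = np.sort(pts[:npts])
    E = np.random.exponential()
    s0 = t0
    for si in range(npts + 1):
        s1 = seg[si] if si < npts else np.inf
        if s1 <= s0:
            continue
        n_act = 0
        th = 1.0
        for k in range(nc):
            if clo[k] <= s0 < chi[k]:
                n_act += 1
                th = cth[k]
        if n_act > 0:
            lam = 2.0 * n_act / th
            span = s1 - s0
            if lam * span >= E:
                t_star = s0 + E / lam
                pick = np.random.randint(0, n_act)
                j = 0
                for k in range(nc):
                    if clo[k] <= s0 < chi[k]:
                        if j == pick:
                            return cv[k], t_star
                        j += 1
            E -= lam * span
        s0 = s1
    return np.int64(-1), np.nan


@njit(cache=True)
def msc_logdens(sp_parent, sp_age, sp_mask, sp_theta, n_species,
                gt_age, gt_mask, n_tips, tip_counts, h):
    """MSC log density of a gene tree (nuclear-scale ages, theta_eff=h*theta).

    Returns -inf when a coalescence is younger than the split separating
    the species beneath it.
    """
    nn = gt_age.shape[0]
    n_int = nn - n_tips
    n_pop = sp_age.shape[0]
    host = np.empty(n_int, dtype=np.int64)
    for k in range(n_int):
        v = n_tips + k
        m = gt_mask[v]
        i = 0
        while ((m >> i) & 1) == 0:
            i += 1
        p = i
        while (m & ~sp_mask[p]) != 0:
            p = sp_parent[p]
        if gt_age[v] < sp_age[p] - 1e-15:
            return -np.inf
        while sp_parent[p] != -1 and sp_age[sp_parent[p]] <= gt_age[v]:
            p = sp_parent[p]
        host[k] = p
    order = np.argsort(gt_age[n_tips:])
    logd = 0.0
    for p in range(n_pop):
        clade = sp_mask[p]
        tips_in = 0
        for s in range(n_species):
            if ((clade >> s) & 1) == 1:
                tips_in += tip_counts[s]
        if tips_in == 0:
            continue
        lo = sp_age[p]
        hi = np.inf if sp_parent[p] == -1 else sp_age[sp_parent[p]]
        below = 0
        for k in range(n_int):
            if gt_age[n_tips + k] < lo - 1e-15 and \
                    (gt_mask[n_tips + k] & ~clade) == 0:
                below += 1
        j = tips_in - below
        th = h * sp_theta[p]
        t = lo
        for kk in range(n_int):
            k = order[kk]
            if host[k] != p:
                continue
            te = gt_age[n_tips + k]
            if j < 2:
                return -np.inf
            logd += math.log(2.0 / th) - j * (j - 1) / th * (te - t)
            j -= 1
            t = te
        if hi < np.inf and j >= 2:
            logd += -j * (j - 1) / th * (hi - t)
    return logd
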