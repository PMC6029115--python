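"""Numba kernel for the relaxed-clock Metropolis-Hastings sampler.

Everything here operates on flat arrays in the engine's internal units
(time in 100 Ma, rates in substitutions/site/100 Ma).  The pruning
likelihood uses per-subtree pattern compression: each internal node stores
conditional likelihoods only for the distinct site patterns restricted to
its subtree's tips, with precomputed index maps into its children's pattern
tables.  A proposal that touches one branch therefore recomputes partials
only along the path from that branch to the root.

The sampler sweeps: one sliding-window move per internal-node age
(reflected at the ordering bounds), one multiplicative move per branch
rate, multiplicative moves for the mean rate mu and the rate variance
sigma2, and a likelihood-free rescale move (all ages times c, all rates and
mu divided by c) that decorrelates the absolute time scale.  Step sizes are
tuned toward 30% acceptance during burn-in only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SIGMA2_FLOOR = 1e-8


@njit(cache=True)
def soft_bound_logpdf(t, lo, hi, tail):
    """Log density of the soft uniform bound: mass 1-2*tail on [lo, hi],
    a power tail below lo and an exponential tail above hi, each holding
    ``tail`` mass and continuous at the bounds."""
    if t <= 0.0:
        return -np.inf
    h = (1.0 - 2.0 * tail) / (hi - lo)
    if t < lo:
        theta = h * lo / tail
        return math.log(h) + (theta - 1.0) * (math.log(t) - math.log(lo))
    elif t > hi:
        lam = h / tail
        return math.log(h) - lam * (t - hi)
    return math.log(h)


@njit(cache=True)
def gamma_logpdf(x, shape, invscale):
    if x <= 0.0:
        return -np.inf
    return (
        shape * math.log(invscale)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(x)
        - invscale * x
    )


@njit(cache=True)
def full_log_prior(
    age, rate, mu, s2, root, n_nodes,
    cal_node, cal_lo, cal_hi, cal_tail,
    a_mu, b_mu, a_s2, b_s2,
):
    """Joint log prior: soft-bound calibrations, flat (order-statistic)
    density for uncalibrated ages, iid lognormal branch rates with mean mu,
    and gamma hyperpriors.  Age ordering is enforced by the proposal bounds,
    not here."""
    lp = 0.0
    for k in range(cal_node.shape[0]):
        lp += soft_bound_logpdf(age[cal_node[k]], cal_lo[k], cal_hi[k], cal_tail[k])
    m = math.log(mu) - 0.5 * s2
    c = -0.5 * math.log(2.0 * math.pi * s2)
    for v in range(n_nodes):
        if v != root:
            lr = math.log(rate[v])
            d = lr - m
            lp += c - lr - d * d / (2.0 * s2)
    lp += gamma_logpdf(mu, a_mu, b_mu)
    lp += gamma_logpdf(s2, a_s2, b_s2)
    return lp


@njit(cache=True, inline="always")
def _fill_pmat(d, eigw, eigU, eigUinv, out):
    e0 = math.exp(eigw[0] * d)
    e1 = math.exp(eigw[1] * d)
    e2 = math.exp(eigw[2] * d)
    e3 = math.exp(eigw[3] * d)
    for s in range(4):
        a0 = eigU[s, 0] * e0
        a1 = eigU[s, 1] * e1
        a2 = eigU[s, 2] * e2
        a3 = eigU[s, 3] * e3
        for x in range(4):
            p = a0 * eigUinv[0, x] + a1 * eigUinv[1, x] + a2 * eigUinv[2, x] + a3 * eigUinv[3, x]
            out[s, x] = p if p > 0.0 else 0.0


@njit(cache=True)
def _node_partial(
    iv, left, right, int_of_node, npat, pat_off, part_off, lidx, ridx,
    partial, scratch, fresh, pmat_l, pmat_r,
):
    """Compute node iv's conditional likelihoods into ``scratch``; children
    are read from ``scratch`` where ``fresh`` flags them as recomputed."""
    l = left[iv]
    r = right[iv]
    li = int_of_node[l]
    ri = int_of_node[r]
    off = part_off[iv]
    po = pat_off[iv]
    lsrc = partial
    if li >= 0 and fresh[li]:
        lsrc = scratch
    rsrc = partial
    if ri >= 0 and fresh[ri]:
        rsrc = scratch
    lo_l = part_off[li] if li >= 0 else 0
    lo_r = part_off[ri] if ri >= 0 else 0
    for k in range(npat[iv]):
        kl = lidx[po + k]
        kr = ridx[po + k]
        for s in range(4):
            if li < 0:
                a = pmat_l[s, kl]
            else:
                row = lo_l + kl
                a = (
                    pmat_l[s, 0] * lsrc[row, 0]
                    + pmat_l[s, 1] * lsrc[row, 1]
                    + pmat_l[s, 2] * lsrc[row, 2]
                    + pmat_l[s, 3] * lsrc[row, 3]
                )
            if ri < 0:
                b = pmat_r[s, kr]
            else:
                row = lo_r + kr
                b = (
                    pmat_r[s, 0] * rsrc[row, 0]
                    + pmat_r[s, 1] * rsrc[row, 1]
                    + pmat_r[s, 2] * rsrc[row, 2]
                    + pmat_r[s, 3] * rsrc[row, 3]
                )
            scratch[off + k, s] = a * b


@njit(cache=True)
def _root_loglik(root_iv, npat, part_off, counts, pi, store):
    off = part_off[root_iv]
    ll = 0.0
    for k in range(npat[root_iv]):
        site = (
            pi[0] * store[off + k, 0]
            + pi[1] * store[off + k, 1]
            + pi[2] * store[off + k, 2]
            + pi[3] * store[off + k, 3]
        )
        ll += counts[k] * math.log(site)
    return ll


@njit(cache=True)
def _propose_path(
    start_iv, changed, n_changed, newp,
    parent, node_of_int, int_of_node, left, right,
    npat, pat_off, part_off, lidx, ridx,
    partial, scratch, fresh, touched, pmat, counts, pi, root_iv,
):
    """Recompute partials from ``start_iv`` up to the root using the proposed
    P matrices in ``newp`` for the branches listed in ``changed``; returns
    (new log-likelihood, number of touched nodes)."""
    n_t = 0
    iv = start_iv
    while True:
        v = node_of_int[iv]
        l = left[iv]
        r = right[iv]
        pl = pmat[l]
        for j in range(n_changed):
            if changed[j] == l:
                pl = newp[j]
        pr = pmat[r]
        for j in range(n_changed):
            if changed[j] == r:
                pr = newp[j]
        _node_partial(
            iv, left, right, int_of_node, npat, pat_off, part_off, lidx, ridx,
            partial, scratch, fresh, pl, pr,
        )
        fresh[iv] = True
        touched[n_t] = iv
        n_t += 1
        p = parent[v]
        if p < 0:
            break
        iv = int_of_node[p]
    ll = _root_loglik(root_iv, npat, part_off, counts, pi, scratch)
    return ll, n_t


@njit(cache=True)
def _commit(touched, n_t, changed, n_changed, newp, npat, part_off, partial, scratch, fresh, pmat):
    for j in range(n_t):
        iv = touched[j]
        off = part_off[iv]
        for k in range(npat[iv]):
            for s in range(4):
                partial[off + k, s] = scratch[off + k, s]
        fresh[iv] = False
    for j in range(n_changed):
        b = changed[j]
        for s in range(4):
            for x in range(4):
                pmat[b, s, x] = newp[j, s, x]


@njit(cache=True)
def _clear_fresh(touched, n_t, fresh):
    for j in range(n_t):
        fresh[touched[j]] = False


@njit(cache=True)
def run_chain(
    parent, root, age_init, rate_init, mu_init, s2_init,
    node_of_int, int_of_node, left, right,
    npat, pat_off, part_off, lidx, ridx, counts, pi,
    eigw, eigU, eigUinv,
    cal_node, cal_lo, cal_hi, cal_tail,
    a_mu, b_mu, a_s2, b_s2,
    n_sweeps, burnin, thin, seed, prior_only,
):
    """One Metropolis-Hastings chain; returns (age trace, rate trace,
    mu trace, s2 trace, log-posterior trace, acceptance fractions)."""
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    n_int = node_of_int.shape[0]
    n_br = n_nodes - 1
    root_iv = int_of_node[root]

    age = age_init.copy()
    rate = rate_init.copy()
    mu = mu_init
    s2 = s2_init

    total_pat = lidx.shape[0]
    partial = np.zeros((total_pat, 4))
    scratch = np.zeros((total_pat, 4))
    fresh = np.zeros(n_int, dtype=np.bool_)
    touched = np.zeros(n_int, dtype=np.int64)
    pmat = np.zeros((n_nodes, 4, 4))
    newp = np.zeros((3, 4, 4))
    changed = np.zeros(3, dtype=np.int64)

    # initial P matrices and full set of partials
    if not prior_only:
        for v in range(n_nodes):
            if v != root:
                d = rate[v] * (age[parent[v]] - age[v])
                _fill_pmat(d, eigw, eigU, eigUinv, pmat[v])
        for iv in range(n_int):
            _node_partial(
                iv, left, right, int_of_node, npat, pat_off, part_off, lidx, ridx,
                partial, partial, fresh, pmat[left[iv]], pmat[right[iv]],
            )
        cur_ll = _root_loglik(root_iv, npat, part_off, counts, pi, partial)
    else:
        cur_ll = 0.0
    cur_lp = full_log_prior(
        age, rate, mu, s2, root, n_nodes,
        cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
    )

    # step sizes (ages in 100 Ma units, others on the log scale)
    w_age = np.full(n_int, 0.05)
    w_cage = np.full(n_int, 0.1)
    w_rate = np.full(n_nodes, 0.5)
    w_mu = 0.3
    w_s2 = 0.8
    w_resc = 0.1
    acc_age = np.zeros(n_int)
    try_age = np.zeros(n_int)
    acc_cage = np.zeros(n_int)
    try_cage = np.zeros(n_int)
    acc_rate = np.zeros(n_nodes)
    try_rate = np.zeros(n_nodes)
    acc_sc = np.zeros(3)
    try_sc = np.zeros(3)
    total_acc = np.zeros(6)
    total_try = np.zeros(6)

    n_samples = (n_sweeps - burnin) // thin
    tr_age = np.zeros((n_samples, n_int))
    tr_rate = np.zeros((n_samples, n_nodes))
    tr_mu = np.zeros(n_samples)
    tr_s2 = np.zeros(n_samples)
    tr_lp = np.zeros(n_samples)
    isamp = 0

    for sweep in range(n_sweeps):
        tuning = sweep < burnin
        # ---- node age moves -------------------------------------------------
        for iv in range(n_int):
            v = node_of_int[iv]
            l = left[iv]
            r = right[iv]
            lo = age[l] if age[l] > age[r] else age[r]
            has_hi = parent[v] >= 0
            hi = age[parent[v]] if has_hi else np.inf
            t_old = age[v]
            t_new = t_old + w_age[iv] * (np.random.random() - 0.5)
            for _ in range(100):  # reflect into (lo, hi)
                if t_new < lo:
                    t_new = 2.0 * lo - t_new
                elif has_hi and t_new > hi:
                    t_new = 2.0 * hi - t_new
                else:
                    break
            if t_new <= lo or (has_hi and t_new >= hi):
                continue
            age[v] = t_new
            new_lp = full_log_prior(
                age, rate, mu, s2, root, n_nodes,
                cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
            )
            n_changed = 0
            if prior_only:
                new_ll = 0.0
                n_t = 0
            else:
                for b in (l, r, v):
                    if b != root and (b == l or b == r or has_hi):
                        changed[n_changed] = b
                        d = rate[b] * (age[parent[b]] - age[b])
                        _fill_pmat(d, eigw, eigU, eigUinv, newp[n_changed])
                        n_changed += 1
                new_ll, n_t = _propose_path(
                    iv, changed, n_changed, newp,
                    parent, node_of_int, int_of_node, left, right,
                    npat, pat_off, part_off, lidx, ridx,
                    partial, scratch, fresh, touched, pmat, counts, pi, root_iv,
                )
            try_age[iv] += 1.0
            total_try[0] += 1.0
            if math.log(np.random.random()) < (new_lp + new_ll) - (cur_lp + cur_ll):
                cur_lp = new_lp
                if not prior_only:
                    cur_ll = new_ll
                    _commit(touched, n_t, changed, n_changed, newp, npat, part_off,
                            partial, scratch, fresh, pmat)
                acc_age[iv] += 1.0
                total_acc[0] += 1.0
            else:
                age[v] = t_old
                if not prior_only:
                    _clear_fresh(touched, n_t, fresh)
        # ---- branch rate moves ---------------------------------------------
        # each branch is proposed on alternating sweeps (the compensated age
        # moves below adjust rates every sweep, so rate mixing stays fast at
        # half the likelihood cost)
        for v in range(n_nodes):
            if v == root or (v + sweep) % 2 == 0:
                continue
            r_old = rate[v]
            lfac = w_rate[v] * (np.random.random() - 0.5)
            r_new = r_old * math.exp(lfac)
            rate[v] = r_new
            new_lp = full_log_prior(
                age, rate, mu, s2, root, n_nodes,
                cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
            )
            if prior_only:
                new_ll = 0.0
                n_t = 0
            else:
                changed[0] = v
                d = r_new * (age[parent[v]] - age[v])
                _fill_pmat(d, eigw, eigU, eigUinv, newp[0])
                new_ll, n_t = _propose_path(
                    int_of_node[parent[v]], changed, 1, newp,
                    parent, node_of_int, int_of_node, left, right,
                    npat, pat_off, part_off, lidx, ridx,
                    partial, scratch, fresh, touched, pmat, counts, pi, root_iv,
                )
            try_rate[v] += 1.0
            total_try[1] += 1.0
            # multiplicative proposal: Hastings term log(r_new/r_old) = lfac
            if math.log(np.random.random()) < (new_lp + new_ll) - (cur_lp + cur_ll) + lfac:
                cur_lp = new_lp
                if not prior_only:
                    cur_ll = new_ll
                    _commit(touched, n_t, changed, 1, newp, npat, part_off,
                            partial, scratch, fresh, pmat)
                acc_rate[v] += 1.0
                total_acc[1] += 1.0
            else:
                rate[v] = r_old
                if not prior_only:
                    _clear_fresh(touched, n_t, fresh)
        # ---- compensated age moves (branch lengths preserved) ---------------
        # shift one node age and rescale the three adjacent branch rates so
        # every rate x duration stays fixed: the likelihood is untouched and
        # the move carries the Jacobian of the rate rescaling.
        for iv in range(n_int):
            v = node_of_int[iv]
            l = left[iv]
            r = right[iv]
            lo = age[l] if age[l] > age[r] else age[r]
            has_hi = parent[v] >= 0
            hi = age[parent[v]] if has_hi else np.inf
            t_old = age[v]
            t_new = t_old + w_cage[iv] * (np.random.random() - 0.5)
            for _ in range(100):
                if t_new < lo:
                    t_new = 2.0 * lo - t_new
                elif has_hi and t_new > hi:
                    t_new = 2.0 * hi - t_new
                else:
                    break
            if t_new <= lo or (has_hi and t_new >= hi):
                continue
            rl_old = rate[l]
            rr_old = rate[r]
            rv_old = rate[v]
            jac = 0.0
            age[v] = t_new
            rate[l] = rl_old * (t_old - age[l]) / (t_new - age[l])
            jac += math.log((t_old - age[l]) / (t_new - age[l]))
            rate[r] = rr_old * (t_old - age[r]) / (t_new - age[r])
            jac += math.log((t_old - age[r]) / (t_new - age[r]))
            if has_hi:
                rate[v] = rv_old * (hi - t_old) / (hi - t_new)
                jac += math.log((hi - t_old) / (hi - t_new))
            new_lp = full_log_prior(
                age, rate, mu, s2, root, n_nodes,
                cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
            )
            try_cage[iv] += 1.0
            total_try[5] += 1.0
            if math.log(np.random.random()) < new_lp - cur_lp + jac:
                cur_lp = new_lp
                acc_cage[iv] += 1.0
                total_acc[5] += 1.0
            else:
                age[v] = t_old
                rate[l] = rl_old
                rate[r] = rr_old
                rate[v] = rv_old

        # ---- wide compensated moves (bracket-scaled, untuned) ---------------
        # same construction with a window of half the local age bracket:
        # low acceptance, but the accepted jumps traverse the weakly
        # identified directions (uncalibrated deep nodes) quickly.
        for iv in range(n_int):
            v = node_of_int[iv]
            l = left[iv]
            r = right[iv]
            lo = age[l] if age[l] > age[r] else age[r]
            has_hi = parent[v] >= 0
            hi = age[parent[v]] if has_hi else np.inf
            span = (hi - lo) if has_hi else 0.4
            t_old = age[v]
            t_new = t_old + 0.5 * span * (np.random.random() - 0.5)
            for _ in range(100):
                if t_new < lo:
                    t_new = 2.0 * lo - t_new
                elif has_hi and t_new > hi:
                    t_new = 2.0 * hi - t_new
                else:
                    break
            if t_new <= lo or (has_hi and t_new >= hi):
                continue
            rl_old = rate[l]
            rr_old = rate[r]
            rv_old = rate[v]
            jac = 0.0
            age[v] = t_new
            rate[l] = rl_old * (t_old - age[l]) / (t_new - age[l])
            jac += math.log((t_old - age[l]) / (t_new - age[l]))
            rate[r] = rr_old * (t_old - age[r]) / (t_new - age[r])
            jac += math.log((t_old - age[r]) / (t_new - age[r]))
            if has_hi:
                rate[v] = rv_old * (hi - t_old) / (hi - t_new)
                jac += math.log((hi - t_old) / (hi - t_new))
            new_lp = full_log_prior(
                age, rate, mu, s2, root, n_nodes,
                cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
            )
            if math.log(np.random.random()) < new_lp - cur_lp + jac:
                cur_lp = new_lp
            else:
                age[v] = t_old
                rate[l] = rl_old
                rate[r] = rr_old
                rate[v] = rv_old

        # ---- hyperparameters (prior-only terms) -----------------------------
        lfac = w_mu * (np.random.random() - 0.5)
        mu_new = mu * math.exp(lfac)
        new_lp = full_log_prior(
            age, rate, mu_new, s2, root, n_nodes,
            cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
        )
        try_sc[0] += 1.0
        total_try[2] += 1.0
        if math.log(np.random.random()) < new_lp - cur_lp + lfac:
            mu = mu_new
            cur_lp = new_lp
            acc_sc[0] += 1.0
            total_acc[2] += 1.0

        lfac = w_s2 * (np.random.random() - 0.5)
        s2_new = s2 * math.exp(lfac)
        try_sc[1] += 1.0
        total_try[3] += 1.0
        if s2_new >= SIGMA2_FLOOR:
            new_lp = full_log_prior(
                age, rate, mu, s2_new, root, n_nodes,
                cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
            )
            if math.log(np.random.random()) < new_lp - cur_lp + lfac:
                s2 = s2_new
                cur_lp = new_lp
                acc_sc[1] += 1.0
                total_acc[3] += 1.0

        # ---- rescale move (likelihood-invariant) ----------------------------
        lfac = w_resc * (np.random.random() - 0.5)
        c = math.exp(lfac)
        for v in range(n_nodes):
            if v != root:
                rate[v] /= c
        for iv in range(n_int):
            age[node_of_int[iv]] *= c
        mu_new = mu / c
        new_lp = full_log_prior(
            age, rate, mu_new, s2, root, n_nodes,
            cal_node, cal_lo, cal_hi, cal_tail, a_mu, b_mu, a_s2, b_s2,
        )
        try_sc[2] += 1.0
        total_try[4] += 1.0
        jac = (n_int - n_br - 1) * lfac
        if math.log(np.random.random()) < new_lp - cur_lp + jac:
            mu = mu_new
            cur_lp = new_lp
            acc_sc[2] += 1.0
            total_acc[4] += 1.0
        else:
            for v in range(n_nodes):
                if v != root:
                    rate[v] *= c
            for iv in range(n_int):
                age[node_of_int[iv]] /= c

        # ---- step-size tuning during burn-in --------------------------------
        if tuning and (sweep + 1) % 100 == 0:
            for iv in range(n_int):
                if try_age[iv] > 0:
                    w_age[iv] *= math.exp(acc_age[iv] / try_age[iv] - 0.3)
                    w_age[iv] = min(max(w_age[iv], 1e-4), 2.0)
                acc_age[iv] = 0.0
                try_age[iv] = 0.0
                if try_cage[iv] > 0:
                    w_cage[iv] *= math.exp(acc_cage[iv] / try_cage[iv] - 0.3)
                    w_cage[iv] = min(max(w_cage[iv], 1e-4), 2.0)
                acc_cage[iv] = 0.0
                try_cage[iv] = 0.0
            for v in range(n_nodes):
                if try_rate[v] > 0:
                    w_rate[v] *= math.exp(acc_rate[v] / try_rate[v] - 0.3)
                    w_rate[v] = min(max(w_rate[v], 1e-3), 5.0)
                acc_rate[v] = 0.0
                try_rate[v] = 0.0
            if try_sc[0] > 0:
                w_mu = min(max(w_mu * math.exp(acc_sc[0] / try_sc[0] - 0.3), 1e-3), 5.0)
            if try_sc[1] > 0:
                w_s2 = min(max(w_s2 * math.exp(acc_sc[1] / try_sc[1] - 0.3), 1e-3), 5.0)
            if try_sc[2] > 0:
                w_resc = min(max(w_resc * math.exp(acc_sc[2] / try_sc[2] - 0.3), 1e-4), 2.0)
            acc_sc[:] = 0.0
            try_sc[:] = 0.0
            if sweep + 1 == burnin // 2:
                total_acc[:] = 0.0
                total_try[:] = 0.0

        # ---- sampling --------------------------------------------------------
        if sweep >= burnin and (sweep - burnin) % thin == 0 and isamp < n_samples:
            for iv in range(n_int):
                tr_age[isamp, iv] = age[node_of_int[iv]]
            for v in range(n_nodes):
                tr_rate[isamp, v] = rate[v]
            tr_mu[isamp] = mu
            tr_s2[isamp] = s2
            tr_lp[isamp] = cur_lp + cur_ll
            isamp += 1

    acc_frac = np.zeros(6)
    for j in range(6):
        acc_frac[j] = total_acc[j] / total_try[j] if total_try[j] > 0 else np.nan
    return tr_age, tr_rate, tr_mu, tr_s2, tr_lp, acc_frac
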