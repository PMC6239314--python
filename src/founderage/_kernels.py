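"""Compiled inner loops (numba) for the age estimators.

Everything in here is a plain-array transliteration of formulas defined
and documented in :mod:`coalescent` and :mod:`birthdeath`; keep the
science there and only mechanics here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# star-likelihood Metropolis-Hastings
#
# Per marker i the composite likelihood needs only sufficient statistics:
#   M_i      = number of observed carrier alleles matching the ancestral a_i
#   nobs_i   = number of observed carrier alleles
#   C_i      = sum of log population frequencies over observed mismatches
#   pa_i     = population frequency of a_i
# giving  ll_i(t) = M_i*log(s + (1-s)*pa_i) + (nobs_i-M_i)*log(1-s) + C_i
# with s = exp(-theta_i * t).


@njit(cache=True)
def _col_ll(t, theta_i, M_i, nobs_i, C_i, pa_i):
    s = np.exp(-theta_i * t)
    ll = M_i * np.log(s + (1.0 - s) * pa_i) + C_i
    mism = nobs_i - M_i
    if mism > 0:
        if s >= 1.0:
            return -np.inf
        ll += mism * np.log(1.0 - s)
    return ll


@njit(cache=True)
def _total_ll(t, theta, M, nobs, C, pa):
    tot = 0.0
    for i in range(theta.shape[0]):
        tot += _col_ll(t, theta[i], M[i], nobs[i], C[i], pa[i])
    return tot


@njit(cache=True)
def _fold(x, lo, hi):
    """Reflect x into [lo, hi] (handles proposals far outside the box)."""
    span = hi - lo
    if span <= 0.0:
        return lo
    r = (x - lo) % (2.0 * span)
    if r < 0.0:
        r += 2.0 * span
    return lo + (span - abs(r - span))


@njit(cache=True)
def mcmc_star(
    Xc,  # (n, m) int64 allele codes, -1 missing
    logp_x,  # (n, m) float64 log pop freq of the observed allele (0 if missing)
    freq,  # (m, K) float64 population frequencies
    theta,  # (m,) float64 recombination fraction to the variant
    n_alleles,  # (m,) int64
    a0,  # (m,) int64 initial ancestral haplotype codes
    t0,
    t_min,
    t_max,
    n_iter,
    burn_in,
    thin,
    step0,
    adapt,
    seed,
):
    np.random.seed(seed)
    n, m = Xc.shape
    a = a0.copy()
    # sufficient statistics for the current ancestral haplotype
    M = np.zeros(m, dtype=np.int64)
    nobs = np.zeros(m, dtype=np.int64)
    C = np.zeros(m)
    pa = np.ones(m)
    for i in range(m):
        for j in range(n):
            c = Xc[j, i]
            if c < 0:
                continue
            nobs[i] += 1
            if c == a[i]:
                M[i] += 1
            else:
                C[i] += logp_x[j, i]
        if m > 0:
            pa[i] = freq[i, a[i]]
    t = t0
    ll = _total_ll(t, theta, M, nobs, C, pa)
    sum_logpa = 0.0
    for i in range(m):
        sum_logpa += np.log(pa[i])

    n_keep = 0
    if n_iter > burn_in:
        n_keep = (n_iter - burn_in + thin - 1) // thin
    t_draws = np.empty(n_keep)
    lp_draws = np.empty(n_keep)
    keep = 0
    step = step0
    acc_t = 0
    acc_a = 0
    n_a_prop = 0
    win_acc = 0
    win_n = 0
    for it in range(n_iter):
        # --- age update: reflected Gaussian random walk
        tp = _fold(t + step * np.random.normal(), t_min, t_max)
        llp = _total_ll(tp, theta, M, nobs, C, pa)
        if np.log(np.random.random()) < llp - ll:
            t = tp
            ll = llp
            acc_t += 1
            win_acc += 1
        win_n += 1
        if adapt and it < burn_in and win_n == 50:
            rate = win_acc / 50.0
            step *= np.exp(rate - 0.44)
            if step < 1e-3:
                step = 1e-3
            if step > (t_max - t_min):
                step = t_max - t_min
            win_acc = 0
            win_n = 0
        # --- ancestral-haplotype update: single-marker proposal from pop freqs
        if m > 0:
            i = np.random.randint(m)
            u = np.random.random()
            K = n_alleles[i]
            cum = 0.0
            k = K - 1
            for kk in range(K):
                cum += freq[i, kk]
                if u < cum:
                    k = kk
                    break
            n_a_prop += 1
            if k != a[i]:
                newM = 0
                newC = 0.0
                for j in range(n):
                    c = Xc[j, i]
                    if c < 0:
                        continue
                    if c == k:
                        newM += 1
                    else:
                        newC += logp_x[j, i]
                new_ll_i = _col_ll(t, theta[i], newM, nobs[i], newC, freq[i, k])
                old_ll_i = _col_ll(t, theta[i], M[i], nobs[i], C[i], pa[i])
                if np.log(np.random.random()) < new_ll_i - old_ll_i:
                    sum_logpa += np.log(freq[i, k]) - np.log(pa[i])
                    a[i] = k
                    M[i] = newM
                    C[i] = newC
                    pa[i] = freq[i, k]
                    ll += new_ll_i - old_ll_i
                    acc_a += 1
        if it >= burn_in and (it - burn_in) % thin == 0:
            t_draws[keep] = t
            lp_draws[keep] = ll + sum_logpa
            keep += 1
    acc_t_rate = acc_t / n_iter if n_iter > 0 else 0.0
    acc_a_rate = acc_a / n_a_prop if n_a_prop > 0 else 0.0
    return t_draws[:keep], lp_draws[:keep], acc_t_rate, acc_a_rate, step, a


# ---------------------------------------------------------------------------
# birth-death reconstructed-process genealogies and the ancestral-class
# size distribution on a tree


@njit(cache=True)
def _invert_recon_cdf(u, t, lam, mu, rho):
    """Inverse CDF of a reconstructed-process coalescence age on [0, t]."""
    d = lam - mu
    A = rho * lam
    B = mu - lam * (1.0 - rho)
    Et = np.exp(-d * t)
    qt = (1.0 - Et) / (A - B * Et)
    y = u * qt
    E = (1.0 - y * A) / (1.0 - y * B)
    if E <= 0.0:
        E = 1e-300
    s = -np.log(E) / d
    if s < 0.0:
        s = 0.0
    if s > t:
        s = t
    return s


@njit(cache=True)
def _k_dist_prob(times, ju, t_origin, r_exit, k_obs):
    """P(ancestral-class size == k_obs) for a genealogy built from sorted
    coalescence ages ``times`` and join randomness ``ju``.

    A lineage exits the ancestral haplotype class at rate ``r_exit`` per
    generation; an exit anywhere on a branch removes every descendant
    leaf from the class.  The distribution of the number of leaves still
    in the class is accumulated bottom-up as a polynomial per node.
    """
    nc = times.shape[0]
    n = nc + 1
    size = 2 * n - 1
    parent = np.full(size, -1, dtype=np.int64)
    node_time = np.zeros(size)
    left = np.full(size, -1, dtype=np.int64)
    right = np.full(size, -1, dtype=np.int64)
    active = np.empty(size, dtype=np.int64)
    for i in range(n):
        active[i] = i
    n_active = n
    nxt = n
    for j in range(nc):
        ia = int(ju[j, 0] * n_active)
        if ia >= n_active:
            ia = n_active - 1
        a = active[ia]
        active[ia] = active[n_active - 1]
        n_active -= 1
        ib = int(ju[j, 1] * n_active)
        if ib >= n_active:
            ib = n_active - 1
        b = active[ib]
        active[ib] = active[n_active - 1]
        n_active -= 1
        parent[a] = nxt
        parent[b] = nxt
        left[nxt] = a
        right[nxt] = b
        node_time[nxt] = times[j]
        active[n_active] = nxt
        n_active += 1
        nxt += 1

    # bottom-up polynomial in the class-size counting variable
    poly = np.zeros((size, n + 1))
    deg = np.zeros(size, dtype=np.int64)
    work = np.zeros(n + 1)
    for v in range(size):
        if v < n:
            p_top = t_origin if parent[v] < 0 else node_time[parent[v]]
            s = np.exp(-r_exit * (p_top - 0.0))
            poly[v, 0] = 1.0 - s
            poly[v, 1] = s
            deg[v] = 1
        else:
            a = left[v]
            b = right[v]
            da = deg[a]
            db = deg[b]
            for k in range(da + db + 1):
                work[k] = 0.0
            for ka in range(da + 1):
                pa_k = poly[a, ka]
                if pa_k == 0.0:
                    continue
                for kb in range(db + 1):
                    work[ka + kb] += pa_k * poly[b, kb]
            p_top = t_origin if parent[v] < 0 else node_time[parent[v]]
            s = np.exp(-r_exit * (p_top - node_time[v]))
            for k in range(da + db + 1):
                poly[v, k] = s * work[k]
            poly[v, 0] += 1.0 - s
            deg[v] = da + db
    root = size - 1
    if k_obs < 0 or k_obs > n:
        return 0.0
    return poly[root, k_obs]


@njit(cache=True)
def _traj_coal_ages(u_row, t, d, C, out):
    """Sequential coalescence ages under the endpoint-constrained
    trajectory N(s) = 1 + (C-1)(exp(d(t-s)) - 1)/(exp(dt) - 1).

    Each uniform drives one inter-coalescence waiting time via the
    closed-form inverse of the integrated rate.  Lineages that have not
    coalesced by the founding event are merged just below it (all copies
    descend from the single founder, so the conditioning concentrates
    there).  Ages come out sorted ascending in ``out``.
    """
    nc = u_row.shape[0]
    n = nc + 1
    use_exp = abs(d) > 1e-12 and d * t < 600.0 and C > 1.0
    if use_exp:
        a = (C - 1.0) / (np.exp(d * t) - 1.0)
        c = 1.0 - a
    else:
        a = 0.0
        c = 1.0
    k_lin = (C - 1.0) / t
    s = 0.0
    clamped = 0
    rate_scale = 2.0 * (1.0 + d)  # birth-death ancestry: lambda k(k-1)/N
    for j in range(nc):
        k = n - j
        Ck = 0.5 * k * (k - 1) * rate_scale
        e = -np.log(u_row[j])
        tau = e / Ck
        s_new = t  # default: merge at the founding event
        if not use_exp:
            if C > 1.0:
                # N = 1 + k_lin (t - s); integral has a log closed form
                u0 = t - s
                arg = np.log(1.0 + k_lin * u0) - k_lin * tau
                if arg > 0.0:
                    u_new = (np.exp(arg) - 1.0) / k_lin
                    if u_new > 0.0:
                        s_new = t - u_new
            else:
                s_new = s + tau
        else:
            y0 = np.exp(d * (t - s))
            if abs(c) > 1e-9:
                # denom and c share their sign while the event falls before
                # the founding event; y0*c/denom is then the new e^{d(t-s)}
                denom = np.exp(d * c * tau) * (c + a * y0) - a * y0
                if denom != 0.0:
                    y = y0 * c / denom
                    if y >= y0:  # numerical round-off: zero waiting time
                        s_new = s
                    elif y > 1.0:
                        s_new = t - np.log(y) / d
            else:
                # c == 0: N = a exp(d u); integral = (exp(-d u) - ...)/(d a)
                y = 1.0 / (1.0 / y0 + d * a * tau)
                if y > 1.0:
                    s_new = t - np.log(y) / d
        if s_new >= t:
            clamped += 1
            s_new = t * (1.0 - 1e-9 * (nc - j))
        if s_new <= s:
            s_new = s + 1e-12
        out[j] = s_new
        s = s_new
    return clamped


@njit(cache=True)
def bd_class_profile(
    grid,  # (G,) candidate ages
    U,  # (R, n-1) uniforms for coalescence ages (common random numbers)
    J,  # (R, n-1, 2) uniforms for topology joins
    k_obs,
    d,  # growth rate of the mutant class
    C,  # implied present-day copy number (n / sampled proportion)
    r_exit,
):
    """Monte-Carlo mean and variance of P(class size = k_obs | age) per grid age."""
    G = grid.shape[0]
    R = U.shape[0]
    nc = U.shape[1]
    mean = np.zeros(G)
    var = np.zeros(G)
    times = np.empty(nc)
    for g in range(G):
        t = grid[g]
        acc = 0.0
        acc2 = 0.0
        for r in range(R):
            _traj_coal_ages(U[r], t, d, C, times)
            p = _k_dist_prob(times, J[r], t, r_exit, k_obs)
            acc += p
            acc2 += p * p
        mean[g] = acc / R
        var[g] = acc2 / R - (acc / R) ** 2
    return mean, var


@njit(cache=True)
def bd_pipeline_profile(
    grid,  # (G,) candidate ages
    n,  # carrier chromosomes
    n_reps,
    base_seed,
    d,  # growth rate
    C,  # implied present-day copy number
    dist,  # (m,) marker-variant distances in Morgans
    is_left,  # (m,) True for markers proximal (upstream) of the variant
    freq,  # (m, K) population allele frequencies
    n_alleles,  # (m,) int64
    k_obs,
):
    """Simulation-based likelihood of the observed intact-class count.

    For each replicate a genealogy is drawn from the growth-conditioned
    coalescent, the ancestral haplotype is drawn from the population
    frequencies, recombination is laid down branch by branch
    (first-crossover-censors-distal, with post-crossover material shared
    by descendants), and the *same statistic pipeline as the data* — the
    per-marker modal carrier allele, then the count of chromosomes
    matching it everywhere — is applied to the simulated panel.  The
    likelihood at each age is the fraction of replicates reproducing
    ``k_obs`` exactly, so the estimator-side selection bias of the
    plug-in ancestral haplotype is part of the model rather than a
    confounder.  Each replicate draws its uniforms once and reuses them
    at every grid age (common random numbers).
    """
    np.random.seed(base_seed)
    G = grid.shape[0]
    m = dist.shape[0]
    nn = 2 * n - 1
    hits = np.zeros(G)
    times = np.empty(n - 1)
    parent = np.empty(nn, dtype=np.int64)
    left = np.empty(nn, dtype=np.int64)
    right = np.empty(nn, dtype=np.int64)
    node_time = np.empty(nn)
    order = np.empty(nn, dtype=np.int64)
    haps = np.empty((nn, m), dtype=np.int16)
    counts = np.empty((m, freq.shape[1]), dtype=np.int64)
    modal = np.empty(m, dtype=np.int16)
    # per-replicate randomness, reused across the grid
    u_ages = np.empty(n - 1)
    u_anc = np.empty(m)
    u_cross = np.empty((nn, 2))
    u_repl = np.empty((nn, 2, m))
    for r in range(n_reps):
        for j in range(n - 1):
            u_ages[j] = np.random.random()
        for i in range(m):
            u_anc[i] = np.random.random()
        for v in range(nn):
            for side in range(2):
                u_cross[v, side] = np.random.random()
                for i in range(m):
                    u_repl[v, side, i] = np.random.random()
        jr1 = np.random.random(n - 1)
        jr2 = np.random.random(n - 1)
        for g in range(G):
            t = grid[g]
            _traj_coal_ages(u_ages, t, d, C, times)
            # topology joins from the replicate's own uniforms
            for v in range(nn):
                parent[v] = -1
                left[v] = -1
                right[v] = -1
                node_time[v] = 0.0
            active = order  # reuse as scratch
            for i in range(n):
                active[i] = i
            n_active = n
            nxt = n
            for j in range(n - 1):
                ia = int(jr1[j] * n_active)
                if ia >= n_active:
                    ia = n_active - 1
                a = active[ia]
                active[ia] = active[n_active - 1]
                n_active -= 1
                ib = int(jr2[j] * n_active)
                if ib >= n_active:
                    ib = n_active - 1
                b = active[ib]
                active[ib] = active[n_active - 1]
                n_active -= 1
                parent[a] = nxt
                parent[b] = nxt
                left[nxt] = a
                right[nxt] = b
                node_time[nxt] = times[j]
                active[n_active] = nxt
                n_active += 1
                nxt += 1
            _postorder(parent, left, right, n, order)
            # ancestral haplotype from the population frequencies
            for i in range(m):
                cum = 0.0
                k = n_alleles[i] - 1
                for kk in range(n_alleles[i]):
                    cum += freq[i, kk]
                    if u_anc[i] < cum:
                        k = kk
                        break
                haps[nn - 1, i] = k
            # transmit down the tree; pre-order so parents come first
            for oi in range(nn - 1, -1, -1):
                v = order[oi]
                p = parent[v]
                if p < 0:
                    top = t
                    src = nn - 1  # root row already holds the ancestral
                else:
                    top = node_time[p]
                    src = p
                L = top - node_time[v]
                if v != src:
                    for i in range(m):
                        haps[v, i] = haps[src, i]
                for side in range(2):
                    gpos = -np.log(u_cross[v, side]) / L if L > 0.0 else 1e30
                    for i in range(m):
                        on_side = is_left[i] if side == 0 else not is_left[i]
                        if on_side and dist[i] > gpos:
                            cum = 0.0
                            k = n_alleles[i] - 1
                            for kk in range(n_alleles[i]):
                                cum += freq[i, kk]
                                if u_repl[v, side, i] < cum:
                                    k = kk
                                    break
                            haps[v, i] = k
            # the data pipeline's statistic: modal allele per marker,
            # then the count of chromosomes intact everywhere
            for i in range(m):
                for kk in range(n_alleles[i]):
                    counts[i, kk] = 0
                for j in range(n):
                    counts[i, haps[j, i]] += 1
                best = 0
                for kk in range(1, n_alleles[i]):
                    if counts[i, kk] > counts[i, best]:
                        best = kk
                modal[i] = best
            k_hat = 0
            for j in range(n):
                ok = True
                for i in range(m):
                    if haps[j, i] != modal[i]:
                        ok = False
                        break
                if ok:
                    k_hat += 1
            if k_hat == k_obs:
                hits[g] += 1.0
    return hits / n_reps


# ---------------------------------------------------------------------------
# genealogy-model MCMC
#
# State: the age t plus an explicit time-tree (parent/left/right arrays,
# node ages).  Prior: coalescence ages iid from the reconstructed
# birth-death age CDF (the random-join ranked topology makes the
# topology factor constant, so any parent-age > child-age configuration
# is valid).  Likelihood: per-marker peeling under the
# jump-to-stationarity recombination model, with the ancestral allele
# marginalised at the root against the population frequencies.


@njit(cache=True)
def _logq(t, lam, mu, rho):
    d = lam - mu
    A = rho * lam
    B = mu - lam * (1.0 - rho)
    if abs(d) < 1e-12:
        return np.log(t / (1.0 + A * t))
    Et = np.exp(-d * t)
    return np.log((1.0 - Et) / (A - B * Et))


@njit(cache=True)
def _coal_logprior(ages_sorted, t, d, C):
    """Log density of coalescence ages under the intra-allelic coalescent
    with the endpoint-constrained mutant-class trajectory

        N(s) = 1 + (C - 1) * (exp(d (t - s)) - 1) / (exp(d t) - 1),

    i.e. exactly one copy at the founding event (age t), C copies today,
    and the exponential shape of a surviving supercritical birth-death
    class in between (fast escape from low copy numbers, long-run rate
    d).  With k lineages, pairs coalesce at rate k(k-1)/(2 N(s)); the
    density is the standard inhomogeneous-exponential product, using the
    closed-form antiderivative of 1/N.  Ages must be sorted ascending
    and all below t; the normalising probability of full coalescence by
    t (~1, since the rate approaches k(k-1)/2 at the founding) is
    omitted.
    """
    nc = ages_sorted.shape[0]
    n = nc + 1
    if nc == 0:
        return 0.0
    if ages_sorted[nc - 1] >= t or t <= 0.0:
        return -np.inf
    if C < 1.0:
        C = 1.0
    rate_scale = 2.0 * (1.0 + d)  # birth-death ancestry: lambda k(k-1)/N
    use_exp = abs(d) > 1e-12 and d * t < 600.0
    if use_exp:
        a = (C - 1.0) / (np.exp(d * t) - 1.0) if C > 1.0 else 0.0
        c = 1.0 - a
    else:
        a = 0.0
        c = 1.0
    k_lin = (C - 1.0) / t  # linear fallback (d ~ 0): N = 1 + k_lin * u

    lp = 0.0
    prev = 0.0
    for j in range(nc):
        kk = n - j
        Ck = 0.5 * kk * (kk - 1) * rate_scale
        s = ages_sorted[j]
        u1 = t - s  # time since founding at the coalescence
        u2 = t - prev
        if use_exp and a > 0.0:
            N_s = c + a * np.exp(d * u1)
            lp += np.log(Ck) - np.log(N_s)
            # integral of 1/N over ages [prev, s] == over u in [u1, u2]
            if abs(c) > 1e-9:
                G1 = (u1 - np.log(c + a * np.exp(d * u1)) / d) / c
                G2 = (u2 - np.log(c + a * np.exp(d * u2)) / d) / c
            else:  # c == 0: N = a exp(d u)
                G1 = -np.exp(-d * u1) / (d * a)
                G2 = -np.exp(-d * u2) / (d * a)
            lp -= Ck * (G2 - G1)
        elif C > 1.0:
            N_s = 1.0 + k_lin * u1
            lp += np.log(Ck) - np.log(N_s)
            lp -= Ck * (np.log(1.0 + k_lin * u2) - np.log(1.0 + k_lin * u1)) / k_lin
        else:
            lp += np.log(Ck)
            lp -= Ck * (s - prev)
        prev = s
    return lp


@njit(cache=True)
def _log_copy_prior(t, d, C, n):
    """Log prior of the present copy number C under the linear birth-death
    law (lambda = 1 + d, mu = 1) at age t, conditioned on C >= n:
    P(C) = (1 - beta) beta^(C - n)."""
    lam = 1.0 + d
    mu = 1.0
    if t <= 0.0:
        return -np.inf
    if abs(d) < 1e-12:
        beta = lam * t / (1.0 + lam * t)
    else:
        E = np.exp(d * t)
        beta = lam * (E - 1.0) / (lam * E - mu)
    if beta <= 0.0 or beta >= 1.0:
        return -np.inf
    return np.log(1.0 - beta) + (C - n) * np.log(beta)


@njit(cache=True)
def _postorder(parent, left, right, n, order):
    nn = 2 * n - 1
    stack = np.empty(nn, dtype=np.int64)
    top = 0
    stack[top] = nn - 1  # root
    top = 1
    pos = nn
    while top > 0:
        top -= 1
        v = stack[top]
        pos -= 1
        order[pos] = v
        if v >= n:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    # the pre-order pop sequence was written back-to-front, so ``order``
    # is its reverse: children always precede their parents


@njit(cache=True)
def _peel_all(Xc, freq, n_alleles, theta, parent, left, right, node_time, order, t, partial):
    """Total log-likelihood of the carrier panel given the tree, with the
    ancestral haplotype integrated against the population frequencies."""
    n, m = Xc.shape
    nn = 2 * n - 1
    total = 0.0
    for i in range(m):
        K = n_alleles[i]
        logscale = 0.0
        for oi in range(nn):
            v = order[oi]
            if v < n:
                c = Xc[v, i]
                if c < 0:
                    for k in range(K):
                        partial[v, k] = 1.0
                else:
                    for k in range(K):
                        partial[v, k] = 0.0
                    partial[v, c] = 1.0
            else:
                for k in range(K):
                    partial[v, k] = 1.0
                for side in range(2):
                    ch = left[v] if side == 0 else right[v]
                    s = np.exp(-theta[i] * (node_time[v] - node_time[ch]))
                    dot = 0.0
                    for k in range(K):
                        dot += freq[i, k] * partial[ch, k]
                    for k in range(K):
                        partial[v, k] *= s * partial[ch, k] + (1.0 - s) * dot
                mx = 0.0
                for k in range(K):
                    if partial[v, k] > mx:
                        mx = partial[v, k]
                if mx <= 0.0:
                    return -np.inf
                for k in range(K):
                    partial[v, k] /= mx
                logscale += np.log(mx)
        root = nn - 1
        s0 = np.exp(-theta[i] * (t - node_time[root]))
        dot = 0.0
        for k in range(K):
            dot += freq[i, k] * partial[root, k]
        marg = 0.0
        for k in range(K):
            marg += freq[i, k] * (s0 * partial[root, k] + (1.0 - s0) * dot)
        if marg <= 0.0:
            return -np.inf
        total += np.log(marg) + logscale
    return total


@njit(cache=True)
def _join_random(ages_sorted, n, parent, left, right, node_time):
    """Random ranked-topology joins over sorted coalescence ages (in place)."""
    nn = 2 * n - 1
    for v in range(nn):
        parent[v] = -1
        left[v] = -1
        right[v] = -1
        node_time[v] = 0.0
    active = np.empty(nn, dtype=np.int64)
    for i in range(n):
        active[i] = i
    n_active = n
    nxt = n
    for j in range(n - 1):
        ia = np.random.randint(n_active)
        a = active[ia]
        active[ia] = active[n_active - 1]
        n_active -= 1
        ib = np.random.randint(n_active)
        b = active[ib]
        active[ib] = active[n_active - 1]
        n_active -= 1
        parent[a] = nxt
        parent[b] = nxt
        left[nxt] = a
        right[nxt] = b
        node_time[nxt] = ages_sorted[j]
        active[n_active] = nxt
        n_active += 1
        nxt += 1


@njit(cache=True)
def _sorted_ages(node_time, n, buf):
    for j in range(n - 1):
        buf[j] = node_time[n + j]
    return np.sort(buf)


@njit(cache=True)
def mcmc_genealogy(
    Xc,  # (n, m) int64 allele codes, -1 missing
    freq,  # (m, K)
    theta,  # (m,)
    n_alleles,  # (m,) int64
    d,  # mutant-class growth rate per generation
    C,  # present-day mutant copy number (n / sampled proportion)
    t0,
    t_min,
    t_max,
    n_iter,
    burn_in,
    thin,
    step0,
    adapt,
    refresh_every,
    seed,
):
    np.random.seed(seed)
    n, m = Xc.shape
    nn = 2 * n - 1
    parent = np.empty(nn, dtype=np.int64)
    left = np.empty(nn, dtype=np.int64)
    right = np.empty(nn, dtype=np.int64)
    node_time = np.empty(nn)
    order = np.empty(nn, dtype=np.int64)
    Kmax = freq.shape[1]
    partial = np.empty((nn, Kmax))

    t = t0
    ages = np.empty(n - 1)
    horizon = min(t0 * 0.9, max(np.log(max(C, 2.0)) / d + 10.0, 5.0) if d > 1e-12 else t0 * 0.9)
    for j in range(n - 1):
        ages[j] = horizon * (j + 1.0) / n
    _join_random(ages, n, parent, left, right, node_time)
    _postorder(parent, left, right, n, order)
    ll = _peel_all(Xc, freq, n_alleles, theta, parent, left, right, node_time, order, t, partial)
    scratch_ages = np.empty(n - 1)
    lp_prior = _coal_logprior(_sorted_ages(node_time, n, scratch_ages), t, d, C)
    lp_copy = _log_copy_prior(t, d, C, n)

    n_keep = 0
    if n_iter > burn_in:
        n_keep = (n_iter - burn_in + thin - 1) // thin
    t_draws = np.empty(n_keep)
    lp_draws = np.empty(n_keep)
    keep = 0
    step = step0
    acc_t = 0
    win_acc = 0
    win_n = 0
    for it in range(n_iter):
        # ---- age-of-variant move (ages kept; prior density re-evaluated)
        tp = _fold(t + step * np.random.normal(), t_min, t_max)
        lp_prior_p = _coal_logprior(_sorted_ages(node_time, n, scratch_ages), tp, d, C)
        lp_copy_p = _log_copy_prior(tp, d, C, n)
        if lp_prior_p > -np.inf:
            llp = _peel_all(
                Xc, freq, n_alleles, theta, parent, left, right, node_time, order, tp, partial
            )
            logacc = (llp - ll) + (lp_prior_p - lp_prior) + (lp_copy_p - lp_copy)
            if np.log(np.random.random()) < logacc:
                t = tp
                ll = llp
                lp_prior = lp_prior_p
                lp_copy = lp_copy_p
                acc_t += 1
                win_acc += 1
        win_n += 1
        if adapt and it < burn_in and win_n == 50:
            rate = win_acc / 50.0
            step *= np.exp(rate - 0.44)
            if step < 1e-3:
                step = 1e-3
            if step > (t_max - t_min):
                step = t_max - t_min
            win_acc = 0
            win_n = 0
        # ---- joint time-scaling move: (t, all node ages) *= gamma
        gamma = np.exp(0.3 * (np.random.random() - 0.5))
        tp = t * gamma
        if t_min <= tp <= t_max:
            for j in range(n - 1):
                node_time[n + j] *= gamma
            lp_prior_p = _coal_logprior(_sorted_ages(node_time, n, scratch_ages), tp, d, C)
            lp_copy_p = _log_copy_prior(tp, d, C, n)
            llp = _peel_all(
                Xc, freq, n_alleles, theta, parent, left, right, node_time, order, tp, partial
            )
            logacc = (
                (llp - ll)
                + (lp_prior_p - lp_prior)
                + (lp_copy_p - lp_copy)
                + n * np.log(gamma)
            )
            if np.log(np.random.random()) < logacc:
                t = tp
                ll = llp
                lp_prior = lp_prior_p
                lp_copy = lp_copy_p
            else:
                for j in range(n - 1):
                    node_time[n + j] /= gamma
        # ---- node-age moves (uniform proposal within the local interval)
        for _rep in range(2):
            v = n + np.random.randint(n - 1)
            lo = max(node_time[left[v]], node_time[right[v]])
            hi = t if parent[v] < 0 else node_time[parent[v]]
            if hi <= lo:
                continue
            s_new = lo + np.random.random() * (hi - lo)
            s_old = node_time[v]
            node_time[v] = s_new
            lp_prior_p = _coal_logprior(_sorted_ages(node_time, n, scratch_ages), t, d, C)
            llp = _peel_all(
                Xc, freq, n_alleles, theta, parent, left, right, node_time, order, t, partial
            )
            if np.log(np.random.random()) < (llp - ll) + (lp_prior_p - lp_prior):
                ll = llp
                lp_prior = lp_prior_p
            else:
                node_time[v] = s_old
        # ---- nearest-neighbour interchange
        for _rep in range(2):
            if n < 3:
                break
            v = n + np.random.randint(n - 2)  # internal, not root
            p = parent[v]
            w = right[p] if left[p] == v else left[p]
            if node_time[w] >= node_time[v]:
                continue
            c = left[v] if np.random.random() < 0.5 else right[v]
            # swap c (child of v) with w (sibling of v)
            if left[v] == c:
                left[v] = w
            else:
                right[v] = w
            parent[w] = v
            if left[p] == w:
                left[p] = c
            else:
                right[p] = c
            parent[c] = p
            _postorder(parent, left, right, n, order)
            llp = _peel_all(
                Xc, freq, n_alleles, theta, parent, left, right, node_time, order, t, partial
            )
            if np.log(np.random.random()) < llp - ll:
                ll = llp
            else:  # revert
                if left[v] == w:
                    left[v] = c
                else:
                    right[v] = c
                parent[c] = v
                if left[p] == c:
                    left[p] = w
                else:
                    right[p] = w
                parent[w] = p
                _postorder(parent, left, right, n, order)
        # ---- occasional whole-topology refresh at the current ages
        if refresh_every > 0 and it % refresh_every == 0:
            for j in range(n - 1):
                scratch_ages[j] = node_time[n + j]
            ages_sorted = np.sort(scratch_ages)
            parent2 = parent.copy()
            left2 = left.copy()
            right2 = right.copy()
            time2 = node_time.copy()
            _join_random(ages_sorted, n, parent, left, right, node_time)
            _postorder(parent, left, right, n, order)
            llp = _peel_all(
                Xc, freq, n_alleles, theta, parent, left, right, node_time, order, t, partial
            )
            if np.log(np.random.random()) < llp - ll:
                ll = llp
            else:
                parent[:] = parent2
                left[:] = left2
                right[:] = right2
                node_time[:] = time2
                _postorder(parent, left, right, n, order)
        if it >= burn_in and (it - burn_in) % thin == 0:
            t_draws[keep] = t
            lp_draws[keep] = ll + lp_prior + lp_copy
            keep += 1
    acc_rate = acc_t / n_iter if n_iter > 0 else 0.0
    return t_draws[:keep], lp_draws[:keep], acc_rate, step


# ---------------------------------------------------------------------------
# forward linear birth-death with full lineage recording


@njit(cache=True)
def bd_forward(t, lam, mu, seed, cap):
    """One forward birth-death realisation from a single founder copy.

    Returns (status, count, parent, tbirth, alive, n_alive) where status
    is 0 on success and 1 if ``cap`` individuals were exceeded.  Times
    are forward (0 at the founding event).
    """
    np.random.seed(seed)
    parent = np.full(cap, -1, dtype=np.int64)
    tbirth = np.zeros(cap)
    alive = np.empty(cap, dtype=np.int64)
    alive[0] = 0
    n_alive = 1
    count = 1
    now = 0.0
    total_rate = lam + mu
    while n_alive > 0:
        rate = total_rate * n_alive
        now += -np.log(np.random.random()) / rate
        if now >= t:
            break
        idx = np.random.randint(n_alive)
        if np.random.random() < lam / total_rate:
            if count >= cap:
                return 1, count, parent, tbirth, alive, n_alive
            parent[count] = alive[idx]
            tbirth[count] = now
            alive[n_alive] = count
            n_alive += 1
            count += 1
        else:
            alive[idx] = alive[n_alive - 1]
            n_alive -= 1
    return 0, count, parent, tbirth, alive, n_alive
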