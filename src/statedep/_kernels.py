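"""Numba kernels: two-state CTMC machinery, contrasts likelihood, MCMC sweep.

Everything here operates on flat preorder arrays (node 0 = root, parent[i] < i)
so the reversed node range is a valid children-before-parents order.  All
randomness uses numba's global legacy RNG, seeded once per chain/draw through
:func:`set_seed`, which makes every kernel deterministic given a seed.
"""

import math

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


@njit(cache=True, fastmath=True)
def set_seed(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# Two-state CTMC primitives
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def pij(q01, q10, t):
    """Closed-form transition probabilities (p00, p01, p10, p11)."""
    qs = q01 + q10
    if qs <= 0.0:
        return 1.0, 0.0, 0.0, 1.0
    e = np.exp(-qs * t)
    pi1 = q01 / qs
    pi0 = 1.0 - pi1
    p01 = pi1 * (1.0 - e)
    p10 = pi0 * (1.0 - e)
    return 1.0 - p01, p01, p10, 1.0 - p10


@njit(cache=True, fastmath=True)
def sample_node_states(parent, blen, is_tip, tip_state, q01, q10, root_p0,
                       node_state, f0, f1):
    """Sample internal node states conditional on tip states (pruning + drop-down).

    Partial likelihoods are renormalized per node, which is safe because only
    conditional ratios are used.  Returns 0 on success, 1 if the tip
    configuration has zero probability under the rates.
    """
    n = parent.shape[0]
    for v in range(n - 1, -1, -1):
        if is_tip[v]:
            f0[v] = 1.0 if tip_state[v] == 0 else 0.0
            f1[v] = 1.0 - f0[v]
        else:
            f0[v] = 1.0
            f1[v] = 1.0
    # accumulate child contributions into parents (reverse preorder)
    for v in range(n - 1, 0, -1):
        p00, p01, p10, p11 = pij(q01, q10, blen[v])
        l0 = p00 * f0[v] + p01 * f1[v]
        l1 = p10 * f0[v] + p11 * f1[v]
        pa = parent[v]
        f0[pa] *= l0
        f1[pa] *= l1
        s = f0[pa] + f1[pa]
        if s <= 0.0:
            return 1
        f0[pa] /= s
        f1[pa] /= s
    w0 = root_p0 * f0[0]
    w1 = (1.0 - root_p0) * f1[0]
    s = w0 + w1
    if s <= 0.0:
        return 1
    node_state[0] = 0 if np.random.random() * s < w0 else 1
    for v in range(1, n):
        p00, p01, p10, p11 = pij(q01, q10, blen[v])
        if node_state[parent[v]] == 0:
            w0 = p00 * f0[v]
            w1 = p01 * f1[v]
        else:
            w0 = p10 * f0[v]
            w1 = p11 * f1[v]
        s = w0 + w1
        if s <= 0.0:
            return 1
        node_state[v] = 0 if np.random.random() * s < w0 else 1
    return 0


@njit(cache=True, fastmath=True)
def forward_branch(a, t, q01, q10):
    """Unconditional piecewise-constant path from state ``a`` over time ``t``."""
    cap = 8
    states = np.empty(cap, np.int8)
    durs = np.empty(cap, np.float64)
    cur = np.int64(a)
    tt = 0.0
    nseg = 0
    done = False
    while not done:
        rate = q01 if cur == 0 else q10
        if rate <= 0.0:
            dt = (t - tt) + 1.0
        else:
            dt = np.random.exponential(1.0 / rate)
        if nseg == cap:
            cap = cap * 2
            s2 = np.empty(cap, np.int8)
            d2 = np.empty(cap, np.float64)
            s2[:nseg] = states[:nseg]
            d2[:nseg] = durs[:nseg]
            states = s2
            durs = d2
        if tt + dt >= t:
            states[nseg] = cur
            durs[nseg] = t - tt
            done = True
        else:
            states[nseg] = cur
            durs[nseg] = dt
            tt = tt + dt
            cur = 1 - cur
        nseg = nseg + 1
    return nseg, states, durs


@njit(cache=True, fastmath=True)
def bridge(a, b, t, q01, q10):
    """Endpoint-conditioned path via uniformization (rate 1.1 * max rate).

    Returns ``(nseg, states, durs)`` with collapsed real segments summing to
    ``t``; ``nseg = -1`` flags an impossible endpoint pair.
    """
    one = np.empty(1, np.int8)
    oned = np.empty(1, np.float64)
    if t <= 0.0:
        if a == b:
            one[0] = a
            oned[0] = t
            return 1, one, oned
        return -1, one, oned
    qs = q01 + q10
    if qs <= 0.0:
        if a != b:
            return -1, one, oned
        one[0] = a
        oned[0] = t
        return 1, one, oned
    mu = 1.1 * max(q01, q10)
    lam = 1.0 - qs / mu
    pi1 = q01 / qs
    pib = pi1 if b == 1 else 1.0 - pi1
    dab = 1.0 if a == b else 0.0
    pab = pib + (dab - pib) * np.exp(-qs * t)
    if pab <= 0.0:
        return -1, one, oned
    mt = mu * t
    if mt > 500.0:
        # Poisson-weight underflow territory: endpoints are near-stationary,
        # so forward simulation with endpoint rejection is efficient and exact.
        for _ in range(10000):
            nseg, st, du = forward_branch(a, t, q01, q10)
            if st[nseg - 1] == b:
                return nseg, st, du
        return -1, one, oned
    u = np.random.random() * pab
    w = np.exp(-mt)
    lamn = 1.0
    acc = 0.0
    nj = 0
    done = False
    while not done:
        acc = acc + w * (pib + (dab - pib) * lamn)
        if acc >= u or nj > 100000:
            done = True
        else:
            nj = nj + 1
            w = w * mt / nj
            lamn = lamn * lam
    if nj == 0:
        one[0] = a
        oned[0] = t
        return 1, one, oned
    times = np.sort(np.random.random(nj)) * t
    states = np.empty(nj + 1, np.int8)
    durs = np.empty(nj + 1, np.float64)
    r00 = 1.0 - q01 / mu
    r01 = q01 / mu
    r10 = q10 / mu
    r11 = 1.0 - q10 / mu
    d0b = 1.0 if b == 0 else 0.0
    d1b = 1.0 if b == 1 else 0.0
    cur = np.int64(a)
    seg_start = 0.0
    nseg = 0
    for i in range(nj):
        m = nj - i - 1
        lamm = lam ** m
        rm0b = pib + (d0b - pib) * lamm
        rm1b = pib + (d1b - pib) * lamm
        if cur == 0:
            w0 = r00 * rm0b
            w1 = r01 * rm1b
        else:
            w0 = r10 * rm0b
            w1 = r11 * rm1b
        nxt = np.int64(0) if np.random.random() * (w0 + w1) < w0 else np.int64(1)
        if nxt != cur:
            states[nseg] = cur
            durs[nseg] = times[i] - seg_start
            nseg += 1
            seg_start = times[i]
            cur = nxt
    states[nseg] = cur
    durs[nseg] = t - seg_start
    nseg += 1
    return nseg, states, durs


@njit(cache=True, fastmath=True)
def bridge_into(a, b, t, q01, q10, seg_state, seg_dur, pos, times_buf):
    """Allocation-free endpoint-conditioned path written at seg_*[pos:].

    Returns the number of segments, -1 for an impossible endpoint pair, or
    -2 when the caller's buffers are too small (caller grows and retries).
    """
    cap = seg_state.shape[0]
    if pos >= cap:
        return -2
    if t <= 0.0 or q01 + q10 <= 0.0:
        if a != b:
            return -1
        seg_state[pos] = a
        seg_dur[pos] = t
        return 1
    qs = q01 + q10
    mu = 1.1 * max(q01, q10)
    lam = 1.0 - qs / mu
    pi1 = q01 / qs
    pib = pi1 if b == 1 else 1.0 - pi1
    dab = 1.0 if a == b else 0.0
    pab = pib + (dab - pib) * np.exp(-qs * t)
    if pab <= 0.0:
        return -1
    mt = mu * t
    if mt > 500.0:
        # underflow regime: fall back to the allocating rejection sampler
        nseg, st, du = bridge(a, b, t, q01, q10)
        if nseg < 0:
            return -1
        if pos + nseg > cap:
            return -2
        for i in range(nseg):
            seg_state[pos + i] = st[i]
            seg_dur[pos + i] = du[i]
        return nseg
    u = np.random.random() * pab
    w = np.exp(-mt)
    lamn = 1.0
    acc = 0.0
    nj = 0
    done = False
    while not done:
        acc = acc + w * (pib + (dab - pib) * lamn)
        if acc >= u or nj > 100000:
            done = True
        else:
            nj = nj + 1
            w = w * mt / nj
            lamn = lamn * lam
    if nj == 0:
        seg_state[pos] = a
        seg_dur[pos] = t
        return 1
    if nj > times_buf.shape[0] or pos + nj + 1 > cap:
        return -2
    for i in range(nj):
        times_buf[i] = np.random.random() * t
    # insertion sort (nj is almost always tiny)
    for i in range(1, nj):
        key = times_buf[i]
        j = i - 1
        while j >= 0 and times_buf[j] > key:
            times_buf[j + 1] = times_buf[j]
            j -= 1
        times_buf[j + 1] = key
    r00 = 1.0 - q01 / mu
    r01 = q01 / mu
    r10 = q10 / mu
    r11 = 1.0 - q10 / mu
    d0b = 1.0 if b == 0 else 0.0
    d1b = 1.0 if b == 1 else 0.0
    cur = np.int64(a)
    seg_start = 0.0
    nseg = 0
    for i in range(nj):
        m = nj - i - 1
        lamm = lam ** m
        rm0b = pib + (d0b - pib) * lamm
        rm1b = pib + (d1b - pib) * lamm
        if cur == 0:
            w0 = r00 * rm0b
            w1 = r01 * rm1b
        else:
            w0 = r10 * rm0b
            w1 = r11 * rm1b
        nxt = np.int64(0) if np.random.random() * (w0 + w1) < w0 else np.int64(1)
        if nxt != cur:
            seg_state[pos + nseg] = cur
            seg_dur[pos + nseg] = times_buf[i] - seg_start
            nseg += 1
            seg_start = times_buf[i]
            cur = nxt
    seg_state[pos + nseg] = cur
    seg_dur[pos + nseg] = t - seg_start
    return nseg + 1


@njit(cache=True, fastmath=True)
def forward_branch_into(a, t, q01, q10, seg_state, seg_dur, pos):
    """Allocation-free unconditional path; -2 when the buffer is too small."""
    cap = seg_state.shape[0]
    cur = np.int64(a)
    tt = 0.0
    nseg = 0
    done = False
    while not done:
        rate = q01 if cur == 0 else q10
        if rate <= 0.0:
            dt = (t - tt) + 1.0
        else:
            dt = np.random.exponential(1.0 / rate)
        if pos + nseg >= cap:
            return -2
        if tt + dt >= t:
            seg_state[pos + nseg] = cur
            seg_dur[pos + nseg] = t - tt
            done = True
        else:
            seg_state[pos + nseg] = cur
            seg_dur[pos + nseg] = dt
            tt = tt + dt
            cur = 1 - cur
        nseg = nseg + 1
    return nseg


@njit(cache=True, fastmath=True)
def sample_history_into(parent, blen, is_tip, tip_state, q01, q10,
                        root_mode, root_p0_fixed, conditional,
                        node_state, f0, f1, dwell0, seg_ptr,
                        seg_state, seg_dur, times_buf):
    """Buffer-reusing history draw; returns (err, n_gains, n_losses).

    err: 0 ok, 1 unreachable tip configuration, 2 segment buffers too small.
    """
    n = parent.shape[0]
    qs = q01 + q10
    if root_mode == 0:
        root_p0 = q10 / qs if qs > 0.0 else 0.5
    else:
        root_p0 = root_p0_fixed
    ng = 0
    nl = 0
    if conditional == 1:
        err = sample_node_states(parent, blen, is_tip, tip_state, q01, q10,
                                 root_p0, node_state, f0, f1)
        if err != 0:
            return 1, ng, nl
    else:
        node_state[0] = 0 if np.random.random() < root_p0 else 1
    pos = 0
    seg_ptr[0] = 0
    seg_ptr[1] = 0
    for v in range(1, n):
        if conditional == 1:
            nseg = bridge_into(node_state[parent[v]], node_state[v], blen[v],
                               q01, q10, seg_state, seg_dur, pos, times_buf)
        else:
            nseg = forward_branch_into(node_state[parent[v]], blen[v], q01, q10,
                                       seg_state, seg_dur, pos)
            if nseg > 0:
                node_state[v] = seg_state[pos + nseg - 1]
        if nseg == -1:
            return 1, ng, nl
        if nseg == -2:
            return 2, ng, nl
        d0 = 0.0
        for i in range(nseg):
            if seg_state[pos + i] == 0:
                d0 += seg_dur[pos + i]
            if i > 0:
                if seg_state[pos + i] == 1:
                    ng += 1
                else:
                    nl += 1
        dwell0[v] = d0
        pos += nseg
        seg_ptr[v + 1] = pos
    return 0, ng, nl


# ---------------------------------------------------------------------------
# Contrasts (REML) likelihood
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def full_fold(parent, child_ptr, child_list, is_tip, v, x, Sinv, logdetS,
              xw, uw, contrib):
    """Pruning pass: fold tips toward the root, accumulating contrast densities.

    ``v`` holds the effective length of the branch above each node; ``x`` the
    (n_nodes, k) value array with tip rows filled.  ``xw``/``uw``/``contrib``
    are per-node work arrays (folded value, residual variance, log-density
    contribution) that stay valid for incremental path refolds.  Returns the
    REML log-likelihood (root marginalized); -inf when a zero-variance
    contrast carries a nonzero difference.
    """
    n = parent.shape[0]
    k = x.shape[1]
    if k == 1:
        total = 0.0
        s00 = Sinv[0, 0]
        for node in range(n - 1, -1, -1):
            if is_tip[node]:
                xw[node, 0] = x[node, 0]
                uw[node] = 0.0
                contrib[node] = 0.0
            else:
                lo = child_ptr[node]
                hi = child_ptr[node + 1]
                c0 = child_list[lo]
                cu = uw[c0] + v[c0]
                cx = xw[c0, 0]
                cc = 0.0
                for ci in range(lo + 1, hi):
                    c = child_list[ci]
                    ou = uw[c] + v[c]
                    V = cu + ou
                    d = xw[c, 0] - cx
                    if V <= 0.0:
                        if d != 0.0:
                            contrib[node] = -np.inf
                            return -np.inf
                    else:
                        cc += -0.5 * (LOG2PI + np.log(V) + logdetS + d * d * s00 / V)
                        cx += (cu / V) * d
                        cu = cu * ou / V
                xw[node, 0] = cx
                uw[node] = cu
                contrib[node] = cc
                total += cc
        return total
    total = 0.0
    for node in range(n - 1, -1, -1):
        if is_tip[node]:
            for j in range(k):
                xw[node, j] = x[node, j]
            uw[node] = 0.0
            contrib[node] = 0.0
        else:
            lo = child_ptr[node]
            hi = child_ptr[node + 1]
            c0 = child_list[lo]
            cu = uw[c0] + v[c0]
            for j in range(k):
                xw[node, j] = xw[c0, j]
            cc = 0.0
            for ci in range(lo + 1, hi):
                c = child_list[ci]
                ou = uw[c] + v[c]
                V = cu + ou
                q = 0.0
                for j1 in range(k):
                    d1 = xw[c, j1] - xw[node, j1]
                    for j2 in range(k):
                        q += d1 * Sinv[j1, j2] * (xw[c, j2] - xw[node, j2])
                if V <= 0.0:
                    if q > 0.0:
                        contrib[node] = -np.inf
                        return -np.inf
                    # identical values at zero variance: degenerate point mass
                else:
                    cc += -0.5 * (k * (LOG2PI + np.log(V)) + logdetS + q / V)
                    wnew = cu / V
                    for j in range(k):
                        xw[node, j] += wnew * (xw[c, j] - xw[node, j])
                    cu = cu * ou / V
            uw[node] = cu
            contrib[node] = cc
            total += cc
    return total


@njit(cache=True, fastmath=True)
def _fold_one(node, child_ptr, child_list, v, Sinv, logdetS, xw, uw, contrib):
    """Recompute the fold at a single internal node from its children."""
    k = xw.shape[1]
    if k == 1:
        lo = child_ptr[node]
        hi = child_ptr[node + 1]
        c0 = child_list[lo]
        cu = uw[c0] + v[c0]
        cx = xw[c0, 0]
        s00 = Sinv[0, 0]
        cc = 0.0
        for ci in range(lo + 1, hi):
            c = child_list[ci]
            ou = uw[c] + v[c]
            V = cu + ou
            d = xw[c, 0] - cx
            if V <= 0.0:
                if d != 0.0:
                    contrib[node] = -np.inf
                    return -np.inf
            else:
                cc += -0.5 * (LOG2PI + np.log(V) + logdetS + d * d * s00 / V)
                cx += (cu / V) * d
                cu = cu * ou / V
        xw[node, 0] = cx
        uw[node] = cu
        contrib[node] = cc
        return cc
    lo = child_ptr[node]
    hi = child_ptr[node + 1]
    c0 = child_list[lo]
    cu = uw[c0] + v[c0]
    for j in range(k):
        xw[node, j] = xw[c0, j]
    cc = 0.0
    for ci in range(lo + 1, hi):
        c = child_list[ci]
        ou = uw[c] + v[c]
        V = cu + ou
        q = 0.0
        for j1 in range(k):
            d1 = xw[c, j1] - xw[node, j1]
            for j2 in range(k):
                q += d1 * Sinv[j1, j2] * (xw[c, j2] - xw[node, j2])
        if V <= 0.0:
            if q > 0.0:
                contrib[node] = -np.inf
                return -np.inf
        else:
            cc += -0.5 * (k * (LOG2PI + np.log(V)) + logdetS + q / V)
            wnew = cu / V
            for j in range(k):
                xw[node, j] += wnew * (xw[c, j] - xw[node, j])
            cu = cu * ou / V
    uw[node] = cu
    contrib[node] = cc
    return cc


@njit(cache=True, fastmath=True)
def refold_path(node0, parent, child_ptr, child_list, v, Sinv, logdetS,
                xw, uw, contrib, path_nodes, old_x, old_u, old_c):
    """After changing v[node0], refold all ancestors; returns (delta_ll, n_path).

    Old values are stored so :func:`restore_path` can undo a rejected move.
    """
    k = xw.shape[1]
    delta = 0.0
    npath = 0
    p = parent[node0]
    while p >= 0:
        path_nodes[npath] = p
        for j in range(k):
            old_x[npath, j] = xw[p, j]
        old_u[npath] = uw[p]
        old_c[npath] = contrib[p]
        newc = _fold_one(p, child_ptr, child_list, v, Sinv, logdetS, xw, uw, contrib)
        npath += 1
        if newc == -np.inf:
            return -np.inf, npath
        delta += newc - old_c[npath - 1]
        p = parent[p]
    return delta, npath


@njit(cache=True, fastmath=True)
def restore_path(npath, path_nodes, xw, uw, contrib, old_x, old_u, old_c):
    k = xw.shape[1]
    for i in range(npath):
        p = path_nodes[i]
        for j in range(k):
            xw[p, j] = old_x[i, j]
        uw[p] = old_u[i]
        contrib[p] = old_c[i]


# ---------------------------------------------------------------------------
# Priors and history density (kernel-side copies of the model definitions)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def log_priors(sigma2, nu, q01, q10, z0, delta, beta, pr):
    """Joint log prior density.  pr = [sig_m, sig_s, nu_rate, alpha, p_dep, q_rate].

    sigma2 ~ lognormal(sig_m, sig_s); nu ~ Exp(nu_rate); beta_l | nu ~ i.i.d.
    lognormal(0, nu) (median 1); (zeta0/2) ~ Beta(alpha, alpha) when delta = 1;
    P(delta=1) = p_dep; q01, q10 ~ Exp(q_rate).
    """
    sig_m = pr[0]
    sig_s = pr[1]
    nu_rate = pr[2]
    alpha = pr[3]
    p_dep = pr[4]
    q_rate = pr[5]
    ls = np.log(sigma2)
    lp = -ls - 0.5 * (LOG2PI + 2.0 * np.log(sig_s)) - (ls - sig_m) ** 2 / (2.0 * sig_s ** 2)
    lp += np.log(nu_rate) - nu_rate * nu
    n = beta.shape[0]
    for i in range(1, n):
        lb = np.log(beta[i])
        lp += -lb - 0.5 * (LOG2PI + 2.0 * np.log(nu)) - lb * lb / (2.0 * nu * nu)
    lp += np.log(q_rate) - q_rate * q01 + np.log(q_rate) - q_rate * q10
    if delta == 1:
        w0 = z0 / 2.0
        lp += np.log(p_dep)
        lp += (math.lgamma(2.0 * alpha) - 2.0 * math.lgamma(alpha)
               + (alpha - 1.0) * (np.log(w0) + np.log(1.0 - w0)))
    else:
        lp += np.log(1.0 - p_dep)
    return lp


@njit(cache=True, fastmath=True)
def history_logdensity(ng, nl, t0, t1, root_state, q01, q10, root_mode, root_p0_fixed):
    """Log density of a full character history under the CTMC."""
    qs = q01 + q10
    if root_mode == 0:
        root_p0 = q10 / qs if qs > 0.0 else 0.5
    else:
        root_p0 = root_p0_fixed
    lp = -q01 * t0 - q10 * t1
    if ng > 0:
        lp += ng * np.log(q01)
    if nl > 0:
        lp += nl * np.log(q10)
    lp += np.log(root_p0) if root_state == 0 else np.log(1.0 - root_p0)
    return lp


# ---------------------------------------------------------------------------
# The reversible-jump sweep
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def run_chain_kernel(parent, blen, child_ptr, child_list, is_tip, tip_state,
                     x, Sinv, logdetS, pr, tune,
                     n_gen, burnin_gen, thin,
                     likelihood_on, conditional, root_mode, root_p0_fixed,
                     fix_q, fix_delta,
                     init, beta, out):
    """Run one rj-MCMC chain; fills ``out`` ((n_out, 12 + 2B) float64).

    One generation = full-history independence-MH move (stochastic-mapping
    proposal, trait-likelihood acceptance), scale moves on sigma2/nu/q01/q10,
    a per-branch beta sweep with incremental path refolds, a joint sigma2-beta
    rescale, a zeta simplex move (delta = 1 only) and the rj toggle on delta.

    Column layout per row: gen, log_post, log_lik, sigma2, nu, zeta0, zeta1,
    delta, q01, q10, n_gains, n_losses, beta[1..n-1], dwell1_frac[1..n-1].
    Returns 0 on success, 1 for an unreachable tip configuration, 2 for a
    non-finite likelihood at the initial state.
    """
    n = parent.shape[0]
    k = x.shape[1]
    nb = n - 1
    sigma2 = init[0]
    nu = init[1]
    q01 = init[2]
    q10 = init[3]
    z0 = init[4]
    z1 = init[5]
    delta = int(init[6])

    t_sig = tune[0]
    t_nu = tune[1]
    t_q = tune[2]
    t_beta = tune[3]
    t_joint = tune[4]
    z_win = tune[5]

    v = np.empty(n, np.float64)
    v_try = np.empty(n, np.float64)
    lbeta = np.zeros(n, np.float64)
    for j in range(1, n):
        lbeta[j] = np.log(beta[j])
    xw = np.empty((n, k), np.float64)
    uw = np.empty(n, np.float64)
    contrib = np.empty(n, np.float64)
    xw2 = np.empty((n, k), np.float64)
    uw2 = np.empty(n, np.float64)
    contrib2 = np.empty(n, np.float64)
    dwell0 = np.zeros(n, np.float64)
    path_nodes = np.empty(n, np.int64)
    old_x = np.empty((n, k), np.float64)
    old_u = np.empty(n, np.float64)
    old_c = np.empty(n, np.float64)

    node_state = np.zeros(n, np.int8)
    ns_try = np.zeros(n, np.int8)
    f0 = np.empty(n, np.float64)
    f1 = np.empty(n, np.float64)
    d0_try = np.zeros(n, np.float64)
    seg_ptr = np.zeros(n + 1, np.int64)
    seg_cap = 8 * n + 64
    seg_state = np.empty(seg_cap, np.int8)
    seg_dur = np.empty(seg_cap, np.float64)
    times_buf = np.empty(1024, np.float64)
    ng = 0
    nl = 0

    # initial history + likelihood
    err = 2
    g_ = 0
    l_ = 0
    while err == 2:
        err, g_, l_ = sample_history_into(
            parent, blen, is_tip, tip_state, q01, q10, root_mode, root_p0_fixed,
            conditional, ns_try, f0, f1, d0_try, seg_ptr, seg_state, seg_dur, times_buf)
        if err == 2:
            seg_cap *= 2
            seg_state = np.empty(seg_cap, np.int8)
            seg_dur = np.empty(seg_cap, np.float64)
    if err != 0:
        return 1
    node_state[:] = ns_try
    dwell0[:] = d0_try
    ng = g_
    nl = l_
    ze0 = z0 if delta == 1 else 1.0
    ze1 = z1 if delta == 1 else 1.0
    for j in range(1, n):
        v[j] = sigma2 * beta[j] * (dwell0[j] * ze0 + (blen[j] - dwell0[j]) * ze1)
    v[0] = 0.0
    if likelihood_on == 1:
        ll = full_fold(parent, child_ptr, child_list, is_tip, v, x, Sinv, logdetS,
                       xw, uw, contrib)
        if not np.isfinite(ll):
            return 2
    else:
        ll = 0.0

    n_out = out.shape[0]
    row = 0

    for gen in range(n_gen):
        # --- 1. full-history move (independence MH) ------------------------
        err = 2
        while err == 2:
            err, g_, l_ = sample_history_into(
                parent, blen, is_tip, tip_state, q01, q10, root_mode, root_p0_fixed,
                conditional, ns_try, f0, f1, d0_try, seg_ptr, seg_state, seg_dur,
                times_buf)
            if err == 2:
                seg_cap *= 2
                seg_state = np.empty(seg_cap, np.int8)
                seg_dur = np.empty(seg_cap, np.float64)
        if err != 0:
            return 1
        if likelihood_on == 1:
            ze0 = z0 if delta == 1 else 1.0
            ze1 = z1 if delta == 1 else 1.0
            for j in range(1, n):
                v_try[j] = sigma2 * beta[j] * (d0_try[j] * ze0 + (blen[j] - d0_try[j]) * ze1)
            v_try[0] = 0.0
            ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                               Sinv, logdetS, xw2, uw2, contrib2)
            accept = np.log(np.random.random()) < (ll_try - ll)
        else:
            accept = True
            ll_try = 0.0
        if accept:
            node_state[:] = ns_try
            dwell0[:] = d0_try
            ng = g_
            nl = l_
            if likelihood_on == 1:
                v, v_try = v_try, v
                xw, xw2 = xw2, xw
                uw, uw2 = uw2, uw
                contrib, contrib2 = contrib2, contrib
                ll = ll_try

        # --- 2. sigma2 scale move ------------------------------------------
        m = np.exp(t_sig * (np.random.random() - 0.5))
        s_new = sigma2 * m
        lpd = (-np.log(s_new) - (np.log(s_new) - pr[0]) ** 2 / (2.0 * pr[1] ** 2)) \
            - (-np.log(sigma2) - (np.log(sigma2) - pr[0]) ** 2 / (2.0 * pr[1] ** 2))
        if likelihood_on == 1:
            for j in range(1, n):
                v_try[j] = v[j] * m
            v_try[0] = 0.0
            ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                               Sinv, logdetS, xw2, uw2, contrib2)
            loga = (ll_try - ll) + lpd + np.log(m)
        else:
            ll_try = 0.0
            loga = lpd + np.log(m)
        if np.log(np.random.random()) < loga:
            sigma2 = s_new
            if likelihood_on == 1:
                v, v_try = v_try, v
                xw, xw2 = xw2, xw
                uw, uw2 = uw2, uw
                contrib, contrib2 = contrib2, contrib
                ll = ll_try

        # --- 3. nu scale move (beta hyperprior only) ------------------------
        m = np.exp(t_nu * (np.random.random() - 0.5))
        nu_new = nu * m
        s2sum = 0.0
        for j in range(1, n):
            s2sum += lbeta[j] * lbeta[j]
        lpd = (-nb * np.log(nu_new) - s2sum / (2.0 * nu_new * nu_new) - pr[2] * nu_new) \
            - (-nb * np.log(nu) - s2sum / (2.0 * nu * nu) - pr[2] * nu)
        if np.log(np.random.random()) < lpd + np.log(m):
            nu = nu_new

        # --- 4. CTMC rate moves --------------------------------------------
        if fix_q == 0:
            t0 = 0.0
            for j in range(1, n):
                t0 += dwell0[j]
            t1 = blen[1:].sum() - t0
            for which in range(2):
                m = np.exp(t_q * (np.random.random() - 0.5))
                if which == 0:
                    qn = q01 * m
                    lh_new = history_logdensity(ng, nl, t0, t1, node_state[0], qn, q10,
                                                root_mode, root_p0_fixed)
                    lh_old = history_logdensity(ng, nl, t0, t1, node_state[0], q01, q10,
                                                root_mode, root_p0_fixed)
                    loga = lh_new - lh_old - pr[5] * (qn - q01) + np.log(m)
                    if np.log(np.random.random()) < loga:
                        q01 = qn
                else:
                    qn = q10 * m
                    lh_new = history_logdensity(ng, nl, t0, t1, node_state[0], q01, qn,
                                                root_mode, root_p0_fixed)
                    lh_old = history_logdensity(ng, nl, t0, t1, node_state[0], q01, q10,
                                                root_mode, root_p0_fixed)
                    loga = lh_new - lh_old - pr[5] * (qn - q10) + np.log(m)
                    if np.log(np.random.random()) < loga:
                        q10 = qn

        # --- 5. per-branch beta moves --------------------------------------
        # full deterministic sweep on small trees; on large trees a random
        # scan of 128 branches per generation (exact, cheaper per generation)
        ze0 = z0 if delta == 1 else 1.0
        ze1 = z1 if delta == 1 else 1.0
        n_sweep = nb if nb <= 128 else 128
        for it in range(n_sweep):
            if nb <= 128:
                node = 1 + it
            else:
                node = 1 + np.int64(np.random.random() * nb)
            b_old = beta[node]
            lm = t_beta * (np.random.random() - 0.5)
            m = np.exp(lm)
            b_new = b_old * m
            lb_old = lbeta[node]
            lb_new = lb_old + lm
            lpd = (-lb_new - lb_new * lb_new / (2.0 * nu * nu)) \
                - (-lb_old - lb_old * lb_old / (2.0 * nu * nu))
            if likelihood_on == 1:
                v_old_node = v[node]
                v[node] = sigma2 * b_new * (dwell0[node] * ze0 + (blen[node] - dwell0[node]) * ze1)
                dll, npath = refold_path(node, parent, child_ptr, child_list, v,
                                         Sinv, logdetS, xw, uw, contrib,
                                         path_nodes, old_x, old_u, old_c)
                loga = dll + lpd + lm
                if np.log(np.random.random()) < loga:
                    beta[node] = b_new
                    lbeta[node] = lb_new
                    ll += dll
                else:
                    v[node] = v_old_node
                    restore_path(npath, path_nodes, xw, uw, contrib, old_x, old_u, old_c)
            else:
                if np.log(np.random.random()) < lpd + lm:
                    beta[node] = b_new
                    lbeta[node] = lb_new

        # --- 6. joint sigma2 / beta rescale (likelihood-invariant) ----------
        lm = t_joint * (np.random.random() - 0.5)
        m = np.exp(lm)
        s_new = sigma2 * m
        lpd = (-np.log(s_new) - (np.log(s_new) - pr[0]) ** 2 / (2.0 * pr[1] ** 2)) \
            - (-np.log(sigma2) - (np.log(sigma2) - pr[0]) ** 2 / (2.0 * pr[1] ** 2))
        for j in range(1, n):
            lb_old = lbeta[j]
            lb_new = lb_old - lm
            lpd += (-lb_new - lb_new * lb_new / (2.0 * nu * nu)) \
                - (-lb_old - lb_old * lb_old / (2.0 * nu * nu))
        loga = lpd + (1.0 - nb) * lm
        if np.log(np.random.random()) < loga:
            sigma2 = s_new
            for j in range(1, n):
                beta[j] /= m
                lbeta[j] -= lm
            # v unchanged: sigma2 * beta products are preserved

        # --- 6b. nu / beta shrink-expand: nu' = nu*m, log beta' = m*log beta.
        # In (nu, log beta) coordinates the lognormal terms cancel, leaving the
        # likelihood ratio, the Exp prior on nu, and the Jacobian log m.
        m = np.exp(t_nu * (np.random.random() - 0.5))
        nu_new = nu * m
        ze0 = z0 if delta == 1 else 1.0
        ze1 = z1 if delta == 1 else 1.0
        if likelihood_on == 1:
            for j in range(1, n):
                bnew = np.exp(m * lbeta[j])
                v_try[j] = sigma2 * bnew * (dwell0[j] * ze0 + (blen[j] - dwell0[j]) * ze1)
            v_try[0] = 0.0
            ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                               Sinv, logdetS, xw2, uw2, contrib2)
            loga = (ll_try - ll) - pr[2] * (nu_new - nu) + np.log(m)
        else:
            ll_try = 0.0
            loga = -pr[2] * (nu_new - nu) + np.log(m)
        if np.log(np.random.random()) < loga:
            nu = nu_new
            for j in range(1, n):
                lbeta[j] *= m
                beta[j] = np.exp(lbeta[j])
            if likelihood_on == 1:
                v, v_try = v_try, v
                xw, xw2 = xw2, xw
                uw, uw2 = uw2, uw
                contrib, contrib2 = contrib2, contrib
                ll = ll_try

        # --- 7. zeta simplex move (delta = 1 only) --------------------------
        if delta == 1:
            w0 = z0 / 2.0
            w0n = w0 + z_win * (np.random.random() - 0.5)
            while w0n <= 0.0 or w0n >= 1.0:
                if w0n <= 0.0:
                    w0n = -w0n
                if w0n >= 1.0:
                    w0n = 2.0 - w0n
            z0n = 2.0 * w0n
            z1n = 2.0 - z0n
            lpd = (pr[3] - 1.0) * (np.log(w0n) + np.log(1.0 - w0n)
                                   - np.log(w0) - np.log(1.0 - w0))
            if likelihood_on == 1:
                for j in range(1, n):
                    v_try[j] = sigma2 * beta[j] * (dwell0[j] * z0n + (blen[j] - dwell0[j]) * z1n)
                v_try[0] = 0.0
                ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                                   Sinv, logdetS, xw2, uw2, contrib2)
                loga = (ll_try - ll) + lpd
            else:
                ll_try = 0.0
                loga = lpd
            if np.log(np.random.random()) < loga:
                z0 = z0n
                z1 = z1n
                if likelihood_on == 1:
                    v, v_try = v_try, v
                    xw, xw2 = xw2, xw
                    uw, uw2 = uw2, uw
                    contrib, contrib2 = contrib2, contrib
                    ll = ll_try

        # --- 8. reversible-jump toggle --------------------------------------
        # attempted with probability 1/2: an always-accepted toggle (e.g.
        # likelihood off, even prior odds) would otherwise alternate delta
        # with period 2 and alias against any even thinning interval
        if fix_delta < 0 and np.random.random() < 0.5:
            if delta == 0:
                w0n = np.random.beta(pr[3], pr[3])
                z0n = 2.0 * w0n
                z1n = 2.0 - z0n
                prior_odds = np.log(pr[4]) - np.log(1.0 - pr[4])
                if likelihood_on == 1:
                    for j in range(1, n):
                        v_try[j] = sigma2 * beta[j] * (dwell0[j] * z0n + (blen[j] - dwell0[j]) * z1n)
                    v_try[0] = 0.0
                    ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                                       Sinv, logdetS, xw2, uw2, contrib2)
                    loga = (ll_try - ll) + prior_odds
                else:
                    ll_try = 0.0
                    loga = prior_odds
                if np.log(np.random.random()) < loga:
                    delta = 1
                    z0 = z0n
                    z1 = z1n
                    if likelihood_on == 1:
                        v, v_try = v_try, v
                        xw, xw2 = xw2, xw
                        uw, uw2 = uw2, uw
                        contrib, contrib2 = contrib2, contrib
                        ll = ll_try
            else:
                prior_odds = np.log(1.0 - pr[4]) - np.log(pr[4])
                if likelihood_on == 1:
                    for j in range(1, n):
                        v_try[j] = sigma2 * beta[j] * blen[j]
                    v_try[0] = 0.0
                    ll_try = full_fold(parent, child_ptr, child_list, is_tip, v_try, x,
                                       Sinv, logdetS, xw2, uw2, contrib2)
                    loga = (ll_try - ll) + prior_odds
                else:
                    ll_try = 0.0
                    loga = prior_odds
                if np.log(np.random.random()) < loga:
                    delta = 0
                    z0 = 1.0
                    z1 = 1.0
                    if likelihood_on == 1:
                        v, v_try = v_try, v
                        xw, xw2 = xw2, xw
                        uw, uw2 = uw2, uw
                        contrib, contrib2 = contrib2, contrib
                        ll = ll_try

        # --- 9. record -------------------------------------------------------
        g1 = gen + 1
        if g1 > burnin_gen and (g1 - burnin_gen) % thin == 0 and row < n_out:
            t0 = 0.0
            for j in range(1, n):
                t0 += dwell0[j]
            t1 = blen[1:].sum() - t0
            lp = ll + log_priors(sigma2, nu, q01, q10, z0, delta, beta, pr)
            lp += history_logdensity(ng, nl, t0, t1, node_state[0], q01, q10,
                                     root_mode, root_p0_fixed)
            out[row, 0] = g1
            out[row, 1] = lp
            out[row, 2] = ll
            out[row, 3] = sigma2
            out[row, 4] = nu
            out[row, 5] = z0
            out[row, 6] = z1
            out[row, 7] = delta
            out[row, 8] = q01
            out[row, 9] = q10
            out[row, 10] = ng
            out[row, 11] = nl
            for j in range(1, n):
                out[row, 11 + j] = beta[j]
                bl = blen[j]
                out[row, 11 + nb + j] = (bl - dwell0[j]) / bl if bl > 0 else 0.0
            row += 1
    return 0
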