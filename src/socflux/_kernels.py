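"""Compiled fixed-step RK4 kernels for the four decomposition models.

All kernels integrate the labeled/unlabeled pool system plus two cumulative
CO2 ledgers (one per isotope label) with a classical 4th-order Runge-Kutta
scheme on a fixed grid (default dt = 0.05 day) and linearly interpolate the
state onto the requested output times.  State layouts (mg C g^-1 soil):

    conventional (id 0): [lN, lL, lR, nN, nL, nR, co2_l, co2_n]
    interactive  (id 1): [lN, lO, nN, nO, co2_l, co2_n]
    michaelis    (id 2): [lN, lO, lB, nN, nO, nB, co2_l, co2_n]
    reverse mm   (id 3): [lN, lO, lB, nN, nO, nB, co2_l, co2_n]

`l` prefixes the isotope-labeled masses (the added substrate), `n` the
non-labeled (native soil) masses.  Every right-hand side conserves each label
separately: d(pools_l)/dt + d(co2_l)/dt = labeled input rate, and likewise
for the unlabeled side, so RK4 preserves mass balance to round-off.

A continuous input I(t) (piecewise-linear in time, knots `f_ts`/`f_rs`) is
routed to the new-C pool of one label selected by `lab_in`.
"""

import numpy as np
from numba import njit

CONVENTIONAL = 0
INTERACTIVE = 1
MICHAELIS = 2
REVERSE_MM = 3

STATE_SIZE = {CONVENTIONAL: 8, INTERACTIVE: 6, MICHAELIS: 8, REVERSE_MM: 8}


@njit(cache=False)
def _rate_at(t, f_ts, f_rs):
    """Piecewise-linear input rate, clamped to the end values outside knots."""
    n = f_ts.size
    if n == 0:
        return 0.0
    if t <= f_ts[0]:
        return f_rs[0]
    if t >= f_ts[n - 1]:
        return f_rs[n - 1]
    for i in range(1, n):
        if t <= f_ts[i]:
            w = (t - f_ts[i - 1]) / (f_ts[i] - f_ts[i - 1])
            return f_rs[i - 1] * (1.0 - w) + f_rs[i] * w
    return f_rs[n - 1]


@njit(cache=False)
def _rhs(model_id, p, y, t, f_ts, f_rs, lab_in, dy):
    rate = _rate_at(t, f_ts, f_rs)
    il = rate if lab_in == 1 else 0.0
    inn = rate if lab_in == 0 else 0.0
    if model_id == 0:
        # conventional first-order three-pool (new, labile, recalcitrant)
        K_N, K_L, K_R = p[0], p[1], p[2]
        a_LN, a_RN, a_LR, a_RL = p[3], p[4], p[5], p[6]
        lN, lL, lR, nN, nL, nR = y[0], y[1], y[2], y[3], y[4], y[5]
        dy[0] = il - K_N * lN
        dy[1] = K_N * lN * a_LN + K_R * lR * a_LR - K_L * lL
        dy[2] = K_N * lN * a_RN + K_L * lL * a_RL - K_R * lR
        dy[3] = inn - K_N * nN
        dy[4] = K_N * nN * a_LN + K_R * nR * a_LR - K_L * nL
        dy[5] = K_N * nN * a_RN + K_L * nL * a_RL - K_R * nR
        dy[6] = (K_N * lN * (1.0 - a_LN - a_RN) + K_L * lL * (1.0 - a_RL)
                 + K_R * lR * (1.0 - a_LR))
        dy[7] = (K_N * nN * (1.0 - a_LN - a_RN) + K_L * nL * (1.0 - a_RL)
                 + K_R * nR * (1.0 - a_LR))
    elif model_id == 1:
        # interactive two-pool: old-C decay rate K_O + K_p * N^p
        K_N, K_O, r, K_p, pw = p[0], p[1], p[2], p[3], p[4]
        lN, lO, nN, nO = y[0], y[1], y[2], y[3]
        Nt = lN + nN
        if Nt > 0.0:
            kO = K_O + K_p * Nt ** pw
        else:
            kO = K_O
        dy[0] = il - K_N * lN
        dy[1] = r * K_N * lN - kO * lO
        dy[2] = inn - K_N * nN
        dy[3] = r * K_N * nN - kO * nO
        dy[4] = (1.0 - r) * K_N * lN + kO * lO
        dy[5] = (1.0 - r) * K_N * nN + kO * nO
    elif model_id == 2:
        # forward Michaelis-Menten with explicit microbial biomass
        V_N, V_O, KmN, KmO, mu_B, eps = p[0], p[1], p[2], p[3], p[4], p[5]
        lN, lO, lB, nN, nO, nB = y[0], y[1], y[2], y[3], y[4], y[5]
        Nt = lN + nN
        Ot = lO + nO
        Bt = lB + nB
        sN = Bt * V_N / (Nt + KmN)    # specific uptake rate from new C
        sO = Bt * V_O / (Ot + KmO)
        UlN = sN * lN
        UnN = sN * nN
        UlO = sO * lO
        UnO = sO * nO
        dy[0] = il - UlN
        dy[1] = mu_B * lB - UlO
        dy[2] = -mu_B * lB + eps * (UlN + UlO)
        dy[3] = inn - UnN
        dy[4] = mu_B * nB - UnO
        dy[5] = -mu_B * nB + eps * (UnN + UnO)
        dy[6] = (1.0 - eps) * (UlN + UlO)
        dy[7] = (1.0 - eps) * (UnN + UnO)
    else:
        # reverse Michaelis-Menten: uptake saturates in biomass
        mu_N, mu_O, mu_B, K_B, eps = p[0], p[1], p[2], p[3], p[4]
        lN, lO, lB, nN, nO, nB = y[0], y[1], y[2], y[3], y[4], y[5]
        Bt = lB + nB
        g = Bt / (Bt + K_B)
        UlN = mu_N * lN * g
        UnN = mu_N * nN * g
        UlO = mu_O * lO * g
        UnO = mu_O * nO * g
        dy[0] = il - UlN
        dy[1] = mu_B * lB - UlO
        dy[2] = -mu_B * lB + eps * (UlN + UlO)
        dy[3] = inn - UnN
        dy[4] = mu_B * nB - UnO
        dy[5] = -mu_B * nB + eps * (UnN + UnO)
        dy[6] = (1.0 - eps) * (UlN + UlO)
        dy[7] = (1.0 - eps) * (UnN + UnO)


@njit(cache=False)
def integrate(model_id, p, y0, t0, t_out, dt, f_ts, f_rs, lab_in, out):
    """RK4 integration from t=t0 to t_out[-1]; fills `out` (len(t_out) x ns).

    Returns 0 on success, 1 if the state became non-finite or blew past
    1e12 (parameter set numerically divergent at this step size).
    """
    ns = y0.size
    y = y0.copy()
    yp = np.empty(ns)
    k1 = np.empty(ns)
    k2 = np.empty(ns)
    k3 = np.empty(ns)
    k4 = np.empty(ns)
    ytmp = np.empty(ns)
    nt = t_out.size
    idx = 0
    # outputs at (or numerically at) the segment start
    while idx < nt and t_out[idx] <= t0 + 1e-12:
        for j in range(ns):
            out[idx, j] = y[j]
        idx += 1
    t = t0
    t_end = t_out[nt - 1]
    while idx < nt:
        for j in range(ns):
            yp[j] = y[j]
        _rhs(model_id, p, y, t, f_ts, f_rs, lab_in, k1)
        for j in range(ns):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(model_id, p, ytmp, t + 0.5 * dt, f_ts, f_rs, lab_in, k2)
        for j in range(ns):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(model_id, p, ytmp, t + 0.5 * dt, f_ts, f_rs, lab_in, k3)
        for j in range(ns):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(model_id, p, ytmp, t + dt, f_ts, f_rs, lab_in, k4)
        ok = True
        for j in range(ns):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not np.isfinite(y[j]) or abs(y[j]) > 1e12:
                ok = False
        if not ok:
            return 1
        t += dt
        while idx < nt and t_out[idx] <= t + 1e-9:
            h = t_out[idx] - (t - dt)
            if h <= 1e-12:
                for j in range(ns):
                    out[idx, j] = yp[j]
            elif h >= dt - 1e-12:
                for j in range(ns):
                    out[idx, j] = y[j]
            else:
                # off-grid output: take one partial RK4 step from the
                # previous grid state (full order, no interpolation error)
                t0p = t - dt
                _rhs(model_id, p, yp, t0p, f_ts, f_rs, lab_in, k1)
                for j in range(ns):
                    ytmp[j] = yp[j] + 0.5 * h * k1[j]
                _rhs(model_id, p, ytmp, t0p + 0.5 * h, f_ts, f_rs, lab_in, k2)
                for j in range(ns):
                    ytmp[j] = yp[j] + 0.5 * h * k2[j]
                _rhs(model_id, p, ytmp, t0p + 0.5 * h, f_ts, f_rs, lab_in, k3)
                for j in range(ns):
                    ytmp[j] = yp[j] + h * k3[j]
                _rhs(model_id, p, ytmp, t0p + h, f_ts, f_rs, lab_in, k4)
                for j in range(ns):
                    out[idx, j] = yp[j] + (h / 6.0) * (
                        k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            idx += 1
        if t > t_end + dt:
            break
    return 0


_EMPTY = np.empty(0)


@njit(cache=False)
def _loglik_design(model_id, theta, ctl_sel, trt_sel, b_ctl, A_ctl, b_trt, A_trt,
                   t_union, dt, obs_sim, obs_col, obs_tidx, obs_z, obs_sd,
                   need_ctl):
    """Gaussian log-likelihood (up to a constant) of one study's cumulative
    CO2 series under parameter vector `theta`.

    The initial state is affine in theta (y0 = b + A theta, which encodes the
    initial-fraction parameters) and the kernel parameter vector is a
    selection of theta's coordinates.  Returns -inf for divergent runs.
    """
    nk = trt_sel.size
    ns = b_trt.size
    kp = np.empty(nk)
    for i in range(nk):
        kp[i] = theta[trt_sel[i]]
    y0 = np.empty(ns)
    for i in range(ns):
        acc = b_trt[i]
        for j in range(theta.size):
            acc += A_trt[i, j] * theta[j]
        y0[i] = acc
    buf_t = np.empty((t_union.size, ns))
    if integrate(model_id, kp, y0, 0.0, t_union, dt, _EMPTY, _EMPTY, 0, buf_t) != 0:
        return -np.inf
    buf_c = np.empty((1, 1))
    if need_ctl == 1:
        kpc = np.empty(ctl_sel.size)
        for i in range(ctl_sel.size):
            kpc[i] = theta[ctl_sel[i]]
        y0c = np.empty(ns)
        for i in range(ns):
            acc = b_ctl[i]
            for j in range(theta.size):
                acc += A_ctl[i, j] * theta[j]
            y0c[i] = acc
        buf_c = np.empty((t_union.size, ns))
        if integrate(model_id, kpc, y0c, 0.0, t_union, dt, _EMPTY, _EMPTY, 0,
                     buf_c) != 0:
            return -np.inf
    ll = 0.0
    for i in range(obs_z.size):
        if obs_sim[i] == 1:
            x = buf_t[obs_tidx[i], obs_col[i]]
        else:
            x = buf_c[obs_tidx[i], obs_col[i]]
        r = obs_z[i] - x
        ll -= r * r / (2.0 * obs_sd[i] * obs_sd[i])
    return ll


@njit(cache=False)
def _cholesky_lower(C, L):
    """Manual Cholesky of a small SPD matrix; returns 0 on success, 1 on
    failure (not positive definite).  Fills lower-triangular L."""
    k = C.shape[0]
    for i in range(k):
        for j in range(k):
            L[i, j] = 0.0
    for i in range(k):
        for j in range(i + 1):
            s = C[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0:
                    return 1
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return 0


@njit(cache=False)
def run_chain(model_id, lo, hi, cons, ctl_sel, trt_sel, b_ctl, A_ctl,
              b_trt, A_trt, t_union, dt, obs_sim, obs_col, obs_tidx,
              obs_z, obs_sd, need_ctl, S, burn, adapt_interval, w0,
              t_anneal, seed, theta0):
    """Adaptive Metropolis chain with annealed burn-in.

    Proposals are multivariate Gaussian steps scale * L z (z standard
    normal), reflected into the prior box [lo, hi].  During the first `burn`
    iterations only: (i) the acceptance temperature is annealed from
    `t_anneal` down to 1 so the walk can cross between likelihood basins,
    (ii) every `adapt_interval` iterations L is refreshed from the windowed
    sample covariance (jittered; kept if not positive definite) and the
    global scale is halved / doubled to hold the windowed acceptance rate
    inside [0.2, 0.5].  Everything is frozen after burn-in, so the retained
    chain is a valid Metropolis sample of the posterior.  Rows of `cons`
    are joint constraints theta[i] + theta[j] <= 1 (zero prior mass
    outside).  Returns (chain S x k, log-likelihoods, accepted count,
    effective per-parameter step widths scale * ||L_j||).
    """
    np.random.seed(seed)
    k = lo.size
    chain = np.empty((S, k))
    lls = np.empty(S)
    theta = theta0.copy()
    ll = _loglik_design(model_id, theta, ctl_sel, trt_sel, b_ctl, A_ctl,
                        b_trt, A_trt, t_union, dt, obs_sim, obs_col,
                        obs_tidx, obs_z, obs_sd, need_ctl)
    tries = 0
    while (not np.isfinite(ll)) and tries < 1000:
        for j in range(k):
            theta[j] = lo[j] + (hi[j] - lo[j]) * np.random.random()
        ok = True
        for c in range(cons.shape[0]):
            if theta[cons[c, 0]] + theta[cons[c, 1]] > 1.0:
                ok = False
        if ok:
            ll = _loglik_design(model_id, theta, ctl_sel, trt_sel, b_ctl,
                                A_ctl, b_trt, A_trt, t_union, dt, obs_sim,
                                obs_col, obs_tidx, obs_z, obs_sd, need_ctl)
        tries += 1
    L = np.zeros((k, k))
    for j in range(k):
        L[j, j] = w0[j]
    Lnew = np.empty((k, k))
    C = np.empty((k, k))
    mu = np.empty(k)
    scale = 1.0
    nacc = 0
    win_acc = 0
    prop = np.empty(k)
    z = np.empty(k)
    for s in range(S):
        if s < burn and burn > 0 and t_anneal > 1.0:
            temp = t_anneal ** (1.0 - s / burn)
        else:
            temp = 1.0
        for j in range(k):
            z[j] = np.random.standard_normal()
        for j in range(k):
            step = 0.0
            for m in range(j + 1):
                step += L[j, m] * z[m]
            v = theta[j] + scale * step
            if hi[j] > lo[j]:
                # mirror the step back into the box (symmetric proposal)
                span = hi[j] - lo[j]
                while v < lo[j] or v > hi[j]:
                    if v < lo[j]:
                        v = 2.0 * lo[j] - v
                    if v > hi[j]:
                        v = 2.0 * hi[j] - v
            else:
                v = lo[j]
            prop[j] = v
        ok = True
        for c in range(cons.shape[0]):
            if prop[cons[c, 0]] + prop[cons[c, 1]] > 1.0:
                ok = False
        if ok:
            llp = _loglik_design(model_id, prop, ctl_sel, trt_sel, b_ctl,
                                 A_ctl, b_trt, A_trt, t_union, dt, obs_sim,
                                 obs_col, obs_tidx, obs_z, obs_sd, need_ctl)
            if np.isfinite(llp) and np.log(np.random.random()) < (llp - ll) / temp:
                for j in range(k):
                    theta[j] = prop[j]
                ll = llp
                nacc += 1
                win_acc += 1
        for j in range(k):
            chain[s, j] = theta[j]
        lls[s] = ll
        if s < burn and adapt_interval > 0 and (s + 1) % adapt_interval == 0:
            rate = win_acc / adapt_interval
            if rate < 0.02:
                scale = max(scale * 0.25, 1e-9)  # essentially stuck: cut hard
            elif rate < 0.2:
                scale = max(scale * 0.5, 1e-9)
            elif rate > 0.5:
                scale = min(scale * 2.0, 1e6)
            if rate >= 0.1:
                # covariance over the accumulated burn-in history (first
                # quarter dropped as transient); a single window would
                # underestimate the posterior spread and freeze tiny steps
                i0 = (s + 1) // 4
                nh = s + 1 - i0
                for a in range(k):
                    m = 0.0
                    for i in range(i0, s + 1):
                        m += chain[i, a]
                    mu[a] = m / nh
                for a in range(k):
                    for b in range(a, k):
                        cv = 0.0
                        for i in range(i0, s + 1):
                            cv += (chain[i, a] - mu[a]) * (chain[i, b] - mu[b])
                        cv /= nh
                        C[a, b] = cv
                        C[b, a] = cv
                for a in range(k):
                    span = hi[a] - lo[a]
                    jit = (1e-9 * span) ** 2 if span > 0 else 1e-30
                    C[a, a] += jit
                if _cholesky_lower(C, Lnew) == 0:
                    opt = 2.38 / np.sqrt(k)
                    for a in range(k):
                        for b in range(k):
                            L[a, b] = opt * Lnew[a, b]
                    # the 2.38/sqrt(k) factor already targets ~0.23
                    # acceptance; the old scale belonged to the previous L
                    scale = 1.0
            win_acc = 0
    weff = np.empty(k)
    for j in range(k):
        s2 = 0.0
        for m in range(k):
            s2 += L[j, m] * L[j, m]
        weff[j] = scale * np.sqrt(s2)
    return chain, lls, nacc, weff
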