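"""Numba inner loops for the stochastic simulators.

All kernels seed numba's per-thread RNG themselves, so identical seeds give
bit-identical trajectories.  They work in molecule counts internally (SSA)
or concentrations (SDE/PDMP) and sample onto a uniform grid by zero-order
hold (piecewise-constant jump processes) or exact grid landing (continuous
paths).  Infinite noise scales are passed as boolean mode flags, never as
large floats.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _off_rate(n_P: float, omega_P0: float, h: float, lam: float) -> float:
    # promoter ON->OFF propensity lam * (P / P0)^h, P in concentration units
    x = n_P / omega_P0
    if x <= 0.0:
        return 0.0
    return lam * np.exp(h * np.log(x))


@njit(cache=True)
def ssa_full(
    alpha_M, alpha_P, mu_M, mu_P, h, P0, tau,
    omega, bursting, lam,
    T, sample_dt, seed,
    nM0, nP0, sigma0,
    queue_cap,
):
    """Delayed SSA for the full feedback model (or its fast-bursting limit).

    Returns (M_counts, P_counts, sigma, n_initiated, n_delivered,
    queue_residue, status).  status: 0 ok, 1 delay-queue overflow.
    """
    np.random.seed(seed)
    n_samp = int(np.floor(T / sample_dt + 1e-9)) + 1
    M_out = np.empty(n_samp)
    P_out = np.empty(n_samp)
    s_out = np.empty(n_samp)

    queue = np.empty(queue_cap)
    q_head = 0
    q_tail = 0
    q_count = 0
    n_init = 0
    n_deliv = 0

    nM = float(nM0)
    nP = float(nP0)
    sigma = float(sigma0)
    t = 0.0
    s_idx = 0
    omega_P0 = omega * P0
    status = 0

    while True:
        # propensities (molecule units)
        if bursting:
            a_tx = alpha_M * omega * sigma
            if sigma > 0.5:
                a_sw = _off_rate(nP, omega_P0, h, lam)
            else:
                a_sw = lam
        else:
            x = nP / omega_P0
            f = 1.0 / (1.0 + np.exp(h * np.log(x))) if x > 0.0 else 1.0
            a_tx = alpha_M * omega * f
            a_sw = 0.0
        a_dM = mu_M * nM
        a_tl = alpha_P * nM
        a_dP = mu_P * nP
        a0 = a_tx + a_dM + a_tl + a_dP + a_sw

        if a0 > 0.0:
            t_next = t + np.random.exponential(1.0 / a0)
        else:
            t_next = np.inf

        from_queue = False
        if q_count > 0 and queue[q_head] <= t_next:
            t_new = queue[q_head]
            from_queue = True
        else:
            t_new = t_next

        # zero-order hold onto the sample grid up to (not including) t_new
        while s_idx < n_samp and s_idx * sample_dt < t_new:
            M_out[s_idx] = nM
            P_out[s_idx] = nP
            s_out[s_idx] = sigma
            s_idx += 1
        if t_new > T:
            break

        if from_queue:
            # scheduled mRNA arrival; exponential clock redrawn next loop
            q_head = (q_head + 1) % queue_cap
            q_count -= 1
            nM += 1.0
            n_deliv += 1
            t = t_new
            continue

        r = np.random.random() * a0
        if r < a_tx:
            if tau > 0.0:
                if q_count >= queue_cap:
                    status = 1
                    break
                queue[q_tail] = t_new + tau
                q_tail = (q_tail + 1) % queue_cap
                q_count += 1
                n_init += 1
            else:
                nM += 1.0
                n_init += 1
                n_deliv += 1
        elif r < a_tx + a_dM:
            nM -= 1.0
        elif r < a_tx + a_dM + a_tl:
            nP += 1.0
        elif r < a_tx + a_dM + a_tl + a_dP:
            nP -= 1.0
        else:
            sigma = 1.0 - sigma
        t = t_new

    # fill any remaining grid points (process ran past T or went silent)
    while s_idx < n_samp:
        M_out[s_idx] = nM
        P_out[s_idx] = nP
        s_out[s_idx] = sigma
        s_idx += 1

    return M_out, P_out, s_out, n_init, n_deliv, q_count, status


@njit(cache=True)
def ssa_toggle(
    alpha, mu, h, P0, omega, lam,
    T, sample_dt, seed,
    nA0, nB0, sA0, sB0,
):
    """Gillespie simulation of the two-gene telegraph toggle switch."""
    np.random.seed(seed)
    n_samp = int(np.floor(T / sample_dt + 1e-9)) + 1
    A_out = np.empty(n_samp)
    B_out = np.empty(n_samp)
    sA_out = np.empty(n_samp)
    sB_out = np.empty(n_samp)

    nA = float(nA0)
    nB = float(nB0)
    sA = float(sA0)
    sB = float(sB0)
    t = 0.0
    s_idx = 0
    omega_P0 = omega * P0

    while True:
        a1 = alpha * omega * sA          # produce A
        a2 = alpha * omega * sB          # produce B
        a3 = mu * nA                     # degrade A
        a4 = mu * nB                     # degrade B
        a5 = _off_rate(nB, omega_P0, h, lam) if sA > 0.5 else 0.0
        a6 = lam * (1.0 - sA)
        a7 = _off_rate(nA, omega_P0, h, lam) if sB > 0.5 else 0.0
        a8 = lam * (1.0 - sB)
        a0 = a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8

        t_new = t + np.random.exponential(1.0 / a0) if a0 > 0.0 else np.inf

        while s_idx < n_samp and s_idx * sample_dt < t_new:
            A_out[s_idx] = nA
            B_out[s_idx] = nB
            sA_out[s_idx] = sA
            sB_out[s_idx] = sB
            s_idx += 1
        if t_new > T:
            break

        r = np.random.random() * a0
        if r < a1:
            nA += 1.0
        elif r < a1 + a2:
            nB += 1.0
        elif r < a1 + a2 + a3:
            nA -= 1.0
        elif r < a1 + a2 + a3 + a4:
            nB -= 1.0
        elif r < a1 + a2 + a3 + a4 + a5:
            sA = 0.0
        elif r < a1 + a2 + a3 + a4 + a5 + a6:
            sA = 1.0
        elif r < a1 + a2 + a3 + a4 + a5 + a6 + a7:
            sB = 0.0
        else:
            sB = 1.0
        t = t_new

    while s_idx < n_samp:
        A_out[s_idx] = nA
        B_out[s_idx] = nB
        sA_out[s_idx] = sA
        sB_out[s_idx] = sB
        s_idx += 1

    return A_out, B_out, sA_out, sB_out


@njit(cache=True)
def _hill(P, P0, h):
    x = P / P0
    if x <= 0.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(h * np.log(x)))


@njit(cache=True)
def _burst_var(P, P0, h, scale):
    # 2 x^h / (1 + x^h)^3 * scale, evaluated stably for large x^h
    x = P / P0
    if x <= 0.0:
        return 0.0
    xh = np.exp(h * np.log(x))
    if xh > 1e100:
        return 0.0
    return scale * 2.0 * xh / (1.0 + xh) ** 3


@njit(cache=True)
def cle_feedback(
    alpha_M, alpha_P, mu_M, mu_P, h, P0, tau,
    copy_noise, omega, bursting, lam,
    T, dt, seed,
    M0, Pinit, history_fill,
    stride, drift_alpha_m,
):
    """Euler-Maruyama integration of the extended chemical Langevin equation.

    Returns (M_samples, P_samples, status); status 1 flags a NaN state with
    the offending step index in place of further samples.
    """
    np.random.seed(seed)
    lag = int(round(tau / dt))
    depth = lag if lag > 0 else 1
    hist = np.empty(depth)
    for i in range(depth):
        hist[i] = history_fill
    widx = 0

    n_steps = int(round(T / dt))
    n_samp = n_steps // stride + 1
    M_out = np.empty(n_samp)
    P_out = np.empty(n_samp)

    M = M0
    P = Pinit
    M_out[0] = M
    P_out[0] = P
    s_idx = 1
    status = 0
    amp_drift = alpha_M if drift_alpha_m else 1.0
    burst_scale = alpha_M * alpha_M / lam if bursting else 0.0

    for step in range(n_steps):
        if lag > 0:
            Pd = hist[widx]  # value written lag steps ago
        else:
            Pd = P
        f = _hill(Pd, P0, h)
        var_M = 0.0
        if bursting:
            var_M += _burst_var(Pd, P0, h, burst_scale)
        if copy_noise:
            var_M += (alpha_M * f + mu_M * M) / omega
        drift_M = amp_drift * f - mu_M * M
        drift_P = alpha_P * M - mu_P * P
        var_P = (alpha_P * M + mu_P * P) / omega if copy_noise else 0.0

        zM = np.random.normal()
        zP = np.random.normal()
        M_new = M + drift_M * dt + np.sqrt(var_M * dt) * zM
        P_new = P + drift_P * dt + np.sqrt(var_P * dt) * zP
        if M_new < 0.0:
            M_new = 0.0
        if P_new < 0.0:
            P_new = 0.0
        if np.isnan(M_new) or np.isnan(P_new):
            status = 1
            break
        if lag > 0:
            hist[widx] = P  # store pre-update value at time t
            widx += 1
            if widx == depth:
                widx = 0
        M = M_new
        P = P_new
        if (step + 1) % stride == 0:
            M_out[s_idx] = M
            P_out[s_idx] = P
            s_idx += 1

    return M_out, P_out, status


@njit(cache=True)
def lna_feedback(
    aM_fprime, alpha_P, mu_M, mu_P, tau,
    sig_M, sig_P,
    T, dt, seed, m0, p0, stride,
):
    """Euler-Maruyama for the linear-noise fluctuation equations."""
    np.random.seed(seed)
    lag = int(round(tau / dt))
    depth = lag if lag > 0 else 1
    hist = np.zeros(depth)
    for i in range(depth):
        hist[i] = p0
    widx = 0

    n_steps = int(round(T / dt))
    n_samp = n_steps // stride + 1
    m_out = np.empty(n_samp)
    p_out = np.empty(n_samp)
    m = m0
    p = p0
    m_out[0] = m
    p_out[0] = p
    s_idx = 1
    sq_M = sig_M * np.sqrt(dt)
    sq_P = sig_P * np.sqrt(dt)

    for step in range(n_steps):
        pd = hist[widx] if lag > 0 else p
        dm = (aM_fprime * pd - mu_M * m) * dt + sq_M * np.random.normal()
        dp = (alpha_P * m - mu_P * p) * dt + sq_P * np.random.normal()
        if lag > 0:
            hist[widx] = p
            widx += 1
            if widx == depth:
                widx = 0
        m += dm
        p += dp
        if (step + 1) % stride == 0:
            m_out[s_idx] = m
            p_out[s_idx] = p
            s_idx += 1

    return m_out, p_out


@njit(cache=True)
def cle_toggle(
    alpha, mu, h, P0,
    copy_noise, omega, bursting, lam,
    T, dt, seed, A0, B0, stride,
):
    """Euler-Maruyama for the toggle-switch chemical Langevin equations."""
    np.random.seed(seed)
    n_steps = int(round(T / dt))
    n_samp = n_steps // stride + 1
    A_out = np.empty(n_samp)
    B_out = np.empty(n_samp)
    A = A0
    B = B0
    A_out[0] = A
    B_out[0] = B
    s_idx = 1
    burst_scale = alpha * alpha / lam if bursting else 0.0
    status = 0

    for step in range(n_steps):
        fB = _hill(B, P0, h)
        fA = _hill(A, P0, h)
        var_A = 0.0
        var_B = 0.0
        if bursting:
            var_A += _burst_var(B, P0, h, burst_scale)
            var_B += _burst_var(A, P0, h, burst_scale)
        if copy_noise:
            var_A += (alpha * fB + mu * A) / omega
            var_B += (alpha * fA + mu * B) / omega
        A_new = A + (alpha * fB - mu * A) * dt + np.sqrt(var_A * dt) * np.random.normal()
        B_new = B + (alpha * fA - mu * B) * dt + np.sqrt(var_B * dt) * np.random.normal()
        if A_new < 0.0:
            A_new = 0.0
        if B_new < 0.0:
            B_new = 0.0
        if np.isnan(A_new) or np.isnan(B_new):
            status = 1
            break
        A = A_new
        B = B_new
        if (step + 1) % stride == 0:
            A_out[s_idx] = A
            B_out[s_idx] = B
            s_idx += 1

    return A_out, B_out, status


@njit(cache=True)
def _heun_cascade(M, P, u, alpha_P, mu_M, mu_P, hstep):
    # one Heun step of dM = u - mu_M M, dP = alpha_P M - mu_P P
    dM0 = u - mu_M * M
    dP0 = alpha_P * M - mu_P * P
    Mp = M + hstep * dM0
    Pp = P + hstep * dP0
    dM1 = u - mu_M * Mp
    dP1 = alpha_P * Mp - mu_P * Pp
    return M + 0.5 * hstep * (dM0 + dM1), P + 0.5 * hstep * (dP0 + dP1)


@njit(cache=True)
def pdmp_feedback(
    alpha_M, alpha_P, mu_M, mu_P, h, P0, tau, lam,
    T, sample_dt, dt_int, seed,
    M0, Pinit, sigma0,
    max_switches,
):
    """Piecewise-deterministic process: Heun ODE flow + stochastic switching.

    The ON->OFF hazard lam*(P/P0)^h is accumulated by the trapezoid rule on
    the integration grid and the crossing time located by linear
    interpolation within the step; OFF->ON dwell times are exponential(lam).
    Returns (M, P, sigma samples, switch_times, n_switches, status);
    status 1 = switch-history overflow.
    """
    np.random.seed(seed)
    stride = int(round(sample_dt / dt_int))
    n_samp = int(np.floor(T / sample_dt + 1e-9)) + 1
    n_micro = (n_samp - 1) * stride
    M_out = np.empty(n_samp)
    P_out = np.empty(n_samp)
    s_out = np.empty(n_samp)

    sw_times = np.empty(max_switches)
    n_sw = 0
    status = 0

    M = M0
    P = Pinit
    sigma = float(sigma0)
    t = 0.0
    M_out[0] = M
    P_out[0] = P
    s_out[0] = sigma
    s_idx = 1

    d_idx = 0  # switches with time <= t - tau
    # hazard bookkeeping for the current ON period
    E = np.random.exponential(1.0) if sigma > 0.5 else 0.0
    H = 0.0
    t_on = t + np.random.exponential(1.0 / lam) if sigma < 0.5 else np.inf

    eps = 1e-9  # progress guard, min; far below any dynamical timescale
    for i_micro in range(n_micro):
        t_end = (i_micro + 1) * dt_int
        while t < t_end - eps:
            # process a due OFF->ON switch
            if sigma < 0.5 and t_on <= t + eps:
                sigma = 1.0
                if n_sw >= max_switches:
                    status = 1
                    break
                t_rec = t_on
                if n_sw > 0 and t_rec <= sw_times[n_sw - 1]:
                    t_rec = sw_times[n_sw - 1] + eps
                sw_times[n_sw] = t_rec
                n_sw += 1
                E = np.random.exponential(1.0)
                H = 0.0
                t_on = np.inf
                continue

            # delayed promoter state driving transcription
            while d_idx < n_sw and sw_times[d_idx] + tau <= t + eps:
                d_idx += 1
            if d_idx % 2 == 0:
                sigma_d = float(sigma0)
            else:
                sigma_d = 1.0 - float(sigma0)
            u = alpha_M * sigma_d

            # substep boundary: micro grid, delayed switch, scheduled ON time
            t_sub = t_end
            if d_idx < n_sw and sw_times[d_idx] + tau < t_sub:
                t_sub = sw_times[d_idx] + tau
            if sigma < 0.5 and t_on < t_sub:
                t_sub = t_on
            if t_sub < t + eps:
                t_sub = t + eps

            hstep = t_sub - t
            M1, P1 = _heun_cascade(M, P, u, alpha_P, mu_M, mu_P, hstep)

            if sigma > 0.5:
                r0 = _off_rate(P, P0, h, lam)
                r1 = _off_rate(P1, P0, h, lam)
                dH = 0.5 * hstep * (r0 + r1)
                if H + dH >= E and dH > 0.0:
                    theta = (E - H) / dH
                    if theta < 0.0:
                        theta = 0.0
                    if theta > 1.0:
                        theta = 1.0
                    t_sw = t + theta * hstep
                    if t_sw < t + eps:
                        t_sw = t + eps
                    M, P = _heun_cascade(M, P, u, alpha_P, mu_M, mu_P, t_sw - t)
                    t = t_sw
                    sigma = 0.0
                    if n_sw >= max_switches:
                        status = 1
                        break
                    if n_sw > 0 and t_sw <= sw_times[n_sw - 1]:
                        t_sw = sw_times[n_sw - 1] + eps
                    sw_times[n_sw] = t_sw
                    n_sw += 1
                    t_on = t_sw + np.random.exponential(1.0 / lam)
                    continue
                H += dH

            M, P = M1, P1
            t = t_sub
        if status != 0:
            break
        t = t_end  # suppress float drift
        if (i_micro + 1) % stride == 0:
            M_out[s_idx] = M
            P_out[s_idx] = P
            s_out[s_idx] = sigma
            s_idx += 1

    while s_idx < n_samp:
        M_out[s_idx] = M
        P_out[s_idx] = P
        s_out[s_idx] = sigma
        s_idx += 1

    return M_out, P_out, s_out, sw_times[:n_sw].copy(), n_sw, status
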