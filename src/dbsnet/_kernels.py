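"""Numba-compiled inner loops for the network integrators.

These kernels mirror the reference implementations in :mod:`dbsnet.neurons`
and :mod:`dbsnet.topology` exactly (the test suite checks step-for-step
equivalence against the scalar code); they exist only so that multi-second
populations integrate in seconds.  All state is passed in flat arrays and all
parameters as scalars; nothing here owns configuration.

Error handling: the kernels return a status tuple ``(code, step, neuron)``
with code 0 on success and 1 on a non-finite state, so the engine can raise
a diagnostic without numba string formatting.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ml_network", "izh_network", "izh_two_populations"]


@njit(cache=True)
def _pulse(t, amp_pos, amp_neg, t_pos, t_neg, period):
    ph = t % period
    if ph < t_pos:
        return amp_pos
    if ph < t_pos + t_neg:
        return amp_neg
    return 0.0


@njit(cache=True)
def _ml_rhs(
    v, w, islow, s, v_del, i_syn_ext, noise_col, stim_t, stim_prof, slow_prof,
    g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi, v_star, alpha, s1,
    eps, syn_pref, v_rev, w_mat,
    alpha_s, beta_s, theta_s, sigma_s,
    dv, dw, dislow, ds,
):
    n = v.shape[0]
    ws = w_mat @ s
    for j in range(n):
        m_inf = 0.5 * (1.0 + np.tanh((v[j] - v1) / v2))
        w_inf = 0.5 * (1.0 + np.tanh((v[j] - v3) / v4))
        # clamp the cosh argument so a diverging trajectory reaches the
        # engine's non-finite diagnostic instead of dividing by zero here
        arg = (v[j] - v3) / (2.0 * v4)
        arg = min(max(arg, -300.0), 300.0)
        tau_w = 1.0 / np.cosh(arg)
        i_ion = (
            -g_ca * m_inf * (v[j] - v_ca)
            - g_k * w[j] * (v[j] - v_k)
            - g_l * (v[j] - v_l)
        )
        i_syn = syn_pref * ws[j] * (v[j] - v_rev) + i_syn_ext[j]
        dv[j] = (
            i_ion + islow[j] + i_syn + noise_col[j] + s1 * stim_t * stim_prof[j]
        ) / cap
        dw[j] = phi * (w_inf - w[j]) / tau_w
        # afferent-inhibition pathway: |stimulation current| hyperpolarizes
        # through the slow (GPe-feedback) current; slow_prof is zero when the
        # pathway is disabled
        dislow[j] = (
            eps[j] * (v_star - v_del[j] - alpha * islow[j])
            - slow_prof[j] * abs(stim_t)
        )
        h = 1.0 / (1.0 + np.exp(-(v[j] - theta_s) / sigma_s))
        ds[j] = alpha_s * h * (1.0 - s[j]) - beta_s * s[j]


@njit(cache=True)
def ml_network(
    v, w, islow, s, eps, w_mat,
    syn_pref, v_rev,
    stim_prof, slow_prof, amp_pos, amp_neg, t_pos, t_neg, period, t_on, t_off,
    noise, noise_stride,
    g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi, v_star, alpha, s1,
    alpha_s, beta_s, theta_s, sigma_s,
    dt, n_steps, delay_steps, rec_stride,
    v_rec, iion_rec,
):
    """RK4 integration of the delayed Morris-Lecar lattice.

    The delayed membrane potential uses a per-neuron ring-buffer history
    (constant initial history), linearly interpolated at the RK4 midpoint.
    Records v and the total non-stimulation current every ``rec_stride``
    steps.  With ``delay_steps == 0`` the delayed term reads the running
    stage value, so the delayed and instantaneous formulations coincide.
    """
    n = v.shape[0]
    buf_len = delay_steps + 2
    hist = np.empty((buf_len, n))
    for i in range(buf_len):
        hist[i] = v
    zeros = np.zeros(n)
    dv1 = np.empty(n); dw1 = np.empty(n); di1 = np.empty(n); ds1 = np.empty(n)
    dv2 = np.empty(n); dw2 = np.empty(n); di2 = np.empty(n); ds2 = np.empty(n)
    dv3 = np.empty(n); dw3 = np.empty(n); di3 = np.empty(n); ds3 = np.empty(n)
    dv4 = np.empty(n); dw4 = np.empty(n); di4 = np.empty(n); ds4 = np.empty(n)
    i_rec = 0
    for i in range(n_steps):
        t = i * dt
        noise_col = noise[:, min(i // noise_stride, noise.shape[1] - 1)]
        x1 = 1.0 if (t_on <= t < t_off) else 0.0
        stim_a = x1 * _pulse(t, amp_pos, amp_neg, t_pos, t_neg, period)
        t_mid = t + 0.5 * dt
        x1m = 1.0 if (t_on <= t_mid < t_off) else 0.0
        stim_b = x1m * _pulse(t_mid, amp_pos, amp_neg, t_pos, t_neg, period)
        t_end = t + dt
        x1e = 1.0 if (t_on <= t_end < t_off) else 0.0
        stim_c = x1e * _pulse(t_end, amp_pos, amp_neg, t_pos, t_neg, period)

        if delay_steps > 0:
            v_del_a = hist[(i - delay_steps) % buf_len]
            v_del_c = hist[(i - delay_steps + 1) % buf_len]
            v_del_b = 0.5 * (v_del_a + v_del_c)
        else:
            v_del_a = v
            v_del_b = v  # replaced per stage below
            v_del_c = v

        if i % rec_stride == 0:
            # total non-stimulation current = C * dv/dt - stim term
            _ml_rhs(v, w, islow, s, v_del_a, zeros, noise_col, stim_a, stim_prof, slow_prof,
                    g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi,
                    v_star, alpha, s1, eps, syn_pref, v_rev, w_mat,
                    alpha_s, beta_s, theta_s, sigma_s, dv1, dw1, di1, ds1)
            for j in range(n):
                v_rec[j, i_rec] = v[j]
                iion_rec[j, i_rec] = cap * dv1[j] - s1 * stim_a * stim_prof[j]
            i_rec += 1

        _ml_rhs(v, w, islow, s, v_del_a, zeros, noise_col, stim_a, stim_prof, slow_prof,
                g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi,
                v_star, alpha, s1, eps, syn_pref, v_rev, w_mat,
                alpha_s, beta_s, theta_s, sigma_s, dv1, dw1, di1, ds1)
        va = v + 0.5 * dt * dv1; wa = w + 0.5 * dt * dw1
        ia = islow + 0.5 * dt * di1; sa = s + 0.5 * dt * ds1
        vd = va if delay_steps == 0 else v_del_b
        _ml_rhs(va, wa, ia, sa, vd, zeros, noise_col, stim_b, stim_prof, slow_prof,
                g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi,
                v_star, alpha, s1, eps, syn_pref, v_rev, w_mat,
                alpha_s, beta_s, theta_s, sigma_s, dv2, dw2, di2, ds2)
        vb = v + 0.5 * dt * dv2; wb = w + 0.5 * dt * dw2
        ib = islow + 0.5 * dt * di2; sb = s + 0.5 * dt * ds2
        vd = vb if delay_steps == 0 else v_del_b
        _ml_rhs(vb, wb, ib, sb, vd, zeros, noise_col, stim_b, stim_prof, slow_prof,
                g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi,
                v_star, alpha, s1, eps, syn_pref, v_rev, w_mat,
                alpha_s, beta_s, theta_s, sigma_s, dv3, dw3, di3, ds3)
        vc = v + dt * dv3; wc = w + dt * dw3
        ic = islow + dt * di3; sc = s + dt * ds3
        vd = vc if delay_steps == 0 else v_del_c
        _ml_rhs(vc, wc, ic, sc, vd, zeros, noise_col, stim_c, stim_prof, slow_prof,
                g_ca, g_k, g_l, v_ca, v_k, v_l, v1, v2, v3, v4, cap, phi,
                v_star, alpha, s1, eps, syn_pref, v_rev, w_mat,
                alpha_s, beta_s, theta_s, sigma_s, dv4, dw4, di4, ds4)
        for j in range(n):
            v[j] += dt / 6.0 * (dv1[j] + 2 * dv2[j] + 2 * dv3[j] + dv4[j])
            # w is a gating fraction; clamping also tames the stiff w
            # relaxation (tau_w -> 0) at strongly hyperpolarized potentials
            wj = w[j] + dt / 6.0 * (dw1[j] + 2 * dw2[j] + 2 * dw3[j] + dw4[j])
            w[j] = min(1.0, max(0.0, wj))
            islow[j] += dt / 6.0 * (di1[j] + 2 * di2[j] + 2 * di3[j] + di4[j])
            sj = s[j] + dt / 6.0 * (ds1[j] + 2 * ds2[j] + 2 * ds3[j] + ds4[j])
            s[j] = min(1.0, max(0.0, sj))
            if not np.isfinite(v[j]):
                return 1, i, j
        hist[(i + 1) % buf_len] = v
    return 0, n_steps, -1


@njit(cache=True)
def _izh_step_pop(
    v, u, s, w_mat, i_ext, noise_col,
    syn_pref, v_rev, v_scale, i_scale,
    a, b, c_reset, d, drive, spike_cut,
    alpha_s, beta_s, theta_s, sigma_s,
    dt, iion_out,
):
    """One forward-Euler step of an Izhikevich population; returns spike mask.

    ``i_ext`` carries stimulation plus any feedforward input; ``iion_out``
    receives the total non-stimulation current for LFP use (computed by the
    caller passing stimulation separately via i_ext decomposition is avoided:
    the caller subtracts the stim part it added).
    """
    n = v.shape[0]
    ws = w_mat @ s
    spiked = np.zeros(n, dtype=np.bool_)
    for j in range(n):
        i_syn = i_scale * syn_pref * ws[j] * (v_scale * v[j] - v_rev)
        i_tot = i_syn + noise_col[j] + drive[j] + i_ext[j]
        dv = 0.04 * v[j] * v[j] + 5.0 * v[j] + 140.0 - u[j] + i_tot
        du = a * (b * v[j] - u[j])
        iion_out[j] = i_syn + noise_col[j] + drive[j]  # currents feeding the LFP
        h = 1.0 / (1.0 + np.exp(-(v[j] - theta_s) / sigma_s))
        sj = s[j] + dt * (alpha_s * h * (1.0 - s[j]) - beta_s * s[j])
        s[j] = min(1.0, max(0.0, sj))
        v[j] += dt * dv
        u[j] += dt * du
        if v[j] >= spike_cut:
            v[j] = c_reset
            u[j] += d
            spiked[j] = True
    return spiked


@njit(cache=True)
def izh_network(
    v, u, s, w_mat,
    syn_pref, v_rev, v_scale, i_scale,
    stim_prof, stim_weight, amp_pos, amp_neg, t_pos, t_neg, period, t_on, t_off,
    noise, noise_stride,
    a, b, c_reset, d, drive, spike_cut,
    alpha_s, beta_s, theta_s, sigma_s,
    dt, n_steps, rec_stride,
    v_rec, iion_rec, spike_times, spike_counts,
):
    """Forward-Euler integration of the Izhikevich lattice with spike logging."""
    n = v.shape[0]
    i_ext = np.empty(n)
    iion = np.empty(n)
    max_spk = spike_times.shape[1]
    i_rec = 0
    for i in range(n_steps):
        t = i * dt
        noise_col = noise[:, min(i // noise_stride, noise.shape[1] - 1)]
        x1 = 1.0 if (t_on <= t < t_off) else 0.0
        stim_t = x1 * _pulse(t, amp_pos, amp_neg, t_pos, t_neg, period)
        for j in range(n):
            i_ext[j] = stim_weight * stim_t * stim_prof[j]
        record = i % rec_stride == 0
        if record:
            for j in range(n):
                v_rec[j, i_rec] = v[j]
        spiked = _izh_step_pop(
            v, u, s, w_mat, i_ext, noise_col,
            syn_pref, v_rev, v_scale, i_scale,
            a, b, c_reset, d, drive, spike_cut,
            alpha_s, beta_s, theta_s, sigma_s, dt, iion,
        )
        if record:
            for j in range(n):
                iion_rec[j, i_rec] = iion[j]
            i_rec += 1
        for j in range(n):
            if not np.isfinite(v[j]):
                return 1, i, j
            if spiked[j] and spike_counts[j] < max_spk:
                spike_times[j, spike_counts[j]] = t
                spike_counts[j] += 1
    return 0, n_steps, -1


@njit(cache=True)
def izh_two_populations(
    v1, u1, s1, w_mat1,
    v2, u2, s2, w_mat2,
    w_ff,
    syn_pref1, syn_pref2, syn_pref_ff, v_rev, v_scale, i_scale,
    stim_prof, stim_weight, amp_pos, amp_neg, t_pos, t_neg, period, t_on, t_off,
    noise1, noise2, noise_stride,
    a, b, c_reset, d, drive1, drive2, spike_cut,
    alpha_s, beta_s, theta_s, sigma_s,
    dt, n_steps, rec_stride,
    v_rec1, iion_rec1, spike_times1, spike_counts1,
    v_rec2, iion_rec2, spike_times2, spike_counts2,
):
    """Pacemaker (stimulated) population driving a weakly coupled second one.

    Population 2 receives the Gaussian-random feedforward current from the
    pacemaker gates in addition to its weak intra-coupling; the pathway is
    strictly one-way.
    """
    n1 = v1.shape[0]
    n2 = v2.shape[0]
    i_ext1 = np.empty(n1)
    i_ext2 = np.empty(n2)
    iion1 = np.empty(n1)
    iion2 = np.empty(n2)
    max1 = spike_times1.shape[1]
    max2 = spike_times2.shape[1]
    i_rec = 0
    for i in range(n_steps):
        t = i * dt
        ncol1 = noise1[:, min(i // noise_stride, noise1.shape[1] - 1)]
        ncol2 = noise2[:, min(i // noise_stride, noise2.shape[1] - 1)]
        x1 = 1.0 if (t_on <= t < t_off) else 0.0
        stim_t = x1 * _pulse(t, amp_pos, amp_neg, t_pos, t_neg, period)
        for j in range(n1):
            i_ext1[j] = stim_weight * stim_t * stim_prof[j]
        ffs = w_ff @ s1  # uses pacemaker gates from the current step
        for j in range(n2):
            i_ext2[j] = i_scale * syn_pref_ff * ffs[j] * (v_scale * v2[j] - v_rev)
        record = i % rec_stride == 0
        if record:
            for j in range(n1):
                v_rec1[j, i_rec] = v1[j]
            for j in range(n2):
                v_rec2[j, i_rec] = v2[j]
        spk1 = _izh_step_pop(
            v1, u1, s1, w_mat1, i_ext1, ncol1,
            syn_pref1, v_rev, v_scale, i_scale,
            a, b, c_reset, d, drive1, spike_cut,
            alpha_s, beta_s, theta_s, sigma_s, dt, iion1,
        )
        spk2 = _izh_step_pop(
            v2, u2, s2, w_mat2, i_ext2, ncol2,
            syn_pref2, v_rev, v_scale, i_scale,
            a, b, c_reset, d, drive2, spike_cut,
            alpha_s, beta_s, theta_s, sigma_s, dt, iion2,
        )
        if record:
            for j in range(n1):
                iion_rec1[j, i_rec] = iion1[j]
            for j in range(n2):
                # the feedforward drive is an ionic input to population 2
                iion_rec2[j, i_rec] = iion2[j] + i_ext2[j]
            i_rec += 1
        for j in range(n1):
            if not np.isfinite(v1[j]):
                return 1, i, j
            if spk1[j] and spike_counts1[j] < max1:
                spike_times1[j, spike_counts1[j]] = t
                spike_counts1[j] += 1
        for j in range(n2):
            if not np.isfinite(v2[j]):
                return 2, i, j
            if spk2[j] and spike_counts2[j] < max2:
                spike_times2[j, spike_counts2[j]] = t
                spike_counts2[j] += 1
    return 0, n_steps, -1
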