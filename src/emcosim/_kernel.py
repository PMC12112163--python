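"""Compiled inner loop of the electrophysiology integrator.

This mirrors, operation for operation, the numpy reference update in
:mod:`emcosim.ephys` (`_batch_step`); a unit test keeps the two paths in
agreement.  Parameter and state rows are packed 2-D float arrays whose row
order is fixed by ``ephys._ParamArrays.packed`` / ``run_batch_segment``.
"""

import math

import numba
import numpy as np

from .constants import RTF_MV

# parameter row indices
(P_CM, P_G_LEAK, P_E_LEAK, P_G_NA, P_G_KD, P_V_T, P_G_M, P_TAU_MAX_M, P_G_CA,
 P_E_CA, P_G_KCA, P_KD_KCA, P_TAU_CA, P_CA_REST, P_CA_GAMMA, P_G_D, P_TAU_D2,
 P_G_NA_LEAK, P_TAU_CL, P_CL_REST, P_NA_O, P_K_O, P_ATP_FLOOR, P_PUMP_VMAX,
 P_PUMP_KM_NA, P_PUMP_KM_K, P_PUMP_KM_ATP, P_PUMP_VHALF, P_PUMP_VSLOPE,
 P_I_TO_FLUX, P_NA_TO_DENS, P_FLUX_TO_I) = range(32)

N_PARAM_ROWS = 32

# state row indices
(S_V, S_NA, S_K, S_CA, S_CL, S_ATP, S_CONSUMED, S_CLAMP, S_OU) = range(9)


@numba.njit(inline="always")
def _lin(u, k):
    x = u / k
    if x > 50.0:
        x = 50.0
    elif x < -50.0:
        x = -50.0
    if abs(x) < 1e-6:
        return k * (1.0 + x / 2.0)
    return u / (1.0 - math.exp(-x))


@numba.njit(inline="always")
def _sexp(x):
    if x > 60.0:
        x = 60.0
    elif x < -60.0:
        x = -60.0
    return math.exp(x)


@numba.njit(cache=True)
def segment_kernel(S, G, P, ou_mean, ou_tau, ou_amp, noise, dt, n_steps,
                   fixed, fixed_val, rec_idx, rec_out, spike_times,
                   spike_counts, t0, thr, refractory):
    nn = S.shape[1]
    sqrt_dt = math.sqrt(dt)
    n_rec = rec_idx.shape[0]
    r = 0
    last_spike = np.full(nn, -1e30)
    status = 0
    t_fail = 0.0

    for k in range(n_steps):
        t = t0 + (k + 1) * dt
        for i in range(nn):
            # OU stimulus
            ou = S[S_OU, i]
            ou += (ou_mean[i] - ou) * (dt / ou_tau[i]) \
                + ou_amp[i] * sqrt_dt * noise[k, i]
            S[S_OU, i] = ou

            v = S[S_V, i]
            na_i = S[S_NA, i]
            k_i = S[S_K, i]
            ca_i = S[S_CA, i]
            cl_i = S[S_CL, i]
            atp = S[S_ATP, i]

            # pump at pre-step state
            fna = (na_i / (na_i + P[P_PUMP_KM_NA, i])) ** 3
            fk = P[P_K_O, i] / (P[P_K_O, i] + P[P_PUMP_KM_K, i])
            fatp = atp / (atp + P[P_PUMP_KM_ATP, i])
            fv = 1.0 / (1.0 + _sexp(-(v - P[P_PUMP_VHALF, i]) / P[P_PUMP_VSLOPE, i]))
            rate = P[P_PUMP_VMAX, i] * fna * fk * fatp * fv

            # gate updates (exponential Euler at pre-step voltage)
            vm = v - P[P_V_T, i]
            a = 0.32 * _lin(vm - 13.0, 4.0)
            b = 0.28 * _lin(-(vm - 40.0), 5.0)
            tau = 1.0 / (a + b)
            G[0, i] += (a * tau - G[0, i]) * -math.expm1(-dt / tau)
            a = 0.128 * _sexp(-(vm - 17.0) / 18.0)
            b = 4.0 / (1.0 + _sexp(-(vm - 40.0) / 5.0))
            tau = 1.0 / (a + b)
            G[1, i] += (a * tau - G[1, i]) * -math.expm1(-dt / tau)
            a = 0.032 * _lin(vm - 15.0, 5.0)
            b = 0.5 * _sexp(-(vm - 10.0) / 40.0)
            tau = 1.0 / (a + b)
            G[2, i] += (a * tau - G[2, i]) * -math.expm1(-dt / tau)
            ev = _sexp((v + 35.0) / 20.0)
            inf = 1.0 / (1.0 + _sexp(-(v + 35.0) / 10.0))
            tau = P[P_TAU_MAX_M, i] / (3.3 * ev + 1.0 / ev)
            G[3, i] += (inf - G[3, i]) * -math.expm1(-dt / tau)
            a = 0.055 * _lin(v + 27.0, 3.8)
            b = 0.94 * _sexp(-(v + 75.0) / 17.0)
            tau = 1.0 / (a + b)
            G[4, i] += (a * tau - G[4, i]) * -math.expm1(-dt / tau)
            inf = 1.0 / (1.0 + _sexp(-(v + 50.0) / 10.0))
            G[5, i] += (inf - G[5, i]) * -math.expm1(-dt / 2.0)
            inf = 1.0 / (1.0 + _sexp((v + 70.0) / 6.0))
            G[6, i] += (inf - G[6, i]) * -math.expm1(-dt / P[P_TAU_D2, i])

            m = G[0, i]
            h = G[1, i]
            ng = G[2, i]
            p = G[3, i]
            q = G[4, i]
            d1 = G[5, i]
            d2 = G[6, i]

            ena = RTF_MV * math.log(P[P_NA_O, i] / na_i)
            ek = RTF_MV * math.log(P[P_K_O, i] / k_i)

            g_na_tot = P[P_G_NA, i] * m * m * m * h + P[P_G_NA_LEAK, i]
            g_k_tot = (P[P_G_KD, i] * ng ** 4 + P[P_G_M, i] * p
                       + P[P_G_KCA, i] * ca_i / (ca_i + P[P_KD_KCA, i])
                       + P[P_G_D, i] * d1 * d2)
            g_ca_eff = P[P_G_CA, i] * q * q

            i_pump = rate * P[P_FLUX_TO_I, i]
            g_tot = P[P_G_LEAK, i] + g_na_tot + g_k_tot + g_ca_eff
            bb = (P[P_G_LEAK, i] * P[P_E_LEAK, i] + g_na_tot * ena
                  + g_k_tot * ek + g_ca_eff * P[P_E_CA, i]
                  + ou * P[P_NA_TO_DENS, i] - i_pump)
            aa = P[P_CM, i] / dt
            v_new = (aa * v + bb) / (aa + g_tot)

            i_na = g_na_tot * (v_new - ena)
            i_k = g_k_tot * (v_new - ek)
            i_ca = g_ca_eff * (v_new - P[P_E_CA, i])

            na_i += dt * (-i_na * P[P_I_TO_FLUX, i] - 3.0 * rate)
            k_i += dt * (-i_k * P[P_I_TO_FLUX, i] + 2.0 * rate)
            ca_i += dt * (-i_ca * P[P_I_TO_FLUX, i] * 0.5 * P[P_CA_GAMMA, i]
                          - (ca_i - P[P_CA_REST, i]) / P[P_TAU_CA, i])
            if ca_i < 0.0:
                ca_i = 0.0
            cl_i += dt * (-(cl_i - P[P_CL_REST, i]) / P[P_TAU_CL, i])

            if fixed:
                S[S_CONSUMED, i] += rate * dt
                atp = fixed_val
            else:
                new_atp = atp - rate * dt
                clipped = new_atp if new_atp > P[P_ATP_FLOOR, i] else P[P_ATP_FLOOR, i]
                S[S_CLAMP, i] += clipped - new_atp
                S[S_CONSUMED, i] += atp - clipped
                atp = clipped

            S[S_NA, i] = na_i
            S[S_K, i] = k_i
            S[S_CA, i] = ca_i
            S[S_CL, i] = cl_i
            S[S_ATP, i] = atp
            S[S_V, i] = v_new

            if v_new >= thr and v < thr and t - last_spike[i] >= refractory:
                # sub-step crossing time by linear interpolation
                ts = t - dt * (v_new - thr) / (v_new - v)
                cnt = spike_counts[i]
                if cnt < spike_times.shape[1]:
                    spike_times[i, cnt] = ts
                    spike_counts[i] = cnt + 1
                last_spike[i] = t

            if not math.isfinite(v_new):
                status = i + 1
                t_fail = t
                return status, t_fail

        if r < n_rec and k + 1 == rec_idx[r]:
            for i in range(nn):
                rec_out[0, r, i] = S[S_V, i]
                rec_out[1, r, i] = S[S_NA, i]
                rec_out[2, r, i] = S[S_K, i]
                rec_out[3, r, i] = S[S_ATP, i]
                rec_out[4, r, i] = S[S_CONSUMED, i]
            r += 1

    return status, t_fail
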