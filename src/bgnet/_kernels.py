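"""Compiled inner loops of the network simulation.

The full network state is one flat float64 vector::

    [STN: V n h r Ca s | GPe: V n h r Ca s | GPi: V n h r Ca s | THA: V h r]

with 500 neurons per basal ganglia nucleus and 200 thalamic neurons
(9600 states).  The right-hand side and the adaptive embedded
Runge-Kutta 3(2) pair (Bogacki-Shampine, the scheme family of MATLAB's
ode23) are compiled with numba; dense output onto the uniform recording
grid uses the cubic Hermite interpolant of the accepted step.

The purely voltage-dependent gating curves (equilibrium activations,
inverse time constants, the synaptic release step) are pre-tabulated on a
0.02 mV grid and linearly interpolated inside the right-hand side; the
interpolation error (< ~1e-6 relative) sits below the integration
tolerances while removing most transcendental calls from the hot loop.
Cell parameters arrive as packed float64 arrays (see the P_*/T_* layout
constants); projection adjacencies as CSR index arrays (row = postsynaptic
neuron).
"""

import numpy as np
from numba import njit

N_BG = 500
N_TH = 200

# state offsets
S_STN = 0
S_GPE = 6 * N_BG
S_GPI = 12 * N_BG
S_THA = 18 * N_BG
NSTATE = 18 * N_BG + 3 * N_TH

# offsets of variables within a BG population block
V_, N_, H_, R_, CA_, SS_ = 0, N_BG, 2 * N_BG, 3 * N_BG, 4 * N_BG, 5 * N_BG

# packed parameter indices for STN/GP cells
(P_GL, P_GK, P_GNA, P_GT, P_GCA, P_GAHP,
 P_EL, P_EK, P_ENA, P_ECA,
 P_THM, P_SGM, P_THH, P_SGH, P_THN, P_SGN,
 P_THR, P_SGR, P_THA_, P_SGA, P_THB, P_SGB, P_THS, P_SGS,
 P_TH0, P_TH1, P_THTH, P_SGTH, P_PHH,
 P_TN0, P_TN1, P_THTN, P_SGTN, P_PHN,
 P_TR0, P_TR1, P_THTR, P_SGTR, P_PHR,
 P_K1, P_K2, P_KCA,
 P_ALPHA, P_BETA, P_THSYN, P_SGSYN,
 P_CAP, P_ISSTN, P_ITECA, P_CONSTTAU) = range(50)

# packed parameter indices for thalamic cells
(T_GL, T_GK, T_GNA, T_GT, T_EL, T_EK, T_ENA, T_ET,
 T_THM, T_SGM, T_THP, T_SGP, T_THH, T_SGH, T_THR, T_SGR,
 T_CAP, T_TAUR_LIT) = range(18)

# gating-table column layout; tables are (n_voltages, n_funcs), row-major so
# one neuron's lookups touch two contiguous rows
(C_MINF, C_SINF, C_AINF, C_NINF, C_HINF, C_RINF,
 C_ITAUN, C_ITAUH, C_ITAUR, C_HSYN) = range(10)
NCOL_BG = 10
(D_MINF, D_PINF, D_HINF, D_RINF, D_ITAUH, D_ITAUR) = range(6)
NCOL_TH = 6

TABLE_V_LO = -150.0
TABLE_V_HI = 80.0
TABLE_DV = 0.02


@njit(cache=True, error_model="numpy")
def _pulse(t, amp, width, period):
    ph = t % period
    if ph < 0.0:
        ph += period
    return amp if ph < width else 0.0


@njit(cache=True, fastmath=True, error_model="numpy", inline="always")
def _csr_sum(indptr, indices, x, i):
    acc = 0.0
    for k in range(indptr[i], indptr[i + 1]):
        acc += x[indices[k]]
    return acc


@njit(cache=True, fastmath=True, error_model="numpy")
def network_rhs(t, y, dy, pstn, pgpe, pgpi, ptha,
                tstn, tgpe, tgpi, ttha, inv_dv,
                stst_p, stst_i, gpst_p, gpst_i,
                gege_p, gege_i, stge_p, stge_i,
                gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i,
                gith_p, gith_i,
                gsyn, erev, i_app, sm, dbs):
    """Time derivative of the full network state.

    gsyn/erev: conductance and reversal per projection in the order
    (STST, GPST, GPeGPe, STGPe, GPiGPi, GPeGPi, STGPi, GPiTha).
    i_app: constant drives (STN, GPe, GPi).
    sm: (A, width, period) sensorimotor train; dbs: (active, A, width, period).
    """
    i_sm = _pulse(t, sm[0], sm[1], sm[2])
    i_dbs = _pulse(t, dbs[1], dbs[2], dbs[3]) if dbs[0] > 0.5 else 0.0

    s_stn = y[S_STN + SS_:S_STN + SS_ + N_BG]
    s_gpe = y[S_GPE + SS_:S_GPE + SS_ + N_BG]
    s_gpi = y[S_GPI + SS_:S_GPI + SS_ + N_BG]

    nrow = tstn.shape[0]
    for pop in range(3):
        if pop == 0:
            base, p, tbl = S_STN, pstn, tstn
        elif pop == 1:
            base, p, tbl = S_GPE, pgpe, tgpe
        else:
            base, p, tbl = S_GPI, pgpi, tgpi
        is_stn = p[P_ISSTN] > 0.5
        b_off = 1.0 / (1.0 + np.exp(-p[P_THB] / p[P_SGB]))
        inv_cap = 1.0 / p[P_CAP]
        for i in range(N_BG):
            v = y[base + V_ + i]
            n = y[base + N_ + i]
            h = y[base + H_ + i]
            r = y[base + R_ + i]
            ca = y[base + CA_ + i]
            s = y[base + SS_ + i]

            # synaptic input
            if pop == 0:
                syn = (gsyn[0] * (v - erev[0]) * _csr_sum(stst_p, stst_i, s_stn, i)
                       + gsyn[1] * (v - erev[1]) * _csr_sum(gpst_p, gpst_i, s_gpe, i))
                i_stim = i_app[0] + i_dbs
            elif pop == 1:
                syn = (gsyn[2] * (v - erev[2]) * _csr_sum(gege_p, gege_i, s_gpe, i)
                       + gsyn[3] * (v - erev[3]) * _csr_sum(stge_p, stge_i, s_stn, i))
                i_stim = i_app[1]
            else:
                syn = (gsyn[4] * (v - erev[4]) * _csr_sum(gigi_p, gigi_i, s_gpi, i)
                       + gsyn[5] * (v - erev[5]) * _csr_sum(gegi_p, gegi_i, s_gpe, i)
                       + gsyn[6] * (v - erev[6]) * _csr_sum(stgi_p, stgi_i, s_stn, i))
                i_stim = i_app[2]

            # tabulated gating curves, linear interpolation in V
            u = (v - TABLE_V_LO) * inv_dv
            if u < 0.0:
                u = 0.0
            elif u > nrow - 2:
                u = float(nrow - 2)
            j = int(u)
            w = u - j
            r0 = tbl[j]
            r1 = tbl[j + 1]
            m_inf = r0[C_MINF] + w * (r1[C_MINF] - r0[C_MINF])
            s_inf = r0[C_SINF] + w * (r1[C_SINF] - r0[C_SINF])
            a_inf = r0[C_AINF] + w * (r1[C_AINF] - r0[C_AINF])
            n_inf = r0[C_NINF] + w * (r1[C_NINF] - r0[C_NINF])
            h_inf = r0[C_HINF] + w * (r1[C_HINF] - r0[C_HINF])
            r_inf = r0[C_RINF] + w * (r1[C_RINF] - r0[C_RINF])
            itau_n = r0[C_ITAUN] + w * (r1[C_ITAUN] - r0[C_ITAUN])
            itau_h = r0[C_ITAUH] + w * (r1[C_ITAUH] - r0[C_ITAUH])
            itau_r = r0[C_ITAUR] + w * (r1[C_ITAUR] - r0[C_ITAUR])
            h_syn = r0[C_HSYN] + w * (r1[C_HSYN] - r0[C_HSYN])

            i_leak = p[P_GL] * (v - p[P_EL])
            i_k = p[P_GK] * n ** 4 * (v - p[P_EK])
            i_na = p[P_GNA] * m_inf ** 3 * h * (v - p[P_ENA])
            i_ca = p[P_GCA] * s_inf * s_inf * (v - p[P_ECA])
            if is_stn:
                b = 1.0 / (1.0 + np.exp((r - p[P_THB]) / p[P_SGB])) - b_off
                i_t = p[P_GT] * a_inf ** 3 * b * b * (v - p[P_ECA])
            else:
                e_t = p[P_ECA] if p[P_ITECA] > 0.5 else p[P_EK]
                i_t = p[P_GT] * a_inf ** 3 * r * (v - e_t)
            i_ahp = p[P_GAHP] * (ca / (ca + p[P_K1])) * (v - p[P_EK])

            dy[base + V_ + i] = (-i_leak - i_k - i_na - i_ca - i_t - i_ahp
                                 - syn + i_stim) * inv_cap
            dy[base + N_ + i] = (n_inf - n) * itau_n
            dy[base + H_ + i] = (h_inf - h) * itau_h
            dy[base + R_ + i] = (r_inf - r) * itau_r
            dy[base + CA_ + i] = p[P_K2] * (-i_ca - i_t - p[P_KCA] * ca)
            dy[base + SS_ + i] = p[P_ALPHA] * (1.0 - s) * h_syn - p[P_BETA] * s

    # thalamus
    p = ptha
    inv_cap = 1.0 / p[T_CAP]
    for i in range(N_TH):
        v = y[S_THA + i]
        h = y[S_THA + N_TH + i]
        r = y[S_THA + 2 * N_TH + i]
        syn = gsyn[7] * (v - erev[7]) * _csr_sum(gith_p, gith_i, s_gpi, i)

        u = (v - TABLE_V_LO) * inv_dv
        if u < 0.0:
            u = 0.0
        elif u > nrow - 2:
            u = float(nrow - 2)
        j = int(u)
        w = u - j
        r0 = ttha[j]
        r1 = ttha[j + 1]
        m_inf = r0[D_MINF] + w * (r1[D_MINF] - r0[D_MINF])
        p_inf = r0[D_PINF] + w * (r1[D_PINF] - r0[D_PINF])
        h_inf = r0[D_HINF] + w * (r1[D_HINF] - r0[D_HINF])
        r_inf = r0[D_RINF] + w * (r1[D_RINF] - r0[D_RINF])
        itau_h = r0[D_ITAUH] + w * (r1[D_ITAUH] - r0[D_ITAUH])
        itau_r = r0[D_ITAUR] + w * (r1[D_ITAUR] - r0[D_ITAUR])

        i_leak = p[T_GL] * (v - p[T_EL])
        i_k = p[T_GK] * (0.75 * (1.0 - h)) ** 4 * (v - p[T_EK])
        i_na = p[T_GNA] * m_inf ** 3 * h * (v - p[T_ENA])
        i_t = p[T_GT] * p_inf * p_inf * r * (v - p[T_ET])

        dy[S_THA + i] = (-i_leak - i_k - i_na - i_t - syn + i_sm) * inv_cap
        dy[S_THA + N_TH + i] = (h_inf - h) * itau_h
        dy[S_THA + 2 * N_TH + i] = (r_inf - r) * itau_r


@njit(cache=True, error_model="numpy")
def integrate_rk23(y0, t0, t1, rtol, atol, max_step, first_step, grid, rec_idx,
                   pstn, pgpe, pgpi, ptha, tstn, tgpe, tgpi, ttha, inv_dv,
                   stst_p, stst_i, gpst_p, gpst_i,
                   gege_p, gege_i, stge_p, stge_i,
                   gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i,
                   gith_p, gith_i,
                   gsyn, erev, i_app, sm, dbs):
    """Adaptive Bogacki-Shampine 3(2) integration with dense recording.

    Records the states listed in ``rec_idx`` at every time in ``grid``
    (must lie within [t0, t1], strictly increasing).  Returns
    (rec, status, n_steps, n_rejected, n_fevals, t_fail, i_fail):
    status 0 = success, 1 = non-finite state encountered.
    """
    ny = y0.size
    y = y0.copy()
    k1 = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    ytmp = np.empty(ny)
    ynew = np.empty(ny)

    rec = np.empty((grid.size, rec_idx.size))
    igrid = 0
    while igrid < grid.size and grid[igrid] <= t0:
        for j in range(rec_idx.size):
            rec[igrid, j] = y[rec_idx[j]]
        igrid += 1

    network_rhs(t0, y, k1, pstn, pgpe, pgpi, ptha, tstn, tgpe, tgpi, ttha,
                inv_dv,
                stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                gsyn, erev, i_app, sm, dbs)
    n_fev = 1
    n_steps = 0
    n_rej = 0
    t = t0
    h = min(first_step, max_step)
    just_rejected = False

    while t < t1:
        if h > t1 - t:
            h = t1 - t
        for j in range(ny):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        network_rhs(t + 0.5 * h, ytmp, k2, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            ytmp[j] = y[j] + 0.75 * h * k2[j]
        network_rhs(t + 0.75 * h, ytmp, k3, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            ynew[j] = y[j] + h * (2.0 / 9.0 * k1[j] + 1.0 / 3.0 * k2[j]
                                  + 4.0 / 9.0 * k3[j])
        network_rhs(t + h, ynew, k4, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        n_fev += 3

        err_norm = 0.0
        for j in range(ny):
            e = h * (5.0 / 72.0 * k1[j] - 1.0 / 12.0 * k2[j]
                     - 1.0 / 9.0 * k3[j] + 1.0 / 8.0 * k4[j])
            ay = abs(y[j])
            ayn = abs(ynew[j])
            scale = atol + rtol * (ay if ay > ayn else ayn)
            q = e / scale
            err_norm += q * q
        err_norm = np.sqrt(err_norm / ny)

        if not np.isfinite(err_norm):
            for j in range(ny):
                if not np.isfinite(ynew[j]):
                    return rec, 1, n_steps, n_rej, n_fev, t, j
            return rec, 1, n_steps, n_rej, n_fev, t, -1

        if err_norm <= 1.0:
            t_new = t + h
            while igrid < grid.size and grid[igrid] <= t_new + 1e-12:
                tau = (grid[igrid] - t) / h
                h00 = (1.0 + 2.0 * tau) * (1.0 - tau) ** 2
                h10 = tau * (1.0 - tau) ** 2
                h01 = tau * tau * (3.0 - 2.0 * tau)
                h11 = tau * tau * (tau - 1.0)
                for j in range(rec_idx.size):
                    jj = rec_idx[j]
                    rec[igrid, j] = (h00 * y[jj] + h10 * h * k1[jj]
                                     + h01 * ynew[jj] + h11 * h * k4[jj])
                igrid += 1
            for j in range(ny):
                y[j] = ynew[j]
                k1[j] = k4[j]  # FSAL
            t = t_new
            n_steps += 1
            # damped I controller; growth is frozen right after a rejection
            if err_norm > 0.0:
                factor = 0.9 * err_norm ** (-1.0 / 3.0)
            else:
                factor = 5.0
            if factor > 5.0:
                factor = 5.0
            if just_rejected and factor > 1.0:
                factor = 1.0
            just_rejected = False
            h *= factor
        else:
            n_rej += 1
            just_rejected = True
            factor = 0.9 * err_norm ** (-1.0 / 3.0)
            if factor < 0.2:
                factor = 0.2
            h *= factor
        if h > max_step:
            h = max_step
        if h < 1e-10:
            return rec, 1, n_steps, n_rej, n_fev, t, -1

    return rec, 0, n_steps, n_rej, n_fev, t1, -1


@njit(cache=True, error_model="numpy")
def integrate_rk4(y0, t0, t1, dt, grid, rec_idx,
                  pstn, pgpe, pgpi, ptha, tstn, tgpe, tgpi, ttha, inv_dv,
                  stst_p, stst_i, gpst_p, gpst_i,
                  gege_p, gege_i, stge_p, stge_i,
                  gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i,
                  gith_p, gith_i,
                  gsyn, erev, i_app, sm, dbs):
    """Fixed-step classical RK4 fallback; records nearest-step values."""
    ny = y0.size
    y = y0.copy()
    k1 = np.empty(ny); k2 = np.empty(ny); k3 = np.empty(ny); k4 = np.empty(ny)
    ytmp = np.empty(ny)
    rec = np.empty((grid.size, rec_idx.size))
    igrid = 0
    n_steps = int(np.ceil((t1 - t0) / dt))
    t = t0
    while igrid < grid.size and grid[igrid] <= t0:
        for j in range(rec_idx.size):
            rec[igrid, j] = y[rec_idx[j]]
        igrid += 1
    for _ in range(n_steps):
        hh = min(dt, t1 - t)
        network_rhs(t, y, k1, pstn, pgpe, pgpi, ptha, tstn, tgpe, tgpi, ttha,
                    inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            ytmp[j] = y[j] + 0.5 * hh * k1[j]
        network_rhs(t + 0.5 * hh, ytmp, k2, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            ytmp[j] = y[j] + 0.5 * hh * k2[j]
        network_rhs(t + 0.5 * hh, ytmp, k3, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            ytmp[j] = y[j] + hh * k3[j]
        network_rhs(t + hh, ytmp, k4, pstn, pgpe, pgpi, ptha,
                    tstn, tgpe, tgpi, ttha, inv_dv,
                    stst_p, stst_i, gpst_p, gpst_i, gege_p, gege_i, stge_p, stge_i,
                    gigi_p, gigi_i, gegi_p, gegi_i, stgi_p, stgi_i, gith_p, gith_i,
                    gsyn, erev, i_app, sm, dbs)
        for j in range(ny):
            y[j] += hh / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        t += hh
        while igrid < grid.size and grid[igrid] <= t + 1e-12:
            for j in range(rec_idx.size):
                rec[igrid, j] = y[rec_idx[j]]
            igrid += 1
    return rec, 0, n_steps, 0, 4 * n_steps, t1, -1
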