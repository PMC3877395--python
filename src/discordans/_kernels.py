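"""Numba kernels advancing the coupled voltage / subcellular-Ca state.

One kernel (:func:`step_frame`) integrates every scale of the model: the
membrane sites (0D cell, multi-cell group with shared voltage, 1D cable, 2D
sheet) differ only in the array shapes and the diffusion flags passed in.

State layout
------------
``V, vgate, wgate`` : shape (S,) — one membrane per lattice site.
``ci, cs, cnsr, cjsr, rgate`` : shape (S, Mt) — ``Mt`` sarcomeres share each
membrane; for a multi-cell group ``Mt = n_cells * M`` and ``edge_open`` has
zeros at cell boundaries (no inter-cell Ca diffusion).

Integration
-----------
Forward Euler for voltage, gates and most Ca fluxes; the stiff JSR release
and the release gate are updated semi-implicitly (the release flux is
evaluated at the stabilised end-of-step JSR value, which keeps the update
exactly conservative and positive at any step in the working range).
Voltage diffusion is a split substep: FTCS in 1D, Peaceman–Rachford ADI in
2D, both with zero-flux boundaries.
"""

import math

import numpy as np
from numba import njit

from ._params import (
    P_V_REST, P_V_AMP, P_C_M, P_U_C, P_U_V, P_TAU_D, P_TAU_V1M, P_TAU_V2M,
    P_TAU_VP, P_TAU_0, P_TAU_R, P_TAU_SI, P_K_SI, P_U_CSI, P_TAU_WM,
    P_TAU_WP, P_G_NCX_V, P_K_NCX, P_C_FCA, P_U_RELEASE, P_C_JSR_THRESH,
    P_C_JSR_SLOPE, P_V_UP_MAX, P_K_UP, P_SIGMA_STEP, P_TAU_DIFF_CYTO,
    P_TAU_DIFF_NSR, P_TAU_TR, P_TAU_SM, P_TAU_R_RECOVER, P_TAU_R_SPEND,
    P_NU_S, P_NU_N, P_NU_J, P_G_CA_INFLUX, P_G_NCX_FLUX, P_G_LEAK_IN,
    P_G_SR_LEAK, P_NOISE_MODE, P_G_TRIG, P_TAU_SPARK, P_G_REL_LIN,
    P_U_SCALE, P_U_D, P_K_D, P_U_FI, P_K_FI, P_TAU_F_INACT, P_TAU_F_REC,
    P_BUF_B, P_BUF_K, P_TAU_DIFF_JSR,
)


@njit(cache=True, inline="always")
def _free_ca(total, b, k):
    """Free Ca from total for the instantaneous buffer (closed form)."""
    a = total - b - k
    return 0.5 * (a + math.sqrt(a * a + 4.0 * k * total))

# error codes returned by step_frame (0 = ok; >0 names the failing field)
ERR_OK = 0
ERR_CI = 1
ERR_CS = 2
ERR_CNSR = 3
ERR_CJSR = 4
ERR_V = 5

ERR_NAMES = {ERR_CI: "c_i", ERR_CS: "c_s", ERR_CNSR: "c_nsr",
             ERR_CJSR: "c_jsr", ERR_V: "V"}


@njit(cache=True)
def _thomas_neumann(r, rhs, out, cp, dp):
    """Solve (I - r*Lap1D) out = rhs with zero-flux boundaries (Thomas)."""
    n = rhs.shape[0]
    if n == 1:
        out[0] = rhs[0]
        return
    bend = 1.0 + r
    bmid = 1.0 + 2.0 * r
    cp[0] = -r / bend
    dp[0] = rhs[0] / bend
    for i in range(1, n):
        b = bend if i == n - 1 else bmid
        m = b + r * cp[i - 1]
        cp[i] = -r / m
        dp[i] = (rhs[i] + r * dp[i - 1]) / m
    out[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]


@njit(cache=True)
def _diffuse_v_1d(V, dv, dx, dt, work):
    n = V.shape[0]
    a = dv * dt / (dx * dx)
    for i in range(n):
        acc = 0.0
        if i > 0:
            acc += V[i - 1] - V[i]
        if i < n - 1:
            acc += V[i + 1] - V[i]
        work[i] = a * acc
    for i in range(n):
        V[i] += work[i]


@njit(cache=True)
def _diffuse_v_adi(V, nx, ny, dv, dx, dt, vhalf, line_rhs, line_out, cp, dp):
    """Peaceman–Rachford ADI step on V viewed as (ny, nx) row-major."""
    r = dv * dt / (2.0 * dx * dx)
    # half step 1: implicit in x, explicit in y
    for iy in range(ny):
        for ix in range(nx):
            s = iy * nx + ix
            acc = 0.0
            if iy > 0:
                acc += V[s - nx] - V[s]
            if iy < ny - 1:
                acc += V[s + nx] - V[s]
            line_rhs[ix] = V[s] + r * acc
        _thomas_neumann(r, line_rhs[:nx], line_out[:nx], cp, dp)
        for ix in range(nx):
            vhalf[iy * nx + ix] = line_out[ix]
    # half step 2: implicit in y, explicit in x
    for ix in range(nx):
        for iy in range(ny):
            s = iy * nx + ix
            acc = 0.0
            if ix > 0:
                acc += vhalf[s - 1] - vhalf[s]
            if ix < nx - 1:
                acc += vhalf[s + 1] - vhalf[s]
            line_rhs[iy] = vhalf[s] + r * acc
        _thomas_neumann(r, line_rhs[:ny], line_out[:ny], cp, dp)
        for iy in range(ny):
            V[iy * nx + ix] = line_out[iy]


@njit(cache=True, fastmath=True)
def step_frame(V, vgate, wgate, fgate, ci, cs, cnsr, cjsr, rgate, qrel,
               xi, stim, edge_open, n_sub, dt, P,
               clamp_flag, clamp_v, mem_flux,
               dims, nx, ny, dv, dx,
               work_m, work_m2, work_v, work_v2, line_rhs, line_out, cp, dp):
    """Advance the full state by ``n_sub`` substeps of length ``dt``.

    ``xi`` (S, Mt) holds the noise variates for this frame (standard normal
    for SERCA noise, pre-scaled uniform for release noise); the same draw is
    applied to every substep of the frame, so the frame-integrated
    fluctuation is independent of the substep choice.

    Returns (max |dV/dt| in mV/ms, negative-concentration clip count,
    error code).
    """
    S, Mt = ci.shape
    v_rest = P[P_V_REST]
    v_amp = P[P_V_AMP]
    c_m = P[P_C_M]
    u_c = P[P_U_C]
    u_v = P[P_U_V]
    tau_d = P[P_TAU_D]
    tau_v1m = P[P_TAU_V1M]
    tau_v2m = P[P_TAU_V2M]
    tau_vp = P[P_TAU_VP]
    tau_0 = P[P_TAU_0]
    tau_r = P[P_TAU_R]
    tau_si = P[P_TAU_SI]
    k_si = P[P_K_SI]
    u_csi = P[P_U_CSI]
    tau_wm = P[P_TAU_WM]
    tau_wp = P[P_TAU_WP]
    g_ncx_v = P[P_G_NCX_V]
    k_ncx = P[P_K_NCX]
    c_fca = P[P_C_FCA]
    u_rel = P[P_U_RELEASE]
    c_jth = P[P_C_JSR_THRESH]
    c_jsl = P[P_C_JSR_SLOPE]
    v_up = P[P_V_UP_MAX]
    k_up = P[P_K_UP]
    sig_step = P[P_SIGMA_STEP]
    tau_dc = P[P_TAU_DIFF_CYTO]
    tau_dn = P[P_TAU_DIFF_NSR]
    tau_tr = P[P_TAU_TR]
    tau_sm = P[P_TAU_SM]
    tau_rrec = P[P_TAU_R_RECOVER]
    tau_rsp = P[P_TAU_R_SPEND]
    nu_s = P[P_NU_S]
    nu_n = P[P_NU_N]
    nu_j = P[P_NU_J]
    g_cain = P[P_G_CA_INFLUX]
    g_ncxf = P[P_G_NCX_FLUX]
    g_bg = P[P_G_LEAK_IN]
    g_srl = P[P_G_SR_LEAK]
    noise_mode = int(P[P_NOISE_MODE])
    g_trig = P[P_G_TRIG]
    tau_spark = P[P_TAU_SPARK]
    g_rel_lin = P[P_G_REL_LIN]
    u_scale = P[P_U_SCALE]
    u_d = P[P_U_D]
    k_d = P[P_K_D]
    u_fi = P[P_U_FI]
    k_fi = P[P_K_FI]
    tau_fi = P[P_TAU_F_INACT]
    tau_fr = P[P_TAU_F_REC]
    buf_b = P[P_BUF_B]
    buf_k = P[P_BUF_K]
    tau_dj = P[P_TAU_DIFF_JSR]

    max_dv = 0.0
    n_clip = 0
    err = ERR_OK

    for _ in range(n_sub):
        for s in range(S):
            u = (V[s] - v_rest) / v_amp
            p = 1.0 if u >= u_c else 0.0
            q = 1.0 if u >= u_v else 0.0
            i_fi = -vgate[s] * p * (1.0 - u) * (u - u_c) / tau_d
            i_so = u * (1.0 - p) / tau_0 + p * (1.0 + 3.0 * max(u - 1.0, 0.0)) / tau_r
            s_inf = 0.5 * (1.0 + math.tanh(k_si * (u - u_csi)))
            wts = wgate[s] * s_inf
            d_inf = 1.0 / (1.0 + math.exp(-(u - u_d) / k_d))
            dfg = d_inf * fgate[s]
            acc = 0.0
            for k in range(Mt):
                cik = ci[s, k]      # total cytosolic Ca
                csk = cs[s, k]      # total submembrane Ca
                cnk = cnsr[s, k]
                cjk = cjsr[s, k]
                rgk = rgate[s, k]
                cif = _free_ca(cik, buf_b, buf_k)
                csf = _free_ca(csk, buf_b, buf_k)

                fca_inact = 1.0 / (1.0 + (cif / c_fca) * (cif / c_fca))
                trig = dfg * fca_inact
                occ = csf / (csf + k_ncx)
                acc += -wts * fca_inact / tau_si - g_ncx_v * occ

                # --- subcellular Ca fluxes (cytosol-referred, µM/ms)
                # spark recruitment: amplitude latched to the load at trigger
                # time, then decaying with the spark lifetime
                sgm = 1.0 / (1.0 + math.exp(-(cjk - c_jth) / c_jsl))
                gain = u_rel * (g_rel_lin + (u_rel / u_scale) * sgm)
                recr = nu_j * g_trig * rgk * trig * gain * cjk
                qk = qrel[s, k]
                f_rel = qk
                if noise_mode == 2:
                    f_rel *= (1.0 + xi[s, k])
                avail = 0.9 * nu_j * cjk / dt
                if f_rel > avail:
                    f_rel = avail
                qrel[s, k] = qk + dt * (recr - qk / tau_spark)
                f_tr = nu_j * (cnk - cjk) / tau_tr
                j_up = v_up * cif * cif / (k_up * k_up + cif * cif)
                if noise_mode == 1:
                    j_up *= (1.0 + sig_step * xi[s, k])
                f_leak = g_srl * (cnk - cif)
                f_sm = nu_s * (csf - cif) / tau_sm
                f_cain = mem_flux * g_cain * trig
                f_ncx = mem_flux * g_ncxf * occ
                f_bg = mem_flux * g_bg

                ci_n = cik + dt * (f_sm - j_up + f_leak)
                cs_n = csk + dt * ((f_rel + f_cain + f_bg - f_ncx - f_sm) / nu_s)
                cn_n = cnk + dt * ((j_up - f_tr - f_leak) / nu_n)
                cj_n = cjk + dt * ((f_tr - f_rel) / nu_j)
                rg_n = (rgk + dt / tau_rrec) / (
                    1.0 + dt * (1.0 / tau_rrec + trig / tau_rsp))

                if not (ci_n == ci_n):
                    return max_dv, n_clip, ERR_CI
                if not (cs_n == cs_n):
                    return max_dv, n_clip, ERR_CS
                if not (cn_n == cn_n):
                    return max_dv, n_clip, ERR_CNSR
                if not (cj_n == cj_n):
                    return max_dv, n_clip, ERR_CJSR
                if ci_n < 0.0:
                    ci_n = 0.0
                    n_clip += 1
                if cs_n < 0.0:
                    cs_n = 0.0
                    n_clip += 1
                if cn_n < 0.0:
                    cn_n = 0.0
                    n_clip += 1
                if cj_n < 0.0:
                    cj_n = 0.0
                    n_clip += 1
                if rg_n < 0.0:
                    rg_n = 0.0
                elif rg_n > 1.0:
                    rg_n = 1.0

                ci[s, k] = ci_n
                cs[s, k] = cs_n
                cnsr[s, k] = cn_n
                cjsr[s, k] = cj_n
                rgate[s, k] = rg_n

            i_ion = i_fi + i_so + acc / Mt
            dudt = -i_ion + stim[s] / (c_m * v_amp)
            dvdt = v_amp * dudt
            if clamp_flag == 1:
                V[s] = clamp_v[s]
            else:
                V[s] = V[s] + dt * dvdt
                if abs(dvdt) > max_dv:
                    max_dv = abs(dvdt)
            if not (V[s] == V[s]) or V[s] > 200.0 or V[s] < -200.0:
                return max_dv, n_clip, ERR_V

            tvm = tau_v1m if q >= 1.0 else tau_v2m
            vg = vgate[s] + dt * ((1.0 - p) * (1.0 - vgate[s]) / tvm
                                  - p * vgate[s] / tau_vp)
            wgv = wgate[s] + dt * ((1.0 - p) * (1.0 - wgate[s]) / tau_wm
                                   - p * wgate[s] / tau_wp)
            vgate[s] = min(max(vg, 0.0), 1.0)
            wgate[s] = min(max(wgv, 0.0), 1.0)
            f_inf = 1.0 / (1.0 + math.exp((u - u_fi) / k_fi))
            tf = tau_fi if u >= u_fi else tau_fr
            fg = fgate[s] + dt * (f_inf - fgate[s]) / tf
            fgate[s] = min(max(fg, 0.0), 1.0)

        # --- intra-cell sarcomere Ca diffusion (flux form, exact antisymmetry;
        #     tau_diff_cyto encodes the EFFECTIVE (buffered) diffusion
        #     coefficient, so the exchange acts on total cytosolic Ca)
        if Mt > 1:
            for s in range(S):
                a = dt / tau_dc
                for k in range(Mt):
                    d = 0.0
                    if k > 0 and edge_open[k - 1] > 0.0:
                        d += ci[s, k - 1] - ci[s, k]
                    if k < Mt - 1 and edge_open[k] > 0.0:
                        d += ci[s, k + 1] - ci[s, k]
                    work_m[s, k] = a * d
                for k in range(Mt):
                    ci[s, k] += work_m[s, k]
                a = dt / tau_dn
                for k in range(Mt):
                    d = 0.0
                    if k > 0 and edge_open[k - 1] > 0.0:
                        d += cnsr[s, k - 1] - cnsr[s, k]
                    if k < Mt - 1 and edge_open[k] > 0.0:
                        d += cnsr[s, k + 1] - cnsr[s, k]
                    work_m[s, k] = a * d
                for k in range(Mt):
                    cnsr[s, k] += work_m[s, k]
                # luminal diffusion also couples the junctional terminals,
                # which are continuous with the SR network (slower route)
                a = dt / tau_dj
                for k in range(Mt):
                    d = 0.0
                    if k > 0 and edge_open[k - 1] > 0.0:
                        d += cjsr[s, k - 1] - cjsr[s, k]
                    if k < Mt - 1 and edge_open[k] > 0.0:
                        d += cjsr[s, k + 1] - cjsr[s, k]
                    work_m[s, k] = a * d
                for k in range(Mt):
                    cjsr[s, k] += work_m[s, k]

        # --- voltage diffusion substep
        if dv > 0.0 and S > 1 and clamp_flag == 0:
            if dims == 1:
                _diffuse_v_1d(V, dv, dx, dt, work_v)
            elif dims == 2:
                _diffuse_v_adi(V, nx, ny, dv, dx, dt, work_v2,
                               line_rhs, line_out, cp, dp)

    return max_dv, n_clip, err
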