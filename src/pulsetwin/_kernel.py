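"""Numba hot loop for the 1-D pulse-wave network solver.

The network is flattened to global node arrays; each cardiac cycle is
integrated with a two-step (predictor/corrector) MacCormack scheme on
the (A, Q) system, with characteristic-based boundary closures:

* inlet    -- lumped two-chamber heart (or a prescribed inflow array),
* junctions -- Newton solve conserving mass and total pressure,
* outlets  -- three-element Windkessel, closed end, or absorbing end.

All quantities are SI.  The module is deliberately free of Python
objects so the whole multi-cycle run stays inside one jitted call.
"""

import numpy as np
from numba import njit

# inlet kinds
INLET_HEART = 0
INLET_PRESCRIBED = 1
# outlet kinds
OUT_WK3 = 0
OUT_CLOSED = 1
OUT_ABSORBING = 2

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _activation(phase, t_rise, t_fall):
    """Normalized elastance activation, phase in [0, 1)."""
    if phase < t_rise:
        return 0.5 * (1.0 - np.cos(np.pi * phase / t_rise))
    if phase < t_fall:
        return 0.5 * (1.0 + np.cos(np.pi * (phase - t_rise) / (t_fall - t_rise)))
    return 0.0


@njit(cache=True)
def _pel(A, A0, c0, b, rho, P0, Pext):
    if b == 2.0:
        ratio = A / A0
    else:
        ratio = (A / A0) ** (0.5 * b)
    return P0 + Pext + (2.0 * rho * c0 * c0 / b) * (ratio - 1.0)


@njit(cache=True)
def _dpel_dA(A, A0, c0, b, rho):
    if b == 2.0:
        return rho * c0 * c0 / A0
    return rho * c0 * c0 / A0 * (A / A0) ** (0.5 * b - 1.0)


@njit(cache=True)
def _csound(A, A0, c0, b):
    if b == 2.0:
        return c0 * np.sqrt(A / A0)
    return c0 * (A / A0) ** (0.25 * b)


@njit(cache=True)
def _area_from_c(c, A0, c0, b):
    if b == 2.0:
        r = c / c0
        return A0 * r * r
    return A0 * (c / c0) ** (4.0 / b)


@njit(cache=True)
def _solve_inlet_area(Qt, Wm, A_guess, A0, c0, b):
    """Area at an inflow boundary: Qt/A - (4/b)(c(A)-c0) = Wm."""
    A = A_guess
    for _ in range(60):
        c = _csound(A, A0, c0, b)
        f = Qt / A - (4.0 / b) * (c - c0) - Wm
        df = -Qt / (A * A) - c / A
        dA = f / df
        if abs(dA) > 0.5 * A:
            dA = 0.5 * A * (1.0 if dA > 0 else -1.0)
        A -= dA
        if A <= 0.0:
            A = 0.1 * A_guess
        if abs(dA) < 1e-14 * A0:
            break
    return A


@njit(cache=True)
def _solve_inlet_valve(P_lv, Rav, Wm, A_guess, A0, c0, b, rho, P0, Pext):
    """Open aortic valve: A*u(A) = (P_lv - Pel(A))/Rav with the
    incoming characteristic u(A) = Wm + (4/b)(c(A) - c0).

    Returns (A, Q); a non-positive flow at the solution means the valve
    is actually closed.
    """
    A = A_guess
    for _ in range(60):
        c = _csound(A, A0, c0, b)
        u = Wm + (4.0 / b) * (c - c0)
        f = A * u - (P_lv - _pel(A, A0, c0, b, rho, P0, Pext)) / Rav
        df = u + c + _dpel_dA(A, A0, c0, b, rho) / Rav
        dA = f / df
        if abs(dA) > 0.5 * A:
            dA = 0.5 * A * (1.0 if dA > 0 else -1.0)
        A -= dA
        if A <= 0.0:
            A = 0.1 * A_guess
        if abs(dA) < 1e-14 * A0:
            break
    c = _csound(A, A0, c0, b)
    u = Wm + (4.0 / b) * (c - c0)
    return A, A * u


@njit(cache=True)
def _solve_outlet_wk3(Wp, A_guess, A0, c0, b, rho, P0, Pext, Zc, Pc):
    """Area at a WK3 boundary: Pel(A) = Pc + Zc*A*u(A), u from W+."""
    A = A_guess
    for _ in range(60):
        c = _csound(A, A0, c0, b)
        u = Wp - (4.0 / b) * (c - c0)
        g = _pel(A, A0, c0, b, rho, P0, Pext) - Pc - Zc * A * u
        dg = _dpel_dA(A, A0, c0, b, rho) - Zc * (u - c)
        dA = g / dg
        if abs(dA) > 0.5 * A:
            dA = 0.5 * A * (1.0 if dA > 0 else -1.0)
        A -= dA
        if A <= 0.0:
            A = 0.1 * A_guess
        if abs(dA) < 1e-14 * A0:
            break
    c = _csound(A, A0, c0, b)
    u = Wp - (4.0 / b) * (c - c0)
    return A, u


@njit(cache=True)
def _gauss_solve(J, r, n):
    """In-place Gaussian elimination with partial pivoting (small n)."""
    for col in range(n):
        piv = col
        best = abs(J[col, col])
        for row in range(col + 1, n):
            if abs(J[row, col]) > best:
                best = abs(J[row, col])
                piv = row
        if piv != col:
            for k in range(n):
                tmp = J[col, k]
                J[col, k] = J[piv, k]
                J[piv, k] = tmp
            tmp = r[col]
            r[col] = r[piv]
            r[piv] = tmp
        d = J[col, col]
        for row in range(col + 1, n):
            f = J[row, col] / d
            for k in range(col, n):
                J[row, k] -= f * J[col, k]
            r[row] -= f * r[col]
    for col in range(n - 1, -1, -1):
        s = r[col]
        for k in range(col + 1, n):
            s -= J[col, k] * r[k]
        r[col] = s / J[col, col]


@njit(cache=True)
def _junction_solve(Apar, A0p, c0p, bp, Wps,
                    Ach, A0c, c0c, bc, Wms, m, rho,
                    P0, Pext, out_A, out_u):
    """Damped Newton on the coupled junction system.

    Unknowns: boundary areas of the parent end and of the m child ends;
    velocities follow from the outgoing characteristic invariants.
    Equations: mass balance and parent-child total-pressure equality.
    Returns the relative mass residual at the solution.
    """
    n = m + 1
    x = np.empty(n)
    x[0] = Apar
    for i in range(m):
        x[1 + i] = Ach[i]
    J = np.empty((n, n))
    r = np.empty(n)
    for it in range(80):
        cp = _csound(x[0], A0p, c0p, bp)
        up = Wps - (4.0 / bp) * (cp - c0p)
        Pp = _pel(x[0], A0p, c0p, bp, rho, P0, Pext) + 0.5 * rho * up * up
        mass = x[0] * up
        for row in range(n):
            for col in range(n):
                J[row, col] = 0.0
        # mass row
        J[0, 0] = up - cp
        r[0] = mass
        for i in range(m):
            Ai = x[1 + i]
            ci = _csound(Ai, A0c[i], c0c[i], bc[i])
            ui = Wms[i] + (4.0 / bc[i]) * (ci - c0c[i])
            r[0] -= Ai * ui
            J[0, 1 + i] = -(ui + ci)
            # total-pressure row for child i
            Pi = _pel(Ai, A0c[i], c0c[i], bc[i], rho, P0, Pext) + 0.5 * rho * ui * ui
            r[1 + i] = Pp - Pi
            J[1 + i, 0] = _dpel_dA(x[0], A0p, c0p, bp, rho) - rho * up * cp / x[0]
            J[1 + i, 1 + i] = -(_dpel_dA(Ai, A0c[i], c0c[i], bc[i], rho)
                                + rho * ui * ci / Ai)
        # convergence on scaled residual
        res = abs(r[0]) / (abs(mass) + 1e-12)
        for i in range(m):
            res = max(res, abs(r[1 + i]) / (abs(Pp) + 1.0))
        if res < 1e-12 and it > 0:
            break
        _gauss_solve(J, r, n)
        for i in range(n):
            dA = r[i]
            lim = 0.2 * x[i]
            if dA > lim:
                dA = lim
            elif dA < -lim:
                dA = -lim
            x[i] -= dA
            if x[i] <= 0.0:
                x[i] = 0.05 * (A0p if i == 0 else A0c[i - 1])
    cp = _csound(x[0], A0p, c0p, bp)
    up = Wps - (4.0 / bp) * (cp - c0p)
    out_A[0] = x[0]
    out_u[0] = up
    mass = x[0] * up
    flow_out = 0.0
    for i in range(m):
        ci = _csound(x[1 + i], A0c[i], c0c[i], bc[i])
        ui = Wms[i] + (4.0 / bc[i]) * (ci - c0c[i])
        out_A[1 + i] = x[1 + i]
        out_u[1 + i] = ui
        flow_out += x[1 + i] * ui
    # relative mass defect with a 1 uL/s floor on the flow scale
    return abs(mass - flow_out) / max(abs(mass), 1e-9)


@njit(cache=True)
def _compute_pressure(A, Q, P, seg_off, seg_nn, seg_dx, A0, c0,
                      seg_b, seg_gamma, seg_Gamma, seg_P0, seg_Pext, rho,
                      with_visc):
    """Tube-law pressure at every node; the Voigt wall term
    (-Gamma/(A0*sqrt(A)) * dQ/dx) is included only when recording —
    during stepping it is handled by the implicit split."""
    nseg = seg_off.shape[0]
    for s in range(nseg):
        i0 = seg_off[s]
        nn = seg_nn[s]
        dx = seg_dx[s]
        b = seg_b[s]
        G = seg_Gamma[s]
        P0 = seg_P0[s]
        Pext = seg_Pext[s]
        for i in range(i0, i0 + nn):
            P[i] = _pel(A[i], A0[i], c0[i], b, rho, P0, Pext)
            if with_visc == 1 and G > 0.0:
                if i == i0:
                    dqdx = (Q[i + 1] - Q[i]) / dx
                elif i == i0 + nn - 1:
                    dqdx = (Q[i] - Q[i - 1]) / dx
                else:
                    dqdx = (Q[i + 1] - Q[i - 1]) / (2.0 * dx)
                P[i] -= (G / (A0[i] * np.sqrt(A[i]))) * dqdx


@njit(cache=True)
def _viscoelastic_diffuse(A, Q, seg_off, seg_nn, seg_dx, A0, seg_Gamma,
                          rho, dt, lo, di, up, rhs):
    """Implicit (backward Euler) solve of the wall-viscosity diffusion
    dQ/dt = (A/rho) d/dx(eta dQ/dx), eta = Gamma/(A0 sqrt(A)),
    with boundary flows held fixed; Thomas algorithm per segment."""
    nseg = seg_off.shape[0]
    for s in range(nseg):
        G = seg_Gamma[s]
        if G <= 0.0:
            continue
        i0 = seg_off[s]
        nn = seg_nn[s]
        dx2 = seg_dx[s] * seg_dx[s]
        # assemble: identity rows at the ends
        for j in range(nn):
            i = i0 + j
            if j == 0 or j == nn - 1:
                lo[j] = 0.0
                di[j] = 1.0
                up[j] = 0.0
                rhs[j] = Q[i]
            else:
                eta_m = 0.5 * (G / (A0[i - 1] * np.sqrt(A[i - 1]))
                               + G / (A0[i] * np.sqrt(A[i])))
                eta_p = 0.5 * (G / (A0[i] * np.sqrt(A[i]))
                               + G / (A0[i + 1] * np.sqrt(A[i + 1])))
                coef = dt * A[i] / (rho * dx2)
                lo[j] = -coef * eta_m
                up[j] = -coef * eta_p
                di[j] = 1.0 + coef * (eta_m + eta_p)
                rhs[j] = Q[i]
        # Thomas sweep
        for j in range(1, nn):
            w = lo[j] / di[j - 1]
            di[j] -= w * up[j - 1]
            rhs[j] -= w * rhs[j - 1]
        rhs[nn - 1] /= di[nn - 1]
        for j in range(nn - 2, -1, -1):
            rhs[j] = (rhs[j] - up[j] * rhs[j + 1]) / di[j]
        for j in range(nn):
            Q[i0 + j] = rhs[j]


@njit(cache=True)
def run_simulation(
        # grid / geometry
        seg_off, seg_nn, seg_dx, A0, c0,
        seg_b, seg_gamma, seg_Gamma, seg_P0, seg_Pext,
        # topology
        jparent, jnchild, jchild,
        out_seg, out_kind, out_Zc, out_R, out_C, out_Pout, out_Pc,
        inlet_seg, inlet_kind, qin_prescribed,
        # heart parameters: [T, EminV, EmaxV, V0V, trV, tfV, onV,
        #                    EminA, EmaxA, V0A, trA, tfA, onA,
        #                    Rmv, Rav, Rven, Pven]
        heart_par, heart_state,
        # fluid + stepping
        rho, nu, dt, steps_per_cycle, max_cycles, tol_pa,
        # state (modified in place)
        A, Q,
        # outputs
        P_prev, P_curr, Q_curr, q_valve, v_lv, v_la):
    """Run up to ``max_cycles`` cycles; stop when the all-node pressure
    trace repeats within ``tol_pa``.

    Returns (cycles_run, final_cycle_diff_pa, max_junction_mass_residual,
    diverged_flag).  ``P_curr`` holds the last cycle's pressure at every
    node and step; ``q_valve``/``v_lv``/``v_la`` the inlet flow and
    chamber volumes over the last cycle.
    """
    ncell = A.shape[0]
    nseg = seg_off.shape[0]
    nj = jparent.shape[0]
    no = out_seg.shape[0]

    As = np.empty(ncell)
    Qs = np.empty(ncell)
    P = np.empty(ncell)
    Ps = np.empty(ncell)

    max_nn = 0
    for s in range(nseg):
        if seg_nn[s] > max_nn:
            max_nn = seg_nn[s]
    tri_lo = np.empty(max_nn)
    tri_di = np.empty(max_nn)
    tri_up = np.empty(max_nn)
    tri_rhs = np.empty(max_nn)

    jA = np.empty(4)
    jU = np.empty(4)
    cA0 = np.empty(3)
    cC0 = np.empty(3)
    cB = np.empty(3)
    cWm = np.empty(3)
    cAg = np.empty(3)

    T = heart_par[0]
    mass_res_max = 0.0
    cycles_run = 0
    diff = 1e30
    diverged = 0

    for cyc in range(max_cycles):
        for k in range(steps_per_cycle):
            t_phase = k / steps_per_cycle

            _compute_pressure(A, Q, P, seg_off, seg_nn, seg_dx, A0, c0,
                              seg_b, seg_gamma, seg_Gamma, seg_P0, seg_Pext,
                              rho, 0)

            # --- predictor (forward differences) ---
            for s in range(nseg):
                i0 = seg_off[s]
                nn = seg_nn[s]
                dx = seg_dx[s]
                fric = TWO_PI * seg_gamma[s] * nu
                for i in range(i0, i0 + nn - 1):
                    dqdx = (Q[i + 1] - Q[i]) / dx
                    dfdx = (Q[i + 1] * Q[i + 1] / A[i + 1]
                            - Q[i] * Q[i] / A[i]) / dx
                    dpdx = (P[i + 1] - P[i]) / dx
                    As[i] = A[i] - dt * dqdx
                    Qs[i] = Q[i] - dt * (dfdx + (A[i] / rho) * dpdx
                                         + fric * Q[i] / A[i])
                last = i0 + nn - 1
                As[last] = A[last]
                Qs[last] = Q[last]

            _compute_pressure(As, Qs, Ps, seg_off, seg_nn, seg_dx, A0, c0,
                              seg_b, seg_gamma, seg_Gamma, seg_P0, seg_Pext,
                              rho, 0)

            # --- corrector (backward differences) ---
            for s in range(nseg):
                i0 = seg_off[s]
                nn = seg_nn[s]
                dx = seg_dx[s]
                fric = TWO_PI * seg_gamma[s] * nu
                for i in range(i0 + nn - 2, i0, -1):
                    dqdx = (Qs[i] - Qs[i - 1]) / dx
                    dfdx = (Qs[i] * Qs[i] / As[i]
                            - Qs[i - 1] * Qs[i - 1] / As[i - 1]) / dx
                    dpdx = (Ps[i] - Ps[i - 1]) / dx
                    Anew = 0.5 * (A[i] + As[i] - dt * dqdx)
                    Qnew = 0.5 * (Q[i] + Qs[i]
                                  - dt * (dfdx + (As[i] / rho) * dpdx
                                          + fric * Qs[i] / As[i]))
                    A[i] = Anew
                    Q[i] = Qnew

            # --- implicit wall-viscosity diffusion (split step) ---
            _viscoelastic_diffuse(A, Q, seg_off, seg_nn, seg_dx, A0,
                                  seg_Gamma, rho, dt,
                                  tri_lo, tri_di, tri_up, tri_rhs)

            # --- inlet boundary ---
            i0 = seg_off[inlet_seg]
            b_in = seg_b[inlet_seg]
            c1 = _csound(A[i0 + 1], A0[i0 + 1], c0[i0 + 1], b_in)
            Wm = Q[i0 + 1] / A[i0 + 1] - (4.0 / b_in) * (c1 - c0[i0 + 1])
            if inlet_kind == INLET_HEART:
                phase_v = t_phase - heart_par[6]
                phase_v -= np.floor(phase_v)
                phase_a = t_phase - heart_par[12]
                phase_a -= np.floor(phase_a)
                Elv = heart_par[1] + (heart_par[2] - heart_par[1]) * \
                    _activation(phase_v, heart_par[4], heart_par[5])
                Ela = heart_par[7] + (heart_par[8] - heart_par[7]) * \
                    _activation(phase_a, heart_par[10], heart_par[11])
                P_lv = Elv * (heart_state[1] - heart_par[3])
                P_la = Ela * (heart_state[0] - heart_par[9])
                # implicit aortic-valve / characteristic coupling
                Ab, Q_av = _solve_inlet_valve(
                    P_lv, heart_par[14], Wm, A[i0], A0[i0], c0[i0], b_in,
                    rho, seg_P0[inlet_seg], seg_Pext[inlet_seg])
                if Q_av <= 0.0:
                    Ab = _solve_inlet_area(0.0, Wm, A[i0],
                                           A0[i0], c0[i0], b_in)
                    Q_av = 0.0
                Q_mv = (P_la - P_lv) / heart_par[13]
                if Q_mv < 0.0:
                    Q_mv = 0.0
                Q_ven = (heart_par[16] - P_la) / heart_par[15]
                heart_state[0] += dt * (Q_ven - Q_mv)
                heart_state[1] += dt * (Q_mv - Q_av)
                Q_in = Q_av
                A[i0] = Ab
                Q[i0] = Q_in
            else:
                Q_in = qin_prescribed[k]
                A[i0] = _solve_inlet_area(Q_in, Wm, A[i0],
                                          A0[i0], c0[i0], b_in)
                Q[i0] = Q_in
            q_valve[k] = Q_in
            v_la[k] = heart_state[0]
            v_lv[k] = heart_state[1]

            # --- junction boundaries ---
            for j in range(nj):
                ps = jparent[j]
                m = jnchild[j]
                pi = seg_off[ps] + seg_nn[ps] - 1
                bp = seg_b[ps]
                cpm1 = _csound(A[pi - 1], A0[pi - 1], c0[pi - 1], bp)
                Wps = Q[pi - 1] / A[pi - 1] + (4.0 / bp) * (cpm1 - c0[pi - 1])
                for i in range(m):
                    cs = jchild[j, i]
                    ciN = seg_off[cs]
                    bci = seg_b[cs]
                    cc1 = _csound(A[ciN + 1], A0[ciN + 1], c0[ciN + 1], bci)
                    cWm[i] = Q[ciN + 1] / A[ciN + 1] \
                        - (4.0 / bci) * (cc1 - c0[ciN + 1])
                    cA0[i] = A0[ciN]
                    cC0[i] = c0[ciN]
                    cB[i] = bci
                    cAg[i] = A[ciN]
                res = _junction_solve(
                    A[pi], A0[pi], c0[pi], bp, Wps,
                    cAg, cA0, cC0, cB, cWm, m, rho,
                    seg_P0[ps], seg_Pext[ps], jA, jU)
                if res > mass_res_max:
                    mass_res_max = res
                A[pi] = jA[0]
                Q[pi] = jA[0] * jU[0]
                for i in range(m):
                    cs = jchild[j, i]
                    ciN = seg_off[cs]
                    A[ciN] = jA[1 + i]
                    Q[ciN] = jA[1 + i] * jU[1 + i]

            # --- outlet boundaries ---
            for o in range(no):
                s = out_seg[o]
                i1 = seg_off[s] + seg_nn[s] - 1
                b_o = seg_b[s]
                cm1 = _csound(A[i1 - 1], A0[i1 - 1], c0[i1 - 1], b_o)
                Wp = Q[i1 - 1] / A[i1 - 1] + (4.0 / b_o) * (cm1 - c0[i1 - 1])
                if out_kind[o] == OUT_WK3:
                    Ab, ub = _solve_outlet_wk3(
                        Wp, A[i1], A0[i1], c0[i1], b_o, rho,
                        seg_P0[s], seg_Pext[s], out_Zc[o], out_Pc[o])
                    A[i1] = Ab
                    Q[i1] = Ab * ub
                    rc = out_R[o] * out_C[o]
                    out_Pc[o] = (out_Pc[o] + dt / out_C[o]
                                 * (Q[i1] + out_Pout[o] / out_R[o])) \
                        / (1.0 + dt / rc)
                elif out_kind[o] == OUT_CLOSED:
                    cb = c0[i1] + 0.25 * b_o * Wp
                    A[i1] = _area_from_c(cb, A0[i1], c0[i1], b_o)
                    Q[i1] = 0.0
                else:  # absorbing
                    ub = 0.5 * Wp
                    cb = c0[i1] + 0.25 * b_o * ub
                    A[i1] = _area_from_c(cb, A0[i1], c0[i1], b_o)
                    Q[i1] = A[i1] * ub

            # --- record + divergence check ---
            bad = False
            for i in range(ncell):
                if not (A[i] > 0.0) or not np.isfinite(Q[i]):
                    bad = True
                    break
            if bad:
                return cycles_run, diff, mass_res_max, 1
            _compute_pressure(A, Q, P, seg_off, seg_nn, seg_dx, A0, c0,
                              seg_b, seg_gamma, seg_Gamma, seg_P0, seg_Pext,
                              rho, 1)
            for i in range(ncell):
                P_curr[k, i] = P[i]
                Q_curr[k, i] = Q[i]

        cycles_run = cyc + 1
        diff = 0.0
        for k in range(steps_per_cycle):
            for i in range(ncell):
                d = abs(P_curr[k, i] - P_prev[k, i])
                if d > diff:
                    diff = d
        if diff < tol_pa:
            return cycles_run, diff, mass_res_max, 0
        for k in range(steps_per_cycle):
            for i in range(ncell):
                P_prev[k, i] = P_curr[k, i]

    return cycles_run, diff, mass_res_max, 0
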