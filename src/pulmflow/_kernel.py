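"""Compiled time-stepping kernel for the proximal 1D solver.

One call advances the full network state by one cardiac cycle with the
two-step (Richtmyer) Lax-Wendroff scheme on the interior and characteristic
closures at every boundary: prescribed inlet flow, prescribed outlet
pressure, junction solves (flow conservation + static-pressure continuity)
and structured-tree bed coupling by discrete periodic convolution.

All state lives in flat arrays indexed by per-vessel offsets; the wall law is
p = (4/3) K (sqrt(A/A0) - 1), giving wave speed c = c0 (A/A0)^(1/4) with
c0 = sqrt(2K/(3 rho)) and Riemann invariants W+- = u +- 4 (c - c0).

Status codes: 0 ok, 1 CFL violation, 2 Newton failure, 3 nonpositive area.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CFL = 1
STATUS_NEWTON = 2
STATUS_AREA = 3


@njit(cache=True)
def _press(A, K, A0):
    return (4.0 / 3.0) * K * (np.sqrt(A / A0) - 1.0)


@njit(cache=True)
def _cspeed(A, K, A0, c0):
    return c0 * (A / A0) ** 0.25


@njit(cache=True)
def _flux2(A, q, K, A0, rho, delta):
    # momentum flux: delta q^2/A + B(A), B' = c^2
    B = (4.0 * K / (9.0 * rho)) * (A * np.sqrt(A) - A0 * np.sqrt(A0)) / np.sqrt(A0)
    return delta * q * q / A + B


@njit(cache=True)
def _foot_invariant(A, q, o, m, v_dx, K, A0, c0, fc, dt, at_L):
    """Outgoing Riemann invariant at t+dt extrapolated along the
    characteristic foot, with the friction source integrated forward."""
    if at_L:
        ib = o + m - 1
        ii = ib - 1
    else:
        ib = o
        ii = o + 1
    ub = q[ib] / A[ib]
    cb = _cspeed(A[ib], K, A0, c0)
    ui = q[ii] / A[ii]
    ci = _cspeed(A[ii], K, A0, c0)
    if at_L:
        lam = ub + cb
        Wb = ub + 4.0 * (cb - c0)
        Wi = ui + 4.0 * (ci - c0)
    else:
        lam = -(ub - cb)
        Wb = ub - 4.0 * (cb - c0)
        Wi = ui - 4.0 * (ci - c0)
    xi = lam * dt
    if xi < 0.0:
        xi = 0.0
    if xi > v_dx:
        xi = v_dx
    th = xi / v_dx
    src = fc * q[ib] / (A[ib] * A[ib])
    return (1.0 - th) * Wb + th * Wi + dt * src


@njit(cache=True)
def run_cycle(
    A, q, Anew, qnew, Ah, qh,
    off, nn, dx, K, A0, c0,
    dt, n_steps, rho, nu, gamma,
    q_in, inlet_v,
    out_v, p_out,
    jn_n, jn_vs, jn_end,
    bed_art, bed_vein, kern, h, stride, dtau, p_hist,
    newton_tol, newton_maxit,
    monA, monQ, store_full, fullA, fullQ,
):
    nv = off.size
    delta = (gamma + 2.0) / (gamma + 1.0)
    fc = -2.0 * np.pi * nu * (gamma + 2.0)
    n_out = out_v.size
    n_jn = jn_n.size
    nb = bed_art.size
    M = kern.shape[3] if nb > 0 else 0

    for n in range(n_steps):
        idx1 = (n + 1) % n_steps
        cfl_max = 0.0

        # ---- interior: two-step Lax-Wendroff --------------------------------
        for v in range(nv):
            o = off[v]
            m = nn[v]
            d = dx[v]
            kv = K[v]
            a0 = A0[v]
            cv0 = c0[v]
            r = dt / d
            for j in range(m - 1):
                Al = A[o + j]
                Ar = A[o + j + 1]
                ql = q[o + j]
                qr = q[o + j + 1]
                F2l = _flux2(Al, ql, kv, a0, rho, delta)
                F2r = _flux2(Ar, qr, kv, a0, rho, delta)
                S2l = fc * ql / Al
                S2r = fc * qr / Ar
                Ah[o + j] = 0.5 * (Al + Ar) - 0.5 * r * (qr - ql)
                qh[o + j] = (
                    0.5 * (ql + qr) - 0.5 * r * (F2r - F2l)
                    + 0.25 * dt * (S2l + S2r)
                )
                if Ah[o + j] <= 0.0:
                    return STATUS_AREA, v, n
                lam = abs(ql / Al) + _cspeed(Al, kv, a0, cv0)
                if lam * r > cfl_max:
                    cfl_max = lam * r
            lam = abs(q[o + m - 1] / A[o + m - 1]) + _cspeed(
                A[o + m - 1], kv, a0, cv0
            )
            if lam * r > cfl_max:
                cfl_max = lam * r
            for j in range(1, m - 1):
                F2l = _flux2(Ah[o + j - 1], qh[o + j - 1], kv, a0, rho, delta)
                F2r = _flux2(Ah[o + j], qh[o + j], kv, a0, rho, delta)
                S2l = fc * qh[o + j - 1] / Ah[o + j - 1]
                S2r = fc * qh[o + j] / Ah[o + j]
                Anew[o + j] = A[o + j] - r * (qh[o + j] - qh[o + j - 1])
                qnew[o + j] = q[o + j] - r * (F2r - F2l) + 0.5 * dt * (S2l + S2r)
                if Anew[o + j] <= 0.0:
                    return STATUS_AREA, v, n

        if cfl_max > 1.0:
            return STATUS_CFL, -1, n

        # ---- inlet: prescribed flow, W- closes the area ---------------------
        v = inlet_v
        o = off[v]
        Wm = _foot_invariant(A, q, o, nn[v], dx[v], K[v], A0[v], c0[v], fc, dt, False)
        qt = q_in[idx1]
        Ab = A[o]
        ok = False
        for _ in range(newton_maxit):
            cb = _cspeed(Ab, K[v], A0[v], c0[v])
            R = qt / Ab - 4.0 * (cb - c0[v]) - Wm
            dR = -qt / (Ab * Ab) - cb / Ab
            step = R / dR
            Ab -= step
            if Ab < 1e-10:
                Ab = 1e-10
            if abs(R) < newton_tol * (1.0 + abs(qt)):
                ok = True
                break
        if not ok:
            return STATUS_NEWTON, v, n
        Anew[o] = Ab
        qnew[o] = qt

        # ---- outlets: prescribed pressure -----------------------------------
        for k in range(n_out):
            v = out_v[k]
            o = off[v]
            m = nn[v]
            Wp = _foot_invariant(
                A, q, o, m, dx[v], K[v], A0[v], c0[v], fc, dt, True
            )
            s = 1.0 + 0.75 * p_out[k, idx1] / K[v]
            if s <= 0.05:
                return STATUS_AREA, v, n
            Ab = A0[v] * s * s
            cb = _cspeed(Ab, K[v], A0[v], c0[v])
            ub = Wp - 4.0 * (cb - c0[v])
            Anew[o + m - 1] = Ab
            qnew[o + m - 1] = ub * Ab

        # ---- junctions: flow conservation + pressure continuity -------------
        for jn in range(n_jn):
            nm = jn_n[jn]
            # pre-extract member data (junctions have at most 3 members)
            W = np.empty(3)
            pstar = 0.0
            for k in range(nm):
                v = jn_vs[jn, k]
                e = jn_end[jn, k]
                W[k] = _foot_invariant(
                    A, q, off[v], nn[v], dx[v], K[v], A0[v], c0[v], fc, dt,
                    e == 1,
                )
                if k == 0:
                    ib = off[v] + (nn[v] - 1 if e == 1 else 0)
                    pstar = _press(A[ib], K[v], A0[v])
            ok = False
            for _ in range(newton_maxit):
                f = 0.0
                df = 0.0
                qscale = 1.0
                for k in range(nm):
                    v = jn_vs[jn, k]
                    e = jn_end[jn, k]
                    s = 1.0 + 0.75 * pstar / K[v]
                    if s < 0.05:
                        s = 0.05
                    Am = A0[v] * s * s
                    cm = c0[v] * np.sqrt(s)
                    dAdp = 1.5 * A0[v] * s / K[v]
                    dcdp = 3.0 * c0[v] / (8.0 * K[v] * np.sqrt(s))
                    if e == 1:
                        um = W[k] - 4.0 * (cm - c0[v])
                        dudp = -4.0 * dcdp
                        sgn = 1.0
                    else:
                        um = W[k] + 4.0 * (cm - c0[v])
                        dudp = 4.0 * dcdp
                        sgn = -1.0
                    f += sgn * um * Am
                    df += sgn * (um * dAdp + Am * dudp)
                    if abs(um * Am) > qscale:
                        qscale = abs(um * Am)
                pstar -= f / df
                if abs(f) < newton_tol * qscale:
                    ok = True
                    break
            if not ok:
                return STATUS_NEWTON, -(jn + 1), n
            for k in range(nm):
                v = jn_vs[jn, k]
                e = jn_end[jn, k]
                s = 1.0 + 0.75 * pstar / K[v]
                if s < 0.05:
                    s = 0.05
                Am = A0[v] * s * s
                cm = c0[v] * np.sqrt(s)
                if e == 1:
                    um = W[k] - 4.0 * (cm - c0[v])
                    ib = off[v] + nn[v] - 1
                else:
                    um = W[k] + 4.0 * (cm - c0[v])
                    ib = off[v]
                Anew[ib] = Am
                qnew[ib] = um * Am

        # ---- structured-tree beds: convolution coupling ---------------------
        for b in range(nb):
            va = bed_art[b]
            vv = bed_vein[b]
            oa = off[va] + nn[va] - 1
            ov = off[vv]
            Wp = _foot_invariant(
                A, q, off[va], nn[va], dx[va], K[va], A0[va], c0[va], fc, dt, True
            )
            Wm = _foot_invariant(
                A, q, off[vv], nn[vv], dx[vv], K[vv], A0[vv], c0[vv], fc, dt, False
            )
            hist1 = 0.0
            hist2 = 0.0
            for mm in range(1, M):
                ii = (idx1 - mm * stride) % n_steps
                pa = p_hist[b, 0, ii]
                pv = p_hist[b, 1, ii]
                hist1 += kern[b, 0, 0, mm] * pa + kern[b, 0, 1, mm] * pv
                hist2 += kern[b, 1, 0, mm] * pa + kern[b, 1, 1, mm] * pv
            hist1 *= dtau
            hist2 *= dtau

            Aa = A[oa]
            Av = A[ov]
            ok = False
            for _ in range(newton_maxit):
                pa = _press(Aa, K[va], A0[va])
                pv = _press(Av, K[vv], A0[vv])
                ca = _cspeed(Aa, K[va], A0[va], c0[va])
                cv = _cspeed(Av, K[vv], A0[vv], c0[vv])
                ua = Wp - 4.0 * (ca - c0[va])
                uv = Wm + 4.0 * (cv - c0[vv])
                dpa = (2.0 / 3.0) * K[va] / np.sqrt(Aa * A0[va])
                dpv = (2.0 / 3.0) * K[vv] / np.sqrt(Av * A0[vv])
                R1 = ua * Aa - (h[b, 0, 0] * pa + h[b, 0, 1] * pv + hist1)
                R2 = uv * Av - (h[b, 1, 0] * pa + h[b, 1, 1] * pv + hist2)
                qs = abs(ua * Aa)
                if abs(uv * Av) > qs:
                    qs = abs(uv * Av)
                if qs < 1.0:
                    qs = 1.0
                if abs(R1) + abs(R2) < newton_tol * qs:
                    ok = True
                    break
                J11 = ua - ca - h[b, 0, 0] * dpa
                J12 = -h[b, 0, 1] * dpv
                J21 = -h[b, 1, 0] * dpa
                J22 = uv + cv - h[b, 1, 1] * dpv
                det = J11 * J22 - J12 * J21
                dAa = (R1 * J22 - R2 * J12) / det
                dAv = (R2 * J11 - R1 * J21) / det
                Aa -= dAa
                Av -= dAv
                if Aa < 1e-10:
                    Aa = 1e-10
                if Av < 1e-10:
                    Av = 1e-10
            if not ok:
                return STATUS_NEWTON, 1000 + b, n
            pa = _press(Aa, K[va], A0[va])
            pv = _press(Av, K[vv], A0[vv])
            ca = _cspeed(Aa, K[va], A0[va], c0[va])
            cv = _cspeed(Av, K[vv], A0[vv], c0[vv])
            Anew[oa] = Aa
            qnew[oa] = (Wp - 4.0 * (ca - c0[va])) * Aa
            Anew[ov] = Av
            qnew[ov] = (Wm + 4.0 * (cv - c0[vv])) * Av
            p_hist[b, 0, idx1] = pa
            p_hist[b, 1, idx1] = pv

        # ---- commit and record ---------------------------------------------
        for i in range(A.size):
            A[i] = Anew[i]
            q[i] = qnew[i]
        for v in range(nv):
            o = off[v]
            m = nn[v]
            mid = o + (m - 1) // 2
            monA[v, 0, n] = A[o]
            monA[v, 1, n] = A[mid]
            monA[v, 2, n] = A[o + m - 1]
            monQ[v, 0, n] = q[o]
            monQ[v, 1, n] = q[mid]
            monQ[v, 2, n] = q[o + m - 1]
        if store_full:
            for i in range(A.size):
                fullA[i, n] = A[i]
                fullQ[i, n] = q[i]

    return STATUS_OK, 0, n_steps
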