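"""Compiled fixed-step RK4 integrator for the six-state dissolution/PK system.

Used where many thousands of solves are needed (population estimation,
Monte Carlo prediction).  Classical RK4 preserves linear invariants, so the
mass balance holds to machine precision on this system; step-size accuracy
against the adaptive stiff solver is checked in the test suite.

The dissolved fraction is evaluated twice per step (endpoints shared with
the next step, the midpoint reused by the two middle stages); the Hill
denominators' constant powers are hoisted out of the time loop and the
stages are unrolled into scalars to avoid per-step allocation.

Parameter vector layout (dose-normalized release, L/h clearances):
  0 imax  1 t_get  2 hill_stomach  3 diss_max  4 t_itt  5 t_ctt
  6 hill_intestine  7 vmax_invivo  8 am50_invivo  9 k_lag  10 k_a
  11 v1  12 v2  13 cl  14 cld
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _f_diss_c(t, imax, hs, tget_hs, dmax, hi, t1_hi, t2_hi):
    if t <= 0.0:
        return 1.0
    th = t**hs
    stom = 1.0 - imax * th / (tget_hs + th)
    ti = t**hi
    rise = ti / (t1_hi + ti)
    fall = 1.0 - ti / (t2_hi + ti)
    return stom + dmax * rise * fall


@njit(cache=True)
def _integrate_into(p, dose, t_grid, h_max, out):
    imax, tget, hs = p[0], p[1], p[2]
    dmax, titt, tctt, hi = p[3], p[4], p[5], p[6]
    vmax, am50 = p[7], p[8]
    klag, ka, v1, v2, cl, cld = p[9], p[10], p[11], p[12], p[13], p[14]
    tget_hs = tget**hs
    t1_hi = (tget + titt) ** hi
    t2_hi = (tget + titt + tctt) ** hi

    n = t_grid.shape[0]
    xt, xl, xg, x1, x2, xe = 1.0, 0.0, 0.0, 0.0, 0.0, 0.0
    t = 0.0
    f_lo = 1.0
    for i in range(n):
        target = t_grid[i]
        while t < target - 1e-12:
            h = target - t
            if h > h_max:
                h = h_max
            f_mid = _f_diss_c(t + 0.5 * h, imax, hs, tget_hs, dmax, hi, t1_hi, t2_hi)
            f_hi = _f_diss_c(t + h, imax, hs, tget_hs, dmax, hi, t1_hi, t2_hi)

            rel = vmax * xt / (am50 + xt) * f_lo
            c1 = x1 / v1
            c2 = x2 / v2
            k1_0 = -rel
            k1_1 = rel - klag * xl
            k1_2 = klag * xl - ka * xg
            k1_3 = ka * xg * dose - cld * c1 + cld * c2 - cl * c1
            k1_4 = cld * c1 - cld * c2
            k1_5 = cl * c1

            a0 = xt + 0.5 * h * k1_0
            a1 = xl + 0.5 * h * k1_1
            a2 = xg + 0.5 * h * k1_2
            a3 = x1 + 0.5 * h * k1_3
            a4 = x2 + 0.5 * h * k1_4
            rel = vmax * a0 / (am50 + a0) * f_mid
            c1 = a3 / v1
            c2 = a4 / v2
            k2_0 = -rel
            k2_1 = rel - klag * a1
            k2_2 = klag * a1 - ka * a2
            k2_3 = ka * a2 * dose - cld * c1 + cld * c2 - cl * c1
            k2_4 = cld * c1 - cld * c2
            k2_5 = cl * c1

            a0 = xt + 0.5 * h * k2_0
            a1 = xl + 0.5 * h * k2_1
            a2 = xg + 0.5 * h * k2_2
            a3 = x1 + 0.5 * h * k2_3
            a4 = x2 + 0.5 * h * k2_4
            rel = vmax * a0 / (am50 + a0) * f_mid
            c1 = a3 / v1
            c2 = a4 / v2
            k3_0 = -rel
            k3_1 = rel - klag * a1
            k3_2 = klag * a1 - ka * a2
            k3_3 = ka * a2 * dose - cld * c1 + cld * c2 - cl * c1
            k3_4 = cld * c1 - cld * c2
            k3_5 = cl * c1

            a0 = xt + h * k3_0
            a1 = xl + h * k3_1
            a2 = xg + h * k3_2
            a3 = x1 + h * k3_3
            a4 = x2 + h * k3_4
            rel = vmax * a0 / (am50 + a0) * f_hi
            c1 = a3 / v1
            c2 = a4 / v2
            k4_0 = -rel
            k4_1 = rel - klag * a1
            k4_2 = klag * a1 - ka * a2
            k4_3 = ka * a2 * dose - cld * c1 + cld * c2 - cl * c1
            k4_4 = cld * c1 - cld * c2
            k4_5 = cl * c1

            w = h / 6.0
            xt += w * (k1_0 + 2.0 * (k2_0 + k3_0) + k4_0)
            xl += w * (k1_1 + 2.0 * (k2_1 + k3_1) + k4_1)
            xg += w * (k1_2 + 2.0 * (k2_2 + k3_2) + k4_2)
            x1 += w * (k1_3 + 2.0 * (k2_3 + k3_3) + k4_3)
            x2 += w * (k1_4 + 2.0 * (k2_4 + k3_4) + k4_4)
            xe += w * (k1_5 + 2.0 * (k2_5 + k3_5) + k4_5)
            if xt < 0.0:
                xt = 0.0
            t += h
            f_lo = f_hi
        out[i, 0] = xt
        out[i, 1] = xl
        out[i, 2] = xg
        out[i, 3] = x1
        out[i, 4] = x2
        out[i, 5] = xe


@njit(cache=True)
def rk4_integrate(p, dose, t_grid, h_max):
    """Integrate from rest (whole dose in the tablet) and return the states
    at ``t_grid`` (increasing, t_grid[0] >= 0); shape (len(t_grid), 6)."""
    out = np.empty((t_grid.shape[0], 6))
    _integrate_into(p, dose, t_grid, h_max, out)
    return out


@njit(cache=True)
def rk4_conc_batch(pvecs, dose, times, h_max):
    """Central-compartment concentrations (ng/mL) at ``times`` for a batch
    of parameter vectors; shape (len(pvecs), len(times))."""
    m = pvecs.shape[0]
    n = times.shape[0]
    out = np.empty((m, n))
    states = np.empty((n, 6))
    for i in range(m):
        _integrate_into(pvecs[i], dose, times, h_max, states)
        v1 = pvecs[i, 11]
        for j in range(n):
            out[i, j] = states[j, 3] / v1 * 1000.0
    return out
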