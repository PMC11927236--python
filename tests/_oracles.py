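"""Independent reference implementations used only to check the package.

These deliberately avoid the package's integration code paths: a fixed-step
classical RK4 integrator (numba-compiled) for the coupled system, and the
closed-form logistic solution for drug-free growth.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _deriv(y, vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs):
    xe, xf, xb, n = y
    xbp = xb if xb > 0.0 else 0.0
    k_ef = vmax * xbp**hn / (kth**hd + xbp**hd)
    kd = kdmax * xbp / (xbhs + xbp)
    return np.array(
        [
            k_ef * (vi / ve) * xf - kfe * xe,
            kfe * (ve / vi) * xe - k_ef * xf - kbf * xf,
            kbf * xf - gamma * xb,
            kp * n * (1.0 - n / theta) - kd * n,
        ]
    )


@njit(cache=False)
def _rk4_run(y, t0, n_steps, h, record_steps, pars):
    (vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs) = pars
    out = np.empty((record_steps.size, 4))
    j = 0
    if record_steps.size and record_steps[0] == 0:
        out[0] = y
        j = 1
    for i in range(n_steps):
        k1 = _deriv(y, vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs)
        k2 = _deriv(y + 0.5 * h * k1, vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs)
        k3 = _deriv(y + 0.5 * h * k2, vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs)
        k4 = _deriv(y + h * k3, vmax, kth, kfe, kbf, ve, vi, gamma, hn, hd, kp, theta, kdmax, xbhs)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        while j < record_steps.size and record_steps[j] == i + 1:
            out[j] = y
            j += 1
    return out


def rk4_bolus_reference(pk, pd_, dose, n0, grid, exposure_h=3.0, t_start=0.0, h=1e-3):
    """Fixed-step RK4 solution of the coupled system for a single bolus.

    The bolus is applied at ``t_start`` (XE jumps by ``dose``) and washed out
    ``exposure_h`` later (XE reset to 0). ``grid`` times must be multiples
    of ``h`` away from ``t_start``. Returns an (len(grid), 4) state array.
    """
    grid = np.asarray(grid, dtype=float)
    pars = (
        pk.vmax, pk.kth, pk.k_fe, pk.k_bf, pk.v_e, pk.v_i, pk.gamma,
        pk.hill_num, pk.hill_den, pd_.k_p, pd_.theta, pd_.kd_max, pd_.xb_hs,
    )
    t_wash = t_start + exposure_h
    y = np.array([float(dose), 0.0, 0.0, float(n0)])
    out = np.empty((grid.size, 4))

    # phase 1: exposure
    in1 = grid <= t_wash
    steps1 = int(round((t_wash - t_start) / h))
    rec1 = np.round((grid[in1] - t_start) / h).astype(np.int64)
    out[in1] = _rk4_run(y, t_start, steps1, h, rec1, pars)
    # recompute the end state exactly (grid may not include t_wash)
    y_end = _rk4_run(y, t_start, steps1, h, np.array([steps1], dtype=np.int64), pars)[0]
    y_end[0] = 0.0  # washout

    in2 = grid > t_wash
    if in2.any():
        steps2 = int(round((grid[-1] - t_wash) / h))
        rec2 = np.round((grid[in2] - t_wash) / h).astype(np.int64)
        out[in2] = _rk4_run(y_end, t_wash, steps2, h, rec2, pars)
    return out


def logistic_closed_form(times, n0, k_p, theta):
    times = np.asarray(times, dtype=float)
    return theta / (1.0 + (theta / n0 - 1.0) * np.exp(-k_p * times))
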