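"""Jitted fixed-step RK4 kernel for the two-mass model.

The parameter inversion loop evaluates tens of thousands of forward
simulations, so the inner loop is compiled with numba.  The readable
NumPy implementation of the same vector field lives in
:mod:`voicefold.model` (``derivatives``) and the test-suite checks the
two against each other; this file is deliberately plain scalar code.

State layout (length 8): [x1l, x2l, x1r, x2r, v1l, v2l, v1r, v2r].
Parameter vector layout (length 21):
  [0:9]   left side  m1, m2, k1, k2, kc, c1, c2, r1, r2
  [9:18]  right side m1, m2, k1, k2, kc, c1, c2, r1, r2
  [18]    a01, [19] a02, [20] L, [21] d, [22] Ps, [23] rho, [24] x0,
  [25] beta, [26] hard_switch (0/1)
"""

import numpy as np
from numba import njit

NPAR = 27


@njit(cache=True, fastmath=False)
def _omega(x, x0, hard):
    if x <= 0.0:
        return 0.0
    if hard:
        return 1.0
    return np.tanh(50.0 * x / x0)


@njit(cache=True, fastmath=False)
def _deriv(y, p, dy):
    x1l, x2l, x1r, x2r = y[0], y[1], y[2], y[3]
    v1l, v2l, v1r, v2r = y[4], y[5], y[6], y[7]

    a01, a02, L, d = p[18], p[19], p[20], p[21]
    Ps, x0 = p[22], p[24]
    beta = p[25]
    hard = p[26] != 0.0

    a1 = a01 + L * (x1l + x1r)
    a2 = a02 + L * (x2l + x2r)
    amin = min(a1, a2)

    # driving pressure on the lower masses (zero once the glottis closes)
    og1 = _omega(a1, x0, hard)
    if og1 > 0.0:
        q = amin / max(a1, 1e-12)
        P1 = Ps * (1.0 - _omega(amin, x0, hard) * q * q) * og1
    else:
        P1 = 0.0

    m1l, m2l = p[0], p[1]
    k1l, k2l, kcl = p[2], p[3], p[4]
    c1l, c2l = p[5], p[6]
    r1l, r2l = p[7], p[8]
    m1r, m2r = p[9], p[10]
    k1r, k2r, kcr = p[11], p[12], p[13]
    c1r, c2r = p[14], p[15]
    r1r, r2r = p[16], p[17]

    F1l = L * d * P1 / m1l
    F1r = L * d * P1 / m1r

    # collision accelerations, momentum-consistent asymmetric form
    wl = beta / (beta + 1.0)
    wr = 1.0 / (beta + 1.0)
    I1l = I2l = I1r = I2r = 0.0
    if a1 < 0.0:
        I1l = -(c1l / m1l) * (a1 / L) * wl
        I1r = -(c1r / m1r) * (a1 / L) * wr
    if a2 < 0.0:
        I2l = -(c2l / m2l) * (a2 / L) * wl
        I2r = -(c2r / m2r) * (a2 / L) * wr

    dy[0] = v1l
    dy[1] = v2l
    dy[2] = v1r
    dy[3] = v2r
    dy[4] = F1l + I1l - (r1l * v1l + k1l * x1l + kcl * (x1l - x2l)) / m1l
    dy[5] = I2l - (r2l * v2l + k2l * x2l + kcl * (x2l - x1l)) / m2l
    dy[6] = F1r + I1r - (r1r * v1r + k1r * x1r + kcr * (x1r - x2r)) / m1r
    dy[7] = I2r - (r2r * v2r + k2r * x2r + kcr * (x2r - x1r)) / m2r


@njit(cache=True, fastmath=False)
def integrate_rk4(y0, p, dt, nsteps, xmax):
    """Fixed-step RK4 trajectory with per-step observables.

    Returns (Y, a1, a2, Ug, P1, n_ok) where n_ok is the number of valid
    samples (nsteps+1 if the run completed, fewer if |x| exceeded xmax).
    """
    n = nsteps + 1
    Y = np.empty((n, 8))
    A1 = np.empty(n)
    A2 = np.empty(n)
    UG = np.empty(n)
    P1A = np.empty(n)

    y = y0.copy()
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    yt = np.empty(8)

    a01, a02, L = p[18], p[19], p[20]
    Ps, rho = p[22], p[23]
    flow_coef = np.sqrt(2.0 * Ps / rho)
    x0 = p[24]
    hard = p[26] != 0.0

    for s in range(n):
        a1 = a01 + L * (y[0] + y[2])
        a2 = a02 + L * (y[1] + y[3])
        amin = min(a1, a2)
        Y[s] = y
        A1[s] = a1
        A2[s] = a2
        UG[s] = flow_coef * amin if amin > 0.0 else 0.0
        og1 = _omega(a1, x0, hard)
        if og1 > 0.0:
            q = amin / max(a1, 1e-12)
            P1A[s] = Ps * (1.0 - _omega(amin, x0, hard) * q * q) * og1
        else:
            P1A[s] = 0.0

        bad = False
        for j in range(4):
            if not np.isfinite(y[j]) or abs(y[j]) > xmax:
                bad = True
        if bad or not np.isfinite(y[4:]).all():
            return Y, A1, A2, UG, P1A, s

        if s == nsteps:
            break

        _deriv(y, p, k1)
        for j in range(8):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _deriv(yt, p, k2)
        for j in range(8):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _deriv(yt, p, k3)
        for j in range(8):
            yt[j] = y[j] + dt * k3[j]
        _deriv(yt, p, k4)
        for j in range(8):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

    return Y, A1, A2, UG, P1A, n
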