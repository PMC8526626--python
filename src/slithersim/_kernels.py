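"""Compiled right-hand side of the reduced dynamics (uniform substrates).

Numerically identical (to floating-point reassociation) to the reference
assembly in :mod:`slithersim.dynamics`; used by :func:`slithersim.simulate`
to keep parameter sweeps tractable.  Heterogeneous friction maps take the
pure-numpy path instead.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


TWO_PI = 2.0 * np.pi
LIFT_COSINE, LIFT_EXP, LIFT_NONE = 0, 1, 2


@njit(cache=True)
def _mean_zero(f, s, w, out):
    n = f.size
    out[0] = 0.0
    for i in range(1, n):
        out[i] = out[i - 1] + 0.5 * (f[i] + f[i - 1]) * (s[i] - s[i - 1])
    m = 0.0
    for i in range(n):
        m += w[i] * out[i]
    for i in range(n):
        out[i] -= m


@njit(cache=True)
def rhs_uniform(t, y, s, w, eps, k, A, phi, k_l, lift_code, mu_t, mu_b, fr, delta):
    n = s.size
    omega = TWO_PI * k

    kappa = np.empty(n)
    kappa_t = np.empty(n)
    kappa_tt = np.empty(n)
    for i in range(n):
        ph = omega * (s[i] + t)
        c = np.cos(ph)
        kappa[i] = eps * c
        kappa_t[i] = -omega * eps * np.sin(ph)
        kappa_tt[i] = -(omega * omega) * eps * c

    scratch = np.empty(n)
    _mean_zero(kappa, s, w, scratch)
    tx = np.empty(n)
    ty = np.empty(n)
    for i in range(n):
        a = y[4] + scratch[i]
        tx[i] = np.cos(a)
        ty[i] = np.sin(a)

    Ix = np.empty(n)
    Iy = np.empty(n)
    _mean_zero(tx, s, w, Ix)
    _mean_zero(ty, s, w, Iy)

    _mean_zero(kappa_t, s, w, scratch)
    alpha_t = np.empty(n)
    for i in range(n):
        alpha_t[i] = y[5] + scratch[i]

    # node velocities: v = com_vel + I[alpha_t * n], n = (-ty, tx)
    f1 = np.empty(n)
    f2 = np.empty(n)
    for i in range(n):
        f1[i] = alpha_t[i] * (-ty[i])
        f2[i] = alpha_t[i] * tx[i]
    vx = np.empty(n)
    vy = np.empty(n)
    _mean_zero(f1, s, w, vx)
    _mean_zero(f2, s, w, vy)
    for i in range(n):
        vx[i] += y[2]
        vy[i] += y[3]

    # normalised weight
    nhat = np.empty(n)
    if lift_code == LIFT_NONE:
        for i in range(n):
            nhat[i] = 1.0
    elif lift_code == LIFT_EXP:
        for i in range(n):
            nhat[i] = np.exp(-kappa[i])
    else:
        wl = TWO_PI * k_l
        for i in range(n):
            raw = A * np.cos(wl * (s[i] + t + phi)) + 1.0
            nhat[i] = raw if raw > 0.0 else 0.0
    total = 0.0
    for i in range(n):
        total += w[i] * nhat[i]

    # friction force density and its net force / torque
    fnx = 0.0
    fny = 0.0
    torque = 0.0
    J = 0.0
    for i in range(n):
        denom = np.sqrt(vx[i] * vx[i] + vy[i] * vy[i] + delta * delta)
        ux = vx[i] / denom
        uy = vy[i] / denom
        nxi = -ty[i]
        nyi = tx[i]
        un = ux * nxi + uy * nyi
        ut = ux * tx[i] + uy * ty[i]
        heav = 0.5 * (1.0 + np.sign(ut))
        fore = heav + mu_b * (1.0 - heav)
        mux = mu_t * un * nxi + fore * ut * tx[i]
        muy = mu_t * un * nyi + fore * ut * ty[i]
        Fx = -(nhat[i] / total) * mux
        Fy = -(nhat[i] / total) * muy
        fnx += w[i] * Fx
        fny += w[i] * Fy
        torque += w[i] * (Ix[i] * Fy - Iy[i] * Fx)
        J += w[i] * (Ix[i] * Ix[i] + Iy[i] * Iy[i])

    # inertial correction of the angular equation
    Inx = np.empty(n)
    Iny = np.empty(n)
    for i in range(n):
        f1[i] = -ty[i]
        f2[i] = tx[i]
    _mean_zero(f1, s, w, Inx)
    _mean_zero(f2, s, w, Iny)
    _mean_zero(kappa_tt, s, w, scratch)  # I[kappa_tt]
    for i in range(n):
        f1[i] = tx[i] * scratch[i]
        f2[i] = ty[i] * scratch[i]
    Itk1 = np.empty(n)
    Itk2 = np.empty(n)
    _mean_zero(f1, s, w, Itk1)
    _mean_zero(f2, s, w, Itk2)
    for i in range(n):
        a2 = alpha_t[i] * alpha_t[i]
        f1[i] = tx[i] * a2
        f2[i] = ty[i] * a2
    Iat1 = np.empty(n)
    Iat2 = np.empty(n)
    _mean_zero(f1, s, w, Iat1)
    _mean_zero(f2, s, w, Iat2)
    corr = 0.0
    for i in range(n):
        corr += w[i] * (Inx[i] * Iat1[i] + Iny[i] * Iat2[i] - Ix[i] * Itk1[i] - Iy[i] * Itk2[i])

    out = np.empty(6)
    out[0] = y[2]
    out[1] = y[3]
    out[2] = fnx / fr
    out[3] = fny / fr
    out[4] = y[5]
    out[5] = torque / (fr * J) + corr / J
    return out
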