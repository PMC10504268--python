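"""Numba-accelerated RK4 stepper for the five-species Min model.

Kept separate so the rest of the package imports cleanly when numba is
missing; the method-of-lines RHS here must stay in lockstep with
``mindyn.rhs`` (the reaction-only ODE oracle in the test suite checks it).
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _rhs(y, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k):
    n = y.shape[1]
    out = np.empty_like(y)
    inv2 = 1.0 / (dx * dx)
    for i in range(n):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < n - 1 else n - 1
        lap0 = (y[0, im] - 2.0 * y[0, i] + y[0, ip]) * inv2
        lap1 = (y[1, im] - 2.0 * y[1, i] + y[1, ip]) * inv2
        lap2 = (y[2, im] - 2.0 * y[2, i] + y[2, ip]) * inv2
        lap3 = (y[3, im] - 2.0 * y[3, i] + y[3, ip]) * inv2
        lap4 = (y[4, im] - 2.0 * y[4, i] + y[4, ip]) * inv2
        bind = (sD + sdD * (y[3, i] + y[4, i])) * y[1, i]
        hyd = sE * y[3, i] * y[2, i]
        rel = sde * y[4, i]
        exch = k * y[0, i]
        out[0, i] = D_D * lap0 - exch + rel
        out[1, i] = D_D * lap1 + exch - bind
        out[2, i] = D_E * lap2 - hyd + rel
        out[3, i] = D_m * lap3 + bind - hyd
        out[4, i] = D_m * lap4 + hyd - rel
    return out


@numba.njit(cache=True)
def step_rk4(y, dt, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k, n_sub):
    for _ in range(n_sub):
        k1 = _rhs(y, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k)
        k2 = _rhs(y + 0.5 * dt * k1, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k)
        k3 = _rhs(y + 0.5 * dt * k2, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k)
        k4 = _rhs(y + dt * k3, dx, D_D, D_E, D_m, sD, sdD, sE, sde, k)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y
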