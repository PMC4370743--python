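"""Red-black successive-over-relaxation sweeps for the PB grid.

The nonlinear Poisson-Boltzmann equation is relaxed with red-black
Gauss-Seidel: each node takes one damped Newton step on its local residual

    F(psi_c) = sum_f eps_f (psi_nbr - psi_c) + s * (q_c + h^3 rho_mob(psi_c))

with s = 4 pi l_B / h (l_B the vacuum Bjerrum length, psi in k_B T/e) and
rho_mob the Boltzmann-weighted mobile charge density, restricted to
ion-accessible nodes.  F' < 0 everywhere, so the update is always defined.

A numba-compiled kernel is used when numba is importable; otherwise a
vectorized numpy implementation with identical red-black semantics runs.
Both clamp the Boltzmann exponent at +/-40 to avoid overflow during early
sweeps far from the solution.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False

_CLAMP = 40.0


def _sweep_py(psi, ex, ey, ez, q_s, acc1, acc2, n_na, n_cl, n_mg, fac, omega, color):
    """One red-black half-sweep (numpy).  Returns max |delta psi|."""
    nx, ny, nz = psi.shape
    I, J, K = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1), indexing="ij"
    )
    mask = ((I + J + K) % 2) == color
    c = psi[1:-1, 1:-1, 1:-1]
    num = (
        ex[:-1, 1:-1, 1:-1] * psi[:-2, 1:-1, 1:-1]
        + ex[1:, 1:-1, 1:-1] * psi[2:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1] * psi[1:-1, :-2, 1:-1]
        + ey[1:-1, 1:, 1:-1] * psi[1:-1, 2:, 1:-1]
        + ez[1:-1, 1:-1, :-1] * psi[1:-1, 1:-1, :-2]
        + ez[1:-1, 1:-1, 1:] * psi[1:-1, 1:-1, 2:]
    )
    diag = (
        ex[:-1, 1:-1, 1:-1] + ex[1:, 1:-1, 1:-1]
        + ey[1:-1, :-1, 1:-1] + ey[1:-1, 1:, 1:-1]
        + ez[1:-1, 1:-1, :-1] + ez[1:-1, 1:-1, 1:]
    )
    p = np.clip(c, -_CLAMP, _CLAMP)
    a1 = acc1[1:-1, 1:-1, 1:-1]
    a2 = acc2[1:-1, 1:-1, 1:-1]
    em = np.exp(-p)
    ep = 1.0 / em
    em2 = em * em
    rho = a1 * (n_na * em - n_cl * ep) + a2 * (2.0 * n_mg * em2)
    drho = a1 * (n_na * em + n_cl * ep) + a2 * (4.0 * n_mg * em2)
    F = num - diag * c + q_s[1:-1, 1:-1, 1:-1] + fac * rho
    denom = diag + fac * drho
    delta = np.where(mask, omega * F / denom, 0.0)
    c += delta
    return float(np.abs(delta).max()) if delta.size else 0.0


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _sweep_nb(psi, ex, ey, ez, q_s, acc1, acc2, n_na, n_cl, n_mg, fac, omega, color):  # pragma: no cover
        nx, ny, nz = psi.shape
        maxd = 0.0
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                k0 = 1 + ((i + j + 1 + color) % 2)
                for k in range(k0, nz - 1, 2):
                    num = (
                        ex[i - 1, j, k] * psi[i - 1, j, k]
                        + ex[i, j, k] * psi[i + 1, j, k]
                        + ey[i, j - 1, k] * psi[i, j - 1, k]
                        + ey[i, j, k] * psi[i, j + 1, k]
                        + ez[i, j, k - 1] * psi[i, j, k - 1]
                        + ez[i, j, k] * psi[i, j, k + 1]
                    )
                    diag = (
                        ex[i - 1, j, k] + ex[i, j, k]
                        + ey[i, j - 1, k] + ey[i, j, k]
                        + ez[i, j, k - 1] + ez[i, j, k]
                    )
                    c = psi[i, j, k]
                    p = c
                    if p > _CLAMP:
                        p = _CLAMP
                    elif p < -_CLAMP:
                        p = -_CLAMP
                    em = np.exp(-p)
                    ep = 1.0 / em
                    a1 = acc1[i, j, k]
                    a2 = acc2[i, j, k]
                    rho = a1 * (n_na * em - n_cl * ep)
                    drho = a1 * (n_na * em + n_cl * ep)
                    if a2 > 0.0:
                        em2 = em * em
                        rho += a2 * 2.0 * n_mg * em2
                        drho += a2 * 4.0 * n_mg * em2
                    F = num - diag * c + q_s[i, j, k] + fac * rho
                    d = omega * F / (diag + fac * drho)
                    psi[i, j, k] = c + d
                    if d < 0.0:
                        d = -d
                    if d > maxd:
                        maxd = d
        return maxd


def sweep(psi, ex, ey, ez, q_s, acc1, acc2, n_na, n_cl, n_mg, fac, omega, color):
    if HAVE_NUMBA:
        return _sweep_nb(psi, ex, ey, ez, q_s, acc1, acc2, n_na, n_cl, n_mg, fac, omega, color)
    return _sweep_py(psi, ex, ey, ez, q_s, acc1, acc2, n_na, n_cl, n_mg, fac, omega, color)
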