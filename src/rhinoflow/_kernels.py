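"""Numba kernels for the D3Q19 lattice-Boltzmann update.

The solver state lives on an indexed list of fluid voxels (distributions
``f[N, 19]``); solid voxels are never touched.  Streaming uses the pull
scheme.  Neighbour codes in ``nbr``:

* ``>= 0`` - fluid source node (plain streaming),
* ``-1``   - static solid (half-way bounce-back),
* ``-2``   - moving wall (bounce-back with momentum correction); a wall
  moving with a normal velocity component injects/extracts mass at exactly
  ``rho0 * u_n`` per unit face area, which is how the Dirichlet flow-rate
  boundary is realised.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# D3Q19 velocity set: rest, 6 axis, 12 face-diagonal directions.
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

W = np.array(
    [1.0 / 3.0]
    + [1.0 / 18.0] * 6
    + [1.0 / 36.0] * 12,
    dtype=np.float64,
)

OPP = np.array(
    [0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17],
    dtype=np.int64,
)

_CF = C.astype(np.float64)


@njit(cache=True, fastmath=True)
def equilibrium(rho, ux, uy, uz, out):
    """D3Q19 second-order equilibrium for a single node, written into out[19]."""
    usq = ux * ux + uy * uy + uz * uz
    for i in range(19):
        cu = _CF[i, 0] * ux + _CF[i, 1] * uy + _CF[i, 2] * uz
        out[i] = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True, fastmath=True)
def init_equilibrium(f, rho0):
    n = f.shape[0]
    for k in range(n):
        for i in range(19):
            f[k, i] = W[i] * rho0


@njit(cache=True, fastmath=True)
def stream_collide(f, f_new, nbr, qtab, tau0, magic, use_les, smag_cs,
                   uwx, uwy, uwz, pres_idx):
    """One fused pull-stream + TRT collide sweep over all fluid nodes.

    Two-relaxation-time collision: the even rate is set by the shear
    viscosity (tau0, plus any Smagorinsky eddy contribution), the odd rate
    by the magic parameter ``Lambda = (tau+ - 1/2)(tau- - 1/2)``; the
    default 3/16 places the bounce-back wall at the half-link independent
    of viscosity.  ``magic <= 0`` recovers plain BGK.

    ``qtab[k, i]`` is the fractional wall distance along a ``-1`` link
    (Bouzidi linear interpolation; 0.5 reduces exactly to half-way
    bounce-back, which is the default for voxel-native geometry).

    (uwx, uwy, uwz) is the moving-wall lattice velocity applied to all
    ``-2``-coded links.  After collision, ambient-pressure nodes are
    overwritten with the equilibrium at rho = 1 and the local velocity.
    Returns the step's maximum |f| for divergence detection.
    """
    n = f.shape[0]
    fi = np.empty(19)
    feq = np.empty(19)
    fmax = 0.0
    for k in range(n):
        # pull streaming with (moving-wall / interpolated) bounce-back
        for i in range(19):
            src = nbr[k, i]
            if src >= 0:
                fi[i] = f[src, i]
            elif src == -1:
                q = qtab[k, i]
                if q == 0.5:
                    fi[i] = f[k, OPP[i]]
                elif q > 0.5:
                    a = 0.5 / q
                    fi[i] = a * f[k, OPP[i]] + (1.0 - a) * f[k, i]
                else:
                    j2 = nbr[k, OPP[i]]
                    if j2 >= 0:
                        b = 2.0 * q
                        fi[i] = b * f[k, OPP[i]] + (1.0 - b) * f[j2, OPP[i]]
                    else:
                        fi[i] = f[k, OPP[i]]
            else:
                cu = _CF[i, 0] * uwx + _CF[i, 1] * uwy + _CF[i, 2] * uwz
                fi[i] = f[k, OPP[i]] + 6.0 * W[i] * cu
        rho = 0.0
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for i in range(19):
            v = fi[i]
            rho += v
            ux += v * _CF[i, 0]
            uy += v * _CF[i, 1]
            uz += v * _CF[i, 2]
        inv = 1.0 / rho
        ux *= inv
        uy *= inv
        uz *= inv
        equilibrium(rho, ux, uy, uz, feq)
        tau = tau0
        if use_les:
            # Smagorinsky closure from the non-equilibrium momentum flux:
            # tau_eff = (tau0 + sqrt(tau0^2 + 18 Cs^2 |Pi| / rho)) / 2
            pxx = 0.0
            pyy = 0.0
            pzz = 0.0
            pxy = 0.0
            pxz = 0.0
            pyz = 0.0
            for i in range(19):
                fneq = fi[i] - feq[i]
                cx = _CF[i, 0]
                cy = _CF[i, 1]
                cz = _CF[i, 2]
                pxx += fneq * cx * cx
                pyy += fneq * cy * cy
                pzz += fneq * cz * cz
                pxy += fneq * cx * cy
                pxz += fneq * cx * cz
                pyz += fneq * cy * cz
            qn = np.sqrt(
                pxx * pxx + pyy * pyy + pzz * pzz
                + 2.0 * (pxy * pxy + pxz * pxz + pyz * pyz)
            )
            tau = 0.5 * (tau0 + np.sqrt(tau0 * tau0 + 18.0 * smag_cs * smag_cs * qn * inv))
        om_p = 1.0 / tau
        if magic > 0.0:
            om_m = 1.0 / (0.5 + magic / (tau - 0.5))
        else:
            om_m = om_p
        for i in range(19):
            j = OPP[i]
            fneq_p = 0.5 * ((fi[i] + fi[j]) - (feq[i] + feq[j]))
            fneq_m = 0.5 * ((fi[i] - fi[j]) - (feq[i] - feq[j]))
            v = fi[i] - om_p * fneq_p - om_m * fneq_m
            f_new[k, i] = v
            a = abs(v)
            if a > fmax:
                fmax = a
    # Ambient-pressure nodes (sphere surface / duct outlet)
    for m in range(pres_idx.shape[0]):
        k = pres_idx[m]
        rho = 0.0
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for i in range(19):
            v = f_new[k, i]
            rho += v
            ux += v * _CF[i, 0]
            uy += v * _CF[i, 1]
            uz += v * _CF[i, 2]
        inv = 1.0 / rho
        equilibrium(1.0, ux * inv, uy * inv, uz * inv, feq)
        for i in range(19):
            f_new[k, i] = feq[i]
    return fmax


@njit(cache=True, fastmath=True)
def run_steps(f, f_new, nbr, qtab, tau0, magic, use_les, smag_cs,
              uwx, uwy, uwz, pres_idx, nsteps):
    """Advance nsteps, ping-ponging f/f_new.  Returns (final_in_first, fmax)."""
    in_first = True
    fmax = 0.0
    for _ in range(nsteps):
        if in_first:
            fmax = stream_collide(f, f_new, nbr, qtab, tau0, magic, use_les,
                                  smag_cs, uwx, uwy, uwz, pres_idx)
        else:
            fmax = stream_collide(f_new, f, nbr, qtab, tau0, magic, use_les,
                                  smag_cs, uwx, uwy, uwz, pres_idx)
        in_first = not in_first
        if not np.isfinite(fmax):
            break
    return in_first, fmax


@njit(cache=True, fastmath=True)
def macroscopic(f, rho, u):
    n = f.shape[0]
    for k in range(n):
        r = 0.0
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for i in range(19):
            v = f[k, i]
            r += v
            ux += v * _CF[i, 0]
            uy += v * _CF[i, 1]
            uz += v * _CF[i, 2]
        rho[k] = r
        inv = 1.0 / r
        u[k, 0] = ux * inv
        u[k, 1] = uy * inv
        u[k, 2] = uz * inv
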