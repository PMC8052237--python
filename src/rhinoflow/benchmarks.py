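"""Analytic flow benchmarks for the lattice-Boltzmann solver.

The circular duct is the standard validation case: at low Reynolds number a
pressure-driven tube flow must reproduce the Hagen-Poiseuille law

    dp = 8 mu L Q / (pi R^4)

The duct is voxelized like an airway, but the side wall uses Bouzidi interpolated
bounce-back on the analytic cylinder surface so that the comparison
isolates solver physics from stair-casing; a piston (momentum-corrected
bounce-back) imposes the flow rate on the inlet plane, ambient pressure is
held on the outlet plane, and dp is measured between two interior
cross-sections in the developed region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lbm import LatticeConfig, LatticeDomain, run_to_stationary

__all__ = ["DuctBenchmark", "build_duct", "poiseuille_duct"]


def build_duct(radius_vox: float, length_vox: int):
    """Voxelize a straight circular duct along axis 0.

    Returns ``(fluid_mask, sdf)`` where a voxel is fluid when its centre
    lies within ``radius_vox`` of the duct axis; ``sdf`` is the signed
    distance to the cylinder wall (positive inside, lattice units).
    """
    d = int(2 * np.ceil(radius_vox)) + 3
    cy = cz = (d - 1) / 2.0
    yy, zz = np.meshgrid(np.arange(d), np.arange(d), indexing="ij")
    rr = np.sqrt((yy - cy) ** 2 + (zz - cz) ** 2)
    disc = rr <= radius_vox
    mask = np.zeros((length_vox, d, d), dtype=bool)
    mask[:] = disc[None, :, :]
    sdf = np.broadcast_to((radius_vox - rr)[None, :, :],
                          mask.shape).copy()
    return mask, sdf


@dataclass
class DuctBenchmark:
    """Outcome of one Poiseuille validation run."""

    dp_sim_pa: float
    dp_analytic_pa: float
    rel_err: float
    q_m3s: float              # measured volumetric flow at mid-plane
    reynolds: float
    converged: bool
    steps_run: int
    centerline_u: float       # m/s at the duct axis, mid-plane
    field: object


def poiseuille_duct(radius_vox: float = 10.0, length_vox: int = None,
                    u_lat: float = 0.015, tau: float = 0.8,
                    dx: float = 1.0e-3, les: bool = False,
                    max_steps: int = 40000,
                    cfg_overrides: dict = None) -> DuctBenchmark:
    """Run the circular-duct benchmark and compare with Hagen-Poiseuille.

    ``u_lat`` is the plug inlet velocity in lattice units; ``tau`` fixes the
    lattice viscosity.  The physical scaling (dx, dt, nu) is synthesized so
    that those lattice targets are met; the comparison is scale-invariant.
    """
    if length_vox is None:
        length_vox = int(radius_vox * 8)
    mask, sdf = build_duct(radius_vox, length_vox)

    # synthesize a physical scaling achieving (u_lat, tau) at this dx
    u_phys = 1.0                                  # m/s, arbitrary anchor
    dt = dx * u_lat / u_phys
    nu_lat = (tau - 0.5) / 3.0
    nu_phys = nu_lat * dx ** 2 / dt
    cfg = LatticeConfig(dx=dx, dt=dt, nu_phys=nu_phys, les=les,
                        max_steps=max_steps, stationarity_abs_pa=1e-12,
                        monitor_window=2000, check_every=100,
                        min_steps=2000)
    if cfg_overrides:
        for k, v in cfg_overrides.items():
            setattr(cfg, k, v)

    nx = length_vox
    # plane x=0 is the moving piston wall (flow-rate boundary)
    piston = np.zeros_like(mask)
    piston[0] = mask[0]
    mask = mask.copy()
    mask[0] = False
    outlet = np.zeros_like(mask)
    outlet[nx - 1] = mask[nx - 1]
    # probe planes: past the entrance length, away from the outlet
    xa, xb = int(0.5 * nx), int(0.85 * nx)
    pa = np.zeros_like(mask)
    pa[xa] = mask[xa]
    pb = np.zeros_like(mask)
    pb[xb] = mask[xb]

    lattice = LatticeDomain.from_masks(
        mask, moving_wall_mask=piston, wall_u=(u_lat, 0.0, 0.0),
        pres_mask=outlet, probe1_mask=pa, probe2_mask=pb, sdf=sdf)
    field = run_to_stationary(lattice, cfg)

    xm = (xa + xb) // 2
    ux = field.velocity[xm, :, :, 0]
    q = np.nansum(ux) * cfg.dx ** 2                       # m^3/s
    p_plane_a = np.nanmean(field.pressure[xa])
    p_plane_b = np.nanmean(field.pressure[xb])
    dp_sim = p_plane_a - p_plane_b

    # the interpolated wall sits exactly on the cylinder surface
    r_eff = radius_vox * cfg.dx
    length = (xb - xa) * cfg.dx
    mu = cfg.nu_phys * cfg.rho_phys
    dp_ana = 8.0 * mu * length * q / (np.pi * r_eff ** 4)
    reynolds = abs(q) / (np.pi * r_eff ** 2) * 2 * r_eff / cfg.nu_phys
    center = np.nanmax(ux)
    return DuctBenchmark(dp_sim_pa=float(dp_sim), dp_analytic_pa=float(dp_ana),
                         rel_err=float(abs(dp_sim - dp_ana) / abs(dp_ana)),
                         q_m3s=float(q), reynolds=float(reynolds),
                         converged=field.converged, steps_run=field.steps_run,
                         centerline_u=float(center), field=field)


def grid_refinement_pair(radius_coarse: float = 5.5, u_lat: float = 0.012,
                         tau_coarse: float = 0.65, dx_coarse: float = 2.0e-3):
    """Run the same physical duct at two resolutions (dx halved).

    Acoustic scaling (dt proportional to dx) holds the piston velocity and
    the physical viscosity fixed, so the fine lattice viscosity doubles:
    tau_fine = 1/2 + 2 (tau_coarse - 1/2).  Mesh convergence of the probe
    pressure drop mirrors the clinical workflow's mesh-independence check.
    """
    coarse = poiseuille_duct(radius_vox=radius_coarse,
                             length_vox=int(8 * radius_coarse),
                             u_lat=u_lat, tau=tau_coarse, dx=dx_coarse)
    tau_fine = 0.5 + 2.0 * (tau_coarse - 0.5)
    fine = poiseuille_duct(radius_vox=2 * radius_coarse,
                           length_vox=int(16 * radius_coarse),
                           u_lat=u_lat, tau=tau_fine, dx=dx_coarse / 2)
    return coarse, fine
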