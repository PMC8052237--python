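"""D3Q19 lattice-Boltzmann flow solver over voxelized airway domains.

The solver produces the pressure scalar field for one prescribed flow
condition: a Dirichlet plug velocity on the outlet face of the oropharynx
cuboid sets the flow rate, the nasal-tip sphere surface is held at ambient
pressure, and all other non-air voxels are no-slip walls (half-way
bounce-back, optionally Bouzidi-interpolated where a signed distance to a
smooth wall is available).  Collision is two-relaxation-time (BGK
selectable), optionally with a Smagorinsky large-eddy closure for runs
whose bare relaxation time sits close to the stability limit.

Unit conventions
----------------
Physical quantities are SI (m, s, Pa); flow rates are ml/s at the API
surface because that is the rhinomanometry convention.  Lattice quantities
are the usual dimensionless LB units with sound speed ``c_s^2 = 1/3``:

* ``u_lat = u_phys * dt / dx``
* ``nu_lat = nu_phys * dt / dx**2``,  ``tau = 3 nu_lat + 1/2``
* ``p_phys = c_s^2 (rho_lat - 1) * rho_phys * (dx/dt)**2``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from ._kernels import C, W

__all__ = [
    "AIR_NU_20C", "AIR_RHO_20C", "CS2",
    "LatticeConfig", "FlowCondition", "PressureField", "LatticeDomain",
    "StabilityError", "DivergenceError",
    "velocity_to_lattice", "viscosity_to_lattice", "pressure_from_lattice",
    "apply_boundaries", "set_flow_rate", "run_to_stationary", "simulate_flow",
]

#: Kinematic viscosity of air at 20 degC, m^2/s.
AIR_NU_20C = 1.516e-5
#: Density of air at 20 degC, kg/m^3.
AIR_RHO_20C = 1.204
#: Lattice sound speed squared.
CS2 = 1.0 / 3.0


class StabilityError(ValueError):
    """Raised when the lattice relaxation time is at or below 1/2 without LES."""


class DivergenceError(RuntimeError):
    """Raised when the distributions blow up (NaN / runaway amplitude)."""


@dataclass
class LatticeConfig:
    """Resolution, fluid properties and stopping rule for one LB run.

    Defaults are the patient-scale values (0.234 mm grid, 1.8e-6 s steps,
    air at 20 degC, c_s = 0.14); desk-scale phantom studies override them
    via :func:`rhinoflow.phantom.desk_scale_config`.
    """

    dx: float = 0.234e-3          # m per lattice node
    dt: float = 1.8e-6            # s per step
    nu_phys: float = AIR_NU_20C   # m^2/s
    rho_phys: float = AIR_RHO_20C # kg/m^3
    les: bool = True
    smagorinsky_cs: float = 0.14
    trt_magic: float = 3.0 / 16.0   # TRT magic parameter; <= 0 selects BGK
    max_steps: int = 13605
    stationarity_tol: float = 0.03   # +-3% peak-to-peak of the running mean
    stationarity_abs_pa: float = 0.25  # absolute floor, Pa (handles dp ~ 0)
    monitor_window: int = 500        # steps over which fluctuation is assessed
    check_every: int = 25
    min_steps: int = 200

    @property
    def lattice_speed(self) -> float:
        """dx/dt in m/s (lattice velocity unit)."""
        return self.dx / self.dt

    @property
    def nu_lattice(self) -> float:
        return viscosity_to_lattice(self, self.nu_phys)

    @property
    def tau(self) -> float:
        return 3.0 * self.nu_lattice + 0.5

    def validate(self) -> "LatticeConfig":
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.stationarity_tol <= 0:
            raise ValueError("stationarity_tol must be positive")
        # tau -> 1/2 is the BGK/TRT stability limit; without an eddy-
        # viscosity closure we refuse to run in the marginal band
        if self.tau <= 0.505 and not self.les:
            raise StabilityError(
                f"relaxation time tau = {self.tau:.6f} is at the stability "
                "limit with LES disabled; increase dt, coarsen dx, or enable "
                "the Smagorinsky closure"
            )
        return self


@dataclass(frozen=True)
class FlowCondition:
    """One prescribed rhinomanometry-style flow condition."""

    flow_rate: float              # ml/s, magnitude of the set flow
    phase: str = "inspiration"    # inspiration | expiration
    side: str = "left"            # which nostril is open

    def __post_init__(self):
        if self.phase not in ("inspiration", "expiration"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if abs(self.flow_rate) > 625.0:
            raise ValueError("flow rate outside the +-625 ml/s analysis span")


def velocity_to_lattice(cfg: LatticeConfig, v_phys: float) -> float:
    """Convert a physical velocity (m/s) to lattice units."""
    return v_phys * cfg.dt / cfg.dx


def viscosity_to_lattice(cfg: LatticeConfig, nu_phys: float) -> float:
    """Convert a kinematic viscosity (m^2/s) to lattice units."""
    return nu_phys * cfg.dt / cfg.dx ** 2


def pressure_from_lattice(cfg: LatticeConfig, drho_lattice) -> float:
    """Convert a lattice density deviation (rho - 1) to gauge pressure in Pa."""
    return CS2 * drho_lattice * cfg.rho_phys * cfg.lattice_speed ** 2


# ---------------------------------------------------------------------------
# lattice domain assembly


@dataclass
class LatticeDomain:
    """Indexed fluid-voxel representation of one boundary-value problem."""

    shape: tuple
    fluid_mask: np.ndarray        # 3D bool
    index: np.ndarray             # 3D int32, -1 at solid
    coords: np.ndarray            # (N, 3)
    nbr: np.ndarray               # (N, 19) pull-neighbour table
    qtab: np.ndarray              # (N, 19) fractional wall distances
    wall_u: np.ndarray            # (3,) lattice velocity of the moving wall
    pres_idx: np.ndarray          # ambient-pressure node indices
    probe1_idx: np.ndarray        # p1 probe (sphere) node indices
    probe2_idx: np.ndarray        # p2 probe (cuboid) node indices

    @property
    def n_fluid(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_masks(cls, fluid_mask, moving_wall_mask=None,
                   wall_u=(0.0, 0.0, 0.0),
                   pres_mask=None, probe1_mask=None, probe2_mask=None,
                   sdf=None):
        """Build the neighbour table and boundary node lists from voxel masks.

        ``moving_wall_mask`` marks *solid* voxels acting as the momentum-
        corrected bounce-back wall (the Dirichlet flow-rate boundary);
        ``wall_u`` is its lattice velocity.  Out-of-grid and other solid pull
        sources bounce back statically.

        ``sdf``, if given, is a signed distance to the true wall surface
        sampled at voxel centres (positive in fluid, lattice units); wall
        links then use Bouzidi linear interpolation at the sub-voxel wall
        position instead of the half-way rule.  Voxel-native (CT mask)
        geometry omits it.
        """
        fluid_mask = np.asarray(fluid_mask, dtype=bool)
        if moving_wall_mask is not None:
            moving_wall_mask = np.asarray(moving_wall_mask, dtype=bool)
            if (moving_wall_mask & fluid_mask).any():
                raise ValueError("moving-wall voxels must be solid")
        shape = fluid_mask.shape
        index = np.full(shape, -1, dtype=np.int32)
        coords = np.argwhere(fluid_mask)
        index[fluid_mask] = np.arange(coords.shape[0], dtype=np.int32)

        n = coords.shape[0]
        nbr = np.full((n, 19), -1, dtype=np.int32)
        qtab = np.full((n, 19), 0.5, dtype=np.float64)
        for i in range(19):
            src = coords - C[i]          # pull scheme: f_i comes from x - c_i
            ok = np.all((src >= 0) & (src < np.array(shape)), axis=1)
            s = src[ok]
            vals = index[s[:, 0], s[:, 1], s[:, 2]].astype(np.int32)
            if moving_wall_mask is not None:
                moving = moving_wall_mask[s[:, 0], s[:, 1], s[:, 2]]
                vals[(vals < 0) & moving] = -2
            nbr[ok, i] = vals
            if sdf is not None and i > 0:
                # fractional distance from the fluid node to the zero level
                # set along the link, by linear interpolation of the SDF
                wall = vals == -1
                if wall.any():
                    kk = np.flatnonzero(ok)[wall]
                    cf = coords[kk]
                    sf = s[wall]
                    phi_f = sdf[cf[:, 0], cf[:, 1], cf[:, 2]]
                    phi_s = sdf[sf[:, 0], sf[:, 1], sf[:, 2]]
                    denom = phi_f - phi_s
                    good = (phi_f >= 0) & (phi_s < 0) & (denom > 0)
                    q = np.full(len(kk), 0.5)
                    q[good] = np.clip(phi_f[good] / denom[good], 0.01, 0.99)
                    qtab[kk, i] = q

        def _idx(mask):
            if mask is None:
                return np.empty(0, dtype=np.int64)
            vals = index[np.asarray(mask, dtype=bool) & fluid_mask]
            return vals[vals >= 0].astype(np.int64)

        return cls(shape, fluid_mask, index, coords, nbr, qtab,
                   np.asarray(wall_u, dtype=np.float64),
                   _idx(pres_mask), _idx(probe1_mask), _idx(probe2_mask))

    def wall_flux(self, u=None) -> float:
        """Net lattice mass injected per step by the moving wall at velocity u.

        Linear in u; used to scale the wall velocity so the injected mass
        flux equals the prescribed flow rate exactly.
        """
        if u is None:
            u = self.wall_u
        u = np.asarray(u, dtype=np.float64)
        total = 0.0
        for i in range(19):
            nlinks = int((self.nbr[:, i] == -2).sum())
            if nlinks:
                total += nlinks * 6.0 * W[i] * float(C[i] @ u)
        return total

    def field_from_nodes(self, values, fill=np.nan, dtype=np.float64):
        """Scatter per-node values back onto the 3D grid."""
        out = np.full(self.shape, fill, dtype=dtype)
        out[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return out


@dataclass
class PressureField:
    """Converged (or flagged) outcome of one LB run at one flow condition."""

    pressure: np.ndarray          # 3D, Pa gauge, NaN at solid voxels
    velocity: np.ndarray          # 3D+component, m/s, NaN at solid voxels
    converged: bool
    steps_run: int
    dp_pa: float                  # sphere-mean minus cuboid-mean pressure
    dp_history: np.ndarray        # monitored dp samples, Pa
    state: np.ndarray = field(repr=False, default=None)  # final f, for warm starts


def run_to_stationary(lattice: LatticeDomain, cfg: LatticeConfig,
                      init_state: Optional[np.ndarray] = None) -> PressureField:
    """Iterate collide-stream until the probe pressure drop is stationary.

    Stationarity: the peak-to-peak fluctuation of the sphere-cuboid pressure
    drop over ``cfg.monitor_window`` steps falls below +-``stationarity_tol``
    of its running mean (with an absolute floor for near-zero drops).  If
    ``max_steps`` is exhausted first the field is returned flagged
    ``converged=False`` rather than raising.
    """
    cfg.validate()
    n = lattice.n_fluid
    if n == 0:
        raise ValueError("empty fluid domain")
    f = np.empty((n, 19), dtype=np.float64)
    if init_state is not None and init_state.shape == f.shape:
        f[:] = init_state
    else:
        _kernels.init_equilibrium(f, 1.0)
    f2 = np.empty_like(f)

    rho = np.empty(n)
    u = np.empty((n, 3))

    def probe_dp(farr):
        _kernels.macroscopic(farr, rho, u)
        d1 = rho[lattice.probe1_idx].mean() if len(lattice.probe1_idx) else 1.0
        d2 = rho[lattice.probe2_idx].mean() if len(lattice.probe2_idx) else 1.0
        return pressure_from_lattice(cfg, d1 - d2)

    window_samples = max(2, cfg.monitor_window // cfg.check_every)
    history = []
    steps = 0
    cur = f
    converged = False
    while steps < cfg.max_steps:
        chunk = min(cfg.check_every, cfg.max_steps - steps)
        a, b = (f, f2) if cur is f else (f2, f)
        in_first, fmax = _kernels.run_steps(
            a, b, lattice.nbr, lattice.qtab, cfg.tau, cfg.trt_magic,
            cfg.les, cfg.smagorinsky_cs,
            lattice.wall_u[0], lattice.wall_u[1], lattice.wall_u[2],
            lattice.pres_idx, chunk)
        steps += chunk
        cur = a if in_first else b
        if not np.isfinite(fmax) or fmax > 1e3:
            raise DivergenceError(f"solver diverged at step {steps}")
        history.append(probe_dp(cur))
        if steps >= cfg.min_steps and len(history) >= window_samples:
            win = np.array(history[-window_samples:])
            mean = win.mean()
            ptp = win.max() - win.min()
            if ptp < max(cfg.stationarity_tol * abs(mean), cfg.stationarity_abs_pa):
                converged = True
                break

    _kernels.macroscopic(cur, rho, u)
    pressure = lattice.field_from_nodes(pressure_from_lattice(cfg, rho - 1.0))
    vel = np.full(lattice.shape + (3,), np.nan)
    vel[lattice.coords[:, 0], lattice.coords[:, 1], lattice.coords[:, 2]] = \
        u * cfg.lattice_speed
    dp = float(np.mean(history[-window_samples:])) if history else 0.0
    return PressureField(pressure=pressure, velocity=vel, converged=converged,
                         steps_run=steps, dp_pa=dp,
                         dp_history=np.array(history), state=cur.copy())


# ---------------------------------------------------------------------------
# boundary assembly for segmented airway domains


def apply_boundaries(domain, cond: FlowCondition, cfg: LatticeConfig) -> LatticeDomain:
    """Assemble the LB boundary-value problem for one airway flow condition.

    ``domain`` is an :class:`rhinoflow.airspace.AirspaceDomain`.  The outlet
    face of the oropharynx cuboid receives a uniform (plug) Dirichlet
    velocity of magnitude ``flow_rate / open_outlet_area``, signed by
    respiration phase (inspiration draws air out through the oropharynx);
    fluid voxels on the tip-sphere surface are held at ambient pressure.
    """
    air = domain.air_mask
    floor_wall = domain.outlet_wall_mask()
    if not floor_wall.any():
        raise ValueError("open outlet area is zero: no air rests on the "
                         "oropharynx cuboid floor")
    lattice = LatticeDomain.from_masks(
        air,
        moving_wall_mask=floor_wall,
        pres_mask=domain.sphere_surface_mask() & air,
        probe1_mask=domain.sphere_mask() & air,
        probe2_mask=domain.cuboid_mask() & air,
        sdf=getattr(domain, "sdf", None),
    )
    set_flow_rate(lattice, domain, cond, cfg)
    return lattice


def set_flow_rate(lattice: LatticeDomain, domain, cond: FlowCondition,
                  cfg: LatticeConfig) -> LatticeDomain:
    """Retarget an assembled lattice to a new flow condition (same geometry).

    Scales the moving-wall velocity so the injected lattice mass flux
    equals the prescribed flow rate exactly.  Used to ramp through a flow
    sweep without rebuilding the neighbour tables.
    """
    q_lat = (cond.flow_rate * 1e-6) * cfg.dt / cfg.dx ** 3
    normal = np.zeros(3)
    normal[domain.si_axis] = 1.0                   # into the floor (inferior)
    flux_unit = lattice.wall_flux(normal)
    if flux_unit == 0.0:
        raise ValueError("open outlet area is zero")
    # inspiration: air leaves the airway through the oropharynx (extraction)
    target = -q_lat if cond.phase == "inspiration" else q_lat
    scale = target / flux_unit
    if abs(scale) > 0.3:
        raise StabilityError(
            f"outlet lattice velocity {scale:.3f} exceeds the incompressible "
            "limit; rescale dt or coarsen the flow sweep")
    lattice.wall_u = normal * scale
    return lattice


def simulate_flow(domain, cond: FlowCondition, cfg: LatticeConfig,
                  init_state: Optional[np.ndarray] = None) -> PressureField:
    """Convenience wrapper: boundaries + run to stationarity."""
    lattice = apply_boundaries(domain, cond, cfg)
    return run_to_stationary(lattice, cfg, init_state=init_state)
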