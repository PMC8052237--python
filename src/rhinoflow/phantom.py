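"""Synthetic nasal phantoms and synthetic rhinomanometry data.

The voxel phantom is a nose-like bent dual-channel geometry: an anterior
exterior-air pocket with a protruding tip cone (so tip detection faces a
real protrusion), two swept-circle channels that arc
anterior-superior-posterior from the nostrils to a shared posterior cavity
(nasopharynx/oropharynx analogue) sized to admit the outlet cuboid, and a
parametric unilateral constriction emulating a deviated septum.  The whole
geometry is built from one signed distance field, which serves three
masters at once: the HU volume, the ground-truth lumen oracle for the
segmentation tests, and the sub-voxel wall positions for the solver.

Synthetic clinical pressure-flow curves follow the Rohrer law
``dp = k1 Q + k2 Q |Q|`` (plus optional Gaussian pressure noise), the
classical quadratic-dominated form of rhinomanometry curves; congested and
decongested mucosal states differ by their coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .airspace import AP, SI, LR, HUVolume
from .curves import AARCurve
from .lbm import LatticeConfig

__all__ = [
    "PhantomSpec", "PhantomTruth", "build_phantom", "build_phantom_truth",
    "desk_scale_config", "RohrerModel", "synth_aar", "breathing_trace",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic nasal phantom.

    Geometry anchors are fractions of the grid; metric quantities derive
    from ``spacing``.  ``hu_air < -460 < hu_tissue`` guarantees that the
    standard threshold separates the two phases.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.0                  # mm per voxel, isotropic
    nostril_radius_mm: float = 9.0        # unconstricted channel radius
    constriction_side: str = "none"       # left | right | none
    constriction_factor: float = 0.85     # multiplies radius at the site
    hu_air: float = -1000.0
    hu_tissue: float = 40.0
    seed: int = 0
    jitter_mm: float = 0.8                # anatomical variability of the arcs
    radius_profile: Optional[Callable[[float, str], float]] = None
    # radius in mm as a function of arc position t in [0, 1] and side;
    # overrides the default constant-with-constriction profile

    # probe-region proportions, mirroring the patient-scale 70 mm sphere
    # and 60x40x30 mm cuboid: sphere diameter = 2.3 x nostril diameter,
    # cuboid edges = (3, 6, 4)/7 x sphere diameter in (AP, SI, LR) order
    sphere_scale: float = 2.3
    cuboid_scale: Tuple[float, float, float] = (3 / 7, 6 / 7, 4 / 7)

    def validate(self) -> "PhantomSpec":
        if not (0.0 < self.constriction_factor <= 1.0):
            raise ValueError("constriction_factor must lie in (0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (self.hu_air < -460.0 < self.hu_tissue):
            raise ValueError("need hu_air < -460 < hu_tissue so thresholding "
                             "separates the phases")
        if self.constriction_side not in ("left", "right", "none"):
            raise ValueError(f"unknown side {self.constriction_side!r}")
        if min(self.grid_shape) < 24:
            raise ValueError("grid too small: all axes need >= 24 voxels")
        return self

    @property
    def sphere_diam_mm(self) -> float:
        return self.sphere_scale * 2.0 * self.nostril_radius_mm

    @property
    def cuboid_dims_mm(self) -> Tuple[float, float, float]:
        d = self.sphere_diam_mm
        return tuple(c * d for c in self.cuboid_scale)

    def channel_radius_mm(self, t: float, side: str) -> float:
        """Channel radius at arc position t in [0, 1] for one side."""
        if self.radius_profile is not None:
            return float(self.radius_profile(t, side))
        r = self.nostril_radius_mm
        if side == self.constriction_side:
            dip = (1.0 - self.constriction_factor) * np.exp(-((t - 0.5) / 0.15) ** 2)
            r = r * (1.0 - dip)
        return r


@dataclass
class PhantomTruth:
    """Construction ground truth: the oracle for segmentation tests."""

    volume: HUVolume
    lumen: np.ndarray                 # exact constructed air mask
    sdf: np.ndarray                   # signed distance, +inside air, voxels
    tip_vox: Tuple[int, int, int]
    channel_masks: Dict[str, np.ndarray]
    cavity_box: Tuple[slice, slice, slice]
    pocket_box: Tuple[slice, slice, slice]
    arc_length_mm: Dict[str, float]
    min_radius_mm: Dict[str, float]
    spec: PhantomSpec = None


def _bezier(p0, p1, p2, t):
    t = np.asarray(t)[:, None]
    return ((1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2)


def _box_sdf(shape, box):
    """Inside-positive distance to an axis-aligned box, per voxel (approx:
    Chebyshev-style min over axis distances, exact inside)."""
    idx = np.indices(shape, dtype=float)
    d = np.full(shape, np.inf)
    for a in range(3):
        lo, hi = box[a].start, box[a].stop - 1
        d = np.minimum(d, np.minimum(idx[a] - (lo - 0.5), (hi + 0.5) - idx[a]))
    return d


def _capsule_sdf(shape, points, radii):
    """Inside-positive distance to a chain of spheres (dense samples).

    Accurate near the surface for sample spacing well below a voxel.
    """
    idx = np.indices(shape, dtype=float)
    phi = np.full(shape, -np.inf)
    for p, r in zip(points, radii):
        lo = np.maximum(np.floor(p - r - 2), 0).astype(int)
        hi = np.minimum(np.ceil(p + r + 3), shape).astype(int)
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        d2 = sum((idx[a][sub] - p[a]) ** 2 for a in range(3))
        phi[sub] = np.maximum(phi[sub], r - np.sqrt(d2))
    return phi


def build_phantom_truth(spec: PhantomSpec) -> PhantomTruth:
    """Construct the phantom and its ground truth from one distance field."""
    spec.validate()
    shape = tuple(spec.grid_shape)
    nap, nsi, nlr = shape
    rng = np.random.default_rng(spec.seed)
    cz = (nlr - 1) / 2.0

    af = int(round(0.22 * nap))              # face plane
    tip_ap = int(round(0.08 * nap))
    tip_si = 0.40 * nsi

    # anterior exterior-air pocket
    pocket_box = (slice(0, af),
                  slice(int(0.22 * nsi), int(0.72 * nsi)),
                  slice(int(0.25 * nlr), int(0.75 * nlr)))
    phi_pocket = _box_sdf(shape, pocket_box)

    # protruding tip cone (tissue): carved out of the pocket air
    idx = np.indices(shape, dtype=float)
    radial = np.sqrt((idx[SI] - tip_si) ** 2 + (idx[LR] - cz) ** 2)
    r_base = 0.14 * nlr
    with np.errstate(invalid="ignore"):
        frac = np.clip((idx[AP] - tip_ap) / max(af - tip_ap, 1), None, 1.0)
    r_cone = 1.2 + (r_base - 1.2) * frac
    phi_cone = np.minimum(r_cone - radial, idx[AP] - (tip_ap - 0.5))
    phi_pocket = np.minimum(phi_pocket, -phi_cone)

    # posterior cavity (nasopharynx/oropharynx analogue)
    cavity_box = (slice(int(0.72 * nap), int(0.93 * nap)),
                  slice(int(0.42 * nsi), int(0.88 * nsi)),
                  slice(int(cz - 0.15 * nlr), int(cz + 0.15 * nlr) + 1))
    phi_cavity = _box_sdf(shape, cavity_box)

    # swept-circle channels along anterior-superior-posterior arcs
    channel_phi = {}
    arc_len = {}
    min_r = {}
    jit = spec.jitter_mm / spec.spacing
    for side, s in (("left", -1.0), ("right", +1.0)):
        p0 = np.array([af - 2.0, 0.52 * nsi, cz + s * 0.11 * nlr])
        p1 = np.array([0.42 * nap, 0.18 * nsi, cz + s * 0.14 * nlr])
        p2 = np.array([0.70 * nap, 0.45 * nsi, cz + s * 0.03 * nlr])
        p1[1:] += rng.normal(0.0, jit, size=2)
        p2[1:] += rng.normal(0.0, jit, size=2)
        ts = np.linspace(0.0, 1.0, 160)
        pts = _bezier(p0, p1, p2, ts)
        radii = np.array([spec.channel_radius_mm(t, side) / spec.spacing
                          for t in ts])
        channel_phi[side] = _capsule_sdf(shape, pts, radii)
        seg = np.diff(pts, axis=0)
        arc_len[side] = float(np.sum(np.linalg.norm(seg, axis=1)) * spec.spacing)
        min_r[side] = float(radii.min() * spec.spacing)

    sdf = np.maximum.reduce([phi_pocket, phi_cavity,
                             channel_phi["left"], channel_phi["right"]])
    lumen = sdf > 0.0

    # sizing checks: the cavity must admit the outlet cuboid
    cub_vox = tuple(int(round(e / spec.spacing)) for e in spec.cuboid_dims_mm)
    cav_dims = tuple(cavity_box[a].stop - cavity_box[a].start for a in range(3))
    for a, name in zip(range(3), ("AP", "SI", "LR")):
        if cav_dims[a] < cub_vox[a]:
            raise ValueError(
                f"grid too small: posterior cavity {name} extent "
                f"{cav_dims[a]} voxels cannot admit the outlet cuboid "
                f"({cub_vox[a]} voxels); enlarge grid_shape[{a}] or spacing")
    if spec.sphere_diam_mm / spec.spacing > min(nsi, nlr):
        raise ValueError("grid too small: tip sphere diameter exceeds the "
                         "SI/LR grid extent")

    hu = np.where(lumen, spec.hu_air, spec.hu_tissue).astype(np.float32)
    vol = HUVolume(hu, spec.spacing)

    # constructed tip voxel: anterior-most cone tissue on the midline
    tip = (tip_ap, int(round(tip_si)), int(np.floor(cz)))
    return PhantomTruth(volume=vol, lumen=lumen, sdf=sdf, tip_vox=tip,
                        channel_masks={k: v > 0 for k, v in channel_phi.items()},
                        cavity_box=cavity_box, pocket_box=pocket_box,
                        arc_length_mm=arc_len, min_radius_mm=min_r, spec=spec)


def build_phantom(spec: PhantomSpec) -> HUVolume:
    """Voxel phantom in Hounsfield units (see :func:`build_phantom_truth`)."""
    return build_phantom_truth(spec).volume


def desk_scale_config(spec: PhantomSpec,
                      target_r150: float = 0.55,
                      tau: float = 0.6,
                      max_steps: int = 12000) -> LatticeConfig:
    """Lattice scaling for desk-scale phantom studies.

    Phantom sweeps use a scaled working fluid instead of air: the kinematic
    viscosity is chosen so that the unconstricted channel's Hagen-
    Poiseuille resistance equals ``target_r150`` Pa/(ml/s), which puts the
    150 Pa working point near 270 ml/s - inside the clinical sweep - while
    keeping the Reynolds number of order 10 (LES off) and the lattice
    comfortably stable (tau = 0.6) on coarse grids.  This is a dynamic-
    similarity device: the pressure-flow curve spans the rhinomanometry
    range at a fraction of the patient-scale lattice cost.
    """
    spec.validate()
    dx = spec.spacing * 1e-3                      # m
    r = spec.nostril_radius_mm * 1e-3
    # resistive path: the channel arc between the nostril plane (face) and
    # the posterior cavity; the exterior pocket and the cavity itself are
    # wide and contribute negligibly
    nap, nsi, nlr = spec.grid_shape
    af, cav = 0.22 * nap, 0.72 * nap
    cz = (nlr - 1) / 2.0
    p0 = np.array([af - 2.0, 0.52 * nsi, cz + 0.11 * nlr])
    p1 = np.array([0.42 * nap, 0.18 * nsi, cz + 0.14 * nlr])
    p2 = np.array([0.70 * nap, 0.45 * nsi, cz + 0.03 * nlr])
    ts = np.linspace(0.0, 1.0, 400)
    pts = _bezier(p0, p1, p2, ts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    mid = 0.5 * (pts[1:, AP] + pts[:-1, AP])
    length = float(seg[(mid >= af) & (mid <= cav)].sum()) * dx
    mu = target_r150 * 1e6 * np.pi * r ** 4 / (8.0 * length)
    rho = 1.204
    nu_phys = mu / rho
    nu_lat = (tau - 0.5) / 3.0
    dt = nu_lat * dx ** 2 / nu_phys
    return LatticeConfig(dx=dx, dt=dt, nu_phys=nu_phys, rho_phys=rho,
                         les=False, max_steps=max_steps,
                         monitor_window=500, check_every=50, min_steps=400,
                         stationarity_abs_pa=0.25)


# ---------------------------------------------------------------------------
# synthetic rhinomanometry (Rohrer model)


@dataclass
class RohrerModel:
    """Empirical pressure-flow law dp = k1 Q + k2 Q |Q| (+ noise).

    k1 in Pa/(ml/s), k2 in Pa/(ml/s)^2; both non-negative, not both zero.
    Noise is additive Gaussian on pressure only - flow is the controlled
    variable in rhinomanometry.
    """

    k1: float
    k2: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0 or (self.k1 == 0 and self.k2 == 0):
            raise ValueError("need k1 >= 0, k2 >= 0 and not both zero")

    def pressure(self, flow) -> np.ndarray:
        q = np.asarray(flow, dtype=float)
        return self.k1 * q + self.k2 * q * np.abs(q)


def synth_aar(model: RohrerModel, flows, subject: str = "", side: str = "",
              state: str = "") -> AARCurve:
    """Synthetic AAR curve at the given signed flows (ml/s).

    Deterministic for a fixed model seed.  Inspiration and expiration
    occupy opposite quadrants by the sign convention of the Rohrer law.
    """
    flows = np.asarray(flows, dtype=float)
    if flows.size == 0:
        raise ValueError("empty flow list")
    if np.abs(flows).max() > 625.0:
        raise ValueError("flows outside the +-625 ml/s analysis span")
    p = model.pressure(flows)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        p = p + rng.normal(0.0, model.noise_sd, size=flows.shape)
    return AARCurve(flows, p, subject=subject, side=side, state=state)


def breathing_trace(model: RohrerModel, n_cycles: int = 3,
                    samples_per_cycle: int = 6000, peak_flow: float = 600.0,
                    cycle_variability: float = 0.15,
                    hysteresis_pa: float = 30.0,
                    flow_noise_sd: float = 15.0,
                    seed: Optional[int] = None):
    """Time-resolved breathing loops, as a rhinomanometer would draw them.

    Flow follows ``n_cycles`` sine cycles with per-half-cycle peak
    variability (inspiration and expiration depths differ breath to
    breath); pressure adds an inertive component proportional to dQ/dt
    (peak amplitude ``hysteresis_pa``) producing the hysteresis loop seen
    on real AAR traces, plus the model's pressure noise.  Both channels
    carry measurement noise, which is what makes rendered traces as thick
    and dense as clinical plots.  Returns (flow, pressure) arrays.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(model.seed if seed is None else seed)
    t = np.linspace(0.0, n_cycles, n_cycles * samples_per_cycle, endpoint=False)
    peaks = peak_flow * (1.0 + cycle_variability
                         * rng.standard_normal(2 * n_cycles))
    # subjects maintain effort: breath depth varies but stays near the
    # target peak, and inside the +-625 ml/s analysis span
    peaks = np.clip(peaks, 0.78 * peak_flow, 620.0)
    amp = np.repeat(np.abs(peaks), samples_per_cycle // 2)
    flow = amp * np.sin(2.0 * np.pi * t)
    if flow_noise_sd > 0:
        # physiological variability wanders slowly (band-limited), so each
        # breath traces a distinct path; fast sensor jitter sits on top and
        # fills the trace band the way dense device sampling does
        slow = gaussian_filter1d(rng.standard_normal(flow.shape),
                                 samples_per_cycle / 60)
        slow *= 2.0 * flow_noise_sd / max(slow.std(), 1e-12)
        fast = rng.normal(0.0, 0.6 * flow_noise_sd, size=flow.shape)
        flow = np.clip(flow + slow + fast, -624.0, 624.0)
    # inertive hysteresis: proportional to dQ/dt, i.e. the cosine branch
    pressure = (model.pressure(flow)
                + hysteresis_pa * (amp / peak_flow) * np.cos(2.0 * np.pi * t))
    if model.noise_sd > 0:
        pressure = pressure + rng.normal(0.0, model.noise_sd, size=flow.shape)
    return flow, pressure
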