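"""Automated nasal air-space segmentation from Hounsfield-unit volumes.

The extraction chain mirrors a fully automated clinical workflow:

1. threshold the volume at -460 HU (inclusive) to a binary air mask;
2. detect the nasal tip as the anterior-most tissue-surface voxel inside a
   central left-right band;
3. place the probe regions: a sphere centred on the tip (inlet/ambient
   boundary, 70 mm diameter at patient scale) and a cuboid on the
   oropharynx (outlet flow boundary, 60 x 40 x 30 mm^3 at patient scale);
4. region-grow from the oropharynx to keep exactly the connected airway
   and discard all other air (paranasal pockets, scanner background, ...);
5. optionally block one nostril with a virtual plug so the open side can
   be simulated alone, as in unilateral rhinomanometry.

Canonical axis order is (AP, SI, LR): index 0 grows anterior to posterior,
index 1 superior to inferior, index 2 left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "HUVolume", "AirspaceDomain", "SegmentationError",
    "threshold_air", "detect_tip", "place_probes", "grow_airway",
    "block_nostril", "extract_airspace",
    "AP", "SI", "LR", "CANONICAL_AXES",
]

AP, SI, LR = 0, 1, 2
CANONICAL_AXES = ("AP", "SI", "LR")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when the automated extraction cannot proceed."""


@dataclass
class HUVolume:
    """Scalar voxel grid in Hounsfield units with spacing metadata.

    ``axes`` labels the anatomical meaning of each array axis; the package
    works internally in canonical (AP, SI, LR) order, use
    :meth:`to_canonical` after loading data in another orientation.
    """

    values: np.ndarray
    spacing: float                      # mm per voxel (isotropic)
    axes: Tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("HU volume must be three-dimensional")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if sorted(self.axes) != sorted(CANONICAL_AXES):
            raise ValueError(
                f"axes must cover {CANONICAL_AXES} exactly once, got {self.axes}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_canonical(self) -> "HUVolume":
        """Permute axes into (AP, SI, LR) order."""
        if self.axes == CANONICAL_AXES:
            return self
        perm = [self.axes.index(a) for a in CANONICAL_AXES]
        return HUVolume(np.transpose(self.values, perm), self.spacing,
                        CANONICAL_AXES)


@dataclass
class AirspaceDomain:
    """Segmented airway: air mask plus inlet-sphere and outlet-cuboid probes.

    The sphere is stored as centre (the detected nasal tip) and diameter;
    the cuboid as voxel origin and edge lengths.  Voxel index sets are
    derived on demand.
    """

    air_mask: np.ndarray
    tip_vox: Tuple[int, int, int]
    sphere_diam_mm: float
    cuboid_origin_vox: Tuple[int, int, int]
    cuboid_dims_vox: Tuple[int, int, int]
    spacing: float
    blocked_side: str = "none"
    sdf: Optional[np.ndarray] = None    # optional smooth-wall distances

    ap_axis: int = AP
    si_axis: int = SI
    lr_axis: int = LR

    @property
    def sphere_radius_vox(self) -> float:
        return 0.5 * self.sphere_diam_mm / self.spacing

    def _tip_distance(self) -> np.ndarray:
        idx = np.indices(self.air_mask.shape, dtype=float)
        d2 = sum((idx[a] - self.tip_vox[a]) ** 2 for a in range(3))
        return np.sqrt(d2)

    def sphere_mask(self) -> np.ndarray:
        """All voxels inside the tip sphere."""
        return self._tip_distance() <= self.sphere_radius_vox

    def sphere_shell_mask(self) -> np.ndarray:
        """Geometric one-voxel shell on the sphere surface."""
        d = self._tip_distance()
        r = self.sphere_radius_vox
        return (d <= r) & (d > r - 1.2)

    def sphere_surface_mask(self) -> np.ndarray:
        """Ambient-pressure boundary: the sphere shell where it meets
        exterior air.

        The shell clips the channel mouths just behind the nostrils; those
        interior voxels must not be vented to ambient (that would partially
        defeat a nostril plug), so the boundary is restricted to the air
        connected to the anterior face.
        """
        return self.sphere_shell_mask() & _exterior_air(self.air_mask)

    def cuboid_mask(self) -> np.ndarray:
        m = np.zeros(self.air_mask.shape, dtype=bool)
        o, e = self.cuboid_origin_vox, self.cuboid_dims_vox
        m[o[0]:o[0] + e[0], o[1]:o[1] + e[1], o[2]:o[2] + e[2]] = True
        return m

    def outlet_wall_mask(self) -> np.ndarray:
        """Solid voxels directly inferior to cuboid air (the outlet face wall).

        These are driven as a momentum-corrected bounce-back wall to impose
        the flow rate; the contact layer is where the oropharynx air rests
        on the cuboid floor.
        """
        cub_air = self.cuboid_mask() & self.air_mask
        wall = np.zeros_like(cub_air)
        # solid voxel at si+1 of cuboid air
        wall[:, 1:, :] = cub_air[:, :-1, :] & ~self.air_mask[:, 1:, :]
        return wall

    def nostril_half(self, side: str) -> slice:
        """LR index range of one side (left = lower indices)."""
        nz = self.air_mask.shape[self.lr_axis]
        half = nz // 2
        return slice(0, half) if side == "left" else slice(half, nz)


# ---------------------------------------------------------------------------
# operations


def threshold_air(vol: HUVolume, hu_cut: float = -460.0) -> np.ndarray:
    """Binary air mask: voxel value <= hu_cut (inclusive boundary).

    -460 HU separates air from soft tissue on CT/DVT; the boundary value
    itself counts as air so the rule is deterministic.
    """
    values = vol.values if isinstance(vol, HUVolume) else np.asarray(vol)
    bad = ~np.isfinite(values)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} non-finite voxel values")
    return values <= hu_cut


def _exterior_air(air: np.ndarray) -> np.ndarray:
    """Air connected (26-conn) to the anterior face of the grid."""
    labels, _ = ndimage.label(air, structure=_STRUCT26)
    front = np.unique(labels[0])
    front = front[front > 0]
    if len(front) == 0:
        return np.zeros_like(air)
    return np.isin(labels, front)


def detect_tip(air: np.ndarray, band_frac: float = 0.25) -> tuple:
    """Locate the nasal tip on a binary air mask.

    Scans anterior to posterior and returns the first tissue voxel whose
    anterior neighbour is exterior air, within a central band of the
    left-right axis (half-width ``band_frac`` of the axis) - i.e. the
    anterior-most point of the tissue surface facing the outside.  Ties
    within the first slice resolve to the voxel closest to the midline.
    """
    air = np.asarray(air, dtype=bool)
    if not air.any():
        raise SegmentationError("air mask is empty")
    exterior = _exterior_air(air)
    if not exterior.any():
        raise SegmentationError("no exterior air touches the anterior face")
    tissue = ~air
    surface = np.zeros_like(tissue)
    surface[1:] = tissue[1:] & exterior[:-1]     # anterior neighbour is outside air
    nz = air.shape[LR]
    mid = (nz - 1) / 2.0
    half = max(1, int(round(band_frac * nz)))
    lo, hi = int(np.ceil(mid - half)), int(np.floor(mid + half)) + 1
    band = np.zeros_like(surface)
    band[:, :, max(lo, 0):min(hi, nz)] = True
    cand = surface & band
    if not cand.any():
        raise SegmentationError("no tissue surface found in the central band")
    coords = np.argwhere(cand)
    first_ap = coords[:, AP].min()
    sl = coords[coords[:, AP] == first_ap]
    order = np.lexsort((sl[:, SI], np.abs(sl[:, LR] - mid)))
    return tuple(int(v) for v in sl[order[0]])


def place_probes(air: np.ndarray, tip: Sequence[int], spacing: float,
                 sphere_diam_mm: float = 70.0,
                 cuboid_dims_mm: Sequence[float] = (30.0, 60.0, 40.0),
                 posterior_frac: float = 0.55) -> AirspaceDomain:
    """Position the inlet sphere and the oropharynx cuboid.

    The sphere is centred on the nasal tip.  The cuboid (mm edges in
    (AP, SI, LR) order) is placed on the oropharynx analogue: the most
    inferior connected air slab posterior to the nasal channels, centred
    on that slab's centroid with its floor at the slab's lowest air.
    """
    air = np.asarray(air, dtype=bool)
    shape = air.shape
    tip = tuple(int(v) for v in tip)

    # the sphere may be clipped by the volume boundary (limited field of
    # view anterior to the nose); it must not be larger than the grid
    r_vox = 0.5 * sphere_diam_mm / spacing
    for a, name in zip(range(3), CANONICAL_AXES):
        if 2 * r_vox > shape[a] or not (0 <= tip[a] < shape[a]):
            raise SegmentationError(
                f"tip sphere (diameter {sphere_diam_mm} mm) exceeds grid "
                f"bounds along the {name} axis")

    dims_vox = tuple(max(1, int(round(e / spacing))) for e in cuboid_dims_mm)
    ap_cut = int(posterior_frac * shape[AP])
    posterior = air.copy()
    posterior[:ap_cut] = False
    if not posterior.any():
        raise SegmentationError("no air posterior to the channel junction")
    si_idx = np.argwhere(posterior)
    si_max = si_idx[:, SI].max()
    slab = posterior & (np.arange(shape[SI])[None, :, None]
                        > si_max - dims_vox[SI])
    centroid = np.argwhere(slab).mean(axis=0)
    origin = [0, 0, 0]
    origin[SI] = int(si_max - dims_vox[SI] + 1)
    origin[AP] = int(round(centroid[AP] - dims_vox[AP] / 2))
    origin[LR] = int(round(centroid[LR] - dims_vox[LR] / 2))
    for a, name in zip(range(3), CANONICAL_AXES):
        if origin[a] < 0 or origin[a] + dims_vox[a] > shape[a]:
            raise SegmentationError(
                f"oropharynx cuboid exceeds grid bounds along the {name} axis")
    return AirspaceDomain(air_mask=air, tip_vox=tip,
                          sphere_diam_mm=sphere_diam_mm,
                          cuboid_origin_vox=tuple(origin),
                          cuboid_dims_vox=dims_vox, spacing=spacing)


def grow_airway(domain: AirspaceDomain) -> AirspaceDomain:
    """Keep exactly the 26-connected air component seeded in the cuboid.

    All other air voxels (disconnected pockets, background) are removed.
    The retained component must reach the sphere surface, otherwise there
    is no airway path between the probes.
    """
    air = domain.air_mask
    seed_region = domain.cuboid_mask() & air
    if not seed_region.any():
        raise SegmentationError("seed is not air: the cuboid contains no air voxel")
    labels, _ = ndimage.label(air, structure=_STRUCT26)
    seed_labels = np.unique(labels[seed_region])
    seed_labels = seed_labels[seed_labels > 0]
    kept = np.isin(labels, seed_labels)
    if not (kept & domain.sphere_surface_mask()).any():
        raise SegmentationError(
            "no airway path: grown component does not reach the sphere surface")
    return replace(domain, air_mask=kept)


def _nostril_aperture(air: np.ndarray, side_slice: slice,
                      start_ap: int = 0) -> tuple:
    """First anterior slice where one side's air is enclosed by tissue.

    Returns ``(ap_index, in-slice mask)`` of the aperture component.
    Enclosed means the in-slice 8-connected air component touches neither
    the grid border nor the opposite half (it is a channel cross-section,
    not exterior air).
    """
    struct2 = np.ones((3, 3), dtype=bool)
    ny, nz = air.shape[SI], air.shape[LR]
    for ap in range(start_ap, air.shape[AP]):
        sl = np.zeros((ny, nz), dtype=bool)
        sl[:, side_slice] = air[ap][:, side_slice]
        if not sl.any():
            continue
        labels, num = ndimage.label(sl, structure=struct2)
        for lab in range(1, num + 1):
            comp = labels == lab
            rr, cc = np.nonzero(comp)
            touches_border = (rr.min() == 0 or rr.max() == ny - 1
                              or cc.min() == 0 or cc.max() == nz - 1)
            touches_cut = (cc.min() == side_slice.start
                           or cc.max() == (side_slice.stop - 1))
            # exterior air in-slice is border-connected; the nostril channel
            # section is fully surrounded by tissue within its half
            if not touches_border and not touches_cut:
                return ap, comp
    raise SegmentationError("nostril aperture not found on that side")


def block_nostril(domain: AirspaceDomain, side: str,
                  plug_thickness: int = 3) -> AirspaceDomain:
    """Convert one nostril aperture to wall (virtual plug).

    The aperture is the most anterior enclosed air cross-section of that
    side's channel; a plug of ``plug_thickness`` slices along the channel
    axis is converted to tissue.  The remaining open side must still
    connect the sphere surface to the cuboid.  ``side="none"`` is the
    identity.
    """
    if side == "none":
        return domain
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    if domain.blocked_side == side:
        return domain
    air = domain.air_mask.copy()
    half = domain.nostril_half(side)
    ap0, _ = _nostril_aperture(air, half)
    for ap in range(ap0, min(ap0 + plug_thickness, air.shape[AP])):
        sl = np.zeros(air.shape[1:], dtype=bool)
        sl[:, half] = air[ap][:, half]
        labels, num = ndimage.label(sl, structure=np.ones((3, 3), dtype=bool))
        for lab in range(1, num + 1):
            comp = labels == lab
            rr, cc = np.nonzero(comp)
            if (rr.min() > 0 and rr.max() < air.shape[SI] - 1
                    and cc.min() > half.start and cc.max() < half.stop - 1):
                air[ap][comp] = False
    blocked = ("both" if domain.blocked_side not in ("none", side) else side)
    out = replace(domain, air_mask=air, blocked_side=blocked)
    # connectivity re-check: the open side must still link the probes
    labels, _ = ndimage.label(air, structure=_STRUCT26)
    sphere_labels = set(np.unique(labels[out.sphere_surface_mask() & air])) - {0}
    cuboid_labels = set(np.unique(labels[out.cuboid_mask() & air])) - {0}
    if not (sphere_labels & cuboid_labels):
        raise SegmentationError(
            "no airway path: blocking disconnected the sphere from the oropharynx")
    return out


def extract_airspace(vol: HUVolume, hu_cut: float = -460.0,
                     sphere_diam_mm: float = 70.0,
                     cuboid_dims_mm: Sequence[float] = (30.0, 60.0, 40.0),
                     band_frac: float = 0.25,
                     posterior_frac: float = 0.55,
                     block: str = "none",
                     sdf: Optional[np.ndarray] = None) -> AirspaceDomain:
    """Full automated extraction: threshold, tip, probes, region growing.

    Optionally blocks one nostril afterwards.  ``sdf`` (signed distance to
    a smooth wall surface, lattice units) is forwarded to the solver when
    the geometry has an analytic surface; CT masks leave it None.
    """
    vol = vol.to_canonical()
    air = threshold_air(vol, hu_cut)
    tip = detect_tip(air, band_frac=band_frac)
    domain = place_probes(air, tip, vol.spacing,
                          sphere_diam_mm=sphere_diam_mm,
                          cuboid_dims_mm=cuboid_dims_mm,
                          posterior_frac=posterior_frac)
    domain = grow_airway(domain)
    domain.sdf = sdf
    if block != "none":
        domain = block_nostril(domain, block)
    return domain
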