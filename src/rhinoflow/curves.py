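"""Pressure-flow (AAR) curve assembly, binning, exclusion and resistance.

Sign conventions follow the rhinomanometry plot quadrants: inspiration
occupies positive flow / positive pressure drop, expiration negative flow /
negative pressure drop.  The simulated sweep covers 0..600 ml/s in steps of
50 ml/s for both respiration phases of each nostril (25 conditions per side
counting the shared zero-flow point).

Flow binning groups samples into 50 ml/s bins centred on multiples of 50
(half-open: a boundary value such as 25 ml/s goes to the upper bin), bins
whose aggregated signed pressure lies within (-25, 25) Pa are excluded
(differentiating inspiration from expiration is impossible there), and
resistance at the 150 Pa working point uses all points whose |dp| falls in
[125, 175] Pa during inspiration: R150 = 150 / mean(|flow|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lbm import (FlowCondition, LatticeConfig, PressureField,
                  apply_boundaries, run_to_stationary, set_flow_rate)

logger = logging.getLogger(__name__)

__all__ = [
    "AARCurve", "BinnedCurve", "ResistanceRecord",
    "SWEEP_FLOWS", "sweep_conditions",
    "extract_dp", "build_sim_curve", "bin_curve", "drop_nearzero",
    "resistance150", "choose_clinical_state", "rohrer_r150_flow",
]

#: Simulated flow-rate magnitudes, ml/s.
SWEEP_FLOWS = tuple(range(0, 601, 50))


def sweep_conditions(side: str) -> list:
    """The 25 flow conditions of one side's sweep (zero flow counted once)."""
    conds = [FlowCondition(q, "inspiration", side) for q in SWEEP_FLOWS]
    conds += [FlowCondition(q, "expiration", side) for q in SWEEP_FLOWS[1:]]
    return conds


@dataclass
class AARCurve:
    """Ordered (flow, pressure) samples of one side/state.

    ``flow`` is signed (ml/s, negative = expiration), ``pressure`` is the
    signed transnasal pressure drop (Pa).  ``flagged`` marks samples from
    non-converged solver runs; they are excluded downstream.
    """

    flow: np.ndarray
    pressure: np.ndarray
    subject: str = ""
    side: str = ""
    state: str = ""
    flagged: Optional[np.ndarray] = None

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.flow.shape != self.pressure.shape:
            raise ValueError("flow and pressure must have equal length")
        if self.flagged is None:
            self.flagged = np.zeros(self.flow.shape, dtype=bool)
        if not (np.isfinite(self.flow).all() and np.isfinite(self.pressure).all()):
            raise ValueError("curve contains non-finite samples")

    def __len__(self) -> int:
        return len(self.flow)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject, "side": self.side, "state": self.state,
            "flow_ml_s": self.flow, "pressure_pa": self.pressure,
        })


@dataclass
class BinnedCurve:
    """Flow-binned aggregate of an AAR curve.

    One row per retained bin: signed bin centre (multiple of 50 ml/s),
    signed mean pressure, mean absolute pressure, sd and count.
    """

    table: pd.DataFrame          # bin_flow, mean_pressure_signed, mean_pressure, sd, n
    subject: str = ""
    side: str = ""
    state: str = ""

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bins(self) -> np.ndarray:
        return self.table["bin_flow"].to_numpy()

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())


@dataclass
class ResistanceRecord:
    """Nasal resistance at the 150 Pa working point (inspiration)."""

    subject: str
    side: str
    resistance: float            # sPa/ml; NaN when no sample reaches the band
    mean_flow: float             # ml/s over the qualifying samples
    n_points: int
    source: str = ""             # clinical | simulated
    phase: str = "inspiration"

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.resistance)


# ---------------------------------------------------------------------------
# solver-facing operations


def extract_dp(pressure_field: PressureField, domain) -> float:
    """Transnasal pressure drop dp = p1 - p2 from one converged run.

    p1 is the mean pressure over the fluid voxels inside the nasal-tip
    sphere, p2 over those inside the oropharynx cuboid.
    """
    air = domain.air_mask
    m1 = domain.sphere_mask() & air
    m2 = domain.cuboid_mask() & air
    if not m1.any() or not m2.any():
        raise ValueError("empty probe fluid set (sphere or cuboid contains no air)")
    p1 = float(np.nanmean(pressure_field.pressure[m1]))
    p2 = float(np.nanmean(pressure_field.pressure[m2]))
    return p1 - p2


def build_sim_curve(domain, cfg: LatticeConfig, side: str,
                    subject: str = "") -> AARCurve:
    """Run the full 0..600 ml/s sweep for both phases of one (blocked) side.

    Within each phase the flow is ramped upward and every run warm-starts
    from the previous converged state, which cuts the transient cost of the
    25-condition sweep by roughly an order of magnitude.  Non-converged
    points are flagged and excluded downstream rather than imputed.
    """
    lattice = apply_boundaries(domain, FlowCondition(0.0, "inspiration", side), cfg)
    flows, dps, flags = [], [], []
    for phase, sign in (("inspiration", 1.0), ("expiration", -1.0)):
        state = None
        mags = SWEEP_FLOWS if phase == "inspiration" else SWEEP_FLOWS[1:]
        for q in mags:
            set_flow_rate(lattice, domain, FlowCondition(q, phase, side), cfg)
            result = run_to_stationary(lattice, cfg, init_state=state)
            state = result.state
            flows.append(sign * q)
            dps.append(result.dp_pa)
            flags.append(not result.converged)
            if not result.converged:
                logger.warning("non-converged run: side=%s phase=%s Q=%g ml/s",
                               side, phase, q)
    return AARCurve(np.array(flows), np.array(dps), subject=subject,
                    side=side, state="simulated", flagged=np.array(flags))


# ---------------------------------------------------------------------------
# binning, exclusion, resistance


def bin_curve(curve: AARCurve) -> BinnedCurve:
    """Group samples into 50 ml/s bins centred on multiples of 50.

    Bin edges are half-open [centre - 25, centre + 25): a sample on the
    boundary joins the upper bin.  Flagged (non-converged) samples are
    dropped first.  Binning conserves the remaining sample count.
    """
    keep = ~curve.flagged
    flow = curve.flow[keep]
    pres = curve.pressure[keep]
    if len(flow) == 0:
        table = pd.DataFrame(columns=["bin_flow", "mean_pressure_signed",
                                      "mean_pressure", "sd", "n"])
        return BinnedCurve(table, curve.subject, curve.side, curve.state)
    centers = 50.0 * np.floor((flow + 25.0) / 50.0)
    df = pd.DataFrame({"bin_flow": centers, "pressure": pres})
    g = df.groupby("bin_flow")["pressure"]
    table = pd.DataFrame({
        "bin_flow": np.array(sorted(g.groups)),
        "mean_pressure_signed": g.mean().loc[sorted(g.groups)].to_numpy(),
        "sd": g.std(ddof=1).loc[sorted(g.groups)].fillna(0.0).to_numpy(),
        "n": g.size().loc[sorted(g.groups)].to_numpy(),
    })
    table["mean_pressure"] = table["mean_pressure_signed"].abs()
    table = table[["bin_flow", "mean_pressure_signed", "mean_pressure", "sd", "n"]]
    return BinnedCurve(table.reset_index(drop=True),
                       curve.subject, curve.side, curve.state)


def drop_nearzero(binned: BinnedCurve) -> BinnedCurve:
    """Remove bins whose aggregated signed pressure lies within (-25, 25) Pa.

    Near-zero pressures cannot be attributed to inspiration or expiration;
    in a simulated sweep this removes the zero-flow bin.
    """
    t = binned.table
    keep = ~t["mean_pressure_signed"].between(-25.0, 25.0, inclusive="neither")
    return BinnedCurve(t[keep].reset_index(drop=True),
                       binned.subject, binned.side, binned.state)


def _points_of(data) -> tuple:
    """(flow, pressure) arrays from an AARCurve or BinnedCurve."""
    if isinstance(data, BinnedCurve):
        return (data.table["bin_flow"].to_numpy(),
                data.table["mean_pressure_signed"].to_numpy())
    keep = ~data.flagged
    return data.flow[keep], data.pressure[keep]


def resistance150(data, phase: str = "inspiration", source: str = "",
                  numerator: str = "labeled") -> ResistanceRecord:
    """Resistance at the 150 Pa working point.

    Samples with |dp| in [125, 175] Pa are titled 150 Pa; their absolute
    flows are averaged and the resistance is ``150 / mean_flow`` (sPa/ml).
    ``numerator="actual"`` divides the qualifying samples' mean |dp|
    instead of the 150 Pa label.  Inspiration samples live in the positive
    flow/pressure quadrant.  Returns a missing-value record (NaN) when no
    sample reaches the band.
    """
    flow, pres = _points_of(data)
    if phase == "inspiration":
        quadrant = (flow > 0) & (pres > 0)
    else:
        quadrant = (flow < 0) & (pres < 0)
    band = quadrant & (np.abs(pres) >= 125.0) & (np.abs(pres) <= 175.0)
    subject = getattr(data, "subject", "")
    side = getattr(data, "side", "")
    if not band.any():
        return ResistanceRecord(subject, side, np.nan, np.nan, 0, source, phase)
    mean_flow = float(np.mean(np.abs(flow[band])))
    num = 150.0 if numerator == "labeled" else float(np.mean(np.abs(pres[band])))
    return ResistanceRecord(subject, side, num / mean_flow, mean_flow,
                            int(band.sum()), source, phase)


def rohrer_r150_flow(k1: float, k2: float, dp: float = 150.0) -> float:
    """Analytic flow Q* at which a noise-free Rohrer curve reaches dp.

    Solves k1 Q + k2 Q^2 = dp for the positive root (inspiration branch).
    """
    if k1 == 0 and k2 == 0:
        raise ValueError("k1 and k2 cannot both be zero")
    if k1 > 0 and 4.0 * k2 * dp < 1e-10 * k1 * k1:
        # quadratic term negligible: series expansion avoids cancellation
        return dp / k1 * (1.0 - k2 * dp / (k1 * k1))
    return (-k1 + np.sqrt(k1 * k1 + 4.0 * k2 * dp)) / (2.0 * k2)


def choose_clinical_state(congested: BinnedCurve, decongested: BinnedCurve,
                          simulated: BinnedCurve, min_common: int = 3):
    """Pick the mucosal state whose curve better matches the simulated one.

    The match criterion is the mean absolute log10 pressure ratio over the
    bins common to both curves (retained, positive pressures).  Ties go to
    the congested state (and are logged).  Returns ``(label, curve)``.
    """
    sim = simulated.table.set_index("bin_flow")["mean_pressure"]

    def distance(cl: BinnedCurve) -> float:
        t = cl.table.set_index("bin_flow")["mean_pressure"]
        common = t.index.intersection(sim.index)
        common = [b for b in common if t[b] > 0 and sim[b] > 0]
        if len(common) < min_common:
            raise ValueError(
                f"fewer than {min_common} common bins between clinical "
                f"({cl.state}) and simulated curves")
        return float(np.mean(np.abs(np.log10(t[common].to_numpy())
                                    - np.log10(sim[common].to_numpy()))))

    d_con = distance(congested)
    d_dec = distance(decongested)
    if d_con == d_dec:
        logger.info("state-match tie (%.4g); choosing congested", d_con)
        return "congested", congested
    if d_con < d_dec:
        return "congested", congested
    return "decongested", decongested
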