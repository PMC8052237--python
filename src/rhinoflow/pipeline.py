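"""End-to-end synthetic study: phantoms -> segmentation -> simulated and
clinical pressure-flow curves -> agreement statistics.

One :func:`run_study` call reproduces the structure of a five-subject
virtual-rhinomanometry comparison: for every subject a bent dual-channel
phantom with a unilateral constriction is built and segmented, each side
is simulated over the 0..600 ml/s sweep with the other nostril blocked
(25 pressure-drop evaluations per side), synthetic congested/decongested
clinical curves are generated from per-subject Rohrer models (optionally
taking the detour through plot rendering and colour-threshold
digitization), and measured and simulated pressures/resistances are
compared by factor-adjusted correlation, Pearson correlation, paired
t-test and log-scale Bland-Altman agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io
from .airspace import extract_airspace, block_nostril
from .curves import (AARCurve, BinnedCurve, bin_curve, build_sim_curve,
                     choose_clinical_state, drop_nearzero, resistance150)
from .digitizer import ColorSpec, DigitizerConfig, digitize_image
from .phantom import (PhantomSpec, RohrerModel, breathing_trace,
                      build_phantom_truth, desk_scale_config)
from .render import PAPER_PALETTE, render_aar_plot
from .stats import (PairedMeasurements, adjusted_correlation, bland_altman,
                    paired_ttest, pearson, plot_bland_altman)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "run_pipeline",
           "clinical_curve", "load_study_tables"]


@dataclass
class StudyConfig:
    """Reproducible configuration of one synthetic comparison study.

    Defaults are the desk-scale five-subject conditions: 48^3 phantoms,
    four right-sided and one left-sided constriction (mirroring the septal
    deviation pattern of a typical septoplasty cohort), clinical Rohrer
    curves with 5 Pa pressure noise, and the digitization detour enabled.
    """

    n_subjects: int = 5
    grid_shape: tuple = (48, 48, 48)
    spacing: float = 2.667                 # mm
    nostril_radius_mm: float = 12.0
    constriction_factor: float = 0.85
    constriction_sides: tuple = ("right", "right", "right", "right", "left")
    clinical_noise_sd: float = 5.0         # Pa
    digitize: bool = True
    target_r150: float = 0.55              # Pa/(ml/s), desk-scale anchor
    seed: int = 0
    write_artifacts: bool = False          # NIfTI masks / PNG plots / CSVs

    def phantom_spec(self, subject_index: int, seed: int) -> PhantomSpec:
        side = self.constriction_sides[subject_index % len(self.constriction_sides)]
        return PhantomSpec(grid_shape=self.grid_shape, spacing=self.spacing,
                           nostril_radius_mm=self.nostril_radius_mm,
                           constriction_side=side,
                           constriction_factor=self.constriction_factor,
                           seed=seed)


@dataclass
class StudyResult:
    """Everything the study computed, plus the manifest of counts."""

    sim_curves: List[AARCurve]
    sim_binned: List[BinnedCurve]
    clinical_binned: List[BinnedCurve]
    chosen_states: Dict[tuple, str]
    pressure_pairs: PairedMeasurements
    resistance_pairs: PairedMeasurements
    pressure_agreement: list
    resistance_agreement: list
    adjusted_r: float
    adjusted_p: float
    resistance_pearson: tuple
    resistance_ttest: dict
    manifest: dict


def clinical_curve(model: RohrerModel, subject: str = "", side: str = "",
                   state: str = "", **trace_kwargs) -> AARCurve:
    """Synthetic clinical AAR curve: a dense, noisy multi-breath recording."""
    flow, pressure = breathing_trace(model, **trace_kwargs)
    return AARCurve(flow, pressure, subject=subject, side=side, state=state)


def _subject_models(rng: np.random.Generator, constricted: str,
                    noise_sd: float) -> Dict[tuple, RohrerModel]:
    """Per-side congested/decongested Rohrer models for one subject.

    Decongested coefficients sit near the anatomical resistance of the
    phantom channels (higher on the constricted side); congestion scales
    both coefficients up, so congested >= decongested holds per side.
    """
    out = {}
    for side in ("left", "right"):
        base_k1 = 0.72 if side == constricted else 0.55
        k1 = base_k1 * (1.0 + rng.normal(0.0, 0.07))
        k2 = 2.0e-4 * (1.0 + rng.normal(0.0, 0.15))
        congestion = rng.uniform(1.4, 1.9)
        seeds = rng.integers(0, 2 ** 31 - 1, size=2)
        out[(side, "decongested")] = RohrerModel(
            k1=max(k1, 0.05), k2=max(k2, 0.0), noise_sd=noise_sd,
            seed=int(seeds[0]))
        out[(side, "congested")] = RohrerModel(
            k1=max(k1, 0.05) * congestion, k2=max(k2, 0.0) * congestion,
            noise_sd=noise_sd, seed=int(seeds[1]))
    return out


def _digitize_subject(curves: Dict[str, AARCurve]) -> Dict[str, AARCurve]:
    """Round-trip the four clinical curves through a rendered report page."""
    traces = {k: (c.flow, c.pressure) for k, c in curves.items()}
    image, calibration = render_aar_plot(traces)
    cfg = DigitizerConfig([ColorSpec(k, PAPER_PALETTE[k]) for k in traces],
                          window=5, axis_calibration=calibration)
    digitized = digitize_image(image, cfg)
    out = {}
    for key, curve in curves.items():
        d = digitized.get(key)
        if d is None or len(d) == 0:
            logger.warning("digitization lost curve %s; using numeric data", key)
            out[key] = curve
        else:
            out[key] = AARCurve(d.flow, d.pressure, subject=curve.subject,
                                side=curve.side, state=curve.state)
    return out


def run_study(cfg: StudyConfig, outdir: Optional[Path] = None) -> StudyResult:
    """Run the full synthetic comparison study (see module docstring)."""
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    sim_curves: List[AARCurve] = []
    sim_binned: List[BinnedCurve] = []
    clinical_binned: List[BinnedCurve] = []
    chosen: Dict[tuple, str] = {}
    pressure_rows = []
    res_rows = []
    dp_evaluations = 0

    for i, sseq in enumerate(subject_seeds):
        subject = f"s{i + 1}"
        child = np.random.default_rng(sseq)
        spec_seed = int(child.integers(0, 2 ** 31 - 1))
        spec = cfg.phantom_spec(i, spec_seed)
        truth = build_phantom_truth(spec)
        lattice_cfg = desk_scale_config(spec, target_r150=cfg.target_r150)
        domain = extract_airspace(truth.volume,
                                  sphere_diam_mm=spec.sphere_diam_mm,
                                  cuboid_dims_mm=spec.cuboid_dims_mm,
                                  sdf=truth.sdf)
        if cfg.write_artifacts and outdir is not None:
            io.save_nifti(truth.volume, outdir / f"{subject}_hu.nii.gz")
            io.save_mask_nifti(domain.air_mask, spec.spacing,
                               outdir / f"{subject}_air.nii.gz")

        models = _subject_models(child, spec.constriction_side,
                                 cfg.clinical_noise_sd)
        raw_clinical = {}
        for (side, state), model in models.items():
            label = f"{state}_{side}"
            raw_clinical[label] = clinical_curve(
                model, subject=subject, side=side, state=state,
                seed=int(child.integers(0, 2 ** 31 - 1)))
        if cfg.digitize:
            raw_clinical = _digitize_subject(raw_clinical)

        for side in ("left", "right"):
            other = "right" if side == "left" else "left"
            blocked = block_nostril(domain, other)
            sim = build_sim_curve(blocked, lattice_cfg, side=side,
                                  subject=subject)
            dp_evaluations += len(sim)
            sim_curves.append(sim)
            sim_b = drop_nearzero(bin_curve(sim))
            sim_binned.append(sim_b)

            con_b = drop_nearzero(bin_curve(raw_clinical[f"congested_{side}"]))
            dec_b = drop_nearzero(bin_curve(raw_clinical[f"decongested_{side}"]))
            clinical_binned.extend([con_b, dec_b])
            state, clin_b = choose_clinical_state(con_b, dec_b, sim_b)
            chosen[(subject, side)] = state

            # paired pressures over the bins common to both curves
            ct = clin_b.table.set_index("bin_flow")
            st = sim_b.table.set_index("bin_flow")
            for b in ct.index.intersection(st.index):
                pressure_rows.append({
                    "subject": subject, "side": side,
                    "phase": "inspiration" if b > 0 else "expiration",
                    "bin_flow": float(b),
                    "rhino_value": float(ct.loc[b, "mean_pressure"]),
                    "sim_value": float(st.loc[b, "mean_pressure"]),
                })

            r_sim = resistance150(sim_b, source="simulated")
            r_rhino = resistance150(clin_b, source="clinical")
            res_rows.append({"subject": subject, "side": side,
                             "rhino_value": r_rhino.resistance,
                             "sim_value": r_sim.resistance,
                             "state": state})

    pressure_pairs = PairedMeasurements(pd.DataFrame(pressure_rows))
    res_table = pd.DataFrame(res_rows).dropna(subset=["rhino_value", "sim_value"])
    resistance_pairs = PairedMeasurements(res_table)

    adj_r, adj_p = adjusted_correlation(pressure_pairs)
    pres_ba = bland_altman(pressure_pairs, stratum_keys=("side", "phase"))
    res_ba = bland_altman(resistance_pairs, stratum_keys=())
    if len(res_table) >= 3:
        res_pearson = pearson(res_table["rhino_value"], res_table["sim_value"])
    else:
        res_pearson = (float("nan"), float("nan"), "undefined")
    if len(res_table) >= 2:
        res_ttest = paired_ttest(res_table["rhino_value"],
                                 res_table["sim_value"])
    else:
        res_ttest = {"n": len(res_table)}

    n_sides = 2 * cfg.n_subjects
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "grid_shape": list(cfg.grid_shape),
        "counts": {
            "dp_evaluations_per_side": len(sim_curves[0]) if sim_curves else 0,
            "dp_evaluations_total": dp_evaluations,
            "simpress_retained": int(sum(len(b) for b in sim_binned)),
            "rhinopress_retained_paired": len(pressure_pairs),
            "simres150": int(np.isfinite(
                pd.DataFrame(res_rows)["sim_value"]).sum()),
            "rhinores150": int(np.isfinite(
                pd.DataFrame(res_rows)["rhino_value"]).sum()),
        },
        "chosen_states": {f"{k[0]}/{k[1]}": v for k, v in chosen.items()},
        "statistics": {
            "adjusted_r_pressure": adj_r,
            "adjusted_p_pressure": adj_p,
            "pearson_r_resistance": res_pearson[0],
            "pearson_p_resistance": res_pearson[1],
            "pearson_category": res_pearson[2],
            "ttest": res_ttest,
            "pressure_agreement": [
                {"stratum": list(a.stratum), "n": a.n,
                 "mean_logdiff_pct": a.percent[0],
                 "half_width_pct": a.percent[1],
                 "ratio_mean": a.ratio_mean,
                 "ratio_half_width": a.ratio_half_width}
                for a in pres_ba],
            "resistance_agreement": [
                {"stratum": list(a.stratum), "n": a.n,
                 "mean_logdiff_pct": a.percent[0],
                 "half_width_pct": a.percent[1],
                 "ratio_mean": a.ratio_mean,
                 "ratio_half_width": a.ratio_half_width}
                for a in res_ba],
        },
    }

    result = StudyResult(
        sim_curves=sim_curves, sim_binned=sim_binned,
        clinical_binned=clinical_binned, chosen_states=chosen,
        pressure_pairs=pressure_pairs, resistance_pairs=resistance_pairs,
        pressure_agreement=pres_ba, resistance_agreement=res_ba,
        adjusted_r=adj_r, adjusted_p=adj_p,
        resistance_pearson=res_pearson, resistance_ttest=res_ttest,
        manifest=manifest)

    if outdir is not None:
        io.save_json(manifest, outdir / "manifest.json")
        io.save_curves(sim_curves, outdir / "simulated_curves.csv")
        io.save_binned(sim_binned, outdir / "simulated_binned.csv")
        io.save_binned(clinical_binned, outdir / "clinical_binned.csv")
        pressure_pairs.table.to_csv(outdir / "pressure_pairs.csv", index=False)
        resistance_pairs.table.to_csv(outdir / "resistance_pairs.csv",
                                      index=False)
        if cfg.write_artifacts:
            plot_bland_altman(pressure_pairs,
                              outdir / "bland_altman_pressure.png")
    return result


# keep the imperative name for the CLI surface
run_pipeline = run_study


def load_study_tables(path) -> PairedMeasurements:
    """Load externally prepared paired tables (CSV) for the agreement stage.

    The schema matches the pipeline's own pressure_pairs.csv: subject,
    side, phase, bin_flow, rhino_value, sim_value (resistance tables omit
    phase/bin_flow).  Raises with the list of missing columns on schema
    mismatch.
    """
    df = pd.read_csv(path)
    required = {"subject", "side", "rhino_value", "sim_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return PairedMeasurements(df)
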