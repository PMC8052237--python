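"""Method-comparison statistics: correlation and log-scale Bland-Altman.

Measured (rhinomanometry) and simulated pressures/resistances are compared
on the log10 scale: the per-row difference d = log10(measured) -
log10(simulated) is the log of the proportional deviation, so 10^d is the
measured/simulated ratio.  Per stratum (nasal side x respiration phase,
or unilateral-inspiration for resistance) the Bland-Altman summary reports
the mean of d and a dispersion half-width (1.96 sd by default), both also
back-transformed to ratio factors: "measured was 10^mean +- 10^halfwidth
times greater than simulated".

The overall pressure correlation removes variation due to subjects, sides
and phases by residualising both log-pressures on those categorical
factors (ordinary least squares on indicator variables) and correlating
the residuals; resistances are compared by plain Pearson correlation and a
paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements", "AgreementSummary",
    "logdiff", "bland_altman", "adjusted_correlation", "pearson",
    "paired_ttest", "correlation_category", "plot_bland_altman",
]

PRESSURE_KEYS = ["subject", "side", "phase", "bin_flow"]


@dataclass
class PairedMeasurements:
    """Paired measured/simulated values, one row per key.

    For pressures: columns subject, side, phase, bin_flow, rhino_value,
    sim_value (Pa).  For resistances: subject, side, rhino_value, sim_value
    (sPa/ml).  Values must be strictly positive (log-transformable).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("rhino_value", "sim_value"):
            if col not in t.columns:
                raise ValueError(f"missing column {col!r}")
            bad = ~(t[col] > 0) | ~np.isfinite(t[col])
            if bad.any():
                rows = t.index[bad].tolist()[:5]
                raise ValueError(
                    f"non-positive or non-finite {col} in rows {rows}")
        if set(PRESSURE_KEYS) <= set(t.columns):
            keys = PRESSURE_KEYS                    # pressure table
        elif {"subject", "side"} <= set(t.columns) and "bin_flow" not in t.columns \
                and "phase" not in t.columns:
            keys = ["subject", "side"]              # resistance table
        else:
            keys = None
        if keys and t.duplicated(subset=keys).any():
            raise ValueError("duplicate rows for the same key")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AgreementSummary:
    """Log-scale Bland-Altman agreement for one stratum.

    ``mean_logdiff`` and ``half_width`` are in log10 units (a value of
    0.02 prints as 2% logarithmic proportional deviation);
    ``ratio_mean = 10^mean_logdiff`` and ``ratio_half_width =
    10^half_width`` are the back-transformed factors.
    """

    stratum: tuple
    n: int
    mean_logdiff: float
    half_width: float
    ratio_mean: float
    ratio_half_width: float

    @property
    def percent(self) -> tuple:
        """(mean, half-width) as percent of log10 units, as printed in
        agreement tables (0.02 -> 2)."""
        return 100.0 * self.mean_logdiff, 100.0 * self.half_width


def logdiff(pairs: PairedMeasurements) -> np.ndarray:
    """Per-row d = log10(measured) - log10(simulated); 10^d is the ratio."""
    t = pairs.table
    return np.log10(t["rhino_value"].to_numpy()) - np.log10(t["sim_value"].to_numpy())


def bland_altman(pairs: PairedMeasurements,
                 stratum_keys: Sequence[str] = ("side", "phase"),
                 ci_multiplier: float = 1.96,
                 min_n: int = 3) -> list:
    """Bland-Altman agreement per stratum on the log10 scale.

    The dispersion half-width is ``ci_multiplier`` (default 1.96) times the
    sample standard deviation of the log-differences.  Strata with fewer
    than ``min_n`` rows are skipped with a warning.  Returns a list of
    :class:`AgreementSummary`.
    """
    t = pairs.table.copy()
    t["_d"] = logdiff(pairs)
    out = []
    keys = list(stratum_keys)
    groups = t.groupby(keys) if keys else [((), t)]
    for name, g in groups:
        name = name if isinstance(name, tuple) else (name,)
        if len(g) < min_n:
            warnings.warn(f"stratum {name}: only {len(g)} pairs, skipped")
            continue
        d = g["_d"].to_numpy()
        mean = float(d.mean())
        half = float(ci_multiplier * d.std(ddof=1))
        out.append(AgreementSummary(stratum=name, n=len(g),
                                    mean_logdiff=mean, half_width=half,
                                    ratio_mean=float(10.0 ** mean),
                                    ratio_half_width=float(10.0 ** half)))
    return out


def _factor_design(t: pd.DataFrame, factors: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(t))]
    for f in factors:
        d = pd.get_dummies(t[f].astype(str), drop_first=True)
        if len(d.columns):
            cols.append(d.to_numpy(dtype=float))
    return np.column_stack(cols)


def adjusted_correlation(pairs: PairedMeasurements,
                         factors: Sequence[str] = ("subject", "side", "phase")):
    """Correlation of log pressures after removing categorical factors.

    Both log10 columns are residualised on the additive factor model
    (least squares on indicator variables); r is the Pearson correlation
    of the residuals and p comes from the t transform with
    df = n - rank(design) - 1.  With constant factors this equals the
    plain Pearson correlation of the logs.
    """
    t = pairs.table
    x = np.log10(t["rhino_value"].to_numpy())
    y = np.log10(t["sim_value"].to_numpy())
    design = _factor_design(t, factors)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient factor design (aliased factor levels)")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float((rx * ry).sum() / denom)
    df = len(x) - rank - 1
    if df <= 0:
        raise ValueError("not enough rows for the factor model")
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    tstat = r_clip * np.sqrt(df / (1.0 - r_clip ** 2))
    p = float(2.0 * sps.t.sf(abs(tstat), df))
    return r, p


def correlation_category(r: float) -> str:
    """Strength label: strong r >= 0.8, moderate 0.6 <= r < 0.8, else weak.

    Boundary values are assigned upward.
    """
    if r >= 0.8:
        return "strong"
    if r >= 0.6:
        return "moderate"
    return "weak"


def pearson(x, y) -> tuple:
    """Product-moment correlation with two-sided p and strength category."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), correlation_category(float(r))


def paired_ttest(rhino, sim) -> dict:
    """Paired t-test plus the per-vector mean +- sd descriptives.

    A degenerate case (all differences equal but nonzero, sd = 0) reports
    an infinite t with a warning; identical vectors give t = 0, p = 1.
    """
    rhino = np.asarray(rhino, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if rhino.shape != sim.shape or len(rhino) < 2:
        raise ValueError("need equal-length paired vectors, n >= 2")
    d = rhino - sim
    out = {
        "rhino_mean": float(rhino.mean()), "rhino_sd": float(rhino.std(ddof=1)),
        "sim_mean": float(sim.mean()), "sim_sd": float(sim.std(ddof=1)),
        "n": len(d),
    }
    if np.allclose(d, 0.0):
        out.update(t=0.0, p=1.0)
        return out
    if np.isclose(d.std(ddof=1), 0.0):
        warnings.warn("all paired differences identical; t is infinite")
        out.update(t=float(np.sign(d.mean()) * np.inf), p=0.0)
        return out
    t, p = sps.ttest_rel(rhino, sim)
    out.update(t=float(t), p=float(p))
    return out


def plot_bland_altman(pairs: PairedMeasurements, path,
                      stratum_keys: Sequence[str] = ("side", "phase"),
                      ci_multiplier: float = 1.96) -> None:
    """Bland-Altman panels (one per stratum) saved as a PNG.

    x: mean of the two log10 values per row; y: their difference; solid
    line at the mean difference, dashed lines at +-``ci_multiplier`` sd,
    green line at perfect agreement.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = pairs.table.copy()
    t["_d"] = logdiff(pairs)
    t["_m"] = 0.5 * (np.log10(t["rhino_value"]) + np.log10(t["sim_value"]))
    keys = list(stratum_keys)
    groups = list(t.groupby(keys)) if keys else [((), t)]
    ncols = min(2, len(groups))
    nrows = (len(groups) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4 * nrows),
                             squeeze=False)
    for ax, (name, g) in zip(axes.ravel(), groups):
        d = g["_d"].to_numpy()
        ax.scatter(g["_m"], d, s=12, alpha=0.7)
        ax.axhline(d.mean(), color="black")
        ax.axhline(0.0, color="green")
        half = ci_multiplier * d.std(ddof=1)
        ax.axhline(d.mean() + half, color="black", linestyle="--")
        ax.axhline(d.mean() - half, color="black", linestyle="--")
        name = name if isinstance(name, tuple) else (name,)
        ax.set_title(" / ".join(str(v) for v in name) or "all")
        ax.set_xlabel("mean of log10 values")
        ax.set_ylabel("log10(measured) - log10(simulated)")
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
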