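"""Processing of raw duty-cycled count series into VMRs and concentrations.

The chain mirrors standard chemical-ionization MS practice: raw channel
counts are normalized to a primary-ion (H3O+ plus H3O+.H2O) rate of 10^6
cps, background corrected, and divided by a normalized sensitivity
(ncps ppbv^-1) obtained from multi-level dynamic-dilution calibrations:

    VMR [ppbv] = I_norm [ncps] / eps_norm [ncps ppbv^-1]

Mass concentrations follow from the ideal gas law. Compounds absent from
the calibration standard are assigned the sensitivity of the closest
calibrated m/z within the same compound class (an oxidation-state proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PRIMARY_ION_TARGET, R_GAS
from .registry import Registry

__all__ = [
    "CalibrationCurve",
    "normalize",
    "background_correct",
    "fit_sensitivity",
    "vmr",
    "vmr_to_mass_conc",
    "mass_conc_to_vmr",
    "assign_surrogate_sensitivity",
    "segment_blocks",
    "block_mean_vmr",
    "process_counts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """Normalized sensitivity of one compound.

    ``eps_norm`` is the slope of a through-origin least-squares fit of
    normalized signal (ncps) against VMR (ppbv); the fit has no intercept
    because a background-corrected signal must vanish at zero VMR.
    """

    compound: str
    levels: tuple          # ((ppbv, ncps), ...)
    eps_norm: float        # ncps ppbv^-1
    r2: float

    def __post_init__(self):
        if self.eps_norm <= 0:
            raise ValueError(f"{self.compound}: eps_norm must be positive")


def normalize(counts, primary):
    """Normalize raw counts (cps) to a primary-ion rate of 10^6 cps."""
    counts = np.asarray(counts, dtype=float)
    primary = np.asarray(primary, dtype=float)
    if np.any(primary <= 0):
        raise ValueError("primary ion rate must be positive (dead primary beam)")
    out = counts * PRIMARY_ION_TARGET / primary
    return float(out) if out.ndim == 0 else out


def background_correct(series, background, floor=True):
    """Subtract a channel background (ncps) from a normalized series.

    Values driven negative by the subtraction are floored at zero (the
    count of floored points is logged); pass ``floor=False`` to keep
    negatives for unbiased averaging.

    Returns ``(corrected, n_floored)``.
    """
    series = np.asarray(series, dtype=float)
    corrected = series - background
    n_floored = 0
    if floor:
        negative = corrected < 0
        n_floored = int(np.count_nonzero(negative))
        if n_floored:
            logger.info("background correction floored %d negative points", n_floored)
        corrected = np.where(negative, 0.0, corrected)
    return (corrected, n_floored)


def fit_sensitivity(levels, compound: str = "") -> CalibrationCurve:
    """Fit a through-origin calibration line to (ppbv, ncps) levels.

    The slope is the normalized sensitivity eps_norm; r2 is computed
    against the through-origin model.
    """
    pts = [(float(x), float(y)) for x, y in levels]
    if len(pts) < 2:
        raise ValueError("calibration requires at least 2 levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(np.unique(x)) < 2:
        raise ValueError("calibration VMR levels must be distinct")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("singular calibration fit (all-zero VMR levels)")
    slope = float(np.dot(x, y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope for {compound or 'compound'}")
    return CalibrationCurve(compound=compound, levels=tuple(pts),
                            eps_norm=slope, r2=r2)


def vmr(i_norm, curve: CalibrationCurve):
    """Background-corrected normalized signal (ncps) to VMR (ppbv)."""
    out = np.asarray(i_norm, dtype=float) / curve.eps_norm
    return float(out) if out.ndim == 0 else out


def vmr_to_mass_conc(v, molar_mass, T, P):
    """VMR (ppbv) to mass concentration (ug m^-3) by the ideal gas law."""
    if T <= 0 or P <= 0:
        raise ValueError("temperature and pressure must be positive")
    out = np.asarray(v, dtype=float) * 1e-9 * P / (R_GAS * T) * molar_mass * 1e6
    return float(out) if out.ndim == 0 else out


def mass_conc_to_vmr(c, molar_mass, T, P):
    """Inverse of :func:`vmr_to_mass_conc`."""
    if T <= 0 or P <= 0:
        raise ValueError("temperature and pressure must be positive")
    out = np.asarray(c, dtype=float) * R_GAS * T / (P * molar_mass) * 1e3
    return float(out) if out.ndim == 0 else out


def assign_surrogate_sensitivity(
    compound_name: str, curves: dict, registry: Registry
) -> CalibrationCurve:
    """Sensitivity for an uncalibrated compound.

    A calibrated compound gets its own curve. Otherwise the choice is
    deterministic: the calibrated compound sharing the same class tag
    whose H3O+ protonated m/z is nearest (ties broken toward lower m/z);
    with no same-class candidate, the nearest calibrated m/z overall is
    used with a warning. The choice is logged.
    """
    if not curves:
        raise ValueError("no calibration curves available")
    if compound_name in curves:
        return curves[compound_name]
    target = registry[compound_name]
    target_mz = target.mz("protonation", "H3O+")

    def candidates(names):
        scored = []
        for name in names:
            mz = registry[name].mz("protonation", "H3O+")
            scored.append((abs(mz - target_mz), mz, name))
        scored.sort()
        return scored

    same_class = [n for n in curves
                  if n in registry and registry[n].class_tag == target.class_tag]
    if same_class:
        _, _, chosen = candidates(same_class)[0]
        logger.info("surrogate sensitivity for %s: %s (same class %s)",
                    compound_name, chosen, target.class_tag)
    else:
        pool = [n for n in curves if n in registry]
        if not pool:
            raise ValueError(
                f"no registry-known calibrated compound for {compound_name!r}")
        _, _, chosen = candidates(pool)[0]
        logger.warning(
            "no %s-class calibration for %s; falling back to nearest m/z (%s)",
            target.class_tag, compound_name, chosen)
    return curves[chosen]


def segment_blocks(df: pd.DataFrame, discard: float = 30.0,
                   min_block: float = 60.0) -> pd.DataFrame:
    """Label contiguous (chamber, mode) blocks and drop settling samples.

    Adds a ``block`` column numbering contiguous runs of identical
    (chamber, mode) labels in time order, then discards the first
    ``discard`` seconds of every block (reagent-ion switching transient).
    Label changes faster than ``min_block`` indicate corrupt input and
    raise.
    """
    if df.empty:
        out = df.copy()
        out["block"] = pd.Series(dtype=int)
        return out
    times = df["time_s"].drop_duplicates().sort_values().to_numpy()
    labels = (df.drop_duplicates("time_s").set_index("time_s")
              .loc[times, ["chamber", "mode"]])
    key = (labels["chamber"] + "|" + labels["mode"]).to_numpy()
    change = np.r_[True, key[1:] != key[:-1]]
    block_of_time = np.cumsum(change) - 1
    starts = times[change]
    # interior block durations: first sample of a block to first of the next
    # (the final block is truncated by the end of acquisition and exempt)
    durations = np.diff(starts)
    if np.any(durations < min_block):
        raise ValueError(
            f"chamber/mode labels change faster than {min_block} s; corrupt input")
    tmap = pd.Series(block_of_time, index=times)
    smap = pd.Series(starts[block_of_time], index=times)
    out = df.copy()
    out["block"] = out["time_s"].map(tmap).astype(int)
    out = out[out["time_s"] - out["time_s"].map(smap) >= discard]
    return out.reset_index(drop=True)


def block_mean_vmr(counts: pd.DataFrame, backgrounds: dict, curves: dict,
                   registry: Registry, discard: float = 30.0,
                   floor: bool = True) -> pd.DataFrame:
    """Counts table -> per-block mean VMR per compound.

    ``backgrounds`` maps (chamber, mode, compound) -> background ncps;
    a missing key raises (a background from the matching chamber type and
    mode is required). ``curves`` maps compound -> CalibrationCurve;
    uncalibrated compounds get a surrogate sensitivity.

    Returns a tidy DataFrame: time_s (block midpoint), chamber, mode,
    block, compound, vmr_ppbv, n_samples.
    """
    seg = segment_blocks(counts, discard=discard)
    rows = []
    for (block, chamber, mode, compound), grp in seg.groupby(
            ["block", "chamber", "mode", "compound"], sort=True):
        key = (chamber, mode, compound)
        if key not in backgrounds:
            raise ValueError(f"missing background for {key}")
        ncps = normalize(grp["counts_raw"].to_numpy(),
                         grp["primary_cps"].to_numpy())
        corrected, _ = background_correct(ncps, backgrounds[key], floor=floor)
        curve = assign_surrogate_sensitivity(compound, curves, registry)
        v = vmr(corrected, curve)
        rows.append({
            "time_s": float(grp["time_s"].mean()),
            "chamber": chamber,
            "mode": mode,
            "block": int(block),
            "compound": compound,
            "vmr_ppbv": float(np.mean(v)),
            "n_samples": int(len(grp)),
        })
    return pd.DataFrame(rows)


def process_counts(counts: pd.DataFrame, backgrounds: dict, curves: dict,
                   registry: Registry, mode: str = "H3O+",
                   discard: float = 30.0, floor: bool = True) -> pd.DataFrame:
    """Full processing chain restricted to one quantification mode.

    Quantification uses the H3O+ (protonated) channels by default, the
    mode in which sensitivities are defined; NO+ blocks serve compound
    identification and are excluded from quantitative averages.
    """
    table = block_mean_vmr(counts, backgrounds, curves, registry,
                           discard=discard, floor=floor)
    return table[table["mode"] == mode].reset_index(drop=True)
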