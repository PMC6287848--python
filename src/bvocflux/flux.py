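"""Chamber mass-balance outputs: emission rates, ozone budget, carbon flux.

At steady state the flow through a well-mixed chamber balances the source,
so the area-based emission rate follows from the concentration difference
across the chamber:

    E = Q * (c_out - c_in) / A      [nmol m^-2 s^-1]

with Q the flow into the chamber and A the leaf (or soil) area. Negative
values are preserved: they indicate net uptake. The ozone budget corrects
the observed in/out difference for the empty-chamber wall loss before
attributing the remainder to the plant, and expresses it both as a flux
and as a deposition velocity v_d = flux / [O3]_ref.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ppbv_to_nmol_m3
from .registry import Registry

__all__ = [
    "EmissionResult",
    "OzoneBudget",
    "emission_rate",
    "emission_series",
    "ozone_budget",
    "carbon_flux",
    "window_means",
    "per_minute",
]

#: 1 nmol m^-2 s^-1 expressed per minute (root-chamber reporting unit).
PER_MINUTE = 60.0


@dataclass(frozen=True)
class EmissionResult:
    """Windowed mean emission of one compound for one plant."""

    compound: str
    plant_id: int
    window: str              # "pre" or "post"
    E: float                 # mean emission over the window
    se: float                # standard error of the window mean
    units: str = "nmol m-2 s-1"
    n: int = 0               # number of block means in the window


@dataclass(frozen=True)
class OzoneBudget:
    inflow: float                 # ppbv
    outflow: float                # ppbv
    wall_loss: float              # ppbv (empty-chamber loss)
    plant_uptake_ppbv: float      # ppbv attributed to the plant
    plant_uptake_flux: float      # nmol m^-2 s^-1
    deposition_velocity: float    # cm s^-1
    reference_o3_ppbv: float      # concentration v_d was referenced to


def emission_rate(c_out, c_in, Q, A):
    """Emission rate from concentrations in nmol m^-3.

    E = Q (c_out - c_in) / A; signed (negative = uptake).
    """
    if Q <= 0 or A <= 0:
        raise ValueError("flow Q and area A must be positive")
    out = Q * (np.asarray(c_out, dtype=float) - np.asarray(c_in, dtype=float)) / A
    return float(out) if out.ndim == 0 else out


def emission_series(vmr_table: pd.DataFrame, Q: float, A: float,
                    T: float, P: float, c_in_ppbv: float = 0.0) -> pd.DataFrame:
    """Per-block VMRs (ppbv) to emission rates (nmol m^-2 s^-1).

    ``vmr_table`` is tidy with columns time_s, compound, vmr_ppbv (as from
    the processing pipeline). The inflow VMR defaults to 0 (VOC-free air
    generator upstream) but is configurable for reanalysis.
    """
    out = vmr_table.copy()
    c_out = ppbv_to_nmol_m3(out["vmr_ppbv"].to_numpy(), T, P)
    c_in = ppbv_to_nmol_m3(c_in_ppbv, T, P)
    out["emission"] = emission_rate(c_out, c_in, Q, A)
    return out


def ozone_budget(inlet, outlet, empty_chamber_loss, Q, A, T, P,
                 reference: str = "outlet",
                 noise_tolerance: float = 1.0) -> OzoneBudget:
    """Attribute the chamber ozone loss to walls and plant.

    Plant uptake (ppbv) = (inlet - outlet) - empty_chamber_loss, floored
    at zero; the uptake flux follows via the ideal gas law and Q/A, and
    the deposition velocity divides that flux by the reference ozone molar
    concentration. ``reference`` selects which concentration v_d is
    referenced to: "outlet" (chamber air, default), "inlet", or "mean".
    """
    if inlet < 0:
        raise ValueError("inlet O3 must be non-negative")
    if outlet > inlet + noise_tolerance:
        raise ValueError("outlet O3 exceeds inlet beyond noise tolerance")
    uptake_ppbv = max((inlet - outlet) - empty_chamber_loss, 0.0)
    flux = emission_rate(ppbv_to_nmol_m3(uptake_ppbv, T, P), 0.0, Q, A)
    ref_ppbv = {"outlet": outlet, "inlet": inlet,
                "mean": 0.5 * (inlet + outlet)}[reference]
    ref_conc = ppbv_to_nmol_m3(ref_ppbv, T, P)  # nmol m^-3
    v_d = (flux / ref_conc * 100.0) if ref_conc > 0 else 0.0  # m->cm s^-1
    return OzoneBudget(
        inflow=inlet, outflow=outlet, wall_loss=empty_chamber_loss,
        plant_uptake_ppbv=uptake_ppbv, plant_uptake_flux=flux,
        deposition_velocity=v_d, reference_o3_ppbv=ref_ppbv,
    )


def carbon_flux(emissions: dict, registry: Registry) -> float:
    """Total carbon emission: sum of E_i * n_carbon_i (nmol C m^-2 s^-1)."""
    total = 0.0
    for name, e in emissions.items():
        compound = registry.get(name)
        if compound is None:
            raise KeyError(f"unknown compound {name!r} in carbon budget")
        total += e * compound.n_carbon
    return total


def window_means(series: pd.DataFrame, fumigation_start: float,
                 width: float = 7200.0, value: str = "emission",
                 plant_id: int = 0, windows=("pre", "post")):
    """Pre/post-fumigation window means of a per-compound emission series.

    ``series`` is tidy with columns time_s, compound and a value column.
    Means and standard errors are taken over the block means falling in
    [start - width, start) and [start, start + width). ``windows``
    restricts which of the two windows are computed.

    Returns a list of :class:`EmissionResult` (one per window per
    compound).
    """
    bounds = {"pre": (fumigation_start - width, fumigation_start),
              "post": (fumigation_start, fumigation_start + width)}
    if not windows or any(w not in bounds for w in windows):
        raise ValueError("windows must be a non-empty subset of ('pre', 'post')")
    t = series["time_s"].to_numpy(dtype=float)
    missing = [f"[{bounds[w][0]}, {bounds[w][1]})" for w in windows
               if not (((t >= bounds[w][0]) & (t < bounds[w][1])).any())]
    if missing:
        raise ValueError(f"series does not cover window(s) {', '.join(missing)}")
    results = []
    for compound, grp in series.groupby("compound", sort=True):
        gt = grp["time_s"].to_numpy(dtype=float)
        for label, (mask_lo, mask_hi) in ((w, bounds[w]) for w in windows):
            vals = grp.loc[(gt >= mask_lo) & (gt < mask_hi), value].to_numpy()
            if len(vals) == 0:
                raise ValueError(
                    f"{compound}: no samples in {label} window [{mask_lo}, {mask_hi})")
            mean = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            results.append(EmissionResult(
                compound=compound, plant_id=plant_id, window=label,
                E=mean, se=se, n=len(vals)))
    return results


def per_minute(E_per_second):
    """Convert nmol m^-2 s^-1 to nmol m^-2 min^-1 (root-chamber units)."""
    out = np.asarray(E_per_second, dtype=float) * PER_MINUTE
    return float(out) if out.ndim == 0 else out
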