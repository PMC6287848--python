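"""Instrument-level simulation of duty-cycled SRI-ToF-MS acquisition.

The spectrometer samples at 1 Hz, switches reagent ion (H3O+ / NO+) every
6 minutes, and alternates between chambers: 24 minutes from the root
chamber followed by 36 minutes from the leaf chamber. Per channel, the
expected normalized signal is

    ncps = sensitivity * VMR + background

which is converted to raw counts through the primary-ion rate
(raw cps = ncps * primary / 1e6) and, when noise is on, drawn from a
Poisson distribution per 1-s sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PRIMARY_ION_TARGET
from .registry import Registry

__all__ = ["InstrumentModel", "duty_cycle", "simulate_instrument"]


@dataclass
class InstrumentModel:
    """Acquisition settings and per-compound response.

    ``sensitivities`` are normalized sensitivities (ncps ppbv^-1) per
    compound; ``backgrounds`` are chamber-independent channel backgrounds
    (ncps) keyed by compound. ``primary_cps`` is the summed H3O+ and
    H3O+.H2O primary-ion rate the normalization divides by.
    """

    sensitivities: dict = field(default_factory=dict)
    backgrounds: dict = field(default_factory=dict)
    primary_cps: float = 6.0e5
    mode_block: float = 360.0     # s per reagent-ion block
    leaf_block: float = 2160.0    # s per leaf-chamber block
    root_block: float = 1440.0    # s per root-chamber block
    sampling: float = 1.0         # s
    noise: bool = True
    root_chamber: bool = True     # False emulates leaf-only operation

    def __post_init__(self):
        if any(s <= 0 for s in self.sensitivities.values()):
            raise ValueError("sensitivities must be positive")
        if any(b < 0 for b in self.backgrounds.values()):
            raise ValueError("backgrounds must be non-negative")
        if self.primary_cps <= 0:
            raise ValueError("primary_cps must be positive")
        for name in ("mode_block", "leaf_block", "root_block"):
            block = getattr(self, name)
            if block <= 0 or (block / self.sampling) % 1 != 0:
                raise ValueError(
                    f"{name} must be a positive multiple of the sampling interval")


def duty_cycle(t, model: InstrumentModel):
    """Mode and chamber labels for sample times t (vectorized).

    Reagent ion alternates every ``mode_block`` starting in H3O+; the
    chamber sequence is root then leaf (``root_block`` + ``leaf_block``
    per cycle) when the root chamber is in use, else always leaf.
    """
    t = np.asarray(t, dtype=float)
    mode_idx = np.floor_divide(t, model.mode_block).astype(int) % 2
    mode = np.where(mode_idx == 0, "H3O+", "NO+")
    if model.root_chamber:
        cycle = model.root_block + model.leaf_block
        chamber = np.where((t % cycle) < model.root_block, "root", "leaf")
    else:
        chamber = np.full(t.shape, "leaf")
    return mode, chamber


def simulate_instrument(
    concentrations: dict,
    model: InstrumentModel,
    registry: Registry,
    seed=None,
) -> pd.DataFrame:
    """Sample true chamber concentrations into a raw count-rate table.

    Parameters
    ----------
    concentrations:
        Mapping chamber name -> DataFrame of true VMRs (ppbv) indexed by
        time (s), one column per compound (as from ``simulate_chamber``).
    model:
        Acquisition settings; compounds without a sensitivity are skipped.
    registry:
        Supplies the ion channel (and hence channel m/z) per compound and
        mode; compounds with no channel in the active mode are not
        recorded in that mode's blocks.
    seed:
        Seed or Generator for the Poisson draw; identical seeds give
        identical output.

    Returns
    -------
    Tidy DataFrame with columns time_s, chamber, mode, compound,
    channel_mz, counts_raw (cps), primary_cps.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for chamber, conc in concentrations.items():
        t = np.asarray(conc.index, dtype=float)
        mode, chamber_label = duty_cycle(t, model)
        on_this_chamber = chamber_label == chamber
        for compound in conc.columns:
            if compound == "O3" or compound not in model.sensitivities:
                continue
            comp = registry[compound]
            sens = model.sensitivities[compound]
            bg = model.backgrounds.get(compound, 0.0)
            for m in ("H3O+", "NO+"):
                ch = comp.channel(m)
                if ch is None:
                    continue
                sel = on_this_chamber & (mode == m)
                if not sel.any():
                    continue
                ncps = sens * conc[compound].to_numpy()[sel] + bg
                raw = ncps * model.primary_cps / PRIMARY_ION_TARGET
                if model.noise:
                    raw = rng.poisson(np.maximum(raw, 0.0) * model.sampling
                                      ) / model.sampling
                frames.append(pd.DataFrame({
                    "time_s": t[sel],
                    "chamber": chamber,
                    "mode": m,
                    "compound": compound,
                    "channel_mz": comp.mz(ch.mechanism, m, display=True),
                    "counts_raw": raw,
                    "primary_cps": model.primary_cps,
                }))
    if not frames:
        return pd.DataFrame(columns=["time_s", "chamber", "mode", "compound",
                                     "channel_mz", "counts_raw", "primary_cps"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["time_s", "compound"], kind="stable").reset_index(drop=True)
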