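"""GC-MS quantification conventions for terpene speciation.

Covers the bookkeeping around an external GC-MS analysis: non-isothermal
Kovats retention indices against an n-alkane ladder (linear van den
Dool-Kratz form, appropriate for temperature-programmed runs), multi-level
calibration with detection limits (LOD = 2 sigma of the blank expressed in
amount units through the slope; LOQ = 5 LOD), internal-standard drift
correction (a fixed amount of delta-2-carene in every sample), and blend
composition percentages for isomer speciation. Chromatogram parsing and
peak integration are out of scope; inputs are peak responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "RILadder",
    "QuantResult",
    "kovats_ri",
    "calibrate_and_quantify",
    "internal_standard_correct",
    "blend_composition",
]

LOQ_LOD_RATIO = 5.0
LOD_SIGMA_MULTIPLIER = 2.0


@dataclass(frozen=True)
class RILadder:
    """n-alkane retention ladder: carbon numbers and retention times (min)."""

    carbon_numbers: tuple
    retention_times: tuple

    def __post_init__(self):
        if len(self.carbon_numbers) != len(self.retention_times):
            raise ValueError("carbon_numbers and retention_times differ in length")
        if len(self.carbon_numbers) < 2:
            raise ValueError("ladder needs at least two rungs")
        rts = list(self.retention_times)
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        cs = list(self.carbon_numbers)
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("carbon numbers must be strictly increasing")


@dataclass(frozen=True)
class QuantResult:
    compound: str
    amount: float      # pmol
    lod: float         # pmol
    loq: float         # pmol
    flag: str          # below_lod | below_loq | ok
    slope: float = float("nan")
    r2: float = float("nan")

    def __post_init__(self):
        if not np.isclose(self.loq, LOQ_LOD_RATIO * self.lod):
            raise ValueError("LOQ must equal 5 x LOD")


def kovats_ri(rt: float, ladder: RILadder) -> float:
    """Non-isothermal (van den Dool-Kratz) Kovats retention index.

    RI = 100 * (n + (rt - t_n) / (t_{n+1} - t_n)) with t_n, t_{n+1} the
    bracketing alkane retention times. No extrapolation outside the
    ladder span.
    """
    rts = ladder.retention_times
    cs = ladder.carbon_numbers
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt} outside ladder span [{rts[0]}, {rts[-1]}]")
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(i, len(rts) - 2)
    n, n_next = cs[i], cs[i + 1]
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    return 100.0 * (n + frac * (n_next - n))


def calibrate_and_quantify(response: float, levels, blank_sd: float,
                           compound: str = "") -> QuantResult:
    """Quantify a peak response against a multi-level calibration.

    ``levels`` are (amount_pmol, response) pairs; an ordinary
    least-squares line (with intercept) is fitted and the sample amount is
    read off the line. The LOD is 2 x blank_sd converted to amount units
    through the slope; the LOQ is 5 x LOD. Amounts below the LOD are
    flagged ``below_lod``, between LOD and LOQ ``below_loq``, else ``ok``.
    """
    pts = [(float(a), float(r)) for a, r in levels]
    if len(pts) < 2:
        raise ValueError("calibration requires at least 2 levels")
    if blank_sd < 0:
        raise ValueError("blank_sd must be non-negative")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = _scipy_stats.linregress(x, y)
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise ValueError("zero calibration slope")
    amount = (response - fit.intercept) / fit.slope
    lod = LOD_SIGMA_MULTIPLIER * blank_sd / abs(fit.slope)
    loq = LOQ_LOD_RATIO * lod
    flag = "ok"
    if amount < lod:
        flag = "below_lod"
    elif amount < loq:
        flag = "below_loq"
    return QuantResult(compound=compound, amount=amount, lod=lod, loq=loq,
                       flag=flag, slope=fit.slope, r2=fit.rvalue**2)


def internal_standard_correct(sample_response, is_response, is_reference):
    """Correct a sample response for sensitivity drift.

    Scales by is_reference / is_response, the ratio of the internal
    standard's nominal response to the one observed in the same run.
    """
    if np.any(np.asarray(is_response) <= 0):
        raise ValueError("internal standard response must be positive")
    out = np.asarray(sample_response, dtype=float) * is_reference / np.asarray(
        is_response, dtype=float)
    return float(out) if out.ndim == 0 else out


def blend_composition(amounts: dict, round_to_int: bool = False) -> dict:
    """Isomer amounts to blend percentages summing to 100.

    With ``round_to_int`` the percentages are rounded by largest
    remainder so they still sum to exactly 100.
    """
    if any(a < 0 for a in amounts.values()):
        raise ValueError("amounts must be non-negative")
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("all amounts are zero; composition undefined")
    pct = {k: 100.0 * v / total for k, v in amounts.items()}
    if not round_to_int:
        return pct
    floors = {k: int(np.floor(v)) for k, v in pct.items()}
    shortfall = 100 - sum(floors.values())
    remainders = sorted(pct, key=lambda k: (pct[k] - floors[k], pct[k]),
                        reverse=True)
    for k in remainders[:shortfall]:
        floors[k] += 1
    return {k: float(v) for k, v in floors.items()}
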