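"""Forward CSTR model of the dynamic leaf/root chamber.

Each chamber is treated as a single continuously stirred tank reactor
(CSTR): a pierced-ring inlet keeps the air well mixed, so the outflow
concentration equals the internal concentration and, per compound,

    dC/dt = E(t) * A / V  +  (Q/V) * (C_in - C)  -  L_chem(t, C) * C  +  P(t, C)

with E the area-based emission rate (nmol m^-2 s^-1), Q the flow
(m^3 s^-1), V the chamber volume (m^3), C_in the inflow concentration and
L_chem the first-order chemical sink. Chemistry comprises gas-phase
ozonolysis (k_O3 [O3]) and reaction with OH radicals; OH is treated in
quasi-steady state, produced with a configurable yield per ozonolysis
event (gas-phase and leaf-surface) and partitioned among its reactants in
proportion to k_OH * C. A configurable fraction of a compound's emission
may be consumed at the leaf surface while ozone is present (surface
ozonolysis of semi-volatile terpenoids), and gas-phase ozonolysis can
feed product compounds through molar-yield maps.

Concentrations are carried in ppbv (a molar unit, so molar product yields
apply directly). At constant forcing the model converges to the closed
form C_ss = (E A / V + (Q/V) C_in) / (Q/V + k_chem).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import AIR_NUMBER_DENSITY, nmol_m3_to_ppbv

__all__ = [
    "EmissionSchedule",
    "SpeciesConfig",
    "ChamberScenario",
    "simulate_chamber",
    "cstr_steady_state",
]


@dataclass(frozen=True)
class EmissionSchedule:
    """Per-compound true emission rate vs time, nmol m^-2 s^-1.

    ``basal`` holds before fumigation; after ``t_start`` (the fumigation
    start) an induced burst rises first-order to a new plateau
    ``basal + induced_delta`` with time constant ``rise_tau``.
    """

    basal: float
    induced_delta: float = 0.0
    rise_tau: float = 1800.0  # s

    def __post_init__(self):
        if self.basal < 0 or self.rise_tau <= 0:
            raise ValueError("basal must be >= 0 and rise_tau > 0")
        if self.basal + self.induced_delta < 0:
            raise ValueError("induced plateau must be non-negative")

    def rate(self, t, t_start):
        """Emission rate at time(s) t given the fumigation start time."""
        t = np.asarray(t, dtype=float)
        burst = np.where(
            t >= t_start,
            self.induced_delta * (1.0 - np.exp(-np.maximum(t - t_start, 0.0) / self.rise_tau)),
            0.0,
        )
        out = self.basal + burst
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "EmissionSchedule":
        return replace(self, basal=self.basal * factor,
                       induced_delta=self.induced_delta * factor)


@dataclass(frozen=True)
class SpeciesConfig:
    """Emission and chemistry switches for one compound in one chamber.

    ``k_o3_gas`` is the gas-phase ozonolysis rate coefficient used by the
    chamber chemistry (cm^3 molecule^-1 s^-1); it may deliberately differ
    from the registry's k_O3 (e.g. zero when in-chamber gas-phase loss is
    attributed elsewhere). ``surface_sink`` is the fraction of the
    emission consumed at the surface while O3 > 0. ``products`` maps
    product compound -> molar yield from gas-phase ozonolysis.
    """

    emission: EmissionSchedule = EmissionSchedule(0.0)
    k_o3_gas: float = 0.0
    k_oh: float = 0.0
    surface_sink: float = 0.0
    products: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k_o3_gas < 0 or self.k_oh < 0:
            raise ValueError("rate coefficients must be non-negative")
        if not 0.0 <= self.surface_sink <= 1.0:
            raise ValueError("surface_sink must be a fraction in [0, 1]")
        if any(y < 0 for y in self.products.values()):
            raise ValueError("product yields must be non-negative")


def _validate_schedule(schedule, name):
    if not schedule:
        raise ValueError(f"{name} must contain at least one (time, value) pair")
    times = [t for t, _ in schedule]
    if any(v < 0 for _, v in schedule):
        raise ValueError(f"{name} contains negative values")
    if sorted(times) != times:
        raise ValueError(f"{name} times must be non-decreasing")
    return [(float(t), float(v)) for t, v in schedule]


def _piecewise(schedule, t):
    """Value of a piecewise-constant schedule [(t_start, value), ...] at t."""
    value = schedule[0][1]
    for ts, v in schedule:
        if t >= ts:
            value = v
        else:
            break
    return value


@dataclass
class ChamberScenario:
    """Geometry, flows, environment and ground-truth schedules.

    Defaults describe the experimental system: a 17.2 L glass leaf chamber
    and 2 L root chamber fed by VOC-free air at ca. 3.0 and 0.5 L min^-1
    respectively. The ozone schedule is the chamber-air mixing ratio
    (piecewise constant, ppbv); the scavenger schedule is the cyclohexane
    mixing ratio in the inflow.
    """

    V_leaf: float = 17.2e-3           # m^3
    V_root: float = 2.0e-3            # m^3
    Q_leaf: float = 3.0 / 60000.0     # m^3 s^-1 (3.0 L min^-1)
    Q_root: float = 0.5 / 60000.0     # m^3 s^-1 (0.5 L min^-1)
    A_leaf: float = 0.05              # m^2 one-sided leaf area
    A_root: float = 0.018             # m^2 soil surface
    T: float = 296.0                  # K
    P: float = 100000.0               # Pa
    o3_schedule: list = field(default_factory=lambda: [(0.0, 0.0)])  # (s, ppbv)
    fumigation_start: float = 9000.0  # s; induced bursts reference this
    scavenger_schedule: list = field(default_factory=lambda: [(0.0, 0.0)])
    oh_yield: float = 0.0             # OH per ozonolysis event (gas + surface)
    species_leaf: dict = field(default_factory=dict)   # name -> SpeciesConfig
    species_root: dict = field(default_factory=dict)
    n_plants: int = 10
    plant_cv: float = 0.4
    seed: int = 0
    t_end: float = 18000.0

    def __post_init__(self):
        for name in ("V_leaf", "V_root", "Q_leaf", "Q_root", "A_leaf", "A_root",
                     "T", "P", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.oh_yield < 0:
            raise ValueError("oh_yield must be non-negative")
        if not 0 <= self.plant_cv:
            raise ValueError("plant_cv must be non-negative")
        self.o3_schedule = _validate_schedule(self.o3_schedule, "o3_schedule")
        self.scavenger_schedule = _validate_schedule(
            self.scavenger_schedule, "scavenger_schedule")

    def residence_time(self, chamber: str = "leaf") -> float:
        """Mean residence time V/Q, s."""
        if chamber == "leaf":
            return self.V_leaf / self.Q_leaf
        return self.V_root / self.Q_root

    def o3_at(self, t: float) -> float:
        return _piecewise(self.o3_schedule, t)

    def scavenger_at(self, t: float) -> float:
        return _piecewise(self.scavenger_schedule, t)

    def breakpoints(self):
        pts = {0.0, self.t_end, self.fumigation_start}
        pts.update(t for t, _ in self.o3_schedule)
        pts.update(t for t, _ in self.scavenger_schedule)
        return sorted(p for p in pts if 0.0 <= p <= self.t_end)

    def plant_emission_factors(self, rng, n_compounds: int):
        """Lognormal per-plant, per-compound emission factors with mean 1.

        The coefficient of variation is ``plant_cv``; sigma^2 = ln(1+CV^2)
        and mu = -sigma^2/2 so the multiplicative factor has mean 1.
        """
        if self.plant_cv == 0:
            return np.ones(n_compounds)
        sigma2 = np.log1p(self.plant_cv**2)
        return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                             size=n_compounds)


def cstr_steady_state(E, A, V, Q, k_chem=0.0, c_in=0.0, T=296.0, P=100000.0):
    """Closed-form CSTR steady state, ppbv.

    C_ss = (E*A/V + (Q/V)*C_in) / (Q/V + k_chem), with E in nmol m^-2 s^-1
    converted through the ideal gas law and c_in in ppbv.
    """
    source = nmol_m3_to_ppbv(E * A / V, T, P)
    return (source + (Q / V) * c_in) / (Q / V + k_chem)


class _ChamberSystem:
    """Assembled RHS for one chamber of a scenario."""

    def __init__(self, scenario: ChamberScenario, chamber: str, plant_factors=None):
        if chamber not in ("leaf", "root"):
            raise ValueError("chamber must be 'leaf' or 'root'")
        self.sc = scenario
        self.chamber = chamber
        species = scenario.species_leaf if chamber == "leaf" else scenario.species_root
        self.names = list(species)
        cfgs = [species[n] for n in self.names]
        if plant_factors is not None:
            cfgs = [replace(c, emission=c.emission.scaled(f))
                    for c, f in zip(cfgs, plant_factors)]
        self.cfgs = cfgs
        n = len(self.names)
        self.V = scenario.V_leaf if chamber == "leaf" else scenario.V_root
        self.Q = scenario.Q_leaf if chamber == "leaf" else scenario.Q_root
        self.A = scenario.A_leaf if chamber == "leaf" else scenario.A_root
        self.k_o3 = np.array([c.k_o3_gas for c in cfgs])
        self.k_oh = np.array([c.k_oh for c in cfgs])
        self.surface = np.array([c.surface_sink for c in cfgs])
        idx = {nm: i for i, nm in enumerate(self.names)}
        self.yield_matrix = np.zeros((n, n))  # [product, parent]
        for j, c in enumerate(cfgs):
            for prod, y in c.products.items():
                if prod in idx:
                    self.yield_matrix[idx[prod], j] = y
        # only the scavenger (cyclohexane) enters through the inflow
        self.scavenger_index = idx.get("cyclohexane")

    def emission(self, t):
        """True emission rates at t, nmol m^-2 s^-1 (chamber-area basis)."""
        return np.array(
            [c.emission.rate(t, self.sc.fumigation_start) for c in self.cfgs]
        )

    def inflow(self, t):
        c_in = np.zeros(len(self.names))
        if self.chamber == "leaf" and self.scavenger_index is not None:
            c_in[self.scavenger_index] = self.sc.scavenger_at(t)
        return c_in

    def loss_and_oh(self, t, C):
        """First-order loss rates (s^-1) and [OH] (cm^-3) at state C (ppbv)."""
        o3_nd = self.sc.o3_at(t) * 1e-9 * AIR_NUMBER_DENSITY
        k_gas = self.k_o3 * o3_nd
        C_nd = np.maximum(C, 0.0) * 1e-9 * AIR_NUMBER_DENSITY
        oh = 0.0
        if self.sc.oh_yield > 0 and o3_nd > 0:
            gas_events = float(np.sum(k_gas * C_nd))  # cm^-3 s^-1
            surf_nmol = self.surface * self.emission(t) * self.A / self.V
            surf_ppbv = nmol_m3_to_ppbv(surf_nmol, self.sc.T, self.sc.P)
            surf_events = float(np.sum(surf_ppbv) * 1e-9 * AIR_NUMBER_DENSITY)
            sink = float(np.sum(self.k_oh * C_nd))
            if sink > 0:
                oh = self.sc.oh_yield * (gas_events + surf_events) / sink
        return k_gas, self.k_oh * oh, oh

    def rhs(self, t, C):
        o3 = self.sc.o3_at(t)
        E = self.emission(t)
        surf = self.surface if o3 > 0 else 0.0
        source = nmol_m3_to_ppbv(E * (1.0 - surf) * self.A / self.V,
                                 self.sc.T, self.sc.P)
        k_gas, k_oh_loss, _ = self.loss_and_oh(t, C)
        flush = self.Q / self.V
        production = self.yield_matrix @ (k_gas * C)
        return (source + flush * (self.inflow(t) - C)
                - (k_gas + k_oh_loss) * C + production)

    def steady_state(self, t, max_iter=200, tol=1e-13):
        """Self-consistent steady state at the forcing frozen at time t."""
        flush = self.Q / self.V
        o3 = self.sc.o3_at(t)
        E = self.emission(t)
        surf = self.surface if o3 > 0 else 0.0
        source = nmol_m3_to_ppbv(E * (1.0 - surf) * self.A / self.V,
                                 self.sc.T, self.sc.P)
        C = (source + flush * self.inflow(t)) / flush
        for _ in range(max_iter):
            k_gas, k_oh_loss, _ = self.loss_and_oh(t, C)
            production = self.yield_matrix @ (k_gas * C)
            C_new = (source + flush * self.inflow(t) + production) / (
                flush + k_gas + k_oh_loss)
            if np.max(np.abs(C_new - C)) <= tol * max(1.0, np.max(np.abs(C_new))):
                return C_new
            C = C_new
        return C


def simulate_chamber(
    scenario: ChamberScenario,
    chamber: str = "leaf",
    plant_factors=None,
    t_grid=None,
    init: str = "steady",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the chamber CSTR and return true concentrations, ppbv.

    Parameters
    ----------
    scenario:
        Scenario with geometry, schedules and species configuration.
    chamber:
        ``"leaf"`` or ``"root"``.
    plant_factors:
        Optional per-compound emission multipliers (one plant's draw).
    t_grid:
        Sample times, s. Defaults to 1 Hz over [0, t_end].
    init:
        ``"steady"`` starts from the self-consistent steady state of the
        initial forcing (transient-free under constant forcing);
        ``"zero"`` starts from an empty chamber.

    Returns
    -------
    DataFrame indexed by time (s) with one ppbv column per compound plus
    an ``O3`` column (the forcing).
    """
    system = _ChamberSystem(scenario, chamber, plant_factors)
    if t_grid is None:
        t_grid = np.arange(0.0, scenario.t_end + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(system.names) == 0:
        raise ValueError(f"scenario defines no species for the {chamber} chamber")

    if init == "steady":
        C = system.steady_state(t_grid[0])
    elif init == "zero":
        C = np.zeros(len(system.names))
    else:
        raise ValueError("init must be 'steady' or 'zero'")

    edges = [b for b in system.sc.breakpoints() if t_grid[0] < b < t_grid[-1]]
    seg_bounds = [t_grid[0]] + edges + [t_grid[-1]]
    out = np.empty((len(t_grid), len(system.names)))
    # integrate piecewise between forcing discontinuities
    filled = np.zeros(len(t_grid), dtype=bool)
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        mask = (t_grid >= a) & (t_grid <= b) & ~filled
        t_eval = t_grid[mask]
        if b > a:
            sol = solve_ivp(
                system.rhs, (a, b), C, method="LSODA",
                t_eval=t_eval if len(t_eval) else None,
                rtol=rtol, atol=atol, max_step=(b - a),
            )
            if not sol.success:
                raise RuntimeError(f"chamber ODE integration failed: {sol.message}")
            if len(t_eval):
                out[mask] = sol.y.T
                filled |= mask
            C = sol.y[:, -1]
        elif len(t_eval):
            out[mask] = C
            filled |= mask
    if not filled.all():  # grid points at exact segment edges
        for i in np.nonzero(~filled)[0]:
            out[i] = out[i - 1] if i else C
    out = np.maximum(out, 0.0)
    df = pd.DataFrame(out, index=pd.Index(t_grid, name="time_s"),
                      columns=system.names)
    df["O3"] = [scenario.o3_at(t) for t in t_grid]
    return df
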