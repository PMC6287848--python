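"""Gas-phase ozonolysis kinetics for chamber chemistry.

Terpenes carry C=C double bonds and react with ozone with rate coefficient
k_O3 (cm^3 molecule^-1 s^-1). At an ozone number density [O3] the e-folding
lifetime is tau = 1/(k_O3 [O3]). In a well-mixed flow-through chamber
(CSTR) with mean residence time tau_res, the fraction of a compound lost
to a first-order chemical sink k_chem before leaving the chamber is

    f = k_chem * tau_res / (1 + k_chem * tau_res)

Ozonolysis also releases OH radicals (via decomposition of the Criegee
intermediate); OH is partitioned among its reactants in proportion to
k_OH,i * C_i, which is what makes an excess of cyclohexane an effective OH
scavenger.

Lifetimes reported by ``lifetime_hours`` are e-folding times 1/(k[O3]),
not ln2/(k[O3]): this convention reproduces the reference table of terpene
lifetimes at 135 ppbv O3 and 296 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AIR_NUMBER_DENSITY, ppbv_to_molecules_cm3
from .registry import Registry

__all__ = [
    "KineticsContext",
    "ProductMap",
    "lifetime_hours",
    "lifetime_table",
    "fractional_loss",
    "oh_scavenging_fraction",
    "apply_product_map",
    "ALPHA_FARNESENE_PRODUCTS",
]


@dataclass(frozen=True)
class KineticsContext:
    """Thermodynamic state for gas-phase rate calculations.

    Defaults correspond to the chamber reference state: 296 K, an air
    number density of 2.46e19 molecules cm^-3 and 135 ppbv ozone.
    """

    T: float = 296.0                    # K
    air_density: float = AIR_NUMBER_DENSITY  # molecules cm^-3
    O3_ppbv: float = 135.0
    residence_time: float = 390.0       # s (ca. 6.5 min)

    def __post_init__(self):
        for name in ("T", "air_density", "residence_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.O3_ppbv < 0:
            raise ValueError("O3_ppbv must be non-negative")

    @property
    def o3_number_density(self) -> float:
        """[O3] in molecules cm^-3."""
        return ppbv_to_molecules_cm3(self.O3_ppbv, self.air_density)


def lifetime_hours(k: float, ctx: KineticsContext = KineticsContext()):
    """Ozonolysis lifetime tau = 1/(k [O3]) in hours.

    Returns ``(tau_rounded, tau)``: the value rounded to one decimal (the
    printed-table convention) and the unrounded value.
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    o3 = ctx.o3_number_density
    if o3 <= 0:
        raise ValueError("O3 number density must be positive for a finite lifetime")
    tau = 1.0 / (k * o3) / 3600.0
    return round(tau, 1), tau


def lifetime_table(registry: Registry, ctx: KineticsContext = KineticsContext()):
    """Lifetimes for every registry compound with a known k_O3.

    Returns a list of dicts (name, k_O3, tau_h, tau_h_unrounded, surrogate)
    in registry order — a replica of the printed terpene-lifetime table when
    run on the default registry at the reference state.
    """
    rows = []
    for c in registry:
        if c.k_O3 is None:
            continue
        tau_r, tau = lifetime_hours(c.k_O3, ctx)
        rows.append(
            {
                "name": c.name,
                "k_O3": c.k_O3,
                "tau_h": tau_r,
                "tau_h_unrounded": tau,
                "surrogate": "k_o3_surrogate" in c.flags,
            }
        )
    return rows


def fractional_loss(k_chem_total, residence_time):
    """Steady-state fraction of a compound lost to chemistry in a CSTR.

    f = k_chem * tau_res / (1 + k_chem * tau_res); bounded in [0, 1) and
    monotone increasing in both arguments.
    """
    k = np.asarray(k_chem_total, dtype=float)
    tau = np.asarray(residence_time, dtype=float)
    if np.any(k < 0) or np.any(tau < 0):
        raise ValueError("k_chem_total and residence_time must be non-negative")
    x = k * tau
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def oh_scavenging_fraction(concentrations: dict, k_oh: dict) -> dict:
    """Fraction of the OH flux consumed by each competitor.

    fraction_i = k_OH,i C_i / sum_j k_OH,j C_j. Concentrations may be in
    any common unit (only ratios matter). Fractions sum to 1.
    """
    names = list(concentrations)
    rates = {}
    for n in names:
        c = concentrations[n]
        k = k_oh.get(n, 0.0) or 0.0
        if c < 0 or k < 0:
            raise ValueError(f"negative concentration or k_OH for {n!r}")
        rates[n] = k * c
    total = sum(rates.values())
    if total <= 0:
        raise ValueError("all k_OH * C products are zero; OH budget undefined")
    return {n: r / total for n, r in rates.items()}


@dataclass(frozen=True)
class ProductMap:
    """Molar yields of stable products from ozonolysis of a parent compound.

    ``products`` maps product name -> molar yield (product formed per
    parent reacted). Carbon conservation is enforced at validation:
    the carbon carried by the products at these yields must not exceed the
    parent's carbon count.
    """

    parent: str
    products: dict  # name -> molar yield
    parent_n_carbon: int = 0
    product_n_carbon: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(y < 0 for y in self.products.values()):
            raise ValueError("product yields must be non-negative")
        if self.parent_n_carbon and self.product_n_carbon:
            c_out = sum(
                y * self.product_n_carbon[p] for p, y in self.products.items()
            )
            if c_out > self.parent_n_carbon + 1e-9:
                raise ValueError(
                    f"carbon in products ({c_out:.3f} C per parent) exceeds "
                    f"parent carbon count ({self.parent_n_carbon})"
                )

    @classmethod
    def from_registry(cls, parent: str, yields: dict, registry: Registry) -> "ProductMap":
        if registry[parent].k_O3 is None:
            raise ValueError(f"{parent!r} has no k_O3; product map undefined")
        return cls(
            parent=parent,
            products=dict(yields),
            parent_n_carbon=registry[parent].n_carbon,
            product_n_carbon={p: registry[p].n_carbon for p in yields},
        )


#: Default molar yields for the short-chain carbonyls formed by ozonolysis
#: of the acyclic sesquiterpene alpha-farnesene. The four products were all
#: observed after fumigation; an equal molar split (subject to carbon
#: conservation: 0.25*(3+4+5+8) = 5 C of 15) is a modeling choice, as only
#: the identities, not the yields, are known.
ALPHA_FARNESENE_PRODUCTS = {
    "acetone": 0.25,
    "methyl vinyl ketone": 0.25,
    "oxopentanal": 0.25,
    "6-methyl-5-hepten-2-one": 0.25,
}


def default_sesquiterpene_product_map(registry: Registry) -> ProductMap:
    """Alpha-farnesene-like product map for the lumped sesquiterpene signal."""
    return ProductMap.from_registry(
        "sesquiterpenes", ALPHA_FARNESENE_PRODUCTS, registry
    )


def apply_product_map(parent_loss_flux: float, pmap: ProductMap) -> dict:
    """Formation flux of each product given a parent chemical-loss flux.

    Fluxes are molar (e.g. nmol m^-2 s^-1); product flux = loss * yield.
    """
    if parent_loss_flux < 0:
        raise ValueError("parent loss flux must be non-negative")
    return {p: parent_loss_flux * y for p, y in pmap.products.items()}
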