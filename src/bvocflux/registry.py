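"""Compound registry: formulas, exact masses and reagent-ion channels.

Chemical-ionization MS with switchable reagent ions detects each analyte M
at an m/z set by the ionization mechanism: proton transfer in H3O+ mode
gives MH+; in NO+ mode an aldehyde typically undergoes hydride abstraction
to [M-H]+, a ketone clusters to M.NO+, and terpenes ionize by charge
transfer to M+. The registry records, per compound, the elemental formula,
carbon count, ozonolysis rate constant where known, and the channels on
which the compound is expected to appear in each mode.

Printed instrument m/z values are treated as display labels of measured
peaks, not identities: matching uses a configurable mass tolerance, and a
few tentatively assigned peaks whose printed m/z is irreconcilable with the
proposed formula are kept but flagged ``anomalous``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import yaml
from pyteomics import mass as _ptmass

from .constants import H_ATOM_MASS, NO_CLUSTER_MASS, PROTON_MASS

__all__ = [
    "IonChannel",
    "Compound",
    "Registry",
    "monoisotopic_mass",
    "channel_mz",
    "load_registry",
    "default_registry",
    "MECHANISMS_BY_MODE",
    "MASS_MATCH_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Default tolerance (Da) when matching a computed channel m/z against a
#: printed instrument label.
MASS_MATCH_TOLERANCE = 0.005

MODES = ("H3O+", "NO+")

#: Which product-ion mechanisms are available under each reagent ion.
#: Water-proton clusters M.H3O+ can appear in either mode (residual water
#: is always present in the drift tube).
MECHANISMS_BY_MODE = {
    "H3O+": ("protonation", "water_proton_cluster"),
    "NO+": ("hydride_abstraction", "NO_cluster", "charge_transfer", "water_proton_cluster"),
}

CLASS_TAGS = (
    "alcohol",
    "aldehyde",
    "ketone",
    "terpene_mono",
    "terpene_sesqui",
    "sulfur",
    "other",
)

_WATER_PROTON_MASS = 18.010565 + PROTON_MASS  # H2O + proton


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a Hill-order formula, Da.

    Parameters
    ----------
    formula:
        Elemental composition in Hill notation, e.g. ``"C10H16"``.

    Raises
    ------
    ValueError
        If the formula is empty, contains an unknown element symbol, or has
        a negative count.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    try:
        comp = _ptmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError on bad symbols
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    if any(n < 0 for n in comp.values()):
        raise ValueError(f"negative element count in {formula!r}")
    if sum(comp.values()) == 0:
        raise ValueError("empty formula")
    for element in comp:
        if element not in _ptmass.nist_mass:
            raise ValueError(f"unknown element symbol {element!r} in {formula!r}")
    return float(_ptmass.calculate_mass(composition=comp))


def formula_carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula."""
    return int(_ptmass.Composition(formula=formula).get("C", 0))


def channel_mz(
    formula_or_mass: "str | float",
    mechanism: str,
    mode: str,
    display: bool = False,
) -> float:
    """m/z of a compound's product ion under a given mechanism and mode.

    Mass shifts (centralized in :mod:`bvocflux.constants`):

    ==================== =======================
    protonation          M + 1.00728 (proton)
    hydride_abstraction  M - 1.00783 (H atom)
    NO_cluster           M + 29.99799
    charge_transfer      M (electron mass neglected)
    water_proton_cluster M + 19.01784
    ==================== =======================

    ``display=True`` rounds to 3 decimals, the convention used in printed
    mass tables.
    """
    if mode not in MODES:
        raise ValueError(f"unknown reagent-ion mode {mode!r}")
    if mechanism not in MECHANISMS_BY_MODE[mode]:
        raise ValueError(f"mechanism {mechanism!r} not available in {mode} mode")
    M = (
        monoisotopic_mass(formula_or_mass)
        if isinstance(formula_or_mass, str)
        else float(formula_or_mass)
    )
    if mechanism == "protonation":
        mz = M + PROTON_MASS
    elif mechanism == "hydride_abstraction":
        mz = M - H_ATOM_MASS
    elif mechanism == "NO_cluster":
        mz = M + NO_CLUSTER_MASS
    elif mechanism == "water_proton_cluster":
        mz = M + _WATER_PROTON_MASS
    else:  # charge_transfer
        mz = M
    return round(mz, 3) if display else mz


@dataclass(frozen=True)
class IonChannel:
    """One expected product-ion channel of a compound.

    ``observed_mz`` is the instrument-calibrated m/z label printed for the
    peak, where one was reported; ``anomalous`` marks tentatively assigned
    peaks whose printed label disagrees with the proposed formula by more
    than the matching tolerance.
    """

    mode: str
    mechanism: str
    observed_mz: "float | None" = None
    anomalous: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mechanism not in MECHANISMS_BY_MODE[self.mode]:
            raise ValueError(
                f"mechanism {self.mechanism!r} not available in {self.mode} mode"
            )
        if self.observed_mz is not None and self.observed_mz <= 0:
            raise ValueError("observed_mz must be positive")


@dataclass(frozen=True)
class Compound:
    name: str
    formula: str
    n_carbon: int
    class_tag: str = "other"
    k_O3: "float | None" = None  # cm^3 molecule^-1 s^-1
    k_OH: "float | None" = None  # cm^3 molecule^-1 s^-1
    channels: tuple = ()
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.class_tag not in CLASS_TAGS:
            raise ValueError(f"{self.name}: unknown class_tag {self.class_tag!r}")
        nc = formula_carbon_count(self.formula)
        if nc != self.n_carbon:
            raise ValueError(
                f"{self.name}: n_carbon={self.n_carbon} but formula "
                f"{self.formula} has {nc} carbons"
            )
        for k, label in ((self.k_O3, "k_O3"), (self.k_OH, "k_OH")):
            if k is not None and k < 0:
                raise ValueError(f"{self.name}: {label} must be non-negative")
        if not self.channels:
            raise ValueError(f"{self.name}: compound must declare at least one channel")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def mass(self) -> float:
        """Monoisotopic mass, Da."""
        return monoisotopic_mass(self.formula)

    def mz(self, mechanism: str, mode: str, display: bool = False) -> float:
        """m/z of this compound under a mechanism/mode."""
        return channel_mz(self.formula, mechanism, mode, display=display)

    def channel(self, mode: str, mechanism: "str | None" = None) -> "IonChannel | None":
        """First declared channel matching mode (and mechanism, if given)."""
        for ch in self.channels:
            if ch.mode == mode and (mechanism is None or ch.mechanism == mechanism):
                return ch
        return None


class Registry:
    """Ordered collection of compounds with name lookup."""

    def __init__(self, compounds):
        self.compounds = list(compounds)
        self._by_name = {c.name: c for c in self.compounds}
        if len(self._by_name) != len(self.compounds):
            seen, dupes = set(), set()
            for c in self.compounds:
                (dupes if c.name in seen else seen).add(c.name)
            raise ValueError(f"duplicate compound names: {sorted(dupes)}")

    def __len__(self):
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def __contains__(self, name):
        return name in self._by_name

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown compound {name!r}") from None

    def get(self, name, default=None):
        return self._by_name.get(name, default)

    @property
    def names(self):
        return [c.name for c in self.compounds]

    def subset(self, names) -> "Registry":
        return Registry([self[n] for n in names])


def _ch(mode, mechanism, observed=None, anomalous=False):
    return IonChannel(mode, mechanism, observed_mz=observed, anomalous=anomalous)


def _default_compounds():
    """Built-in registry covering the study's detected compounds.

    Rate constants k_O3 are room-temperature gas-phase ozonolysis rate
    coefficients (cm^3 molecule^-1 s^-1); the alpha-thujene and beta-elemene
    values are surrogates estimated from compounds with the same number of
    double bonds and carry the ``k_o3_surrogate`` flag. k_OH values are
    literature-typical magnitudes shipped as placeholders for scenario
    configuration (``k_oh_placeholder`` flag), not measured in this study.
    """
    P, N = "H3O+", "NO+"
    return [
        # --- below-ground (root chamber) sulfur compounds -------------------
        Compound("methanethiol", "CH4S", 1, "sulfur", k_OH=3.3e-11,
                 channels=[_ch(P, "protonation", 49.011)],
                 flags={"k_oh_placeholder"}),
        Compound("dimethyl sulfide", "C2H6S", 2, "sulfur", k_OH=4.4e-12,
                 channels=[_ch(P, "protonation", 63.026),
                           _ch(N, "charge_transfer", 62.017)],
                 flags={"k_oh_placeholder"}),
        Compound("methyl thiocyanate", "C2H3NS", 2, "sulfur",
                 channels=[_ch(P, "protonation", 74.005)]),
        Compound("methanedithiol", "CH4S2", 1, "sulfur",
                 channels=[_ch(P, "protonation", 80.962, anomalous=True)]),
        Compound("dimethyl disulfide", "C2H6S2", 2, "sulfur", k_OH=2.3e-10,
                 channels=[_ch(P, "protonation", 94.991, anomalous=True),
                           _ch(N, "charge_transfer", 93.990)],
                 flags={"k_oh_placeholder"}),
        Compound("unknown alcohol C9H10O", "C9H10O", 9, "alcohol",
                 channels=[_ch(P, "protonation", 135.071, anomalous=True)]),
        # --- constitutive above-ground emissions ----------------------------
        Compound("methanol", "CH4O", 1, "alcohol", k_OH=9.0e-13,
                 channels=[_ch(P, "protonation", 33.034),
                           _ch(N, "NO_cluster", 62.018, anomalous=True)],
                 flags={"k_oh_placeholder"}),
        Compound("monoterpenes", "C10H16", 10, "terpene_mono",
                 k_O3=2.0e-16, k_OH=1.5e-10,
                 channels=[_ch(P, "protonation", 137.134),
                           _ch(N, "charge_transfer", 136.130)],
                 flags={"k_oh_placeholder"}),
        Compound("sesquiterpenes", "C15H24", 15, "terpene_sesqui",
                 k_O3=5.9e-16, k_OH=1.0e-10,
                 channels=[_ch(P, "protonation", 205.198),
                           _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("methyl salicylate", "C8H8O3", 8, "other",
                 channels=[_ch(P, "protonation", 153.053)]),
        # --- speciated terpenes (GC-MS identification) ----------------------
        Compound("limonene", "C10H16", 10, "terpene_mono",
                 k_O3=2.0e-16, k_OH=1.6e-10,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("alpha-pinene", "C10H16", 10, "terpene_mono",
                 k_O3=8.4e-17, k_OH=5.3e-11,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("beta-pinene", "C10H16", 10, "terpene_mono",
                 k_O3=1.5e-17, k_OH=7.4e-11,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("gamma-terpinene", "C10H16", 10, "terpene_mono",
                 k_O3=1.4e-16, k_OH=1.7e-10,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("alpha-thujene", "C10H16", 10, "terpene_mono",
                 k_O3=8.4e-17,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_o3_surrogate"}),
        Compound("beta-caryophyllene", "C15H24", 15, "terpene_sesqui",
                 k_O3=1.2e-16, k_OH=2.0e-10,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("isolongifolene", "C15H24", 15, "terpene_sesqui",
                 k_O3=2.5e-17,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")]),
        Compound("alpha-farnesene", "C15H24", 15, "terpene_sesqui",
                 k_O3=5.9e-16, k_OH=3.0e-10,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_oh_placeholder"}),
        Compound("beta-elemene", "C15H24", 15, "terpene_sesqui",
                 k_O3=3.15e-15,
                 channels=[_ch(P, "protonation"), _ch(N, "charge_transfer")],
                 flags={"k_o3_surrogate"}),
        # --- ozone-induced oxygenates and ozonolysis products ---------------
        Compound("acetone", "C3H6O", 3, "ketone", k_OH=1.8e-13,
                 channels=[_ch(P, "protonation", 59.050), _ch(N, "NO_cluster")],
                 flags={"k_oh_placeholder"}),
        Compound("methyl vinyl ketone", "C4H6O", 4, "ketone", k_OH=2.0e-11,
                 channels=[_ch(P, "protonation", 71.050), _ch(N, "NO_cluster")],
                 flags={"k_oh_placeholder"}),
        Compound("oxopentanal", "C5H8O2", 5, "aldehyde", k_OH=3.0e-11,
                 channels=[_ch(P, "protonation", 101.061),
                           _ch(N, "hydride_abstraction")],
                 flags={"k_oh_placeholder"}),
        Compound("6-methyl-5-hepten-2-one", "C8H14O", 8, "ketone", k_OH=1.6e-10,
                 channels=[_ch(P, "protonation", 127.111), _ch(N, "NO_cluster")],
                 flags={"k_oh_placeholder"}),
        Compound("nonanal", "C9H18O", 9, "aldehyde", k_OH=3.0e-11,
                 channels=[_ch(P, "protonation"), _ch(N, "hydride_abstraction")],
                 flags={"k_oh_placeholder"}),
        Compound("decanal", "C10H20O", 10, "aldehyde", k_OH=3.2e-11,
                 channels=[_ch(P, "protonation"), _ch(N, "hydride_abstraction")],
                 flags={"k_oh_placeholder"}),
        # --- OH-scavenger system --------------------------------------------
        Compound("cyclohexane", "C6H12", 6, "other", k_OH=7.0e-12,
                 channels=[_ch(N, "hydride_abstraction")],
                 flags={"k_oh_placeholder"}),
        Compound("cyclohexanone", "C6H10O", 6, "ketone", k_OH=6.4e-12,
                 channels=[_ch(P, "protonation"), _ch(N, "NO_cluster")],
                 flags={"k_oh_placeholder"}),
    ]


def default_registry() -> Registry:
    """The built-in registry of all compounds referenced in the analysis."""
    return Registry(_default_compounds())


def _compound_from_dict(d: dict) -> Compound:
    name = d.get("name", "<unnamed>")
    try:
        channels = tuple(
            IonChannel(
                mode=ch["mode"],
                mechanism=ch["mechanism"],
                observed_mz=ch.get("observed_mz"),
                anomalous=bool(ch.get("anomalous", False)),
            )
            for ch in d.get("channels", [])
        )
        return Compound(
            name=d["name"],
            formula=d["formula"],
            n_carbon=int(d["n_carbon"]),
            class_tag=d.get("class", d.get("class_tag", "other")),
            k_O3=d.get("k_O3"),
            k_OH=d.get("k_OH"),
            channels=channels,
            flags=frozenset(d.get("flags", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid registry entry for compound {name!r}: {exc}") from exc


def load_registry(source) -> Registry:
    """Load a registry from a YAML document, path, or parsed mapping.

    The document is a mapping with a ``compounds`` list; each entry carries
    ``name``, ``formula``, ``n_carbon`` and optional ``class``, ``k_O3``,
    ``k_OH``, ``flags`` and ``channels`` (``mode``/``mechanism`` with
    optional ``observed_mz``). An empty document yields an empty registry
    with a logged warning.
    """
    if isinstance(source, (str,)) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, str):
        doc = yaml.safe_load(source)
    elif isinstance(source, dict) or source is None:
        doc = source
    else:  # file-like
        doc = yaml.safe_load(source)
    if not doc:
        logger.warning("empty registry document; returning empty registry")
        warnings.warn("empty registry document; returning empty registry")
        return Registry([])
    entries = doc.get("compounds", [])
    return Registry([_compound_from_dict(d) for d in entries])
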