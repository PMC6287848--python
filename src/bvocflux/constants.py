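"""Physical constants and ion-chemistry mass shifts used across the package.

All ion-mechanism mass shifts are centralized here so that every m/z in the
package derives from one set of conventions.
"""

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Mass added on protonation (proton: H atom minus electron), Da.
PROTON_MASS = 1.00728

#: Mass removed on hydride abstraction (neutral H atom), Da.
H_ATOM_MASS = 1.00783

#: Mass added on NO+ cluster formation, Da.
NO_CLUSTER_MASS = 29.99799

#: Reference chamber temperature, K.
T_REF = 296.0

#: Reference chamber pressure, Pa.
P_REF = 100000.0

#: Air number density at the reference state, molecules cm^-3.
AIR_NUMBER_DENSITY = 2.46e19

#: Normalization target for primary-ion counts (counts are scaled to a
#: primary beam of 10^6 cps).
PRIMARY_ION_TARGET = 1.0e6


def ppbv_to_molecules_cm3(ppbv: float, air_density: float = AIR_NUMBER_DENSITY) -> float:
    """Volume mixing ratio (ppbv) to number density (molecules cm^-3)."""
    return ppbv * 1.0e-9 * air_density


def ppbv_to_nmol_m3(ppbv, T: float = T_REF, P: float = P_REF):
    """Volume mixing ratio (ppbv) to molar concentration (nmol m^-3).

    1 ppbv corresponds to 1e-9 * P/(R*T) mol m^-3 = P/(R*T) nmol m^-3.
    """
    return ppbv * P / (R_GAS * T)


def nmol_m3_to_ppbv(c, T: float = T_REF, P: float = P_REF):
    """Molar concentration (nmol m^-3) to volume mixing ratio (ppbv)."""
    return c * R_GAS * T / P
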