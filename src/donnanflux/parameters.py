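"""Physical constants, domain types and packaged parameter sets.

Concentration unit is mM throughout, which conveniently equals mol/m^3 in SI,
so no conversion factor appears in Poisson's equation when lengths are in
metres. Chemical-potential corrections are dimensionless (units of RT);
electric potentials are stored as the dimensionless combination
``psi = F * phi / (R T)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# -- physical constants (SI) -------------------------------------------------

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
EPSILON_0 = 8.8541878128e-12  # F/m

#: default experimental temperature, K
TEMPERATURE = 298.15
#: relative permittivity of the aqueous solutions
EPSILON_R = 78.0


def thermal_voltage(temperature: float = TEMPERATURE) -> float:
    """RT/F in volts; converts a dimensionless potential psi to phi."""
    return GAS_CONSTANT * temperature / FARADAY


def debye_length(c_salt_mM: float, temperature: float = TEMPERATURE,
                 epsilon_r: float = EPSILON_R) -> float:
    """Debye screening length (m) of a 1:1 electrolyte at ``c_salt_mM``.

    mM equals mol/m^3, so the ionic strength of a symmetric 1:1 salt is
    simply the concentration.
    """
    kappa_sq = (
        2.0 * FARADAY**2 * c_salt_mM
        / (EPSILON_0 * epsilon_r * GAS_CONSTANT * temperature)
    )
    return 1.0 / np.sqrt(kappa_sq)


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """A mobile ionic species with per-region transport properties.

    ``delta_mu_corr`` is the difference of the non-ideal (excess) chemical
    potential between the polyelectrolyte and the salt solution,
    mu_p^corr - mu_s^corr, in units of RT. The ideal standard potential
    cancels from every difference used here and is not stored.
    """

    name: str
    valence: int
    d_salt_region: float  # m^2/s
    d_poly: float  # m^2/s
    d_membrane: float  # m^2/s
    delta_mu_corr: float  # RT

    def __post_init__(self) -> None:
        for attr in ("d_salt_region", "d_poly", "d_membrane"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")

    def d_in(self, region: str) -> float:
        return {"poly": self.d_poly, "membrane": self.d_membrane,
                "salt": self.d_salt_region}[region]


@dataclass(frozen=True)
class BathComposition:
    """Composition of the two-compartment bath.

    ``fcd`` is the fixed charge density carried by the polyelectrolyte, in mM
    of elementary charge; it is negative for the carboxymethylcellulose /
    glycosaminoglycan systems modelled here.
    """

    c_nacl_salt: float  # mM
    fcd: float  # mM, signed (<= 0 here)
    temperature: float = TEMPERATURE  # K
    c_gd_salt_initial: float = 0.33  # mM

    def __post_init__(self) -> None:
        if self.c_nacl_salt <= 0:
            raise ValueError("c_nacl_salt must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if abs(self.fcd) >= 2.0 * self.c_nacl_salt:
            warnings.warn(
                "|FCD| >= 2 C_NaCl,s: linearized Donnan expressions will be "
                "unreliable for this composition", stacklevel=2)


@dataclass(frozen=True)
class DonnanState:
    """Solved Donnan equilibrium between the two compartments."""

    psi: float  # dimensionless F*delta_phi/RT
    c_na_poly: float  # mM
    c_cl_poly: float  # mM
    fcd: float  # mM
    c_salt: float  # mM
    partition_ratio_gd: float | None = None

    @property
    def electroneutrality_residual(self) -> float:
        """c_Na,p - c_Cl,p + FCD, relative to the salt concentration."""
        return (self.c_na_poly - self.c_cl_poly + self.fcd) / self.c_salt


@dataclass(frozen=True)
class CalibrationModel:
    """Relaxivity calibration converting T1 to contrast-agent concentration.

    1/T1 = 1/t1_pre + relaxivity * c, with relaxivity in (mM s)^-1.
    """

    relaxivity: float  # (mM s)^-1
    t1_pre: float  # s

    def __post_init__(self) -> None:
        if self.relaxivity <= 0 or self.t1_pre <= 0:
            raise ValueError("relaxivity and t1_pre must be positive")

    def t1_of(self, conc_mM):
        """Forward model: T1 at concentration ``conc_mM``."""
        return 1.0 / (1.0 / self.t1_pre + self.relaxivity * np.asarray(conc_mM))


# -- packaged parameter sets -------------------------------------------------


def load_parameter_table() -> dict:
    """Load the packaged experimental parameter table (mM / m^2/s / RT)."""
    with resources.files("donnanflux.data").joinpath(
            "parameter_sets.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ParameterSet:
    """One column of the experimental parameter table, fully hydrated."""

    name: str
    bath: BathComposition
    na: IonSpecies
    cl: IonSpecies
    gd: IonSpecies
    relaxivity_poly: float | None = None
    relaxivity_salt: float = 3.84
    c_na_poly_measured: float | None = None
    c_cl_poly_measured: float | None = None


def get_parameter_set(name: str) -> ParameterSet:
    """Hydrate a named parameter set ('fcd-73', 'fcd-92', 'fcd-108',
    'fcd-50-low', 'fcd-150-stress' or 'ideal')."""
    table = load_parameter_table()
    try:
        row = table["sets"][name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; available: "
            f"{sorted(table['sets'])}") from None
    const = table["constants"]
    bath = BathComposition(
        c_nacl_salt=const["c_nacl_salt_mM"],
        fcd=row["fcd_mM"],
        temperature=const["temperature_K"],
        c_gd_salt_initial=const["c_gd_salt_initial_mM"],
    )
    d_na = const["d_na_m2_per_s"]
    d_cl = const["d_cl_m2_per_s"]
    d_gd_s = const["d_gd_salt_m2_per_s"]
    na = IonSpecies("Na+", +1, d_na, d_na, d_na, row["delta_mu_na_RT"])
    cl = IonSpecies("Cl-", -1, d_cl, d_cl, d_cl, row["delta_mu_cl_RT"])
    gd = IonSpecies(
        "Gd(DTPA)2-", -2, d_gd_s, row["d_gd_poly_m2_per_s"],
        const["d_gd_membrane_m2_per_s"], row["delta_mu_gd_RT"])
    return ParameterSet(
        name=name, bath=bath, na=na, cl=cl, gd=gd,
        relaxivity_poly=row.get("relaxivity_poly_per_mM_per_s"),
        relaxivity_salt=const["relaxivity_salt_per_mM_per_s"],
        c_na_poly_measured=row.get("c_na_poly_mM"),
        c_cl_poly_measured=row.get("c_cl_poly_mM"),
    )
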