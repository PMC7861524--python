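"""Physicochemical adjustment of Gibbs energies.

Implements the transform of standard formation energies to the simulation
conditions: pH, ionic strength I, temperature and (optionally) salinity.

The ionic-strength correction uses either the extended Debye-Hueckel
equation (validity I < 0.1 M, fixed B = 1.6 mol^-1/2 L^1/2) or the Davies
equation (validity I < 0.5 M, beta = 0.3).  The Debye-Hueckel limiting
slope A can be computed from a temperature-only quadratic, or assembled
from physical constants together with seawater density and relative
permittivity so that it also responds to salinity.  Salinity itself can be
estimated from ionic strength through the seawater salinity relation using
the buoyant density of bacterial cells.

Units: energies in kJ/mol, temperatures in K inside formulas (Celsius at
API boundaries where noted), concentrations in mol/L, salinity in g/kg.
A is in mol^-1/2 kg^1/2; commensurability with B assumes 1 kg = 1 L of
solvent.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

from .constants import CELSIUS_OFFSET, CONSTANTS, R_KJ
from .model import Compartment, Reaction, SpeciesThermoRecord

LN10 = math.log(10.0)

#: Species treated as solvent/proton convention carriers: they are excluded
#: from reaction Gibbs-energy sums and from concentration terms (pH enters
#: only through the hydrogen-count term of the species transform).
DEFAULT_PROTON_BASENAMES: Set[str] = {"h"}
DEFAULT_WATER_BASENAMES: Set[str] = {"h2o"}


class PhysChemError(ValueError):
    """Raised for inputs outside a formula's validity window."""


def _basename(species_id: str) -> str:
    """Strip a trailing compartment suffix: ``h2o_c`` -> ``h2o``."""
    return species_id.rsplit("_", 1)[0] if "_" in species_id else species_id


def is_proton(species_id: str, basenames: Set[str] = DEFAULT_PROTON_BASENAMES) -> bool:
    return _basename(species_id) in basenames


def is_water(species_id: str, basenames: Set[str] = DEFAULT_WATER_BASENAMES) -> bool:
    return _basename(species_id) in basenames


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysChemConditions:
    """Simulation conditions for the Gibbs-energy transforms.

    ``ionic_strength`` overrides the per-compartment value for every
    compartment (it is a design factor, not a compartment property, in the
    factorial sweeps); pH always comes from the compartment.

    a_mode selects how the Debye-Hueckel slope A is computed:
    ``temperature`` (quadratic in T) or ``temperature_salinity``
    (physical-constant prefactor with seawater density/permittivity).
    """

    temperature_c: float = 25.0
    ionic_strength: float = 0.0  # mol/L
    salinity: float = 0.0  # g/kg
    adjustment_method: str = "debye_huckel"  # or "davies"
    a_mode: str = "temperature"  # or "temperature_salinity"
    B: float = 1.6  # mol^-1/2 L^1/2
    beta: float = 0.3

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise PhysChemError("ionic strength must be non-negative")
        if self.salinity < 0:
            raise PhysChemError("salinity must be non-negative")
        if not 0.0 < self.temperature_c < 100.0:
            raise PhysChemError("temperature must be in (0, 100) degC")
        if self.B <= 0:
            raise PhysChemError("B must be positive")
        if self.adjustment_method not in ("debye_huckel", "davies"):
            raise PhysChemError(f"unknown adjustment method {self.adjustment_method!r}")
        if self.a_mode not in ("temperature", "temperature_salinity"):
            raise PhysChemError(f"unknown A mode {self.a_mode!r}")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + CELSIUS_OFFSET

    @property
    def RT(self) -> float:
        """R*T in kJ/mol at the simulation temperature."""
        return R_KJ * self.temperature_k

    def param_A(self) -> float:
        if self.a_mode == "temperature":
            return param_A_temperature(self.temperature_k)
        return param_A_temp_salinity(self.temperature_c, self.salinity)

    def fingerprint(self) -> str:
        key = (
            f"{self.temperature_c!r}|{self.ionic_strength!r}|{self.salinity!r}|"
            f"{self.adjustment_method}|{self.a_mode}|{self.B!r}|{self.beta!r}"
        )
        return hashlib.sha1(key.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Debye-Hueckel slope A
# ---------------------------------------------------------------------------

def param_A_temperature(temperature_k: float) -> float:
    """Debye-Hueckel slope from the quadratic temperature fit,
    mol^-1/2 kg^1/2 (natural-log convention).  Valid for liquid water,
    273.15 K < T < 373.15 K."""
    if not CELSIUS_OFFSET < temperature_k < CELSIUS_OFFSET + 100.0:
        raise PhysChemError(
            f"temperature {temperature_k} K outside (273.15, 373.15)"
        )
    T = temperature_k
    return 1.10708 - 1.54508e-3 * T + 5.95584e-6 * T * T


def seawater_density(temperature_c: float, salinity: float) -> float:
    """Density of seawater at one atmosphere, kg/m^3.

    International one-atmosphere equation of state of seawater
    (Millero & Poisson / UNESCO EOS-80); valid for t in [0, 40] degC and
    S in [0, 42] g/kg.
    """
    t, S = temperature_c, salinity
    if not 0.0 <= t <= 40.0:
        raise PhysChemError(f"temperature {t} degC outside density validity [0, 40]")
    if not 0.0 <= S <= 42.0:
        raise PhysChemError(f"salinity {S} g/kg outside density validity [0, 42]")
    # pure-water density (Bigg, as adopted by EOS-80)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    A = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    B = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def seawater_rel_permittivity(temperature_c: float, salinity: float) -> float:
    """Static relative permittivity of seawater (dimensionless).

    Pure-water permittivity from the Malmberg-Maryott polynomial, reduced
    for dissolved salt with Stogryn's normality correction.  Valid for
    t in [0, 40] degC and S in [0, 42] g/kg; decreasing in both t and S.
    """
    t, S = temperature_c, salinity
    if not 0.0 <= t <= 40.0:
        raise PhysChemError(
            f"temperature {t} degC outside permittivity validity [0, 40]"
        )
    if not 0.0 <= S <= 42.0:
        raise PhysChemError(
            f"salinity {S} g/kg outside permittivity validity [0, 42]"
        )
    eps_w = 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3
    # salinity (g/kg) -> solution normality, then multiplicative reduction
    N = S * (1.707e-2 + 1.205e-5 * S + 4.058e-9 * S**2)
    a = 1.000 - 0.2551 * N + 5.151e-2 * N**2 - 6.889e-3 * N**3
    return eps_w * a


def param_A_temp_salinity(temperature_c: float, salinity: float) -> float:
    """Debye-Hueckel slope from physical constants and seawater
    density/permittivity, mol^-1/2 kg^1/2 (natural-log convention).

    A = sqrt(2 pi N_A rho_sw) * (F^2 / (4 pi eps0 N_A R))^(3/2)
        * (eps_sw T)^(-3/2)

    which reduces to the classical limiting slope of an aqueous electrolyte
    at S = 0 and tracks the temperature-only quadratic within 2%.
    """
    T = temperature_c + CELSIUS_OFFSET
    rho = seawater_density(temperature_c, salinity)  # kg/m^3
    eps = seawater_rel_permittivity(temperature_c, salinity)
    c = CONSTANTS
    prefactor = (c.F**2 / (4.0 * math.pi * c.epsilon0 * c.N_A * c.R)) ** 1.5
    return math.sqrt(2.0 * math.pi * c.N_A * rho) * prefactor * (eps * T) ** -1.5


def salinity_from_ionic_strength(ionic_strength: float, buoyant_density: float) -> float:
    """Salinity (g/kg) from ionic strength (mol/L) and solution density
    (kg/L) via the seawater ionic-strength/salinity relation

        I * rho = 19.92 * S / (1000 - 1.005 * S)

    solved in closed form for S."""
    if ionic_strength < 0:
        raise PhysChemError("ionic strength must be non-negative")
    if buoyant_density <= 0:
        raise PhysChemError("density must be positive")
    x = ionic_strength * buoyant_density
    return 1000.0 * x / (19.92 + 1.005 * x)


# ---------------------------------------------------------------------------
# ionic term and species/reaction transforms
# ---------------------------------------------------------------------------

def ionic_term_factor(ionic_strength: float, conditions: PhysChemConditions) -> float:
    """The bracketed ionic-strength term of the activity correction:
    sqrt(I)/(1 + B sqrt(I)) for extended Debye-Hueckel,
    sqrt(I)/(1 + sqrt(I)) - beta*I for Davies.  Both vanish at I = 0."""
    if ionic_strength < 0:
        raise PhysChemError("ionic strength must be non-negative")
    sqrt_i = math.sqrt(ionic_strength)
    if conditions.adjustment_method == "debye_huckel":
        return sqrt_i / (1.0 + conditions.B * sqrt_i)
    return sqrt_i / (1.0 + sqrt_i) - conditions.beta * ionic_strength


@dataclass(frozen=True)
class TransformedEnergy:
    """Standard transformed Gibbs energy of formation at given conditions."""

    species_id: str
    dfg0_transformed: float  # kJ/mol
    fingerprint: str


@dataclass(frozen=True)
class ThermoReactionRecord:
    """Standard transformed Gibbs energy of reaction; ``covered`` is False
    when any non-excluded participant lacks thermodynamic data (or the
    reaction is an exchange/biomass pseudo-reaction)."""

    reaction_id: str
    drg0_transformed: Optional[float]  # kJ/mol; None when not covered
    covered: bool
    fingerprint: str = ""


def transform_formation_energy(
    record: SpeciesThermoRecord,
    compartment: Compartment,
    conditions: PhysChemConditions,
) -> TransformedEnergy:
    """Adjust a reference formation energy to pH, I, T (and S through A):

    dfG'0 = dfG0 + N_H R T ln(10) pH - R T A f(I) (z^2 - N_H)

    with f(I) the method-specific ionic term.  All terms in kJ/mol.
    """
    if not record.known:
        raise PhysChemError(
            f"species {record.species_id}: no reference formation energy"
        )
    RT = conditions.RT
    A = conditions.param_A()
    ion = ionic_term_factor(conditions.ionic_strength, conditions)
    value = (
        record.dfg0_ref
        + record.n_hydrogen * RT * LN10 * compartment.pH
        - RT * A * ion * (record.charge**2 - record.n_hydrogen)
    )
    return TransformedEnergy(
        species_id=record.species_id,
        dfg0_transformed=value,
        fingerprint=conditions.fingerprint(),
    )


def transform_all(
    records: Mapping[str, SpeciesThermoRecord],
    compartments_by_species: Mapping[str, Compartment],
    conditions: PhysChemConditions,
) -> Dict[str, TransformedEnergy]:
    """Transform every known record; species without a compartment entry or
    without data are simply absent from the result."""
    out: Dict[str, TransformedEnergy] = {}
    for sid, rec in records.items():
        if not rec.known or sid not in compartments_by_species:
            continue
        out[sid] = transform_formation_energy(
            rec, compartments_by_species[sid], conditions
        )
    return out


def reaction_transformed_dg0(
    reaction: Reaction,
    energies: Mapping[str, TransformedEnergy],
    conditions: PhysChemConditions,
    proton_basenames: Set[str] = DEFAULT_PROTON_BASENAMES,
    water_basenames: Set[str] = DEFAULT_WATER_BASENAMES,
) -> ThermoReactionRecord:
    """Sum transformed formation energies over the reaction stoichiometry.

    Protons and water are excluded (standard transformed-energy convention;
    pH is already accounted for in the species transform).  Exchange and
    biomass pseudo-reactions are never covered.
    """
    fp = conditions.fingerprint()
    if reaction.is_exchange or reaction.is_biomass or not reaction.thermo_active:
        return ThermoReactionRecord(reaction.id, None, False, fp)
    total = 0.0
    for sid, coeff in reaction.stoichiometry.items():
        if is_proton(sid, proton_basenames) or is_water(sid, water_basenames):
            continue
        if sid not in energies:
            return ThermoReactionRecord(reaction.id, None, False, fp)
        if energies[sid].fingerprint != fp:
            raise PhysChemError(
                f"species {sid}: transformed energy computed at different "
                "conditions than requested"
            )
        total += coeff * energies[sid].dfg0_transformed
    return ThermoReactionRecord(reaction.id, total, True, fp)


def reaction_records_for_model(
    model,
    thermo: Mapping[str, SpeciesThermoRecord],
    conditions: PhysChemConditions,
) -> Dict[str, ThermoReactionRecord]:
    """Transform all species energies and sum them per reaction for a whole
    model (per-compartment pH, shared conditions)."""
    compartments_by_species = {
        sid: model.compartments[sp.compartment]
        for sid, sp in model.species.items()
        if sp.compartment
    }
    energies = transform_all(thermo, compartments_by_species, conditions)
    return {
        rid: reaction_transformed_dg0(rxn, energies, conditions)
        for rid, rxn in model.reactions.items()
    }


def load_conditions_yaml(path):
    """Read a conditions YAML: the PhysChemConditions fields plus an
    optional ``compartments`` block of per-compartment pH/ionic-strength
    overrides.  Returns (conditions, overrides)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    overrides = data.pop("compartments", {}) or {}
    allowed = {
        "temperature_c", "ionic_strength", "salinity",
        "adjustment_method", "a_mode", "B", "beta",
    }
    unknown = set(data) - allowed
    if unknown:
        raise PhysChemError(f"unknown conditions keys: {sorted(unknown)}")
    return PhysChemConditions(**data), overrides


def flux_force_ratio(drg_prime: float, temperature_k: float) -> float:
    """Forward-to-backward flux ratio J+/J- = exp(-drG'/(R T))."""
    if not math.isfinite(drg_prime):
        raise PhysChemError("drG' must be finite")
    return math.exp(-drg_prime / (R_KJ * temperature_k))
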