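"""Metabolic model containers, validation and file I/O.

The package works on a small, explicit in-memory representation
(:class:`MetabolicModel`) rather than wrapping a third-party object, because
the thermodynamic layer needs per-species charges/hydrogen counts and
per-compartment conditions that genome-scale formats do not carry.  Models
can be read from SBML Level 3 (fbc bounds and objective, via cobrapy) or
from a native three-table tabular dialect that is convenient to diff and to
generate as a test fixture.

Charges and hydrogen counts deliberately live in a separate thermodynamic
table (:func:`load_thermo_table`), decoupling network topology from its
thermodynamic parameterization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

logger = logging.getLogger(__name__)

_STOICH_TERM = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+(\S+)\s*$")


class ModelError(ValueError):
    """Raised for unreadable or referentially broken model inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    """A homogeneous sub-volume with its own pH and ionic strength.

    pH and ionic strength (mol/L) parameterize the per-species Gibbs-energy
    transform applied to every species located in the compartment.
    """

    id: str
    pH: float = 7.0
    ionic_strength: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise ModelError(f"compartment {self.id}: pH {self.pH} outside [0, 14]")
        if self.ionic_strength < 0:
            raise ModelError(f"compartment {self.id}: negative ionic strength")


@dataclass
class Species:
    """A metabolite species in a specific compartment.

    ``formula`` is an elemental map (e.g. ``{"C": 6, "H": 12, "O": 6}``) used
    only for balance checking; charge and hydrogen count for thermodynamics
    are supplied separately through the thermo table.
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[Dict[str, int]] = None


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol gDCW^-1 h^-1.

    Negative stoichiometric coefficients denote substrates.  Exchange and
    biomass reactions are pseudo-reactions and are never thermodynamically
    constrained (``thermo_active`` must be False for them).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    is_biomass: bool = False
    thermo_active: bool = True

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if (self.is_exchange or self.is_biomass) and self.thermo_active:
            raise ModelError(
                f"reaction {self.id}: exchange/biomass reactions cannot be "
                "thermodynamically active"
            )

    @property
    def reactants(self) -> List[str]:
        return [s for s, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> List[str]:
        return [s for s, c in self.stoichiometry.items() if c > 0]


@dataclass
class SpeciesThermoRecord:
    """Standard Gibbs energy of formation at the reference state plus the
    species charge and hydrogen-atom count used by the ionic/pH transform."""

    species_id: str
    dfg0_ref: Optional[float]  # kJ/mol; None when unknown
    charge: int = 0
    n_hydrogen: int = 0

    @property
    def known(self) -> bool:
        return self.dfg0_ref is not None


@dataclass
class MetabolicModel:
    """Compartments, species and reactions with a designated objective."""

    compartments: Dict[str, Compartment]
    species: Dict[str, Species]
    reactions: Dict[str, Reaction]
    objective_reaction: str
    id: str = "model"

    def __post_init__(self) -> None:
        for sp in self.species.values():
            if sp.compartment and sp.compartment not in self.compartments:
                raise ModelError(
                    f"species {sp.id}: unknown compartment {sp.compartment!r}"
                )
        for rxn in self.reactions.values():
            for sid in rxn.stoichiometry:
                if sid not in self.species:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown species {sid!r}"
                    )
        if self.objective_reaction not in self.reactions:
            raise ModelError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Species x reactions matrix of signed coefficients."""
        mat = pd.DataFrame(
            0.0,
            index=list(self.species),
            columns=list(self.reactions),
        )
        for rid, rxn in self.reactions.items():
            for sid, coeff in rxn.stoichiometry.items():
                mat.loc[sid, rid] = coeff
        return mat

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def find_uptake_exchange(self) -> Reaction:
        """The substrate-uptake exchange: the unique exchange with a negative
        lower bound.  Raises if zero or several candidates exist."""
        cands = [r for r in self.exchanges() if r.lower_bound < 0 and not _is_free_exchange(r)]
        if len(cands) != 1:
            raise ModelError(
                f"cannot identify a unique uptake exchange (candidates: "
                f"{[r.id for r in cands]})"
            )
        return cands[0]

    def to_cobra(self):
        """Convert to a cobrapy Model (used for SBML export and as an
        independent LP route in cross-checks)."""
        import cobra

        cm = cobra.Model(self.id)
        mets = {}
        for sp in self.species.values():
            m = cobra.Metabolite(sp.id, name=sp.name, compartment=sp.compartment)
            if sp.formula:
                m.formula = format_formula(sp.formula)
            mets[sp.id] = m
        cm.add_metabolites(list(mets.values()))
        rxns = []
        for rxn in self.reactions.values():
            cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                                upper_bound=rxn.upper_bound)
            rxns.append(cr)
        cm.add_reactions(rxns)
        for rxn in self.reactions.values():
            cm.reactions.get_by_id(rxn.id).add_metabolites(
                {mets[s]: c for s, c in rxn.stoichiometry.items()}
            )
        cm.objective = self.objective_reaction
        return cm


def _is_free_exchange(rxn: Reaction) -> bool:
    """Exchanges open in both directions (e.g. water) are not uptakes."""
    return rxn.lower_bound <= -999 and rxn.upper_bound >= 999


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural checks: inverted bounds and empty stoichiometries are
    errors; species participating in no reaction are warnings (orphans are
    routine in genome-scale models)."""
    report = ValidationReport()
    if model.objective_reaction not in model.reactions:
        report.errors.append(f"objective reaction {model.objective_reaction} missing")
    participating = set()
    for rxn in model.reactions.values():
        if not rxn.stoichiometry:
            report.errors.append(f"reaction {rxn.id}: empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            report.errors.append(
                f"reaction {rxn.id}: bounds inverted "
                f"({rxn.lower_bound} > {rxn.upper_bound})"
            )
        participating.update(rxn.stoichiometry)
    for sid in model.species:
        if sid not in participating:
            report.warnings.append(f"species {sid} participates in no reaction")
    return report


# ---------------------------------------------------------------------------
# formula handling
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-style formula string like ``C6H12O6`` into an element map."""
    out: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {text!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ModelError(f"cannot parse formula {text!r}")
    return out


def format_formula(formula: Dict[str, int]) -> str:
    parts = []
    for el in sorted(formula):
        n = formula[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def elemental_imbalance(model: MetabolicModel, reaction_id: str) -> Dict[str, float]:
    """Net element counts (products minus substrates) for one reaction.

    Species without a formula contribute nothing; an all-zero result means
    the reaction is elementally balanced.
    """
    rxn = model.reactions[reaction_id]
    net: Dict[str, float] = {}
    for sid, coeff in rxn.stoichiometry.items():
        formula = model.species[sid].formula or {}
        for el, n in formula.items():
            net[el] = net.get(el, 0.0) + coeff * n
    return {el: v for el, v in net.items() if abs(v) > 1e-9}


# ---------------------------------------------------------------------------
# stoichiometry strings
# ---------------------------------------------------------------------------

def parse_stoichiometry(text: str, reaction_id: str = "?") -> Dict[str, float]:
    """Parse ``"-1 glc_e + 1 g6p_c"`` into a coefficient map."""
    stoich: Dict[str, float] = {}
    for term in text.split(" + "):
        m = _STOICH_TERM.match(term)
        if not m:
            raise ModelError(
                f"reaction {reaction_id}: cannot parse stoichiometry term {term!r}"
            )
        coeff, sid = float(m.group(1)), m.group(2)
        if sid in stoich:
            raise ModelError(f"reaction {reaction_id}: species {sid} repeated")
        stoich[sid] = coeff
    return stoich


def format_stoichiometry(stoich: Dict[str, float]) -> str:
    def fmt(c: float) -> str:
        return str(int(c)) if float(c).is_integer() else repr(float(c))

    return " + ".join(f"{fmt(c)} {s}" for s, c in sorted(stoich.items()))


# ---------------------------------------------------------------------------
# native tabular dialect
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, directory) -> None:
    """Write the three-table native dialect (compartments/species/reactions)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "compartments.tsv", "w") as fh:
        fh.write("id\tpH\tionic_strength\tlabel\n")
        for c in model.compartments.values():
            fh.write(f"{c.id}\t{c.pH!r}\t{c.ionic_strength!r}\t{c.label}\n")
    with open(directory / "species.tsv", "w") as fh:
        fh.write("id\tname\tcompartment\tformula\n")
        for s in model.species.values():
            formula = format_formula(s.formula) if s.formula else ""
            fh.write(f"{s.id}\t{s.name}\t{s.compartment}\t{formula}\n")
    with open(directory / "reactions.tsv", "w") as fh:
        fh.write("id\tstoichiometry\tlower_bound\tupper_bound\tflags\tobjective\n")
        for r in model.reactions.values():
            flags = ",".join(
                name
                for name, on in (
                    ("exchange", r.is_exchange),
                    ("biomass", r.is_biomass),
                    ("thermo", r.thermo_active),
                )
                if on
            )
            obj = "1" if r.id == model.objective_reaction else ""
            fh.write(
                f"{r.id}\t{format_stoichiometry(r.stoichiometry)}\t"
                f"{r.lower_bound!r}\t{r.upper_bound!r}\t{flags}\t{obj}\n"
            )


def _load_native(directory: Path) -> MetabolicModel:
    comp_df = pd.read_csv(directory / "compartments.tsv", sep="\t", dtype=str).fillna("")
    spec_df = pd.read_csv(directory / "species.tsv", sep="\t", dtype=str).fillna("")
    rxn_df = pd.read_csv(directory / "reactions.tsv", sep="\t", dtype=str).fillna("")

    compartments: Dict[str, Compartment] = {}
    for _, row in comp_df.iterrows():
        if row["id"] in compartments:
            raise ModelError(f"duplicate compartment id {row['id']!r}")
        compartments[row["id"]] = Compartment(
            id=row["id"], pH=float(row["pH"]),
            ionic_strength=float(row["ionic_strength"]), label=row.get("label", ""),
        )
    species: Dict[str, Species] = {}
    for _, row in spec_df.iterrows():
        if row["id"] in species:
            raise ModelError(f"duplicate species id {row['id']!r}")
        species[row["id"]] = Species(
            id=row["id"], name=row["name"], compartment=row["compartment"],
            formula=parse_formula(row["formula"]) if row["formula"] else None,
        )
    reactions: Dict[str, Reaction] = {}
    objective = None
    for _, row in rxn_df.iterrows():
        if row["id"] in reactions:
            raise ModelError(f"duplicate reaction id {row['id']!r}")
        flags = set(filter(None, row["flags"].split(",")))
        reactions[row["id"]] = Reaction(
            id=row["id"],
            stoichiometry=parse_stoichiometry(row["stoichiometry"], row["id"]),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            is_exchange="exchange" in flags,
            is_biomass="biomass" in flags,
            thermo_active="thermo" in flags,
        )
        if row["objective"] == "1":
            objective = row["id"]
    if objective is None:
        raise ModelError("no objective reaction marked in reactions.tsv")
    return MetabolicModel(
        compartments=compartments, species=species, reactions=reactions,
        objective_reaction=objective, id=directory.name,
    )


def _load_sbml(path: Path) -> MetabolicModel:
    """Read an SBML L3 (fbc) file through cobrapy.

    SBML carries no compartment pH/ionic strength; those default to pH 7 and
    I = 0 and are expected to be overridden by the simulation conditions.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    compartments = {
        cid: Compartment(id=cid, pH=7.0, ionic_strength=0.0, label=label or "")
        for cid, label in cm.compartments.items()
    }
    species = {}
    for m in cm.metabolites:
        formula = None
        if m.formula:
            try:
                formula = parse_formula(m.formula)
            except ModelError:
                logger.info("ignoring unparseable formula %r on %s", m.formula, m.id)
        if m.compartment and m.compartment not in compartments:
            compartments[m.compartment] = Compartment(id=m.compartment)
        species[m.id] = Species(
            id=m.id, name=m.name or "", compartment=m.compartment or "", formula=formula
        )
    objective_ids = [r.id for r in cm.reactions
                     if r.objective_coefficient not in (0, None)]
    if not objective_ids:
        raise ModelError(f"{path}: SBML model has no objective reaction")
    objective = objective_ids[0]
    reactions = {}
    for r in cm.reactions:
        is_exchange = r in cm.boundary
        is_biomass = r.id == objective and not is_exchange
        reactions[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            is_exchange=is_exchange,
            is_biomass=is_biomass,
            thermo_active=not (is_exchange or is_biomass),
        )
    return MetabolicModel(
        compartments=compartments, species=species, reactions=reactions,
        objective_reaction=objective, id=cm.id or path.stem,
    )


def load_model(path, format: str = "native-table") -> MetabolicModel:
    """Load a model from ``native-table`` (a directory of TSV files) or
    ``sbml`` (a Level 3 file with fbc bounds/objective)."""
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model path {path} does not exist")
    if format == "native-table":
        return _load_native(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ModelError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def load_thermo_table(path) -> Dict[str, SpeciesThermoRecord]:
    """Read ``thermo.tsv`` (species_id, dfg0_kj_mol, charge, n_hydrogen).

    An empty formation energy marks the species as thermodynamically unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: Dict[str, SpeciesThermoRecord] = {}
    for _, row in df.iterrows():
        sid = row["species_id"]
        if sid in records:
            raise ModelError(f"duplicate thermo record for species {sid!r}")
        charge_raw = row["charge"]
        try:
            charge = int(charge_raw)
        except ValueError:
            raise ModelError(
                f"species {sid}: non-integer charge {charge_raw!r}"
            ) from None
        n_h = int(row["n_hydrogen"])
        if n_h < 0:
            raise ModelError(f"species {sid}: negative hydrogen count")
        dfg0 = float(row["dfg0_kj_mol"]) if row["dfg0_kj_mol"] != "" else None
        records[sid] = SpeciesThermoRecord(
            species_id=sid, dfg0_ref=dfg0, charge=charge, n_hydrogen=n_h
        )
    return records


def write_thermo_table(records: Dict[str, SpeciesThermoRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tdfg0_kj_mol\tcharge\tn_hydrogen\n")
        for rec in records.values():
            dfg = repr(rec.dfg0_ref) if rec.dfg0_ref is not None else ""
            fh.write(f"{rec.species_id}\t{dfg}\t{rec.charge}\t{rec.n_hydrogen}\n")


def load_metabolomics(path) -> pd.DataFrame:
    """``metabolomics.tsv``: species_id, concentration_M (mol/L)."""
    df = pd.read_csv(path, sep="\t")
    if (df["concentration_M"] <= 0).any():
        raise ModelError("metabolomics concentrations must be positive")
    return df


def load_reference_fluxes(path) -> pd.DataFrame:
    """``refflux.tsv``: mfa_id, value, direction."""
    return pd.read_csv(path, sep="\t")


def load_mapping(path) -> pd.DataFrame:
    """``mapping.tsv``: gsm_id, mfa_id, sign (+1/-1)."""
    df = pd.read_csv(path, sep="\t")
    if not set(df["sign"]).issubset({1, -1}):
        raise ModelError("mapping signs must be +1 or -1")
    if df.duplicated(["gsm_id", "mfa_id"]).any():
        raise ModelError("duplicate (gsm_id, mfa_id) pair in mapping")
    return df
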