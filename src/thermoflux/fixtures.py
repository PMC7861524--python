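"""Deterministic toy-model fixture generation.

The generator emits a small but complete two-compartment model (cytosol +
extracellular) emulating the structure of the study system: a
phosphotransferase-style glucose uptake, a linear glycolysis-like chain, a
PFK/FBPase futile-cycle pair, a branch point at pyruvate with two
alternative routes of opposite standard reaction energy, fermentative NADH
reoxidation to a secreted byproduct, adenylate currency metabolites and a
biomass reaction.  It also emits a thermodynamic table covering every
species, a metabolomics table, a reference flux table with a GSM-to-MFA
mapping (including a sign-flipped entry), a side-compound list and a
manifest of intended results.

The branch is engineered to be ionic-strength sensitive: the efficient
route (``B1``, substrate-level phosphorylation through a highly charged
intermediate state) is thermodynamically blocked at I = 0 but feasible at
I = 0.25 M under either activity-correction method, so sweeps over the
ionic-strength factor produce genuinely different flux distributions.

Formation energies are constructed by choosing transformed reaction
energies at the reference condition (25 degC, pH 7, I = 0) and propagating
them through the network, then inverting the pH term to obtain reference
ΔfG° values; the seed adds only small jitter (±0.05 kJ/mol on energies,
±5% on concentrations) so that all engineered feasibility margins are
preserved for every seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, R_KJ
from .model import (
    Compartment,
    MetabolicModel,
    Reaction,
    Species,
    SpeciesThermoRecord,
    elemental_imbalance,
    parse_formula,
    write_model,
    write_thermo_table,
)

LN10 = math.log(10.0)
REFERENCE_PH = 7.0
REFERENCE_T_K = 25.0 + CELSIUS_OFFSET

#: Ubiquitous currency species excluded from the centrality graph.
SIDE_COMPOUNDS: List[str] = [
    "atp_c", "adp_c", "amp_c", "pi_c", "h2o_c", "h2o_e",
    "nad_c", "nadh_c", "co2_c", "co2_e",
]


@dataclass
class ToyFixture:
    """Everything :func:`generate_toy_model` produces."""

    model: MetabolicModel
    thermo: Dict[str, SpeciesThermoRecord]
    metabolomics: pd.DataFrame
    reference_fluxes: pd.DataFrame
    mapping: pd.DataFrame
    side_compounds: List[str]
    manifest: Dict


# species id -> (name, compartment, formula, charge)
_SPECIES = {
    "glc_e": ("glucose", "e", "C6H12O6", 0),
    "eth_e": ("ethanol", "e", "C2H6O", 0),
    "co2_e": ("carbon dioxide", "e", "CO2", 0),
    "h2o_e": ("water", "e", "H2O", 0),
    "g6p_c": ("hexose 6-phosphate", "c", "C6H11O9P", -2),
    "f6p_c": ("hexose 6-phosphate isomer", "c", "C6H11O9P", -2),
    "fdp_c": ("hexose 1,6-bisphosphate", "c", "C6H10O12P2", -4),
    "pyr_c": ("pyruvate-like acid", "c", "C3H5O3", -1),
    "acm_c": ("activated C3 acid", "c", "C3H5O3", -3),
    "eth_c": ("ethanol", "c", "C2H6O", 0),
    "co2_c": ("carbon dioxide", "c", "CO2", 0),
    "h2o_c": ("water", "c", "H2O", 0),
    "atp_c": ("ATP analogue", "c", "C10H12O13P3", -4),
    "adp_c": ("ADP analogue", "c", "C10H13O10P2", -3),
    "amp_c": ("AMP analogue", "c", "C10H14O7P", -2),
    "pi_c": ("orthophosphate", "c", "HO4P", -2),
    "nad_c": ("NAD+ analogue", "c", "C21H26N7O14P2", -1),
    "nadh_c": ("NADH analogue", "c", "C21H27N7O14P2", -2),
}

# transformed formation energies g' at the reference condition
# (25 degC, pH 7, I = 0), kJ/mol; chosen so that the reaction energies
# below come out at their designed values.
_GPRIME = {
    "atp_c": -2292.0,
    "adp_c": -1424.0,
    "amp_c": -555.5,
    "pi_c": -898.0,
    "h2o_c": -157.6,
    "h2o_e": -157.6,
    "nad_c": -1200.0,
    "nadh_c": -1158.0,
    "glc_e": -430.0,
    "g6p_c": -1315.0,     # PTS:  -17
    "f6p_c": -1312.5,     # PGI:  +2.5
    "fdp_c": -2190.5,     # PFK:  -10  (FBPase then -20 by closure)
    "pyr_c": -324.25,     # GLY:  -50
    "acm_c": -346.25,     # B1:   +8   (B2 written acm->pyr: +22)
    "eth_c": -186.25,     # ETOH: -32  (with co2 below)
    "co2_c": -150.0,
    "eth_e": -186.25,
    "co2_e": -150.0,
}

# id -> (stoichiometry, lb, ub, is_exchange, is_biomass, thermo_active)
_REACTIONS = {
    "EX_glc": ({"glc_e": -1.0}, -10.0, 1000.0, True, False, False),
    "EX_eth": ({"eth_e": -1.0}, 0.0, 1000.0, True, False, False),
    "EX_co2": ({"co2_e": -1.0}, 0.0, 1000.0, True, False, False),
    "EX_h2o": ({"h2o_e": -1.0}, -1000.0, 1000.0, True, False, False),
    "PTS": ({"glc_e": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0},
            -1000.0, 1000.0, False, False, True),
    "PGI": ({"g6p_c": -1.0, "f6p_c": 1.0}, -1000.0, 1000.0, False, False, True),
    "PFK": ({"f6p_c": -1.0, "atp_c": -1.0, "fdp_c": 1.0, "adp_c": 1.0},
            -1000.0, 1000.0, False, False, True),
    "FBP": ({"fdp_c": -1.0, "h2o_c": -1.0, "f6p_c": 1.0, "pi_c": 1.0},
            -1000.0, 1000.0, False, False, True),
    "GLY": ({"fdp_c": -1.0, "adp_c": -4.0, "pi_c": -2.0, "nad_c": -2.0,
             "pyr_c": 2.0, "atp_c": 4.0, "nadh_c": 2.0, "h2o_c": 2.0},
            -1000.0, 1000.0, False, False, True),
    "B1": ({"pyr_c": -1.0, "pi_c": -1.0, "adp_c": -1.0,
            "acm_c": 1.0, "atp_c": 1.0, "h2o_c": 1.0},
           -1000.0, 1000.0, False, False, True),
    "B2": ({"acm_c": -1.0, "pyr_c": 1.0}, -1000.0, 0.0, False, False, True),
    "ETOH": ({"acm_c": -1.0, "nadh_c": -1.0,
              "eth_c": 1.0, "co2_c": 1.0, "nad_c": 1.0},
             -1000.0, 1000.0, False, False, True),
    "ADK": ({"adp_c": -2.0, "atp_c": 1.0, "amp_c": 1.0},
            -1000.0, 1000.0, False, False, True),
    "ATPM": ({"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0},
             0.0, 1000.0, False, False, True),
    "ETHt": ({"eth_c": -1.0, "eth_e": 1.0}, -1000.0, 1000.0, False, False, True),
    "CO2t": ({"co2_c": -1.0, "co2_e": 1.0}, -1000.0, 1000.0, False, False, True),
    "H2Ot": ({"h2o_c": -1.0, "h2o_e": 1.0}, -1000.0, 1000.0, False, False, False),
    "BIOMASS": ({"acm_c": -1.0, "atp_c": -30.0, "h2o_c": -30.0, "nadh_c": -1.0,
                 "adp_c": 30.0, "pi_c": 30.0, "nad_c": 1.0},
                0.0, 1000.0, False, True, False),
}

# measured concentrations, mol/L (consistent with the intended I=0.25 optimum)
_METABOLOMICS = {
    "g6p_c": 1.0e-3,
    "f6p_c": 2.5e-4,
    "fdp_c": 2.0e-3,
    "pyr_c": 1.5e-2,
    "atp_c": 9.6e-3,
    "adp_c": 5.6e-4,
    "amp_c": 2.8e-4,
    "eth_c": 1.0e-3,
}

# GSM -> MFA mapping; B2 is defined opposite to the MFA convention, and the
# net hexose-phosphate phosphorylation flux sums PFK and -FBP.
_MAPPING = [
    ("PTS", "R_upt", 1),
    ("PGI", "R_pgi", 1),
    ("PFK", "R_fdp", 1),
    ("FBP", "R_fdp", -1),
    ("GLY", "R_gly", 1),
    ("B1", "R_pyr_acm", 1),
    ("B2", "R_pyr_acm", -1),
    ("ETOH", "R_etoh", 1),
    ("BIOMASS", "R_biomass", 1),
    ("ATPM", "R_atpm", 1),
]


def _reference_fluxes(uptake: float) -> Dict[str, float]:
    """Analytic optimum of the thermodynamically constrained model at
    I = 0.25 M (the efficient branch active): the MFA-side reference."""
    mu = 2.0 * uptake / 15.0           # biomass flux, 30-ATP stoichiometry
    return {
        "R_upt": uptake,
        "R_pgi": uptake,
        "R_fdp": uptake,
        "R_gly": uptake,
        "R_pyr_acm": 2.0 * uptake,
        "R_etoh": 2.0 * uptake - mu,
        "R_biomass": mu,
        "R_atpm": 0.0,
    }


def generate_toy_model(seed: int = 42, uptake: float = 10.0) -> ToyFixture:
    """Build the toy fixture; byte-identical outputs for a fixed seed.

    The seed jitters formation energies by up to ±0.05 kJ/mol and measured
    concentrations by ±5%; network topology, bounds and formulas are fixed.
    """
    rng = np.random.default_rng(seed)

    compartments = {
        "c": Compartment("c", pH=7.0, ionic_strength=0.25, label="cytosol"),
        "e": Compartment("e", pH=7.0, ionic_strength=0.25, label="extracellular"),
    }
    species = {
        sid: Species(sid, name=name, compartment=comp, formula=parse_formula(f))
        for sid, (name, comp, f, _z) in _SPECIES.items()
    }
    reactions = {
        rid: Reaction(rid, stoichiometry=dict(st), lower_bound=lb, upper_bound=ub,
                      is_exchange=ex, is_biomass=bm, thermo_active=th)
        for rid, (st, lb, ub, ex, bm, th) in _REACTIONS.items()
    }
    model = MetabolicModel(
        compartments=compartments, species=species, reactions=reactions,
        objective_reaction="BIOMASS", id=f"toy_seed{seed}",
    )

    # every non-pseudo reaction must balance elementally
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange or rxn.is_biomass:
            continue
        imbalance = elemental_imbalance(model, rid)
        assert not imbalance, f"fixture bug: {rid} unbalanced {imbalance}"

    # back out reference formation energies from the transformed targets
    jitter = {sid: float(rng.uniform(-0.05, 0.05)) for sid in sorted(_SPECIES)}
    thermo: Dict[str, SpeciesThermoRecord] = {}
    for sid, (name, comp, formula_s, charge) in _SPECIES.items():
        n_h = parse_formula(formula_s).get("H", 0)
        gprime = _GPRIME[sid] + jitter[sid]
        dfg0 = gprime - n_h * R_KJ * REFERENCE_T_K * LN10 * REFERENCE_PH
        thermo[sid] = SpeciesThermoRecord(
            species_id=sid, dfg0_ref=round(dfg0, 6), charge=charge, n_hydrogen=n_h
        )

    conc_jitter = {sid: float(rng.uniform(0.95, 1.05)) for sid in sorted(_METABOLOMICS)}
    metabolomics = pd.DataFrame(
        {
            "species_id": sorted(_METABOLOMICS),
            "concentration_M": [
                round(_METABOLOMICS[s] * conc_jitter[s], 10)
                for s in sorted(_METABOLOMICS)
            ],
        }
    )

    ref = _reference_fluxes(uptake)
    reference_fluxes = pd.DataFrame(
        {
            "mfa_id": list(ref),
            "value": [round(x, 6) for x in ref.values()],
            "direction": ["+" if x > 1e-9 else "0" for x in ref.values()],
        }
    )
    mapping = pd.DataFrame(_MAPPING, columns=["gsm_id", "mfa_id", "sign"])

    mu_thermo = 2.0 * uptake / 15.0
    manifest = {
        "seed": seed,
        "uptake": uptake,
        "n_compartments": len(compartments),
        "n_species": len(species),
        "n_reactions": len(reactions),
        "objective_reaction": "BIOMASS",
        "uptake_exchange": "EX_glc",
        "covered_reactions": sorted(
            rid for rid, r in reactions.items() if r.thermo_active
        ),
        "intended_active": sorted([
            "EX_glc", "EX_eth", "EX_co2", "PTS", "PGI", "PFK", "GLY",
            "B1", "ETOH", "ETHt", "CO2t", "BIOMASS",
        ]),
        # analytic optima (flux units), exact for every seed
        "fba_objective": 2.0 * uptake,
        "tfa_objective_I025": mu_thermo,
        "tfa_objective_I0": uptake / 15.0,
        "n_measured": len(_METABOLOMICS),
    }

    return ToyFixture(
        model=model, thermo=thermo, metabolomics=metabolomics,
        reference_fluxes=reference_fluxes, mapping=mapping,
        side_compounds=list(SIDE_COMPOUNDS), manifest=manifest,
    )


def write_fixture(fixture: ToyFixture, directory) -> None:
    """Write the complete fixture as the native tabular dialect plus the
    auxiliary tables; deterministic, text-only output."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_model(fixture.model, directory)
    write_thermo_table(fixture.thermo, directory / "thermo.tsv")
    fixture.metabolomics.to_csv(directory / "metabolomics.tsv", sep="\t", index=False)
    fixture.reference_fluxes.to_csv(directory / "refflux.tsv", sep="\t", index=False)
    fixture.mapping.to_csv(directory / "mapping.tsv", sep="\t", index=False)
    (directory / "side_compounds.txt").write_text(
        "\n".join(fixture.side_compounds) + "\n"
    )
    (directory / "manifest.json").write_text(
        json.dumps(fixture.manifest, indent=2, sort_keys=True) + "\n"
    )
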