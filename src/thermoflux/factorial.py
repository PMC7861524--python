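"""The 2^6 full-factorial design over physicochemical and metabolic factors.

Six binary factors are varied: temperature (25/37 degC), ionic strength
(0/0.25 M), salinity (0 or the value implied by I = 0.25 M and a bacterial
buoyant density of 1.11 kg/L), the A-parameter mode (temperature-only or
temperature/salinity), the activity-correction method (extended
Debye-Hueckel or Davies) and the metabolite-concentration constraint mode
(default cofactors or experimental data).  Runs are numbered 1..64 with the
temperature bit varying fastest, then I, S, A-mode, method and finally the
concentration mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import MetabolicModel, SpeciesThermoRecord
from .physchem import (
    PhysChemConditions,
    reaction_transformed_dg0,
    salinity_from_ionic_strength,
    transform_all,
)
from .tfa import (
    NO_GROWTH_THRESHOLD,
    TFASolution,
    apply_concentration_constraints,
    build_tfa_problem,
    solve_tfa,
)

logger = logging.getLogger(__name__)

# factor levels (bit 0 -> first entry, bit 1 -> second)
TEMPERATURE_LEVELS = (25.0, 37.0)  # degC
IONIC_STRENGTH_LEVELS = (0.0, 0.25)  # mol/L
A_MODE_LEVELS = ("temperature", "temperature_salinity")
METHOD_LEVELS = ("debye_huckel", "davies")
MET_LEVELS = ("default_cofactors", "experimental")
BUOYANT_DENSITY = 1.11  # kg/L, bacterial cells

#: factor order, fastest-varying first (fixes the run numbering)
FACTOR_ORDER = ("t", "I", "S", "a_mode", "method", "met")


def salinity_level_value() -> float:
    """The S = 1 level: salinity implied by I = 0.25 M at the bacterial
    buoyant density; computed from the seawater relation, not hard-coded."""
    return salinity_from_ionic_strength(IONIC_STRENGTH_LEVELS[1], BUOYANT_DENSITY)


@dataclass(frozen=True)
class FactorLevels:
    """One corner of the 2^6 design, as six bits."""

    t: int
    I: int
    S: int
    a_mode: int
    method: int
    met: int

    def bits(self) -> Tuple[int, ...]:
        return (self.t, self.I, self.S, self.a_mode, self.method, self.met)

    def run_number(self) -> int:
        return 1 + sum(bit << k for k, bit in enumerate(self.bits()))

    def conditions(self) -> PhysChemConditions:
        return PhysChemConditions(
            temperature_c=TEMPERATURE_LEVELS[self.t],
            ionic_strength=IONIC_STRENGTH_LEVELS[self.I],
            salinity=salinity_level_value() if self.S else 0.0,
            adjustment_method=METHOD_LEVELS[self.method],
            a_mode=A_MODE_LEVELS[self.a_mode],
        )

    @property
    def met_mode(self) -> str:
        return MET_LEVELS[self.met]


def enumerate_design() -> List[FactorLevels]:
    """The 64 runs in order; run r encodes bits of r-1, temperature fastest."""
    runs = []
    for idx in range(64):
        bits = [(idx >> k) & 1 for k in range(6)]
        runs.append(FactorLevels(*bits))
    return runs


@dataclass
class TestResult:
    """Outcome of one factorial run."""

    run_number: int
    levels: FactorLevels
    solution: TFASolution

    @property
    def success(self) -> bool:
        return (
            self.solution.status == "optimal"
            and self.solution.objective_value > NO_GROWTH_THRESHOLD
        )


def run_design(
    model: MetabolicModel,
    thermo: Dict[str, SpeciesThermoRecord],
    metabolomics,
    uptake: float,
    uptake_reaction: Optional[str] = None,
) -> List[TestResult]:
    """Execute all 64 runs: build conditions from the levels, transform the
    formation energies, assemble and solve the TFA MILP.  Solver failures in
    individual runs are recorded as unsuccessful and never abort the sweep.
    """
    compartments_by_species = {
        sid: model.compartments[sp.compartment]
        for sid, sp in model.species.items()
        if sp.compartment
    }
    results: List[TestResult] = []
    for levels in enumerate_design():
        try:
            cond = levels.conditions()
            energies = transform_all(thermo, compartments_by_species, cond)
            records = {
                rid: reaction_transformed_dg0(rxn, energies, cond)
                for rid, rxn in model.reactions.items()
            }
            constraints = apply_concentration_constraints(
                metabolomics, levels.met_mode, model=model
            )
            problem = build_tfa_problem(
                model, records, cond, constraints,
                uptake_rate=uptake, uptake_reaction=uptake_reaction,
            )
            solution = solve_tfa(problem)
        except Exception:  # noqa: BLE001 - a failed run must not kill the sweep
            logger.exception("run %d failed", levels.run_number())
            solution = TFASolution(status="infeasible")
        results.append(
            TestResult(run_number=levels.run_number(), levels=levels,
                       solution=solution)
        )
    return results


# ---------------------------------------------------------------------------
# non-redundant solution classes
# ---------------------------------------------------------------------------

@dataclass
class SolutionClass:
    """A set of runs whose solution vectors agree within tolerance."""

    representative: int  # run number
    members: List[int] = field(default_factory=list)
    level: str = "flux"  # "flux" | "concentration"


def _solution_vector(
    result: TestResult, level: str, subset: Optional[Sequence[str]]
) -> np.ndarray:
    source = (
        result.solution.fluxes
        if level == "flux"
        else result.solution.ln_concentrations
    )
    keys = sorted(source) if subset is None else list(subset)
    return np.array([source.get(k, 0.0) for k in keys])


def group_nonredundant(
    results: Sequence[TestResult],
    tolerance: float = 1e-6,
    level: str = "flux",
    subset: Optional[Sequence[str]] = None,
) -> List[SolutionClass]:
    """Partition successful runs into equivalence classes by single linkage:
    two solutions are directly equivalent when their maximum absolute
    coordinate difference is at most ``tolerance``, and classes are the
    connected components of that relation (hence independent of input
    order).  ``subset`` restricts the compared coordinates, which can merge
    classes but never split them."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ok = [r for r in results if r.success]
    if not ok:
        return []
    vectors = [_solution_vector(r, level, subset) for r in ok]
    n = len(ok)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(vectors[i] - vectors[j])) <= tolerance:
                parent[find(i)] = find(j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    classes = []
    for members in groups.values():
        runs = sorted(ok[i].run_number for i in members)
        classes.append(SolutionClass(representative=runs[0], members=runs,
                                     level=level))
    classes.sort(key=lambda c: c.representative)
    return classes


def design_summary(
    results: Sequence[TestResult],
    flux_classes: Sequence[SolutionClass],
    conc_classes: Sequence[SolutionClass],
) -> pd.DataFrame:
    """Tabular overview: run number, factor bits, success, objective and the
    flux/concentration class each successful run belongs to."""
    flux_of = {run: c.representative for c in flux_classes for run in c.members}
    conc_of = {run: c.representative for c in conc_classes for run in c.members}
    rows = []
    for r in results:
        rows.append(
            {
                "run": r.run_number,
                **dict(zip(FACTOR_ORDER, r.levels.bits())),
                "success": r.success,
                "objective": r.solution.objective_value,
                "flux_class": flux_of.get(r.run_number, pd.NA),
                "conc_class": conc_of.get(r.run_number, pd.NA),
            }
        )
    return pd.DataFrame(rows)
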