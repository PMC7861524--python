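"""Flux balance analysis and thermodynamics-constrained FBA (MILP).

The MILP couples every thermodynamically covered reaction's net flux to the
sign of its transformed reaction Gibbs energy through a pair of direction
binaries (big-M indicator constraints):

    v_i = v_i+ - v_i-,   0 <= v_i+/- <= v_max z_i+/-,   z_i+ + z_i- <= 1
    drG'_i = drG'0_i + R T sum_j s_ij ln c_j     (protons/water excluded)
    drG'_i - K + (K + eps) z_i+ <= 0
   -drG'_i - K + (K + eps) z_i- <= 0

so forward flux requires a driving force of at least ``eps`` and backward
flux the opposite.  Metabolite log-concentrations are free variables inside
configurable bounds; measured metabolites can be pinned to 90-110% of their
measured values.  The MILP is solved through optlang's GLPK interface,
which is deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from optlang.glpk_interface import Constraint, Model as OptModel, Objective, Variable

from .model import MetabolicModel, Reaction
from .physchem import (
    PhysChemConditions,
    ThermoReactionRecord,
    is_proton,
    is_water,
)

logger = logging.getLogger(__name__)

#: Default metabolite concentration window, mol/L (customary TFA range).
DEFAULT_CONC_LB = 1e-5
DEFAULT_CONC_UB = 0.02

#: Default cofactor concentrations (mol/L) pinned in ``default_cofactors``
#: mode; configurable, shipped as a conventional adenylate set.
DEFAULT_COFACTOR_CONCENTRATIONS: Dict[str, float] = {
    "atp_c": 9.6e-3,
    "adp_c": 5.6e-4,
    "amp_c": 2.8e-4,
}

#: Relative half-width of the measured-concentration band (90-110%).
MEASURED_BAND = 0.10

DEFAULT_BIG_M = 1000.0  # kJ/mol
DEFAULT_EPSILON = 1e-4  # kJ/mol, minimum driving force of an active reaction
DEFAULT_V_MAX = 1000.0  # mmol gDCW^-1 h^-1
NO_GROWTH_THRESHOLD = 1e-6  # h^-1

FLUX_TOL = 1e-6


class TFAError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# concentration constraints
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationConstraintSet:
    """Per-species concentration bounds (mol/L) overriding the defaults."""

    mode: str  # "default_cofactors" | "experimental"
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def ln_bounds(self, species_id: str) -> Tuple[float, float]:
        lo, hi = self.bounds.get(species_id, (DEFAULT_CONC_LB, DEFAULT_CONC_UB))
        return math.log(lo), math.log(hi)


def apply_concentration_constraints(
    dataset,
    mode: str,
    model: Optional[MetabolicModel] = None,
    cofactor_concentrations: Optional[Mapping[str, float]] = None,
    band: float = MEASURED_BAND,
) -> ConcentrationConstraintSet:
    """Build the concentration constraint set for a TFA run.

    ``experimental`` pins every measured species to (1-band, 1+band) times
    its measured concentration; ``default_cofactors`` pins only the
    configured cofactor set to its default values with the same band.
    Species absent from the model are skipped with a logged warning.
    """
    if mode not in ("default_cofactors", "experimental"):
        raise TFAError(f"unknown concentration mode {mode!r}")
    bounds: Dict[str, Tuple[float, float]] = {}
    if mode == "experimental":
        if dataset is None:
            raise TFAError("experimental mode requires a metabolomics dataset")
        for _, row in dataset.iterrows():
            sid, conc = row["species_id"], float(row["concentration_M"])
            if conc <= 0:
                raise TFAError(f"non-positive concentration for {sid}")
            if model is not None and sid not in model.species:
                logger.warning("metabolomics species %s not in model; skipped", sid)
                continue
            bounds[sid] = ((1.0 - band) * conc, (1.0 + band) * conc)
    else:
        cofactors = dict(
            cofactor_concentrations
            if cofactor_concentrations is not None
            else DEFAULT_COFACTOR_CONCENTRATIONS
        )
        for sid, conc in cofactors.items():
            if model is not None and sid not in model.species:
                logger.warning("cofactor %s not in model; skipped", sid)
                continue
            bounds[sid] = ((1.0 - band) * conc, (1.0 + band) * conc)
    return ConcentrationConstraintSet(mode=mode, bounds=bounds)


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

@dataclass
class TFASolution:
    """Solver output: fluxes, log-concentrations, reaction energies and the
    direction binaries of the optimum."""

    status: str  # "optimal" | "infeasible" | "no_growth"
    fluxes: Dict[str, float] = field(default_factory=dict)
    ln_concentrations: Dict[str, float] = field(default_factory=dict)
    drg_prime: Dict[str, float] = field(default_factory=dict)
    binaries: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    objective_value: float = 0.0
    slacks: Dict[str, float] = field(default_factory=dict)

    def slack_report(self) -> List[Tuple[str, float]]:
        """Per-reaction relaxation slacks, sorted descending by magnitude."""
        return sorted(self.slacks.items(), key=lambda kv: -abs(kv[1]))


# ---------------------------------------------------------------------------
# plain FBA
# ---------------------------------------------------------------------------

def _fix_uptake(model: MetabolicModel, uptake_rate: float,
                uptake_reaction: Optional[str]) -> MetabolicModel:
    model = model.copy()
    rid = uptake_reaction or model.find_uptake_exchange().id
    rxn = model.reactions[rid]
    rxn.lower_bound = -abs(uptake_rate)
    rxn.upper_bound = -abs(uptake_rate)
    return model


def _add_mass_balance(opt: OptModel, model: MetabolicModel,
                      v: Mapping[str, Variable]) -> None:
    terms: Dict[str, list] = {sid: [] for sid in model.species}
    for rid, rxn in model.reactions.items():
        for sid, coeff in rxn.stoichiometry.items():
            terms[sid].append(coeff * v[rid])
    constraints = []
    for sid, parts in terms.items():
        if parts:
            constraints.append(Constraint(sum(parts), lb=0, ub=0, name=f"mb_{sid}"))
    opt.add(constraints)


def solve_fba(
    model: MetabolicModel,
    uptake_rate: Optional[float] = None,
    uptake_reaction: Optional[str] = None,
) -> TFASolution:
    """LP: maximize the objective flux at steady state, optionally with the
    substrate exchange fixed to ``-uptake_rate``.  No thermodynamics."""
    if uptake_rate is not None:
        model = _fix_uptake(model, uptake_rate, uptake_reaction)
    opt = OptModel(name="fba")
    v = {
        rid: Variable(f"v_{rid}", lb=rxn.lower_bound, ub=rxn.upper_bound)
        for rid, rxn in model.reactions.items()
    }
    opt.add(list(v.values()))
    _add_mass_balance(opt, model, v)
    opt.objective = Objective(1.0 * v[model.objective_reaction], direction="max")
    status = opt.optimize()
    if status != "optimal":
        return TFASolution(status="infeasible")
    fluxes = {rid: var.primal for rid, var in v.items()}
    obj = opt.objective.value
    status = "optimal" if obj > NO_GROWTH_THRESHOLD else "no_growth"
    return TFASolution(status=status, fluxes=fluxes, objective_value=obj)


# ---------------------------------------------------------------------------
# TFA problem
# ---------------------------------------------------------------------------

@dataclass
class TFAProblem:
    """A built thermodynamically constrained MILP ready to solve."""

    model: MetabolicModel
    reaction_records: Dict[str, ThermoReactionRecord]
    conditions: PhysChemConditions
    constraints: ConcentrationConstraintSet
    opt: OptModel
    v: Dict[str, Variable]
    lnc: Dict[str, Variable]
    drg: Dict[str, Variable]
    z_plus: Dict[str, Variable]
    z_minus: Dict[str, Variable]
    slack: Dict[str, Variable]
    covered: List[str]
    K: float
    epsilon: float
    v_max: float

    @property
    def objective_reaction(self) -> str:
        return self.model.objective_reaction


def build_tfa_problem(
    model: MetabolicModel,
    reaction_records: Mapping[str, ThermoReactionRecord],
    conditions: PhysChemConditions,
    constraints: Optional[ConcentrationConstraintSet] = None,
    uptake_rate: Optional[float] = None,
    uptake_reaction: Optional[str] = None,
    K: float = DEFAULT_BIG_M,
    epsilon: float = DEFAULT_EPSILON,
    v_max: float = DEFAULT_V_MAX,
    with_slacks: bool = False,
    slack_cap: float = 1e4,
) -> TFAProblem:
    """Assemble the TFA MILP.

    ``reaction_records`` must all carry the fingerprint of ``conditions``;
    a mismatch means the energies were transformed at different conditions
    and is an error.  With ``with_slacks`` each covered reaction gains a
    non-negative relaxation slack widening its drG'0 symmetrically (used by
    :func:`relax_dg_bounds`).
    """
    if K <= 0 or epsilon < 0:
        raise TFAError("K must be positive and epsilon non-negative")
    if constraints is None:
        constraints = ConcentrationConstraintSet(mode="default_cofactors")
    fp = conditions.fingerprint()
    for rec in reaction_records.values():
        if rec.covered and rec.fingerprint != fp:
            raise TFAError(
                f"thermo record {rec.reaction_id} computed at different conditions"
            )
    if uptake_rate is not None:
        model = _fix_uptake(model, uptake_rate, uptake_reaction)

    RT = conditions.RT
    opt = OptModel(name="tfa")
    v: Dict[str, Variable] = {}
    for rid, rxn in model.reactions.items():
        v[rid] = Variable(f"v_{rid}", lb=rxn.lower_bound, ub=rxn.upper_bound)
    opt.add(list(v.values()))
    _add_mass_balance(opt, model, v)

    covered = [
        rid
        for rid, rxn in model.reactions.items()
        if rid in reaction_records and reaction_records[rid].covered
    ]

    lnc: Dict[str, Variable] = {}
    for sid in model.species:
        if is_proton(sid) or is_water(sid):
            continue
        lo, hi = constraints.ln_bounds(sid)
        if not lo < hi:
            raise TFAError(f"species {sid}: empty concentration window")
        lnc[sid] = Variable(f"lnc_{sid}", lb=lo, ub=hi)
    opt.add(list(lnc.values()))

    drg: Dict[str, Variable] = {}
    z_plus: Dict[str, Variable] = {}
    z_minus: Dict[str, Variable] = {}
    slack: Dict[str, Variable] = {}
    new = []
    for rid in covered:
        rxn = model.reactions[rid]
        rec = reaction_records[rid]
        dv = Variable(f"drg_{rid}", lb=-1e6, ub=1e6)
        zp = Variable(f"zp_{rid}", type="binary")
        zn = Variable(f"zn_{rid}", type="binary")
        vp = Variable(f"vp_{rid}", lb=0, ub=v_max)
        vn = Variable(f"vn_{rid}", lb=0, ub=v_max)
        drg[rid], z_plus[rid], z_minus[rid] = dv, zp, zn
        new.extend([dv, zp, zn, vp, vn])
        # flux split and indicator coupling
        new.append(Constraint(v[rid] - vp + vn, lb=0, ub=0, name=f"split_{rid}"))
        new.append(Constraint(vp - v_max * zp, ub=0, name=f"fwd_cap_{rid}"))
        new.append(Constraint(vn - v_max * zn, ub=0, name=f"rev_cap_{rid}"))
        new.append(Constraint(zp + zn, ub=1, name=f"onedir_{rid}"))
        # drG' definition: drg - RT * sum s_ij lnc_j (- e) = drg0
        conc_terms = [
            coeff * lnc[sid]
            for sid, coeff in rxn.stoichiometry.items()
            if sid in lnc
        ]
        expr = dv - RT * sum(conc_terms) if conc_terms else 1.0 * dv
        if with_slacks:
            e = Variable(f"e_{rid}", lb=-slack_cap, ub=slack_cap)
            s = Variable(f"slk_{rid}", lb=0, ub=slack_cap)
            slack[rid] = s
            new.extend([e, s])
            new.append(Constraint(e - s, ub=0, name=f"slkp_{rid}"))
            new.append(Constraint(-e - s, ub=0, name=f"slkn_{rid}"))
            expr = expr - e
        new.append(
            Constraint(expr, lb=rec.drg0_transformed, ub=rec.drg0_transformed,
                       name=f"drgdef_{rid}")
        )
        # direction indicators
        new.append(
            Constraint(dv + (K + epsilon) * zp, ub=K, name=f"ind_fwd_{rid}")
        )
        new.append(
            Constraint(-dv + (K + epsilon) * zn, ub=K, name=f"ind_rev_{rid}")
        )
    opt.add(new)
    opt.objective = Objective(1.0 * v[model.objective_reaction], direction="max")
    return TFAProblem(
        model=model, reaction_records=dict(reaction_records),
        conditions=conditions, constraints=constraints, opt=opt, v=v, lnc=lnc,
        drg=drg, z_plus=z_plus, z_minus=z_minus, slack=slack, covered=covered,
        K=K, epsilon=epsilon, v_max=v_max,
    )


def _extract_solution(problem: TFAProblem) -> TFASolution:
    fluxes = {rid: var.primal for rid, var in problem.v.items()}
    lnc = {sid: var.primal for sid, var in problem.lnc.items()}
    drg = {rid: var.primal for rid, var in problem.drg.items()}
    binaries = {
        rid: (int(round(problem.z_plus[rid].primal)),
              int(round(problem.z_minus[rid].primal)))
        for rid in problem.covered
    }
    slacks = {rid: var.primal for rid, var in problem.slack.items()}
    obj = problem.v[problem.objective_reaction].primal
    status = "optimal" if obj > NO_GROWTH_THRESHOLD else "no_growth"
    return TFASolution(
        status=status, fluxes=fluxes, ln_concentrations=lnc, drg_prime=drg,
        binaries=binaries, objective_value=obj, slacks=slacks,
    )


def solve_tfa(problem: TFAProblem) -> TFASolution:
    """Solve the MILP, maximizing the objective flux."""
    status = problem.opt.optimize()
    if status != "optimal":
        return TFASolution(status="infeasible")
    return _extract_solution(problem)


def relax_dg_bounds(
    problem: TFAProblem,
    required_growth: float,
    slack_cap: float = 1e4,
) -> TFASolution:
    """Minimal symmetric widening of reaction drG'0 values restoring
    feasibility at ``required_growth``.

    Rebuilds the problem with per-reaction slack variables, requires the
    objective flux to reach the requested growth and minimizes the total
    slack.  Returns the solution with per-reaction slacks (all zero iff the
    unrelaxed problem was already feasible at that growth)."""
    relaxed = build_tfa_problem(
        problem.model, problem.reaction_records, problem.conditions,
        problem.constraints, K=problem.K, epsilon=problem.epsilon,
        v_max=problem.v_max, with_slacks=True, slack_cap=slack_cap,
    )
    growth = Constraint(
        1.0 * relaxed.v[relaxed.objective_reaction], lb=required_growth,
        name="required_growth",
    )
    relaxed.opt.add([growth])
    relaxed.opt.objective = Objective(
        sum(1.0 * s for s in relaxed.slack.values()), direction="min"
    )
    status = relaxed.opt.optimize()
    if status != "optimal":
        return TFASolution(status="infeasible")
    sol = _extract_solution(relaxed)
    sol.objective_value = relaxed.v[relaxed.objective_reaction].primal
    sol.status = "optimal"
    # clean numerical dust off slacks
    sol.slacks = {rid: (0.0 if abs(s) < 1e-9 else s) for rid, s in sol.slacks.items()}
    return sol


def write_solution(problem: TFAProblem, solution: TFASolution, directory) -> None:
    """Write a solved problem as two TSVs: per-reaction fluxes/energies/
    binaries/slacks and per-species log-concentrations with their bounds."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "reactions_solution.tsv", "w") as fh:
        fh.write("reaction_id\tflux\tdrg0\tdrg_prime\tz_plus\tz_minus\tslack\n")
        for rid in problem.model.reactions:
            rec = problem.reaction_records.get(rid)
            drg0 = rec.drg0_transformed if rec is not None and rec.covered else ""
            drg = solution.drg_prime.get(rid, "")
            zp, zn = solution.binaries.get(rid, ("", ""))
            slack = solution.slacks.get(rid, 0.0)
            fh.write(
                f"{rid}\t{solution.fluxes.get(rid, 0.0)!r}\t{drg0!r}\t{drg!r}\t"
                f"{zp}\t{zn}\t{slack!r}\n"
            )
    with open(directory / "species_solution.tsv", "w") as fh:
        fh.write("species_id\tln_concentration\tln_lb\tln_ub\n")
        for sid, var in problem.lnc.items():
            lnc = solution.ln_concentrations.get(sid, "")
            fh.write(f"{sid}\t{lnc!r}\t{var.lb!r}\t{var.ub!r}\n")


# ---------------------------------------------------------------------------
# consistency checking and the enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_thermo_consistency(
    problem: TFAProblem,
    solution: TFASolution,
    tol: float = FLUX_TOL,
    numeric_slack: float = 1e-6,
) -> ConsistencyReport:
    """Check the flux-force sign rule on a solution: every covered reaction
    carrying flux must have a drG' of the opposite sign and magnitude at
    least ``epsilon``.  Zero-flux reactions are unconstrained."""
    report = ConsistencyReport()
    if solution.status != "optimal":
        report.violations.append(f"solution status is {solution.status}")
        return report
    for rid in problem.covered:
        vflux = solution.fluxes.get(rid, 0.0)
        if abs(vflux) <= tol:
            continue
        dg = solution.drg_prime.get(rid)
        if dg is None:
            report.violations.append(f"{rid}: active but no drG' value")
            continue
        if vflux > 0 and not dg <= -(problem.epsilon - numeric_slack):
            report.violations.append(
                f"{rid}: forward flux {vflux:.6g} with drG' {dg:.6g}"
            )
        elif vflux < 0 and not dg >= (problem.epsilon - numeric_slack):
            report.violations.append(
                f"{rid}: backward flux {vflux:.6g} with drG' {dg:.6g}"
            )
    return report


def enumerate_direction_optimum(
    problem: TFAProblem,
    max_patterns: int = 1 << 20,
) -> Tuple[float, Optional[Tuple[int, ...]]]:
    """Exhaustive oracle: best objective over all 2^n forward/backward
    direction patterns of the covered reactions, each solved with the
    binaries fixed.

    Zero flux remains admissible inside either direction, so on networks
    where every covered reaction's drG' can be pushed past +eps or -eps the
    enumeration optimum equals the MILP optimum.  Intended for small
    fixtures; refuses to enumerate more than ``max_patterns`` patterns.
    """
    n = len(problem.covered)
    if 2**n > max_patterns:
        raise TFAError(f"{n} covered reactions: too many patterns to enumerate")
    best = -math.inf
    best_pattern: Optional[Tuple[int, ...]] = None
    try:
        for pattern in itertools.product((1, 0), repeat=n):
            for rid, bit in zip(problem.covered, pattern):
                problem.z_plus[rid].set_bounds(bit, bit)
                problem.z_minus[rid].set_bounds(1 - bit, 1 - bit)
            if problem.opt.optimize() == "optimal":
                obj = problem.v[problem.objective_reaction].primal
                if obj > best + 1e-12:
                    best, best_pattern = obj, pattern
    finally:
        for rid in problem.covered:
            problem.z_plus[rid].set_bounds(0, 1)
            problem.z_minus[rid].set_bounds(0, 1)
    return best, best_pattern
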