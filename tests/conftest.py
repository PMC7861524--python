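import pytest
from hypothesis import settings

from thermoflux import factorial as fm
from thermoflux.fixtures import generate_toy_model
from thermoflux.physchem import PhysChemConditions, reaction_records_for_model
from thermoflux.tfa import (
    apply_concentration_constraints,
    build_tfa_problem,
    solve_tfa,
)

settings.register_profile("package", derandomize=True, deadline=None)
settings.load_profile("package")


@pytest.fixture(scope="session")
def toy():
    return generate_toy_model(seed=42)


def build_toy_problem(toy, ionic_strength=0.25, met_mode="default_cofactors",
                      method="debye_huckel", temperature_c=25.0,
                      a_mode="temperature", salinity=0.0, uptake=10.0,
                      thermo=None):
    """Assemble the toy TFA problem at the requested conditions."""
    cond = PhysChemConditions(
        temperature_c=temperature_c, ionic_strength=ionic_strength,
        salinity=salinity, adjustment_method=method, a_mode=a_mode,
    )
    records = reaction_records_for_model(toy.model, thermo or toy.thermo, cond)
    constraints = apply_concentration_constraints(
        toy.metabolomics, met_mode, model=toy.model
    )
    return build_tfa_problem(toy.model, records, cond, constraints,
                             uptake_rate=uptake)


@pytest.fixture(scope="session")
def toy_solution(toy):
    """Solved TFA at the reference conditions (25 degC, I = 0.25 M)."""
    problem = build_toy_problem(toy)
    solution = solve_tfa(problem)
    assert solution.status == "optimal"
    return problem, solution


@pytest.fixture(scope="session")
def design_results(toy):
    """The full 64-run factorial sweep on the toy model (solved once)."""
    return fm.run_design(toy.model, toy.thermo, toy.metabolomics,
                         uptake=toy.manifest["uptake"])
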