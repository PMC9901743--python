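"""Shared fixtures and the generic SBML trajectory oracle.

The SBML oracle re-simulates an exported document using nothing but the
document itself: species, parameters, assignment rules and kinetic-law
formulas are read back with libsbml and integrated generically. It shares
no rate-law code with the package, so agreement between the two
trajectories checks the export end to end.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ferrisim import Condition, KineticParameters


@pytest.fixture
def params() -> KineticParameters:
    """The shipped in-vitro parameter set (H=4, turnover off)."""
    return KineticParameters()


@pytest.fixture
def fig2a_condition() -> Condition:
    """Calibration assay condition: 2.32 uM ferritin, H=4, 470 atoms/cage dose."""
    return Condition(FT=2.32e-6, H=4, dose_per_cage=470.0)


def _piecewise(*args):
    # SBML piecewise(v1, c1, v2, c2, ..., otherwise)
    for value, cond in zip(args[0::2], args[1::2]):
        if cond:
            return value
    return args[-1] if len(args) % 2 == 1 else 0.0


def simulate_sbml(xml: str, t_eval: np.ndarray, rtol: float = 1e-8, atol: float = 1e-14):
    """Integrate an SBML document generically; returns (species_ids, states).

    Kinetic laws are in substance/time; concentrations evolve as
    d[conc]/dt = (1/volume) * sum(stoichiometry * law).
    """
    import libsbml
    from scipy.integrate import solve_ivp

    doc = libsbml.readSBMLFromString(xml)
    assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
    m = doc.getModel()
    comp_id = m.getCompartment(0).getId()
    vol = m.getCompartment(0).getSize()
    species = [m.getSpecies(i).getId() for i in range(m.getNumSpecies())]
    y0 = np.array([m.getSpecies(i).getInitialConcentration() for i in range(m.getNumSpecies())])
    consts = {m.getParameter(i).getId(): m.getParameter(i).getValue()
              for i in range(m.getNumParameters())}
    consts[comp_id] = vol

    def compile_formula(ast):
        src = libsbml.formulaToL3String(ast).replace("^", "**").replace("&&", " and ").replace("||", " or ")
        return compile(src, "<sbml>", "eval")

    rules = []
    for i in range(m.getNumRules()):
        r = m.getRule(i)
        if r.isAssignment():
            rules.append((r.getVariable(), compile_formula(r.getMath())))

    reactions = []
    for i in range(m.getNumReactions()):
        rx = m.getReaction(i)
        stoich = np.zeros(len(species))
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[species.index(sr.getSpecies())] -= sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[species.index(sr.getSpecies())] += sr.getStoichiometry()
        reactions.append((stoich, compile_formula(rx.getKineticLaw().getMath())))

    env_fns = {"__builtins__": {}, "piecewise": _piecewise, "exp": math.exp,
               "ln": math.log, "log": math.log, "pow": pow, "sqrt": math.sqrt}

    def rhs(t, y):
        env = dict(consts)
        env.update(zip(species, np.maximum(y, 0.0)))
        for var, code in rules:
            env[var] = eval(code, env_fns, env)
        dy = np.zeros_like(y)
        for stoich, code in reactions:
            dy += stoich * eval(code, env_fns, env)
        return dy / vol

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    assert sol.success, sol.message
    return species, sol.y.T
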