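"""SBML Level 3 export of the ferritin sequestration model.

The exported document is a self-contained submodel ("model brick"): one
compartment (the scenario volume), the four species with their scenario
initial concentrations, every rate-law constant as a named global
parameter, and the reactions with kinetic laws written as explicit MathML
of the model's rate expressions. The mean atoms-per-cage is exported as an
assignment-rule parameter ``apc`` (``core/FT`` guarded for ``FT = 0``), and
the mineralization capacity shut-off is a piecewise term that clamps at
zero once ``apc`` reaches capacity. Kinetic laws are multiplied by the
compartment so they are in substance-per-time as SBML requires, making the
concentration dynamics identical to the package's own ODEs.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .scenarios import Scenario

__all__ = ["export_sbml", "scenario_to_sbml_string"]

_PARAM_NAMES = (
    "ox_kcat", "ox_Km", "ox_n", "H", "rO",
    "red_kdeg",
    "nuc_kcat", "nuc_Ki", "nuc_n", "rN",
    "min_kcat", "min_Km", "min_Ki", "min_n", "min_m", "capacity",
    "ft_ksyn", "ft_kdeg",
)

_OX_LAW = (
    "cytosol * ox_kcat * ((H + rO) / (24 + rO)) * FT"
    " * LIP^ox_n / (ox_Km^ox_n + LIP^ox_n)"
)
_RED_LAW = "cytosol * red_kdeg * DFP"
_NUC_LAW = (
    "cytosol * nuc_kcat * DFP^2 * FT * ((24 - H + rN) / (24 + rN))"
    " * nuc_Ki^nuc_n / (nuc_Ki^nuc_n + core^nuc_n)"
)
_MIN_LAW = (
    "cytosol * min_kcat * core * DFP / (min_Km + DFP)"
    " * min_Ki^min_n / (min_Ki^min_n + core^min_n)"
    " * piecewise((capacity^min_m - apc^min_m) / capacity^min_m, apc < capacity, 0)"
)
_APC_RULE = "piecewise(core / FT, FT > 0, capacity)"


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")
    return value


def _add_species(model, sid: str, conc: float) -> None:
    sp = _check(model.createSpecies(), f"species {sid}")
    sp.setId(sid)
    sp.setCompartment("cytosol")
    sp.setInitialConcentration(conc)
    sp.setHasOnlySubstanceUnits(False)
    sp.setBoundaryCondition(False)
    sp.setConstant(False)


def _parse_math(formula: str):
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise RuntimeError(
            f"cannot parse kinetic formula: {libsbml.getLastParseL3Error()}"
        )
    return ast


def _add_reaction(model, rid: str, reactants: dict, products: dict, law: str) -> None:
    rx = _check(model.createReaction(), f"reaction {rid}")
    rx.setId(rid)
    rx.setReversible(False)
    rx.setFast(False)
    for sid, stoich in reactants.items():
        sr = rx.createReactant()
        sr.setSpecies(sid)
        sr.setStoichiometry(float(stoich))
        sr.setConstant(True)
    for sid, stoich in products.items():
        sr = rx.createProduct()
        sr.setSpecies(sid)
        sr.setStoichiometry(float(stoich))
        sr.setConstant(True)
    kl = rx.createKineticLaw()
    _check(kl.setMath(_parse_math(law)), f"kinetic law of {rid}")


def scenario_to_sbml_document(s: Scenario) -> "libsbml.SBMLDocument":
    """Build the SBML document for a scenario's model and initial state."""
    doc = libsbml.SBMLDocument(3, 1)
    model = _check(doc.createModel(), "model")
    model.setId(s.name.replace("-", "_") or "ferritin_sequestration")
    model.setName("Ferritin iron sequestration kinetics")

    comp = _check(model.createCompartment(), "compartment")
    comp.setId("cytosol")
    comp.setSize(s.volume)
    comp.setSpatialDimensions(3)
    comp.setConstant(True)

    st = s.initial_state()
    _add_species(model, "LIP", st.LIP)
    _add_species(model, "DFP", st.DFP)
    _add_species(model, "core", st.core)
    _add_species(model, "FT", st.FT)

    pdict = s.params.to_dict()
    for name in _PARAM_NAMES:
        par = _check(model.createParameter(), f"parameter {name}")
        par.setId(name)
        par.setValue(float(pdict[name]))
        par.setConstant(True)

    apc = _check(model.createParameter(), "parameter apc")
    apc.setId("apc")
    apc.setConstant(False)
    rule = _check(model.createAssignmentRule(), "apc rule")
    rule.setVariable("apc")
    _check(rule.setMath(_parse_math(_APC_RULE)), "apc rule math")

    _add_reaction(model, "oxidation", {"LIP": 2}, {"DFP": 1}, _OX_LAW)
    _add_reaction(model, "reduction", {"DFP": 1}, {"LIP": 2}, _RED_LAW)
    _add_reaction(model, "nucleation", {"DFP": 2}, {"core": 4}, _NUC_LAW)
    _add_reaction(model, "mineralization", {"DFP": 1}, {"core": 2}, _MIN_LAW)

    if s.params.ft_ksyn > 0 or s.params.ft_kdeg > 0:
        _add_reaction(model, "ft_synthesis", {}, {"FT": 1}, "cytosol * ft_ksyn")
        _add_reaction(model, "ft_degradation", {"FT": 1}, {}, "cytosol * ft_kdeg * FT")
        _add_reaction(
            model, "core_release", {"core": 1}, {"LIP": 1}, "cytosol * ft_kdeg * core"
        )

    doc.checkInternalConsistency()
    n_err = doc.getNumErrors()
    fatal = [
        doc.getError(i).getMessage()
        for i in range(n_err)
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if fatal:
        raise RuntimeError("SBML document is inconsistent: " + "; ".join(fatal))
    return doc


def scenario_to_sbml_string(s: Scenario) -> str:
    return libsbml.writeSBMLToString(scenario_to_sbml_document(s))


def export_sbml(s: Scenario, path: str | Path) -> None:
    """Write the scenario's model as an SBML Level 3 file."""
    Path(path).write_text(scenario_to_sbml_string(s))
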