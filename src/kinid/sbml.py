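"""SBML import/export for ODE-compatible models.

Reads an SBML Level 2/3 document, assembles the ODE system from stoichiometry
times kinetic-law rate expressions, and wraps it as a
:class:`~kinid.models.KineticModel`.  Only constructs that map cleanly onto a
plain ODE system are supported: reactions with kinetic laws, constant /
boundary species as fixed inputs, global and local parameters, and a single
compartment treated as unit volume scaling.  Events, algebraic rules,
assignment rules and delays raise :class:`UnsupportedSBMLError` rather than
being silently approximated.

A minimal writer is provided so fixtures can round-trip through files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import libsbml

from .models import ConfigError, KineticModel

__all__ = ["load_sbml", "write_sbml", "SBMLReaction", "UnsupportedSBMLError"]


class UnsupportedSBMLError(ValueError):
    """The SBML document uses a construct outside the ODE-compatible subset."""


def _compile_formula(formula: str, symbols: list[str]):
    """Compile an SBML infix formula to a float function of named symbols."""
    import sympy

    syms = {s: sympy.Symbol(s) for s in symbols}
    try:
        expr = sympy.sympify(formula.replace("^", "**"), locals=syms)
    except Exception as exc:  # noqa: BLE001 - report the offending formula
        raise UnsupportedSBMLError(f"cannot parse rate law {formula!r}: {exc}") from exc
    free = expr.free_symbols - set(syms.values())
    if free:
        raise UnsupportedSBMLError(
            f"rate law {formula!r} references unknown symbols {sorted(map(str, free))}"
        )
    f = sympy.lambdify([syms[s] for s in symbols], expr, modules="numpy")
    return f


def load_sbml(path, observed: list[str] | None = None) -> KineticModel:
    """Load an SBML file as a kinetic ODE model.

    Parameters
    ----------
    path : file path
    observed : list of species ids to expose through the observation map;
        defaults to all dynamic species.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBML(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ConfigError(f"SBML read error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ConfigError(f"no model in SBML file {path}")

    if sbml_model.getNumEvents() > 0:
        raise UnsupportedSBMLError("SBML events are not supported")
    for i in range(sbml_model.getNumRules()):
        raise UnsupportedSBMLError(
            "SBML rules (assignment/rate/algebraic) are not supported"
        )
    if sbml_model.getNumConstraints() > 0:
        raise UnsupportedSBMLError("SBML constraints are not supported")

    dynamic: list[str] = []
    fixed_species: dict[str, float] = {}
    x0: list[float] = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        value = sp.getInitialConcentration()
        if np.isnan(value):
            value = sp.getInitialAmount()
        if sp.getConstant() or sp.getBoundaryCondition():
            fixed_species[sp.getId()] = value
        else:
            dynamic.append(sp.getId())
            x0.append(value)

    params: dict[str, float] = {}
    for i in range(sbml_model.getNumParameters()):
        pr = sbml_model.getParameter(i)
        if not pr.getConstant():
            raise UnsupportedSBMLError(f"non-constant parameter {pr.getId()!r}")
        params[pr.getId()] = pr.getValue()
    compartments: dict[str, float] = {}
    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        v = c.getSize()
        compartments[c.getId()] = 1.0 if np.isnan(v) else v

    param_names = sorted(params)
    rate_fns = []  # (callable, stoichiometry dict species->coeff)
    symbol_order = dynamic + param_names
    constants = dict(fixed_species)
    constants.update(compartments)

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        kl = rxn.getKineticLaw()
        if kl is None:
            raise UnsupportedSBMLError(f"reaction {rxn.getId()!r} has no kinetic law")
        formula = libsbml.formulaToL3String(kl.getMath())
        local = {}
        for j in range(kl.getNumParameters()):
            lp = kl.getParameter(j)
            local[lp.getId()] = lp.getValue()
        all_syms = symbol_order + sorted(set(constants) | set(local))
        fn = _compile_formula(formula, all_syms)
        const_vals = [dict(constants, **local)[s] for s in all_syms[len(symbol_order):]]
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            sid = ref.getSpecies()
            if sid in dynamic:
                stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            sid = ref.getSpecies()
            if sid in dynamic:
                stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        rate_fns.append((fn, const_vals, stoich))

    if observed is None:
        observed = list(dynamic)
    missing = set(observed) - set(dynamic)
    if missing:
        raise ConfigError(f"observed species not in model: {sorted(missing)}")
    obs_idx = [dynamic.index(s) for s in observed]
    species_index = {s: i for i, s in enumerate(dynamic)}
    theta_true = np.array([params[p] for p in param_names])

    def rhs(x, theta, t):
        dx = np.zeros(len(dynamic))
        args_head = list(x) + list(theta)
        for fn, const_vals, stoich in rate_fns:
            rate = float(fn(*args_head, *const_vals))
            for sid, coeff in stoich.items():
                dx[species_index[sid]] += coeff * rate
        return dx

    def observe(x, theta, t):
        return np.asarray(x)[obs_idx]

    return KineticModel(
        name=sbml_model.getId() or "sbml_model",
        rhs=rhs,
        observe=observe,
        state_names=tuple(dynamic),
        param_names=tuple(param_names),
        observed_names=tuple(observed),
        x0=np.array(x0),
        theta_true=theta_true,
    )


@dataclass
class SBMLReaction:
    """Declarative reaction for the minimal SBML writer."""

    rid: str
    reactants: dict = field(default_factory=dict)  # species -> stoichiometry
    products: dict = field(default_factory=dict)
    formula: str = "0"


def write_sbml(
    path,
    *,
    model_id: str,
    species: dict[str, float],
    parameters: dict[str, float],
    reactions: list[SBMLReaction],
    constant_species: dict[str, float] | None = None,
) -> None:
    """Write a minimal single-compartment SBML Level 3 document."""
    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model_id)
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)

    def add_species(sid, value, constant):
        sp = m.createSpecies()
        sp.setId(sid)
        sp.setCompartment("cell")
        sp.setInitialConcentration(float(value))
        sp.setConstant(constant)
        sp.setBoundaryCondition(constant)
        sp.setHasOnlySubstanceUnits(False)

    for sid, value in species.items():
        add_species(sid, value, False)
    for sid, value in (constant_species or {}).items():
        add_species(sid, value, True)
    for pid, value in parameters.items():
        pr = m.createParameter()
        pr.setId(pid)
        pr.setValue(float(value))
        pr.setConstant(True)
    for rx in reactions:
        r = m.createReaction()
        r.setId(rx.rid)
        r.setReversible(False)
        for sid, coeff in rx.reactants.items():
            ref = r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for sid, coeff in rx.products.items():
            ref = r.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        kl = r.createKineticLaw()
        math = libsbml.parseL3Formula(rx.formula)
        if math is None:
            raise ConfigError(f"cannot parse formula {rx.formula!r}")
        kl.setMath(math)
    libsbml.writeSBMLToFile(doc, str(path))
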