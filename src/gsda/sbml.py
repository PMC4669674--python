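"""SBML reader for kinetic models (Level 2/3 core, kinetic laws required).

Parsing is namespace-agnostic over SBML levels and uses lxml plus a
content-MathML-to-sympy converter.  Boundary-condition or constant species
map to clamped species, compartments and global parameters become model
parameters, local (per-reaction) parameters are namespaced as
``<reaction>_<parameter>``, and function definitions are inlined.  Rules,
events, constraints, initial assignments, piecewise math and delay/time
symbols are outside the ODE subset this engine solves and raise
:class:`SBMLUnsupportedError` listing the offending constructs.
"""

from __future__ import annotations

import os
from fractions import Fraction
from typing import Union

import sympy as sp
from lxml import etree

from gsda.model import KineticModel, ModelDefinitionError, Reaction, Species


class SBMLUnsupportedError(ModelDefinitionError):
    """The document uses SBML features outside the supported ODE subset."""


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _children(elem, name):
    return [c for c in elem if isinstance(c.tag, str) and _local(c.tag) == name]


def _find(elem, name):
    hits = _children(elem, name)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# content MathML -> sympy
# ---------------------------------------------------------------------------

_MATHML_CONSTANTS = {
    "pi": sp.pi,
    "exponentiale": sp.E,
    "true": sp.true,
    "false": sp.false,
    "infinity": sp.oo,
    "notanumber": sp.nan,
}

_NARY = {
    "plus": lambda args: sp.Add(*args) if args else sp.Integer(0),
    "times": lambda args: sp.Mul(*args) if args else sp.Integer(1),
}

_UNARY_FUNCS = {
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "cosh": sp.cosh,
    "sinh": sp.sinh,
    "arctan": sp.atan,
    "arcsin": sp.asin,
    "arccos": sp.acos,
}


def _parse_cn(elem) -> sp.Expr:
    ctype = elem.get("type", "real")
    parts = [elem.text or ""]
    for sep in _children(elem, "sep"):
        parts.append(sep.tail or "")
    parts = [p.strip() for p in parts]
    if ctype == "integer":
        return sp.Integer(int(parts[0]))
    if ctype == "rational":
        return sp.Rational(int(parts[0]), int(parts[1]))
    if ctype == "e-notation":
        return sp.Float(f"{parts[0]}e{parts[1]}", 17)
    return sp.Float(parts[0], 17)


def mathml_to_sympy(elem, functions=None) -> sp.Expr:
    """Convert a content-MathML element (``<math>`` or inner node) to sympy."""
    functions = functions or {}
    name = _local(elem.tag)
    if name == "math":
        kids = [c for c in elem if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise SBMLUnsupportedError("expected a single expression under <math>")
        return mathml_to_sympy(kids[0], functions)
    if name == "ci":
        return sp.Symbol(elem.text.strip())
    if name == "cn":
        return _parse_cn(elem)
    if name == "csymbol":
        url = elem.get("definitionURL", "")
        raise SBMLUnsupportedError(f"csymbol {url!r} (time/delay) is unsupported")
    if name in _MATHML_CONSTANTS:
        return _MATHML_CONSTANTS[name]
    if name == "piecewise":
        raise SBMLUnsupportedError("piecewise expressions are unsupported")
    if name != "apply":
        raise SBMLUnsupportedError(f"unsupported MathML element <{name}>")

    kids = [c for c in elem if isinstance(c.tag, str)]
    op = kids[0]
    opname = _local(op.tag)
    args = [mathml_to_sympy(k, functions) for k in kids[1:]]

    if opname == "ci":  # call of a functionDefinition
        fname = op.text.strip()
        if fname not in functions:
            raise SBMLUnsupportedError(f"call of unknown function {fname!r}")
        params, body = functions[fname]
        if len(params) != len(args):
            raise ModelDefinitionError(f"function {fname!r}: wrong argument count")
        return body.xreplace(dict(zip(params, args)))
    if opname in _NARY:
        return _NARY[opname](args)
    if opname == "minus":
        return -args[0] if len(args) == 1 else args[0] - args[1]
    if opname == "divide":
        return args[0] / args[1]
    if opname == "power":
        return sp.Pow(args[0], args[1])
    if opname == "root":
        degree = sp.Integer(2)
        if _local(kids[1].tag) == "degree":
            degree = mathml_to_sympy([c for c in kids[1] if isinstance(c.tag, str)][0],
                                     functions)
            args = [mathml_to_sympy(k, functions) for k in kids[2:]]
        return sp.Pow(args[0], 1 / degree)
    if opname == "log":
        base = sp.Integer(10)
        rest = kids[1:]
        if rest and _local(rest[0].tag) == "logbase":
            base = mathml_to_sympy([c for c in rest[0] if isinstance(c.tag, str)][0],
                                   functions)
            rest = rest[1:]
        return sp.log(mathml_to_sympy(rest[0], functions), base)
    if opname in _UNARY_FUNCS:
        return _UNARY_FUNCS[opname](args[0])
    raise SBMLUnsupportedError(f"unsupported MathML operator <{opname}>")


# ---------------------------------------------------------------------------
# document -> KineticModel
# ---------------------------------------------------------------------------

def read_sbml(source: Union[str, bytes, os.PathLike]) -> KineticModel:
    """Read an SBML document (path, XML string or bytes) into a model."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        tree = etree.parse(str(source))
        root = tree.getroot()
    else:
        data = source.encode() if isinstance(source, str) else source
        root = etree.fromstring(data)
    if _local(root.tag) != "sbml":
        raise ModelDefinitionError("not an SBML document (missing <sbml> root)")
    model_el = _find(root, "model")
    if model_el is None:
        raise ModelDefinitionError("SBML document has no <model>")

    unsupported = []
    for lname, label in [
        ("listOfRules", "rules"),
        ("listOfEvents", "events"),
        ("listOfConstraints", "constraints"),
        ("listOfInitialAssignments", "initial assignments"),
    ]:
        lst = _find(model_el, lname)
        if lst is not None and any(isinstance(c.tag, str) for c in lst):
            ids = [c.get("id") or c.get("variable") or c.get("symbol") or "?"
                   for c in lst if isinstance(c.tag, str)]
            unsupported.append(f"{label}: {ids}")
    if unsupported:
        raise SBMLUnsupportedError("unsupported SBML features: " + "; ".join(unsupported))

    functions = {}
    fd_list = _find(model_el, "listOfFunctionDefinitions")
    if fd_list is not None:
        for fd in _children(fd_list, "functionDefinition"):
            math = _find(fd, "math")
            lam = [c for c in math if isinstance(c.tag, str)][0]
            if _local(lam.tag) != "lambda":
                raise SBMLUnsupportedError("functionDefinition without <lambda>")
            kids = [c for c in lam if isinstance(c.tag, str)]
            bvars = [sp.Symbol(_children(b, "ci")[0].text.strip())
                     for b in kids if _local(b.tag) == "bvar"]
            body_el = [b for b in kids if _local(b.tag) != "bvar"][0]
            functions[fd.get("id")] = (bvars, mathml_to_sympy(body_el, functions))

    parameters: dict = {}
    comp_sizes: dict = {}
    comp_list = _find(model_el, "listOfCompartments")
    if comp_list is not None:
        for c in _children(comp_list, "compartment"):
            size = c.get("size") or c.get("volume") or "1"
            comp_sizes[c.get("id")] = float(size)
            parameters[c.get("id")] = float(size)

    species: list = []
    species_comp: dict = {}
    sp_list = _find(model_el, "listOfSpecies")
    if sp_list is not None:
        for s in _children(sp_list, "species"):
            sid = s.get("id")
            comp = s.get("compartment")
            species_comp[sid] = comp
            if s.get("initialConcentration") is not None:
                value = float(s.get("initialConcentration"))
            elif s.get("initialAmount") is not None:
                value = float(s.get("initialAmount")) / comp_sizes.get(comp, 1.0)
            else:
                value = 0.0
            clamped = s.get("boundaryCondition") == "true" or s.get("constant") == "true"
            species.append(Species(sid, "clamped" if clamped else "variable", value))

    p_list = _find(model_el, "listOfParameters")
    if p_list is not None:
        for p in _children(p_list, "parameter"):
            parameters[p.get("id")] = float(p.get("value", "0"))

    reactions: list = []
    r_list = _find(model_el, "listOfReactions")
    species_ids = {s.id for s in species}
    for r in (_children(r_list, "reaction") if r_list is not None else []):
        rid = r.get("id")
        stoich: dict = {}
        for side, sign in [("listOfReactants", -1), ("listOfProducts", 1)]:
            lst = _find(r, side)
            if lst is None:
                continue
            for ref in _children(lst, "speciesReference"):
                if _find(ref, "stoichiometryMath") is not None:
                    raise SBMLUnsupportedError(f"{rid}: stoichiometryMath is unsupported")
                c = Fraction(str(ref.get("stoichiometry", "1"))
                             if "." not in str(ref.get("stoichiometry", "1"))
                             else str(float(ref.get("stoichiometry", "1"))))
                sid = ref.get("species")
                stoich[sid] = stoich.get(sid, Fraction(0)) + sign * c
        stoich = {k: v for k, v in stoich.items() if v != 0}

        kl = _find(r, "kineticLaw")
        if kl is None:
            raise ModelDefinitionError(f"reaction {rid!r} has no kinetic law")
        local_subs = {}
        for lname in ("listOfParameters", "listOfLocalParameters"):
            lst = _find(kl, lname)
            if lst is None:
                continue
            for p in list(lst):
                if not isinstance(p.tag, str):
                    continue
                pid = p.get("id")
                scoped = f"{rid}_{pid}" if (pid in parameters or pid in species_ids) \
                    else pid
                parameters[scoped] = float(p.get("value", "0"))
                if scoped != pid:
                    local_subs[sp.Symbol(pid)] = sp.Symbol(scoped)
        math = _find(kl, "math")
        if math is None:
            raise ModelDefinitionError(f"reaction {rid!r}: kinetic law has no math")
        expr = mathml_to_sympy(math, functions).xreplace(local_subs)
        reactions.append(Reaction(id=rid, stoichiometry=tuple(stoich.items()), rate=expr))

    # concentration ODEs: ds/dt = (1/V) N v; a common compartment size scales
    # every rate law uniformly
    var_comps = {species_comp[s.id] for s in species if s.role == "variable"}
    sizes = {comp_sizes.get(c, 1.0) for c in var_comps}
    if len(sizes) > 1:
        raise SBMLUnsupportedError(
            f"variable species span compartments of different sizes {sorted(sizes)}")
    size = sizes.pop() if sizes else 1.0
    if size != 1.0:
        reactions = [Reaction(r.id, r.stoichiometry, r.rate / size) for r in reactions]

    name = model_el.get("id") or model_el.get("name") or "sbml_model"
    return KineticModel(species, parameters, reactions, name=name)
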