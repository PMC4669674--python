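"""Plain-text model definition dialect.

One statement per line, UTF-8, ``#`` starts a comment::

    FIX: X0 X1                       # clamped species
    R1: Glc + 2 ADP = 2 Pyr + 2 ATP ; Vmax1*Glc*ADP/(K + ADP)
    Vmax1 = 12.5                     # parameter
    Glc@0 = 1.0                      # initial value

Reactions use ``substrates = products ; rate expression``; stoichiometric
coefficients may be integers, decimals or fractions (``3/2``).  Species are
collected from the FIX line and the reaction stoichiometries; identifiers in
a rate law that are neither species nor declared parameters are a parse
error naming the symbol and line.  Writing is canonical, so
``write(read(write(read(text))))`` is byte-identical to
``write(read(text))``.
"""

from __future__ import annotations

import re
from fractions import Fraction

import sympy as sp

from gsda.model import KineticModel, ModelDefinitionError, Reaction, Species


class DSLParseError(ModelDefinitionError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_NUMBER = r"\d+(?:\.\d+)?(?:[eE][+-]?\d+)?(?:/\d+)?"
_TERM_RE = re.compile(rf"^(?:({_NUMBER})\s+)?([A-Za-z_]\w*)$")
_INIT_RE = re.compile(r"^([A-Za-z_]\w*)@0\s*=\s*(\S+)$")
_PARAM_RE = re.compile(r"^([A-Za-z_]\w*)\s*=\s*(\S+)$")
_RXN_RE = re.compile(r"^([A-Za-z_]\w*)\s*:\s*(.*?)=(.*?);(.*)$")


def _parse_coeff(tok: str, lineno: int) -> Fraction:
    try:
        if "/" in tok:
            num, den = tok.split("/")
            return Fraction(num) / Fraction(den)
        return Fraction(tok) if "." not in tok and "e" not in tok.lower() \
            else Fraction(str(float(tok)))
    except (ValueError, ZeroDivisionError) as exc:
        raise DSLParseError(lineno, f"bad stoichiometric coefficient {tok!r}") from exc


def _parse_side(side: str, lineno: int) -> list:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise DSLParseError(lineno, f"bad stoichiometry term {term!r}")
        coeff = _parse_coeff(m.group(1), lineno) if m.group(1) else Fraction(1)
        out.append((m.group(2), coeff))
    return out


def read_model_dsl(text: str, name: str = None) -> KineticModel:
    """Parse the dialect into a :class:`KineticModel`.

    Species order is first appearance (FIX line, then reaction order);
    species without an ``@0`` line default to an initial value of 1.  A
    leading ``# <name>`` comment names the model.
    """
    if name is None:
        first = text.lstrip().splitlines()[0] if text.strip() else ""
        name = first[1:].strip() if first.startswith("#") else "model"
        name = name or "model"
    fixed: list = []
    rxn_lines: list = []      # (lineno, id, lhs, rhs, rate_text)
    params: dict = {}
    inits: dict = {}
    order: list = []

    def note(sid):
        if sid not in order:
            order.append(sid)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("FIX:"):
            for sid in line[4:].split():
                if not re.match(r"^[A-Za-z_]\w*$", sid):
                    raise DSLParseError(lineno, f"bad species id {sid!r} in FIX")
                if sid in fixed:
                    raise DSLParseError(lineno, f"duplicate clamped species {sid!r}")
                fixed.append(sid)
                note(sid)
            continue
        m = _RXN_RE.match(line)
        if m:
            rid, lhs, rhs, rate = m.groups()
            if any(rid == r[1] for r in rxn_lines):
                raise DSLParseError(lineno, f"duplicate reaction id {rid!r}")
            rxn_lines.append((lineno, rid, _parse_side(lhs, lineno),
                              _parse_side(rhs, lineno), rate.strip()))
            for sid, _ in rxn_lines[-1][2] + rxn_lines[-1][3]:
                note(sid)
            continue
        m = _INIT_RE.match(line)
        if m:
            sid, val = m.groups()
            if sid in inits:
                raise DSLParseError(lineno, f"duplicate initial value for {sid!r}")
            try:
                inits[sid] = float(val)
            except ValueError as exc:
                raise DSLParseError(lineno, f"bad number {val!r}") from exc
            note(sid)
            continue
        m = _PARAM_RE.match(line)
        if m:
            pid, val = m.groups()
            if pid in params:
                raise DSLParseError(lineno, f"duplicate parameter {pid!r}")
            try:
                params[pid] = float(val)
            except ValueError as exc:
                raise DSLParseError(lineno, f"bad number {val!r}") from exc
            continue
        raise DSLParseError(lineno, f"unrecognised statement {line!r}")

    if not rxn_lines:
        raise ModelDefinitionError("no reactions in model text")

    species_ids = [sid for sid in order if sid not in params]
    reactions = []
    known = set(species_ids) | set(params)
    for lineno, rid, lhs, rhs, rate_text in rxn_lines:
        stoich: dict = {}
        for sid, c in lhs:
            stoich[sid] = stoich.get(sid, Fraction(0)) - c
        for sid, c in rhs:
            stoich[sid] = stoich.get(sid, Fraction(0)) + c
        stoich = {k: v for k, v in stoich.items() if v != 0}
        try:
            rxn = Reaction.create(rid, stoich, rate_text)
        except ModelDefinitionError as exc:
            raise DSLParseError(lineno, str(exc)) from exc
        unknown = rxn.free_symbols - known
        if unknown:
            raise DSLParseError(
                lineno, f"undefined symbol(s) {sorted(unknown)} in rate of {rid!r}")
        reactions.append(rxn)

    species = [
        Species(sid, "clamped" if sid in fixed else "variable", inits.get(sid, 1.0))
        for sid in species_ids
    ]
    extra_inits = set(inits) - set(species_ids)
    if extra_inits:
        raise ModelDefinitionError(
            f"initial values for unknown species {sorted(extra_inits)}")
    return KineticModel(species, params, reactions, name=name)


def _fmt_coeff(c: Fraction) -> str:
    if c.denominator == 1:
        return "" if c.numerator == 1 else f"{c.numerator} "
    return f"{c.numerator}/{c.denominator} "


def _fmt_side(terms) -> str:
    return " + ".join(f"{_fmt_coeff(c)}{sid}" for sid, c in terms)


def write_model_dsl(model: KineticModel) -> str:
    """Canonical serialisation (Unix newlines, shortest round-trip floats)."""
    lines = [f"# {model.name}"]
    clamped = [s.id for s in model.species if s.role == "clamped"]
    if clamped:
        lines.append("FIX: " + " ".join(clamped))
    for r in model.reactions:
        lhs = [(sid, -c) for sid, c in r.stoichiometry if c < 0]
        rhs = [(sid, c) for sid, c in r.stoichiometry if c > 0]
        lines.append(f"{r.id}: {_fmt_side(lhs)} = {_fmt_side(rhs)} ; {sp.sstr(r.rate)}")
    for pid, val in model.parameters.items():
        lines.append(f"{pid} = {val!r}")
    # emit @0 lines in the order a reader of this text reconstructs species
    order = list(clamped)
    for r in model.reactions:
        for sid, c in r.stoichiometry:
            if c < 0 and sid not in order:
                order.append(sid)
        for sid, c in r.stoichiometry:
            if c > 0 and sid not in order:
                order.append(sid)
    by_id = {s.id: s for s in model.species}
    for sid in order:
        lines.append(f"{sid}@0 = {by_id[sid].initial_value!r}")
    return "\n".join(lines) + "\n"
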