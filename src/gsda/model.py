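"""Kinetic model representation and stoichiometric structure.

A :class:`KineticModel` is an ordered collection of species (variable or
clamped), parameters, and reactions with symbolic rate laws.  Stoichiometric
structure — the conservation matrix ``G`` spanning the left null space of the
stoichiometric matrix ``N``, the link matrix ``L`` and the reduced matrix
``N_r`` — is computed in exact rational arithmetic so that ``G @ N == 0``
holds exactly and moiety-conserved cycles (ATP/ADP, NADH/NAD+, ...) are
identified reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import sympy as sp


class ModelDefinitionError(ValueError):
    """The model structure or an expression is invalid."""


class NumericEvaluationError(RuntimeError):
    """A rate law evaluated to a non-finite value."""


_ALLOWED_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "ln": sp.log,
    "sqrt": sp.sqrt,
    "Abs": sp.Abs,
    "Pow": sp.Pow,
    "pi": sp.pi,
}


def parse_expression(text: str) -> sp.Expr:
    """Parse an arithmetic rate-law expression into a sympy expression.

    Supports ``+ - * / ** ^ exp log ln sqrt`` over species/parameter
    identifiers.  ``^`` is accepted as a power operator.
    """
    import re

    from sympy.parsing.sympy_parser import parse_expr, standard_transformations

    cleaned = text.replace("^", "**")
    # bind every identifier to a plain Symbol so names like S, E, N, pi never
    # collide with sympy globals
    local = dict(_ALLOWED_FUNCTIONS)
    for ident in set(re.findall(r"[A-Za-z_]\w*", cleaned)):
        if ident not in local:
            local[ident] = sp.Symbol(ident)
    try:
        expr = parse_expr(
            cleaned,
            local_dict=local,
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises many types here
        raise ModelDefinitionError(f"cannot parse rate expression {text!r}: {exc}") from exc
    return expr


@dataclass(frozen=True)
class Species:
    """A chemical species: ``variable`` species evolve, ``clamped`` are fixed."""

    id: str
    role: str = "variable"
    initial_value: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("variable", "clamped"):
            raise ModelDefinitionError(f"species {self.id!r}: role must be variable|clamped")
        if not np.isfinite(self.initial_value) or self.initial_value < 0:
            raise ModelDefinitionError(f"species {self.id!r}: initial value must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed rational stoichiometry and a symbolic rate law.

    Negative stoichiometric coefficients denote consumption.  Species that
    appear in the rate law but not in the stoichiometry are modifiers
    (allosteric effectors); they influence the rate without mass transfer.
    """

    id: str
    stoichiometry: tuple  # tuple of (species_id, Fraction) preserving order
    rate: sp.Expr

    @staticmethod
    def create(id: str, stoichiometry: Mapping[str, object], rate) -> "Reaction":
        stoich = tuple((s, Fraction(c)) for s, c in stoichiometry.items() if Fraction(c) != 0)
        if not stoich:
            raise ModelDefinitionError(f"reaction {id!r}: needs a nonzero stoichiometric entry")
        expr = parse_expression(rate) if isinstance(rate, str) else sp.sympify(rate)
        return Reaction(id=id, stoichiometry=stoich, rate=expr)

    @property
    def stoich_map(self) -> dict:
        return dict(self.stoichiometry)

    @property
    def free_symbols(self) -> set:
        return {str(s) for s in self.rate.free_symbols}

    def modifiers(self) -> set:
        """Species referenced by the rate law but not moved by the reaction."""
        return self.free_symbols - set(self.stoich_map)


class KineticModel:
    """An immutable kinetic model; analyses derive new models (clamp, knockout).

    Ordering of species and reactions is declaration order and is used to
    index every matrix produced by the analysis modules.
    """

    def __init__(
        self,
        species: Sequence[Species],
        parameters: Mapping[str, float],
        reactions: Sequence[Reaction],
        name: str = "model",
        validate: bool = True,
    ) -> None:
        self.species = tuple(species)
        self.parameters = dict(parameters)
        self.reactions = tuple(reactions)
        self.name = name
        self._cache: dict = {}
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def species_ids(self) -> tuple:
        return tuple(s.id for s in self.species)

    @property
    def variable_ids(self) -> tuple:
        return tuple(s.id for s in self.species if s.role == "variable")

    @property
    def clamped_ids(self) -> tuple:
        return tuple(s.id for s in self.species if s.role == "clamped")

    @property
    def reaction_ids(self) -> tuple:
        return tuple(r.id for r in self.reactions)

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ModelDefinitionError("duplicate species ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelDefinitionError("duplicate reaction ids")
        if set(ids) & set(self.parameters):
            clash = sorted(set(ids) & set(self.parameters))
            raise ModelDefinitionError(f"ids used as both species and parameter: {clash}")
        if not self.reactions:
            raise ModelDefinitionError("model needs at least one reaction")
        if not any(s.role == "variable" for s in self.species):
            raise ModelDefinitionError("model needs at least one variable species")
        known = set(ids) | set(self.parameters)
        for r in self.reactions:
            unknown = r.free_symbols - known
            if unknown:
                raise ModelDefinitionError(
                    f"reaction {r.id!r}: unresolved symbols {sorted(unknown)}"
                )
            for sid in r.stoich_map:
                if sid not in ids:
                    raise ModelDefinitionError(
                        f"reaction {r.id!r}: stoichiometry references unknown species {sid!r}"
                    )
        # rate laws must evaluate finitely at the initial state
        evaluate_rates(self, self.initial_state())

    def initial_state(self) -> dict:
        return {s.id: float(s.initial_value) for s in self.species}

    # -- derived numeric machinery (cached; model is immutable) ------------
    def _rate_functions(self):
        """Vectorised rate and rate-Jacobian evaluators over the full state."""
        if "ratefns" not in self._cache:
            syms = [sp.Symbol(sid) for sid in self.species_ids]
            psubs = {sp.Symbol(k): sp.Float(v, 17) for k, v in self.parameters.items()}
            exprs = [r.rate.xreplace(psubs) for r in self.reactions]
            vfun = sp.lambdify(syms, exprs, modules="numpy")
            var = [sp.Symbol(sid) for sid in self.variable_ids]
            jac_exprs = [[sp.diff(e, x) for x in var] for e in exprs]
            jfun = sp.lambdify(syms, jac_exprs, modules="numpy")
            self._cache["ratefns"] = (vfun, jfun)
        return self._cache["ratefns"]

    def rates_vector(self, state: Mapping[str, float]) -> np.ndarray:
        vfun, _ = self._rate_functions()
        args = [float(state[sid]) for sid in self.species_ids]
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.asarray(vfun(*args), dtype=float)
        except ZeroDivisionError as exc:
            raise NumericEvaluationError(f"division by zero in a rate law: {exc}") from exc
        return v

    def rate_jacobian(self, state: Mapping[str, float]) -> np.ndarray:
        """Unscaled dv/ds over variable species, shape (reactions, variables)."""
        _, jfun = self._rate_functions()
        args = [float(state[sid]) for sid in self.species_ids]
        return np.asarray(jfun(*args), dtype=float)

    @property
    def decomposition(self) -> "StoichiometryDecomposition":
        if "decomp" not in self._cache:
            self._cache["decomp"] = stoichiometric_decomposition(self)
        return self._cache["decomp"]

    # -- derivation of new models ------------------------------------------
    def with_species(self, new_species: Sequence[Species], name=None) -> "KineticModel":
        return KineticModel(new_species, self.parameters, self.reactions,
                            name=name or self.name)

    def with_parameters(self, updates: Mapping[str, float], name=None) -> "KineticModel":
        params = dict(self.parameters)
        params.update(updates)
        return KineticModel(self.species, params, self.reactions, name=name or self.name)

    def __repr__(self) -> str:
        return (f"<KineticModel {self.name!r}: {len(self.variable_ids)} variable + "
                f"{len(self.clamped_ids)} clamped species, {len(self.reactions)} reactions>")


@dataclass
class StoichiometryDecomposition:
    """Exact-rational stoichiometric structure of a model.

    ``N`` is the full stoichiometric matrix over variable species,
    ``G`` spans its left null space (one row per conserved moiety, in
    smallest-integer form with positive leading entry), ``L`` is the link
    matrix with ``N == L @ N_r`` and ``N_r`` the reduced matrix over the
    independent species.  ``totals`` holds the conserved totals ``G @ s0``
    at the model's initial state.
    """

    variable_species: tuple
    reaction_ids: tuple
    N: sp.Matrix
    G: sp.Matrix
    L: sp.Matrix
    N_r: sp.Matrix
    independent: tuple
    totals: dict

    @property
    def N_float(self) -> np.ndarray:
        return np.array(self.N, dtype=float)

    @property
    def L_float(self) -> np.ndarray:
        return np.array(self.L, dtype=float)

    @property
    def Nr_float(self) -> np.ndarray:
        return np.array(self.N_r, dtype=float)

    @property
    def G_float(self) -> np.ndarray:
        if self.G.rows == 0:
            return np.zeros((0, len(self.variable_species)))
        return np.array(self.G, dtype=float)

    def conservation_rows(self) -> list:
        """Each conserved moiety as a dict species -> integer coefficient."""
        rows = []
        for i in range(self.G.rows):
            row = {
                sid: int(self.G[i, j])
                for j, sid in enumerate(self.variable_species)
                if self.G[i, j] != 0
            }
            rows.append(row)
        return rows

    def conserved_partners(self, sid: str) -> set:
        """Species sharing a conservation row with ``sid`` (including itself)."""
        out = set()
        for row in self.conservation_rows():
            if sid in row:
                out |= set(row)
        return out


def _normalise_int_row(vec: sp.Matrix) -> sp.Matrix:
    """Scale a rational row vector to primitive integers, leading entry > 0."""
    denoms = [sp.Rational(x).q for x in vec if x != 0]
    nums = [abs(sp.Rational(x).p) for x in vec if x != 0]
    if not denoms:
        return vec
    scale = sp.lcm(denoms)
    vec = vec * scale
    g = sp.gcd([sp.Integer(x) for x in vec if x != 0])
    vec = vec / g
    for x in vec:
        if x != 0:
            if x < 0:
                vec = -vec
            break
    return vec


def stoichiometric_decomposition(model: KineticModel) -> StoichiometryDecomposition:
    """Conservation analysis in exact rational arithmetic.

    Gaussian elimination over the rationals guarantees ``G @ N == 0``
    exactly; floating SVD would only achieve this to round-off and can
    misidentify moieties in ill-scaled models.
    """
    var = model.variable_ids
    rid = model.reaction_ids
    n_s, n_r = len(var), len(rid)
    N = sp.zeros(n_s, n_r)
    for j, r in enumerate(model.reactions):
        for sid, coeff in r.stoichiometry:
            if sid in var:
                N[var.index(sid), j] = sp.Rational(coeff.numerator, coeff.denominator)

    # left null space: g with g^T N = 0
    null = N.T.nullspace()
    if null:
        G = sp.Matrix([_normalise_int_row(v.T) for v in null])
    else:
        G = sp.Matrix(0, n_s, [])

    # independent species: pivot columns of N^T correspond to independent rows of N
    _, pivots = N.T.rref()
    independent = tuple(var[i] for i in pivots)
    idx = [var.index(s) for s in independent]
    N_r = N[idx, :]
    if len(idx) == 0:
        L = sp.Matrix(n_s, 0, [])
    else:
        # solve L @ N_r = N exactly: L = N N_r^T (N_r N_r^T)^{-1}
        M = N_r * N_r.T
        L = N * N_r.T * M.inv()

    s0 = model.initial_state()
    totals = {}
    for i in range(G.rows):
        totals[i] = float(sum(G[i, j] * s0[var[j]] for j in range(n_s)))

    assert (G * N) == sp.zeros(G.rows, n_r)
    assert (L * N_r) == N
    return StoichiometryDecomposition(
        variable_species=var,
        reaction_ids=rid,
        N=N,
        G=G,
        L=L,
        N_r=N_r,
        independent=independent,
        totals=totals,
    )


def evaluate_rates(model: KineticModel, state: Mapping[str, float]) -> dict:
    """Evaluate every reaction rate at ``state`` (pure function of state/params)."""
    missing = set(model.species_ids) - set(state)
    if missing:
        raise ModelDefinitionError(f"state is missing species {sorted(missing)}")
    try:
        v = model.rates_vector(state)
    except NumericEvaluationError:
        # identify the offending reaction by exact evaluation
        subs = {sp.Symbol(k): float(val) for k, val in state.items()}
        subs.update({sp.Symbol(k): v for k, v in model.parameters.items()})
        for r in model.reactions:
            val = r.rate.xreplace({k: sp.Float(v) for k, v in subs.items()}).evalf()
            try:
                ok = math.isfinite(float(val))
            except (TypeError, ValueError, OverflowError):
                ok = False
            if not ok:
                raise NumericEvaluationError(
                    f"rate of reaction {r.id!r} is non-finite at this state")
        raise
    out = {}
    for rid, val in zip(model.reaction_ids, v):
        if not np.isfinite(val):
            raise NumericEvaluationError(f"rate of reaction {rid!r} is non-finite at this state")
        out[rid] = float(val)
    return out


def clamp(model: KineticModel, species_id: str, value: float, *,
          allow_conserved: bool = False) -> KineticModel:
    """Fix a variable species at ``value``; its row leaves the stoichiometry.

    Members of a moiety-conserved cycle are not free to vary on their own and
    cannot be clamped individually — scan their ratio instead (see
    :mod:`gsda.moiety`).  ``allow_conserved`` exists for the ratio machinery,
    which clamps *both* members consistently.
    """
    spec = model.species_by_id(species_id)
    if spec.role != "variable":
        raise ModelDefinitionError(f"{species_id!r} is already clamped")
    if not allow_conserved:
        partners = model.decomposition.conserved_partners(species_id)
        if partners:
            raise ModelDefinitionError(
                f"{species_id!r} is a member of a moiety-conserved cycle "
                f"({sorted(partners)}); clamp the cycle's ratio via "
                f"gsda.moiety.introduce_ratio instead"
            )
    new_species = [
        Species(s.id, "clamped", float(value)) if s.id == species_id else s
        for s in model.species
    ]
    return model.with_species(new_species, name=f"{model.name}|{species_id}={value:g}")
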