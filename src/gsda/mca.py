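"""Metabolic control analysis at a steady state.

Scaled coefficients throughout:

* elasticity        ``eps^v_x  = (dv/dx) * x / v``       (local, one reaction)
* control           ``C^J_vi   = dlnJ / dlnv_i``          (systemic)
* response          ``R^J_x    = dlnJ / dlnx = sum_i C^J_vi * eps^vi_x``

Control coefficients are computed by the structural (matrix) method from the
reduced stoichiometry: unscaled concentration control ``-L (N_r E L)^-1 N_r``
with ``E = dv/ds``, unscaled flux control ``I + E C_s``.  Summation and
connectivity theorem residuals are recorded on every call so a bad state
cannot go unnoticed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from gsda.model import KineticModel
from gsda.steady_state import SteadyStateResult


class SingularJacobianError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# elasticities
# ---------------------------------------------------------------------------

@dataclass
class ElasticityMatrix:
    """Scaled elasticities at a state; missing entries are structural zeros.

    Entries are NaN (and listed in ``near_equilibrium``) where the reaction
    rate is zero at the state — near equilibrium the scaled elasticity
    diverges, which is information, not an error.
    """

    entries: dict
    state: dict
    near_equilibrium: set = field(default_factory=set)

    def get(self, reaction: str, symbol: str) -> float:
        return self.entries.get((reaction, symbol), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rxns = sorted({r for r, _ in self.entries})
        syms = sorted({x for _, x in self.entries})
        return pd.DataFrame(
            [[self.entries.get((r, x), 0.0) for x in syms] for r in rxns],
            index=rxns, columns=syms,
        )


def _scaled_elasticity_symbolic(model, rxn, symbol, state) -> float:
    expr = model.reaction_by_id(rxn).rate
    x = sp.Symbol(symbol)
    if x not in expr.free_symbols:
        return 0.0
    if symbol in model.species_ids:
        # compiled closed-form derivative, cached on the (immutable) model
        cache = model._cache.setdefault("elasfns", {})
        key = (rxn, symbol)
        if key not in cache:
            psubs = {sp.Symbol(k): sp.Float(v, 17) for k, v in model.parameters.items()}
            e = expr.xreplace(psubs)
            syms = [sp.Symbol(sid) for sid in model.species_ids]
            cache[key] = sp.lambdify(syms, [e, sp.diff(e, x)], modules="math")
        args = [float(state[sid]) for sid in model.species_ids]
        v0, d = cache[key](*args)
        x0 = float(state[symbol])
    else:
        subs = {sp.Symbol(k): v for k, v in state.items()}
        subs.update({sp.Symbol(k): v for k, v in model.parameters.items()})
        v0 = float(expr.evalf(subs=subs))
        d = float(sp.diff(expr, x).evalf(subs=subs))
        x0 = float(subs[x])
    if v0 == 0.0:
        # dead rate (e.g. enzyme knocked out): no sensitivity at all;
        # genuine equilibrium (v=0, dv/dx != 0): scaled elasticity diverges
        return 0.0 if d == 0.0 else math.nan
    return d * x0 / v0


def _scaled_elasticity_numeric(model, rxn, symbol, state, h: float = 1e-5) -> float:
    """Central difference with a relative step in log space."""
    i = model.reaction_ids.index(rxn)
    st = dict(state)
    in_state = symbol in st

    def rate_at(x):
        if in_state:
            st2 = dict(st)
            st2[symbol] = x
            return float(model.rates_vector(st2)[i])
        # parameter perturbation: evaluate expression symbolically
        expr = model.reaction_by_id(rxn).rate
        subs = {sp.Symbol(k): v for k, v in st.items()}
        subs.update({sp.Symbol(k): v for k, v in model.parameters.items()})
        subs[sp.Symbol(symbol)] = x
        return float(expr.evalf(subs=subs))

    x0 = st[symbol] if in_state else model.parameters[symbol]
    if x0 <= 0:
        raise ValueError(f"cannot take log-space derivative at {symbol}={x0}")
    v0 = rate_at(x0)
    vp = rate_at(x0 * math.exp(h))
    vm = rate_at(x0 * math.exp(-h))
    if v0 == 0.0:
        return 0.0 if vp == vm == 0.0 else math.nan
    return (vp - vm) / (2.0 * h * v0)


def elasticity(model: KineticModel, reaction: str, symbol: str,
               state: Mapping[str, float], method: str = "symbolic") -> float:
    """One scaled elasticity ``eps^v_symbol`` at ``state``."""
    state = dict(state)
    if method == "symbolic":
        return _scaled_elasticity_symbolic(model, reaction, symbol, state)
    if method == "numeric":
        return _scaled_elasticity_numeric(model, reaction, symbol, state)
    raise ValueError(f"unknown method {method!r}")


def elasticities(model: KineticModel, state: Optional[Mapping[str, float]] = None,
                 wrt: Optional[Sequence[str]] = None,
                 method: str = "symbolic") -> ElasticityMatrix:
    """All scaled elasticities of every reaction toward ``wrt`` (default: every
    species its rate law references)."""
    if state is None:
        state = model.initial_state()
    state = dict(state)
    entries = {}
    flagged = set()
    for r in model.reactions:
        symbols = wrt if wrt is not None else sorted(r.free_symbols & set(model.species_ids))
        for x in symbols:
            if sp.Symbol(x) not in r.rate.free_symbols:
                continue
            val = elasticity(model, r.id, x, state, method=method)
            entries[(r.id, x)] = val
            if isinstance(val, float) and math.isnan(val):
                flagged.add((r.id, x))
    return ElasticityMatrix(entries=entries, state=state, near_equilibrium=flagged)


# ---------------------------------------------------------------------------
# control coefficients
# ---------------------------------------------------------------------------

@dataclass
class ControlMatrices:
    """Scaled flux- and concentration-control coefficients at a steady state.

    ``flux_control.loc[Ji, vj]`` is ``C^{Ji}_{vj}``; rows with zero reference
    flux are left unscaled and listed in ``zero_flux``.  ``theorems`` records
    the worst summation-theorem residuals (flux rows sum to 1, concentration
    rows to 0).
    """

    flux_control: pd.DataFrame
    conc_control: pd.DataFrame
    theorems: dict
    zero_flux: set
    state: dict
    fluxes: dict

    def C_J(self, flux: str, reaction: str) -> float:
        return float(self.flux_control.loc[flux, reaction])

    def C_s(self, species: str, reaction: str) -> float:
        return float(self.conc_control.loc[species, reaction])


def control_coefficients(model: KineticModel, ss: SteadyStateResult,
                         condition_threshold: float = 1e12) -> ControlMatrices:
    """Structural-method control coefficients of the system at ``ss``."""
    if not ss.converged:
        raise ValueError("steady state did not converge; refusing control analysis")
    d = model.decomposition
    var = list(d.variable_species)
    rxns = list(model.reaction_ids)
    state = dict(ss.concentrations)
    v = np.array([ss.fluxes[r] for r in rxns])
    s = np.array([state[x] for x in var])

    E = model.rate_jacobian(state)          # (n_rxn, n_var)
    L = d.L_float
    Nr = d.Nr_float
    if Nr.shape[0] == 0:
        Cs_u = np.zeros((len(var), len(rxns)))
    else:
        M = Nr @ E @ L
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > condition_threshold:
            raise SingularJacobianError(
                f"reduced Jacobian condition {cond:.3g} exceeds {condition_threshold:.3g}"
            )
        Cs_u = -L @ np.linalg.solve(M, Nr)
    CJ_u = np.eye(len(rxns)) + E @ Cs_u

    zero_flux = {rxns[i] for i in range(len(rxns)) if v[i] == 0.0}
    CJ = CJ_u * v[np.newaxis, :]
    for i in range(len(rxns)):
        if v[i] != 0.0:
            CJ[i, :] /= v[i]
        else:  # keep unscaled, flagged
            CJ[i, :] = CJ_u[i, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        Cs = (Cs_u * v[np.newaxis, :]) / s[:, np.newaxis]

    flux_control = pd.DataFrame(CJ, index=rxns, columns=rxns)
    conc_control = pd.DataFrame(Cs, index=var, columns=rxns)

    flux_rows = [r for r in rxns if r not in zero_flux]
    theorems = {
        "flux_summation_max_abs_error": float(
            np.max(np.abs(flux_control.loc[flux_rows].sum(axis=1) - 1.0))
        ) if flux_rows else 0.0,
        "conc_summation_max_abs_error": float(
            np.max(np.abs(conc_control.sum(axis=1)))
        ) if var else 0.0,
    }
    return ControlMatrices(flux_control, conc_control, theorems, zero_flux, state,
                           dict(ss.fluxes))


def connectivity_residuals(model: KineticModel, ss: SteadyStateResult,
                           cm: Optional[ControlMatrices] = None) -> pd.DataFrame:
    """Flux-connectivity sums ``sum_j C^J_vj eps^vj_s`` over the independent
    species (0 at a valid state).

    With moiety conservation a perturbation of an independent species drags
    its dependent cycle partners along, so the elasticities are folded
    through the link matrix (the exact matrix statement is ``C E L = 0``);
    without conservation ``L`` is the identity and this is the textbook sum.
    """
    cm = cm or control_coefficients(model, ss)
    d = model.decomposition
    state = dict(ss.concentrations)
    v = np.array([ss.fluxes[r] for r in model.reaction_ids])
    EL = model.rate_jacobian(state) @ d.L_float        # (rxn, independent)
    s_ind = np.array([state[x] for x in d.independent])
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_L = EL * s_ind[np.newaxis, :] / v[:, np.newaxis]
    rows = {}
    for i, J in enumerate(model.reaction_ids):
        if J in cm.zero_flux:
            continue
        rows[J] = {
            s: sum(cm.C_J(J, r) * eps_L[j, k]
                   for j, r in enumerate(model.reaction_ids))
            for k, s in enumerate(d.independent)
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# response coefficients
# ---------------------------------------------------------------------------

@dataclass
class ResponseCoefficient:
    """A total response with its per-reaction partial decomposition.

    ``decomposition`` maps reaction id -> partial response ``C^J_vi eps^vi_x``
    for every reaction directly sensitive to the perturbed entity; the total
    is their sum (partitioned-response identity).
    """

    target: tuple            # ("flux", rxn) or ("conc", species)
    parameter: str
    value: float
    decomposition: dict
    factors: dict = field(default_factory=dict)  # rxn -> (C, eps)

    def partial(self, reaction: str) -> float:
        return self.decomposition.get(reaction, 0.0)

    def partial_sum(self, reactions) -> float:
        return float(sum(self.decomposition.get(r, 0.0) for r in reactions))


def _parameter_elasticity(model, rxn, parameter, state) -> float:
    """Scaled elasticity toward a plain symbol or a ratio-like object."""
    if hasattr(parameter, "elasticity"):
        return parameter.elasticity(model, rxn, state)
    return elasticity(model, rxn, str(parameter), state)


def response_coefficient(model: KineticModel, ss: SteadyStateResult, parameter,
                         target=None, cm: Optional[ControlMatrices] = None) -> ResponseCoefficient:
    """Response of one steady-state flux or concentration to ``parameter``.

    ``parameter`` is a clamped-species id, a model-parameter id, or a
    :class:`gsda.moiety.MoietyRatio`.  ``target`` defaults to the flux of the
    first reaction; pass ``("flux", rxn)`` or ``("conc", species)``.
    """
    cm = cm or control_coefficients(model, ss)
    if target is None:
        target = ("flux", model.reaction_ids[0])
    kind, name = target
    state = dict(ss.concentrations)
    decomposition, factors = {}, {}
    for r in model.reaction_ids:
        eps = _parameter_elasticity(model, r, parameter, state)
        if eps == 0.0:
            continue
        C = cm.C_J(name, r) if kind == "flux" else cm.C_s(name, r)
        decomposition[r] = C * eps
        factors[r] = (C, eps)
    value = float(sum(decomposition.values())) if decomposition else 0.0
    pname = getattr(parameter, "symbol", str(parameter))
    return ResponseCoefficient(target=target, parameter=pname, value=value,
                               decomposition=decomposition, factors=factors)


def response_coefficients(model: KineticModel, ss: SteadyStateResult, parameter,
                          cm: Optional[ControlMatrices] = None) -> dict:
    """Responses of every reaction flux to ``parameter`` (dict rxn -> R)."""
    cm = cm or control_coefficients(model, ss)
    return {
        r: response_coefficient(model, ss, parameter, ("flux", r), cm=cm)
        for r in model.reaction_ids
    }


def finite_difference_response(model: KineticModel, parameter: str, target,
                               rel_step: float = 1e-3,
                               init: Optional[Mapping[str, float]] = None) -> float:
    """Independent re-solve oracle: ``dlnJ/dlnx`` by perturbing ``parameter``
    multiplicatively and re-solving the steady state on both sides.

    The default step balances the O(h^2) truncation error of the central
    difference against steady-state solver noise (~1e-9 relative), giving
    ~1e-6 relative accuracy.
    """
    from gsda.steady_state import steady_state
    kind, name = target

    def solve_at(factor):
        if parameter in model.parameters:
            m = model.with_parameters({parameter: model.parameters[parameter] * factor})
        else:
            spec = model.species_by_id(parameter)
            if spec.role != "clamped":
                raise ValueError(f"{parameter!r} must be a parameter or clamped species")
            new = [type(s)(s.id, s.role, s.initial_value * factor) if s.id == parameter else s
                   for s in model.species]
            m = model.with_species(new)
        r = steady_state(m, init=init, raise_on_failure=True)
        return r.fluxes[name] if kind == "flux" else r.concentrations[name]

    h = rel_step
    jp = solve_at(math.exp(h))
    jm = solve_at(math.exp(-h))
    j0 = solve_at(1.0)
    if j0 == 0:
        return math.nan
    return (jp - jm) / (2.0 * h * j0)
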