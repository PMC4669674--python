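"""Steady-state solver for kinetic models.

Solves ``N_r @ v(s) = 0`` on the independent species, reconstructing the
dependent ones through the link matrix and the conserved totals, so that
moiety conservation holds exactly at every iterate.  Strategy: a damped
Newton attempt from the initial guess, falling back to ODE integration
(LSODA, suited to the stiff systems typical of branched pathways) toward
stationarity followed by Newton polishing.  Newton steps are damped to keep
every concentration strictly positive, since rate laws may be undefined at
negative concentrations.  The solver is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from gsda.model import KineticModel


class SteadyStateError(RuntimeError):
    pass


@dataclass
class SteadyStateResult:
    concentrations: dict
    fluxes: dict
    residual: float
    jacobian_condition: float
    converged: bool
    model: KineticModel = None

    def flux_vector(self) -> np.ndarray:
        return np.array([self.fluxes[r] for r in self.model.reaction_ids])

    def __repr__(self) -> str:
        return (f"<SteadyStateResult converged={self.converged} "
                f"residual={self.residual:.3g} cond={self.jacobian_condition:.3g}>")


class _ReducedSystem:
    """Independent-species view of a model at fixed clamped values/totals."""

    def __init__(self, model: KineticModel, init: Mapping[str, float]):
        self.model = model
        d = model.decomposition
        self.var = list(d.variable_species)
        self.ind = list(d.independent)
        self.L = d.L_float
        self.Nr = d.Nr_float
        self.ind_idx = [self.var.index(s) for s in self.ind]
        self.state0 = {sid: float(init[sid]) for sid in model.species_ids}
        s_full0 = np.array([self.state0[s] for s in self.var])
        y0 = s_full0[self.ind_idx]
        # s_full = offset + L y reproduces conserved totals of the init state
        self.offset = s_full0 - self.L @ y0
        self.y0 = y0

    def full_state(self, y: np.ndarray) -> dict:
        s_full = self.offset + self.L @ y
        state = dict(self.state0)
        for sid, val in zip(self.var, s_full):
            state[sid] = float(val)
        return state

    def concentrations(self, y: np.ndarray) -> np.ndarray:
        return self.offset + self.L @ y

    def rates(self, y: np.ndarray) -> np.ndarray:
        return self.model.rates_vector(self.full_state(y))

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return self.Nr @ self.rates(y)

    def jac(self, y: np.ndarray) -> np.ndarray:
        Ev = self.model.rate_jacobian(self.full_state(y))
        return self.Nr @ Ev @ self.L


def _damped_newton(sys: _ReducedSystem, y: np.ndarray, *, tol: float,
                   max_steps: int) -> tuple:
    """Newton iteration keeping all variable concentrations > 0."""
    y = y.copy()
    f = sys.rhs(y)
    for _ in range(max_steps):
        vmean = max(np.mean(np.abs(sys.rates(y))), 1e-300)
        if np.max(np.abs(f)) <= tol * vmean:
            return y, True
        J = sys.jac(y)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return y, False
        alpha = 1.0
        for _ in range(60):
            y_new = y + alpha * step
            s = sys.concentrations(y_new)
            if np.all(s > 0):
                f_new = sys.rhs(y_new)
                if np.all(np.isfinite(f_new)) and (
                    np.linalg.norm(f_new) < np.linalg.norm(f) or alpha < 1e-6
                ):
                    break
            alpha *= 0.5
        else:
            return y, False
        y, f = y_new, f_new
    vmean = max(np.mean(np.abs(sys.rates(y))), 1e-300)
    return y, bool(np.max(np.abs(f)) <= tol * vmean)


def steady_state(
    model: KineticModel,
    init: Optional[Mapping[str, float]] = None,
    *,
    residual_tol: float = 1e-9,
    newton_max_steps: int = 100,
    integrate_tol: float = 1e-6,
    t_max: float = 1e9,
    raise_on_failure: bool = False,
) -> SteadyStateResult:
    """Solve for the steady state of ``model`` starting from ``init``.

    ``residual_tol`` bounds ``max |N_r v|`` relative to the mean ``|v|``.
    Integration proceeds over geometrically growing horizons until the
    time-derivative norm drops below ``integrate_tol`` (relative), after
    which Newton polishes the root.  Non-convergence is reported in the
    result (or raised when ``raise_on_failure``); negative concentrations at
    a claimed solution always raise.
    """
    state0 = model.initial_state()
    if init:
        # clamped values are part of the model; init only seeds the variables
        variable = set(model.variable_ids)
        state0.update({k: float(v) for k, v in init.items() if k in variable})
    sys = _ReducedSystem(model, state0)

    if len(sys.ind) == 0:  # fully clamped: the state itself is stationary
        v = sys.rates(np.zeros(0))
        fluxes = dict(zip(model.reaction_ids, map(float, v)))
        return SteadyStateResult(dict(sys.state0), fluxes, 0.0, 1.0, True, model)

    y, ok = _damped_newton(sys, sys.y0, tol=residual_tol, max_steps=newton_max_steps)

    if not ok:
        y = sys.y0.copy()
        t_hi = 10.0
        while t_hi <= t_max:
            sol = solve_ivp(
                lambda t, yy: sys.rhs(yy),
                (0.0, t_hi),
                y,
                method="LSODA",
                jac=lambda t, yy: sys.jac(yy),
                rtol=1e-8,
                atol=1e-12,
            )
            if sol.success:
                y = sol.y[:, -1]
                y = np.maximum(y, 1e-300)
                vmean = max(np.mean(np.abs(sys.rates(y))), 1e-300)
                if np.max(np.abs(sys.rhs(y))) < integrate_tol * vmean:
                    break
            t_hi *= 10.0
        y, ok = _damped_newton(sys, y, tol=residual_tol, max_steps=newton_max_steps)

    s = sys.concentrations(y)
    v = sys.rates(y)
    vmean = max(np.mean(np.abs(v)), 1e-300)
    residual = float(np.max(np.abs(sys.Nr @ v)) / vmean)
    J = sys.jac(y)
    cond = float(np.linalg.cond(J)) if J.size else 1.0

    if ok and np.any(s <= 0):
        raise SteadyStateError(
            "steady-state solution contains non-positive concentrations: "
            + ", ".join(f"{sid}={val:.3g}" for sid, val in zip(sys.var, s) if val <= 0)
        )
    if not ok and raise_on_failure:
        raise SteadyStateError(f"no steady state found (residual {residual:.3g})")

    state = sys.full_state(y)
    concentrations = {sid: state[sid] for sid in model.species_ids}
    fluxes = dict(zip(model.reaction_ids, map(float, v)))
    return SteadyStateResult(concentrations, fluxes, residual, cond, ok, model)
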