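"""Moiety-conserved cycles as single scannable ratio variables.

The members of a conserved cycle (ATP/ADP, NADH/NAD+, AcCoA/CoA) are not
free to vary individually: their total ``C`` is fixed.  To scan such a cycle
the pair is replaced by its ratio ``phi = [numerator]/[denominator]`` at
fixed total, with member concentrations reconstructed as::

    numerator   = phi * C / (1 + phi)
    denominator =       C / (1 + phi)

which sum to ``C`` exactly for every ``phi > 0``.  Only two-member cycles
with unit coefficients are supported; that covers the cofactor cycles this
kind of analysis targets, and anything more general raises a clear error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from gsda.model import KineticModel, ModelDefinitionError, Species
from gsda.steady_state import SteadyStateResult, steady_state
from gsda import mca


@dataclass(frozen=True)
class MoietyRatio:
    """A two-member conserved cycle expressed as a ratio variable."""

    symbol: str
    numerator: str
    denominator: str
    total: float
    value: float  # reference phi (at the full model's steady state)

    def member_values(self, phi: float) -> tuple:
        """Reconstruct (numerator, denominator) concentrations at ``phi``."""
        if phi <= 0:
            raise ValueError(f"{self.symbol} must be > 0, got {phi}")
        den = self.total / (1.0 + phi)
        num = self.total - den   # sums to the total exactly, by construction
        return num, den

    def phi_of_state(self, state) -> float:
        return float(state[self.numerator]) / float(state[self.denominator])

    def elasticity(self, model: KineticModel, reaction: str, state) -> float:
        """Chain rule over the reconstruction equations:
        ``eps_phi = eps_num/(1+phi) - eps_den*phi/(1+phi)``."""
        return ratio_elasticity(model, reaction, self, state)


def _find_pair_row(model: KineticModel, numerator: str, denominator: str):
    for row in model.decomposition.conservation_rows():
        if set(row) == {numerator, denominator}:
            return row
    return None


def introduce_ratio(
    model: KineticModel,
    numerator: str,
    denominator: str,
    symbol: Optional[str] = None,
    reference: Optional[SteadyStateResult] = None,
) -> tuple:
    """Clamp a conserved pair at its reference state and return the ratio handle.

    Returns ``(clamped_model, ratio)``: both members become clamped at their
    reference steady-state concentrations; rescan other ``phi`` values with
    :func:`set_ratio`.  The conserved total is frozen at the reference state
    (conservation makes the initial-state and steady-state totals identical).
    """
    row = _find_pair_row(model, numerator, denominator)
    if row is None:
        raise ModelDefinitionError(
            f"({numerator}, {denominator}) is not a two-member conserved cycle "
            f"of this model"
        )
    if set(row.values()) != {1}:
        raise ModelDefinitionError(
            f"cycle ({numerator}, {denominator}) has non-unit coefficients {row}; "
            f"only (1,1) cycles are supported as ratio variables"
        )
    if reference is None:
        reference = steady_state(model, raise_on_failure=True)
    num0 = reference.concentrations[numerator]
    den0 = reference.concentrations[denominator]
    total = num0 + den0
    ratio = MoietyRatio(
        symbol=symbol or f"phi_{numerator}_{denominator}",
        numerator=numerator,
        denominator=denominator,
        total=float(total),
        value=float(num0 / den0),
    )
    clamped = set_ratio(model, ratio, ratio.value)
    return clamped, ratio


def set_ratio(model: KineticModel, ratio: MoietyRatio, phi: float) -> KineticModel:
    """Model with both cycle members clamped at the values reconstructed from
    ``phi`` and the frozen total."""
    num, den = ratio.member_values(phi)
    values = {ratio.numerator: num, ratio.denominator: den}
    new_species = [
        Species(s.id, "clamped", values[s.id]) if s.id in values else s
        for s in model.species
    ]
    return model.with_species(new_species, name=f"{model.name}|{ratio.symbol}={phi:g}")


def ratio_elasticity(model: KineticModel, reaction: str, ratio: MoietyRatio,
                     state) -> float:
    """Scaled elasticity of a reaction toward the ratio variable.

    Differentiating the reconstruction equations gives
    ``dln(num)/dln(phi) = 1/(1+phi)`` and ``dln(den)/dln(phi) = -phi/(1+phi)``,
    hence ``eps_phi = eps_num/(1+phi) - eps_den*phi/(1+phi)``.
    """
    phi = ratio.phi_of_state(state)
    eps_num = mca.elasticity(model, reaction, ratio.numerator, state)
    eps_den = mca.elasticity(model, reaction, ratio.denominator, state)
    return eps_num / (1.0 + phi) - eps_den * phi / (1.0 + phi)
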