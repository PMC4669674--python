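"""Supply-demand partitioning, rate-characteristic scans and block responses.

Around a clamped variable (a metabolite or a moiety ratio) the network
splits into one reaction block per stoichiometrically adjacent reaction,
each named after that reaction.  A block is a supply block when its adjacent
reaction produces the clamped entity at the reference flux direction, a
demand block when it consumes it; blocks may overlap when one reaction sits
in several of them.  Clamping the variable at a grid of values and
re-solving the steady state each time yields the rate characteristics
(block fluxes vs clamp value), and control analysis of the clamped system
gives the total and partial response coefficients of every block flux to
the clamped variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from gsda.model import KineticModel, ModelDefinitionError, clamp as clamp_species
from gsda.steady_state import SteadyStateResult, steady_state
from gsda.moiety import MoietyRatio, set_ratio
from gsda import mca
from gsda.mca import ControlMatrices, ResponseCoefficient


Clampable = Union[str, MoietyRatio]


@dataclass(frozen=True)
class ReactionBlock:
    """A supply or demand block, named after its adjacent reaction."""

    name: str
    adjacent_reaction: str
    kind: str                       # "supply" | "demand"
    members: frozenset

    def __post_init__(self):
        assert self.kind in ("supply", "demand")
        assert self.adjacent_reaction in self.members


@dataclass
class BlockComparison:
    """Eq-style comparison of supply vs demand responses at one state.

    ``flux_control_ratio = |R_supply / R_demand|``: above 1 the demand block
    controls the flux, below 1 the supply block does.  The homeostasis index
    ``R_demand - R_supply`` grows as concentration homeostasis of the
    linking variable tightens.
    """

    supply_response: float
    demand_response: float

    @property
    def flux_control_ratio(self) -> float:
        if self.demand_response == 0.0:
            return math.inf
        return abs(self.supply_response / self.demand_response)

    @property
    def homeostasis_index(self) -> float:
        return self.demand_response - self.supply_response

    @property
    def demand_controls_flux(self) -> bool:
        return self.flux_control_ratio > 1.0


def _target_species(clamped: Clampable) -> str:
    return clamped.numerator if isinstance(clamped, MoietyRatio) else clamped


def _clamped_model_at(model: KineticModel, clamped: Clampable, value: float) -> KineticModel:
    if isinstance(clamped, MoietyRatio):
        return set_ratio(model, clamped, value)
    if model.species_by_id(clamped).role == "clamped":
        # already-clamped species: move the clamp
        from gsda.model import Species
        new = [Species(s.id, "clamped", float(value)) if s.id == clamped else s
               for s in model.species]
        return model.with_species(new, name=f"{model.name}|{clamped}={value:g}")
    return clamp_species(model, clamped, value)


def partition_blocks(
    model: KineticModel,
    clamped: Clampable,
    fluxes: Optional[Mapping[str, float]] = None,
) -> list:
    """One block per reaction stoichiometrically adjacent to the clamped entity.

    ``model`` is the clamped system (the variable, or both ratio members,
    already clamped).  Membership is stoichiometric connectivity through
    shared *variable* species of the clamped model: allosteric-only links do
    not confer membership (they surface as partial-response routes instead).
    Orientation uses the reference flux signs so reversible reactions
    classify by their operating direction.
    """
    target = _target_species(clamped)
    if target not in model.species_ids:
        raise ModelDefinitionError(f"unknown species {target!r}")
    if fluxes is None:
        fluxes = steady_state(model, raise_on_failure=True).fluxes

    adjacent = [r for r in model.reactions if target in r.stoich_map]
    if not adjacent:
        raise ModelDefinitionError(f"{target!r} has no stoichiometrically adjacent reactions")

    # reaction connectivity graph through variable species
    var = set(model.variable_ids)
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(model.reaction_ids)
    by_species: dict = {}
    for r in model.reactions:
        for sid in r.stoich_map:
            if sid in var:
                by_species.setdefault(sid, []).append(r.id)
    for rxns in by_species.values():
        for a, b in zip(rxns, rxns[1:]):
            g.add_edge(a, b)

    blocks = []
    for r in adjacent:
        coeff = float(r.stoich_map[target])
        j = fluxes.get(r.id, 0.0)
        produced = coeff * (math.copysign(1.0, j) if j != 0.0 else 1.0)
        kind = "supply" if produced > 0 else "demand"
        members = frozenset(nx.node_connected_component(g, r.id))
        blocks.append(ReactionBlock(name=r.id, adjacent_reaction=r.id,
                                    kind=kind, members=members))
    return blocks


def block_responses(
    model: KineticModel,
    clamped: Clampable,
    ss: SteadyStateResult,
    blocks: Optional[Sequence[ReactionBlock]] = None,
    cm: Optional[ControlMatrices] = None,
) -> dict:
    """Total and partial responses of every block flux to the clamped entity.

    The control coefficients are those of the *clamped* system (not of the
    full one), which is what makes the block fluxes respond as independent
    units.  Blocks at equilibrium (zero adjacent flux) get NaN scaled
    coefficients — the rate characteristic has a singularity there.
    """
    if blocks is None:
        blocks = partition_blocks(model, clamped, ss.fluxes)
    cm = cm or mca.control_coefficients(model, ss)
    out = {}
    for b in blocks:
        if ss.fluxes.get(b.adjacent_reaction, 0.0) == 0.0:
            out[b.name] = ResponseCoefficient(
                target=("flux", b.adjacent_reaction),
                parameter=getattr(clamped, "symbol", str(clamped)),
                value=math.nan, decomposition={}, factors={})
            continue
        out[b.name] = mca.response_coefficient(
            model, ss, clamped, target=("flux", b.adjacent_reaction), cm=cm)
    return out


@dataclass
class ScanRecord:
    value: float
    converged: bool
    concentrations: dict = field(default_factory=dict)
    fluxes: dict = field(default_factory=dict)
    responses: dict = field(default_factory=dict)   # block name -> ResponseCoefficient

    def block_flux(self, block: ReactionBlock) -> float:
        return self.fluxes.get(block.adjacent_reaction, math.nan)


@dataclass
class SupplyDemandScan:
    """A rate-characteristic scan of one clamped variable."""

    clamped: str                    # symbol (species id or ratio symbol)
    ref_value: float
    blocks: list
    records: list
    reference: SteadyStateResult = None

    @property
    def grid(self) -> np.ndarray:
        return np.array([p.value for p in self.records])

    def record_at(self, value: float) -> ScanRecord:
        i = int(np.argmin(np.abs(self.grid - value)))
        return self.records[i]

    @property
    def reference_record(self) -> ScanRecord:
        return self.record_at(self.ref_value)

    def block_flux_curve(self, name: str) -> np.ndarray:
        b = next(b for b in self.blocks if b.name == name)
        return np.array([p.block_flux(b) for p in self.records])

    def total_flux_curve(self, kind: str) -> np.ndarray:
        """Summed flux of all supply (or demand) blocks, counting shared
        adjacent reactions once."""
        adj = {b.adjacent_reaction for b in self.blocks if b.kind == kind}
        return np.array([
            sum(p.fluxes.get(r, math.nan) for r in sorted(adj)) for p in self.records
        ])


def rate_characteristic_scan(
    model: KineticModel,
    clamped: Clampable,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
    n_points: int = 256,
    reference: Optional[SteadyStateResult] = None,
    compute_responses: bool = True,
) -> SupplyDemandScan:
    """Scan the clamped entity over a log-spaced grid with continuation.

    ``model`` is the *full* model; the reference steady state defines the
    reference grid value (inserted exactly) and the default range of two
    decades either side.  The solver walks outward from the reference point
    in both directions, seeding each solve with the neighbouring solution —
    initial guesses are best near the physiological state.  Non-converged
    points are flagged, never dropped.
    """
    if isinstance(clamped, MoietyRatio):
        if reference is None:
            ref_model = set_ratio(model, clamped, clamped.value)
            reference = steady_state(ref_model, raise_on_failure=True)
        ref_value = clamped.value
        symbol = clamped.symbol
    else:
        if reference is None:
            reference = steady_state(model, raise_on_failure=True)
        ref_value = reference.concentrations[clamped]
        symbol = clamped
    if ref_value <= 0:
        raise ModelDefinitionError(f"reference value of {symbol} must be positive")
    lo = lo if lo is not None else ref_value / 100.0
    hi = hi if hi is not None else ref_value * 100.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    grid = np.geomspace(lo, hi, n_points)
    grid = np.unique(np.concatenate([grid, [ref_value]]))

    ref_clamped_model = _clamped_model_at(model, clamped, ref_value)
    ref_ss = steady_state(ref_clamped_model, init=reference.concentrations,
                          raise_on_failure=True)
    blocks = partition_blocks(ref_clamped_model, clamped, ref_ss.fluxes)

    records = [None] * len(grid)
    i_ref = int(np.argmin(np.abs(grid - ref_value)))

    def solve_point(i, guess):
        value = float(grid[i])
        m = _clamped_model_at(model, clamped, value)
        try:
            ss = steady_state(m, init=guess)
        except Exception:
            records[i] = ScanRecord(value=value, converged=False)
            return guess
        if not ss.converged:
            records[i] = ScanRecord(value=value, converged=False)
            return guess
        responses = {}
        if compute_responses:
            try:
                responses = block_responses(m, clamped, ss, blocks=blocks)
            except mca.SingularJacobianError:
                responses = {}
        records[i] = ScanRecord(value=value, converged=True,
                                concentrations=dict(ss.concentrations),
                                fluxes=dict(ss.fluxes), responses=responses)
        return ss.concentrations

    guess = solve_point(i_ref, reference.concentrations)
    up = guess
    for i in range(i_ref + 1, len(grid)):
        up = solve_point(i, up)
    down = guess
    for i in range(i_ref - 1, -1, -1):
        down = solve_point(i, down)

    return SupplyDemandScan(clamped=symbol, ref_value=float(ref_value),
                            blocks=blocks, records=records, reference=reference)


def compare_block_responses(
    blocks: Sequence[ReactionBlock],
    responses: Mapping[str, ResponseCoefficient],
    fluxes: Mapping[str, float],
) -> dict:
    """Per-pair and aggregated supply/demand comparisons.

    Aggregation is flux-weighted: for the lumped supply flux
    ``J = sum_b J_b``, ``dlnJ/dlnp = sum_b (J_b/J) dlnJ_b/dlnp``.
    """
    sup = [b for b in blocks if b.kind == "supply"]
    dem = [b for b in blocks if b.kind == "demand"]

    def agg(bs):
        J = sum(fluxes[b.adjacent_reaction] for b in bs)
        if J == 0:
            return math.nan
        return sum(
            fluxes[b.adjacent_reaction] / J * responses[b.name].value for b in bs
        )

    out = {}
    for s in sup:
        for d in dem:
            out[(s.name, d.name)] = BlockComparison(
                supply_response=responses[s.name].value,
                demand_response=responses[d.name].value,
            )
    if sup and dem:
        out["aggregate"] = BlockComparison(supply_response=agg(sup),
                                           demand_response=agg(dem))
    return out


def compare_blocks(scan: SupplyDemandScan, at_value: Optional[float] = None) -> dict:
    """Block comparison at a scan point (default: the reference point)."""
    rec = scan.record_at(scan.ref_value if at_value is None else at_value)
    if not rec.converged or not rec.responses:
        raise ValueError(f"no converged responses at scan value {rec.value}")
    return compare_block_responses(scan.blocks, rec.responses, rec.fluxes)
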