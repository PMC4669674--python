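"""Regulatory-route shares and enzyme knockouts.

A block's total response to its linking variable decomposes into partial
responses, one per route of direct interaction.  When a route runs through a
mediator metabolite (an allosteric inhibitor produced inside another block),
the share of regulation carried by one reaction on the far side of the
mediator is the product of two fractions: the fraction of the primary
response carried by the route's first leg, times the fraction of the
mediator-block response carried by the specific reaction, expressed as a
percentage::

    chi = (sum of stage-1 partials / total primary response)
        * (sum of stage-2 partials / stage-2 denominator group) * 100

Routes declared over an exhaustive, disjoint grouping of the primary
partials sum to 100 %.  Knockouts are parameter substitutions (enzyme
concentration or maximal rate set to zero) after which every analysis runs
unchanged on the modified model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from gsda.model import KineticModel, ModelDefinitionError
from gsda.steady_state import steady_state
from gsda.mca import ResponseCoefficient
from gsda import blocks as _blocks


@dataclass(frozen=True)
class KnockoutSpec:
    """Replace one parameter (typically an enzyme concentration) by ``value``."""

    parameter: str
    value: float = 0.0


@dataclass
class RouteShare:
    """One regulatory route's percentage share of a block's regulation."""

    name: str
    target_block: str
    stage1_group: tuple
    stage2_group: tuple
    chi: float                      # signed percentage
    stage1_fraction: float
    stage2_fraction: float

    @property
    def chi_abs(self) -> float:
        return abs(self.chi)


def route_share(
    primary: ResponseCoefficient,
    group1: Sequence[str],
    mediator: Optional[ResponseCoefficient] = None,
    group2: Optional[Sequence[str]] = None,
    denominator_group: Optional[Sequence[str]] = None,
    name: str = "route",
    strict: bool = True,
) -> RouteShare:
    """Compose a route share from a primary and (optionally) a mediator response.

    ``group1`` names partials of ``primary``; ``group2`` and
    ``denominator_group`` name partials of ``mediator`` (the denominator
    defaults to ``group2``, and omitting the mediator entirely gives an
    identity second stage).  Only partials that pass through the target
    block belong in the denominator group — not the mediator's full
    response.
    """
    if primary.value == 0.0 or math.isnan(primary.value):
        raise ValueError("total primary response is zero/undefined; share undefined")
    if strict:
        for g in group1:
            if g not in primary.decomposition:
                raise KeyError(f"{g!r} is not a partial of the primary response")
    f1 = primary.partial_sum(group1) / primary.value

    if mediator is None:
        f2 = 1.0
        group2 = tuple()
    else:
        if not group2:
            raise ValueError("mediator stage needs a nonempty numerator group")
        den_group = denominator_group if denominator_group is not None else group2
        if strict:
            for g in list(group2) + list(den_group):
                if g not in mediator.decomposition:
                    raise KeyError(f"{g!r} is not a partial of the mediator response")
        den = mediator.partial_sum(den_group)
        if den == 0.0:
            raise ValueError("mediator denominator group sums to zero")
        f2 = mediator.partial_sum(group2) / den
    return RouteShare(
        name=name,
        target_block=primary.target[1],
        stage1_group=tuple(group1),
        stage2_group=tuple(group2),
        chi=f1 * f2 * 100.0,
        stage1_fraction=f1,
        stage2_fraction=f2,
    )


def route_map(
    model: KineticModel,
    clamped: str,
    target_block: str,
    config: Mapping,
    reference=None,
) -> list:
    """Full route decomposition of one block's regulation by ``clamped``.

    ``config`` declares the analyst's grouping (automated discovery of
    mediator groupings is out of scope)::

        {
          "mediators": {"Thr": {"species": "Thr", "block": "R9"}},
          "routes": [
            {"name": "direct",  "stage1": ["R5"]},
            {"name": "via_R1",  "stage1": ["R6", "R7"], "mediator": "Thr",
             "numerator": ["R1"], "denominator": ["R1", "R2"]},
            ...
          ],
        }

    Stage-1 groups must partition the primary response's partials exactly
    (no overlaps, nothing left over), which guarantees the shares of routes
    with a common denominator group sum to 100 %.
    """
    if reference is None:
        reference = steady_state(model, raise_on_failure=True)

    def clamped_analysis(species):
        m = _blocks._clamped_model_at(model, species,
                                      reference.concentrations[species])
        ss = steady_state(m, init=reference.concentrations, raise_on_failure=True)
        return _blocks.block_responses(m, species, ss), ss

    primary_responses, _ = clamped_analysis(clamped)
    if target_block not in primary_responses:
        raise KeyError(f"{target_block!r} is not a block of {clamped!r}")
    primary = primary_responses[target_block]

    mediator_resp = {}
    for mname, mspec in config.get("mediators", {}).items():
        resp, med_ss = clamped_analysis(mspec["species"])
        block_names = mspec.get("blocks") or [mspec["block"]]
        if len(block_names) == 1:
            mediator_resp[mname] = resp[block_names[0]]
        else:
            # several mediator blocks (e.g. two isoenzyme supply blocks):
            # flux-weighted aggregate response, dlnJ/dlnx of the summed flux
            J = {b: med_ss.fluxes[resp[b].target[1]] for b in block_names}
            total_J = sum(J.values())
            if total_J == 0:
                raise ModelDefinitionError(
                    f"mediator {mname!r}: aggregated blocks carry zero flux")
            decomposition: dict = {}
            for b in block_names:
                for rxn, p in resp[b].decomposition.items():
                    decomposition[rxn] = decomposition.get(rxn, 0.0) \
                        + J[b] / total_J * p
            mediator_resp[mname] = ResponseCoefficient(
                target=("flux", "+".join(block_names)),
                parameter=resp[block_names[0]].parameter,
                value=float(sum(decomposition.values())),
                decomposition=decomposition,
            )

    # routes must partition the regulation: distinct stage-1 groups are
    # disjoint and exhaustive, and routes sharing a stage-1 group must split
    # a common denominator group with disjoint, exhaustive numerators
    by_group: dict = {}
    for route in config["routes"]:
        by_group.setdefault(frozenset(route["stage1"]), []).append(route)
    seen: dict = {}
    for group, routes_in in by_group.items():
        for g in group:
            if g in seen:
                raise ModelDefinitionError(
                    f"partial {g!r} appears in two different stage-1 groups; "
                    f"routes must partition the partials")
            seen[g] = True
        if len(routes_in) > 1 or routes_in[0].get("mediator"):
            dens = {tuple(r.get("denominator") or r.get("numerator") or ())
                    for r in routes_in}
            if len(dens) != 1:
                raise ModelDefinitionError(
                    f"routes over stage-1 group {sorted(group)} must share one "
                    f"denominator group")
            den = set(dens.pop())
            nums: list = []
            for r in routes_in:
                for g in r.get("numerator") or ():
                    if g in nums:
                        raise ModelDefinitionError(
                            f"stage-2 partial {g!r} assigned to two routes")
                    nums.append(g)
            if set(nums) != den:
                raise ModelDefinitionError(
                    f"stage-2 numerators {sorted(nums)} must partition the "
                    f"denominator group {sorted(den)}")
    leftover = set(primary.decomposition) - set(seen)
    if leftover:
        raise ModelDefinitionError(
            f"primary partials not assigned to any route: {sorted(leftover)}")

    shares = []
    for route in config["routes"]:
        med = mediator_resp.get(route.get("mediator"))
        shares.append(route_share(
            primary,
            route["stage1"],
            strict=False,  # knockouts legitimately zero whole partials
            mediator=med,
            group2=route.get("numerator"),
            denominator_group=route.get("denominator"),
            name=route["name"],
        ))
    return shares


def apply_knockout(model: KineticModel, spec: KnockoutSpec) -> KineticModel:
    """Model with the knockout applied; downstream analyses run unchanged."""
    if spec.parameter not in model.parameters:
        raise ModelDefinitionError(f"unknown parameter {spec.parameter!r}")
    return model.with_parameters({spec.parameter: float(spec.value)},
                                 name=f"{model.name}|{spec.parameter}={spec.value:g}")
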