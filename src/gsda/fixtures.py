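"""Self-contained test models: linear supply-demand chains and a toy
moiety-conserved cycle.

These generators embody the schematic systems every engine feature is
exercised on: a linear pathway X0 ->1 S1 ->2 P ->3 S2 ->4 X1 (optionally
with allosteric feedback on the first enzyme from the central intermediate
or from a downstream one), and a two-branch model coupled through a
two-member conserved pair.  Kinetics are reversible mass action
``v_i = k_i (s - p/q_i)`` with ``k = (10, 5, 5, 10)`` and an equilibrium
constant of 10 per step; allosteric feedback multiplies the rate by
``1/(1 + (I/K_i)^h)`` with a Hill coefficient of 4 and ``K_i = 1``.  The
boundary concentrations (X0 = 1, X1 = 0.0001) put the supply side of the
central intermediate close to equilibrium and the demand side far from it,
which gives the demand block the larger share of flux control at the
reference state — the classic supply-demand design.  All values are
overridable through :class:`FixtureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from gsda.model import KineticModel, Reaction, Species


@dataclass
class FixtureConfig:
    chain_length: int = 4
    kinetics: str = "mass_action"           # mass_action | reversible_mm
    feedback: str = "none"                   # none | product_on_first | internal_on_first
    feedback_strength: float = 1.0           # inhibition constant K_i
    hill: int = 4
    x0: float = 1.0
    x1: float = 1e-4
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")
        if self.kinetics not in ("mass_action", "reversible_mm"):
            raise ValueError(f"unknown kinetics {self.kinetics!r}")
        if self.feedback not in ("none", "product_on_first", "internal_on_first"):
            raise ValueError(f"unknown feedback {self.feedback!r}")


def _species_names(n: int) -> list:
    """Intermediate names for an n-reaction chain; the middle one is P."""
    inner = n - 1
    mid = inner // 2
    names = []
    s = 0
    for i in range(inner):
        if i == mid:
            names.append("P")
        else:
            s += 1
            names.append(f"S{s}")
    return names


def linear_pathway(config: Optional[FixtureConfig] = None) -> KineticModel:
    """The linear supply-demand chain, optionally with feedback on enzyme 1.

    ``product_on_first`` adds inhibition of reaction 1 by the central
    intermediate P (a second *direct* route between P and its supply block);
    ``internal_on_first`` adds inhibition of reaction 1 by the intermediate
    downstream of P (an *indirect* route transmitted through the demand
    block).
    """
    cfg = config or FixtureConfig()
    n = cfg.chain_length
    inner = _species_names(n)
    chain = ["X0"] + inner + ["X1"]

    k_default = {i: (10.0 if i in (1, n) else 5.0) for i in range(1, n + 1)}
    params = {}
    for i in range(1, n + 1):
        params[f"k{i}"] = k_default[i]
        params[f"q{i}"] = 10.0
    if cfg.feedback != "none":
        params["Ki"] = cfg.feedback_strength
        params["h"] = float(cfg.hill)
    params.update(cfg.parameters)

    species = [Species("X0", "clamped", cfg.x0)]
    for name in inner:
        species.append(Species(name, "variable", 1.0))
    species.append(Species("X1", "clamped", cfg.x1))

    if cfg.feedback == "product_on_first":
        inhibitor = "P"
    elif cfg.feedback == "internal_on_first":
        # first intermediate downstream of P (S2 in the 4-step chain)
        idx = chain.index("P")
        inhibitor = chain[idx + 1]
        if inhibitor == "X1":
            raise ValueError("chain too short for internal feedback downstream of P")
    else:
        inhibitor = None

    reactions = []
    for i in range(1, n + 1):
        s, p = chain[i - 1], chain[i]
        if cfg.kinetics == "mass_action":
            rate = f"k{i}*({s} - {p}/q{i})"
        else:
            rate = f"k{i}*({s} - {p}/q{i})/(1 + {s} + {p})"
        if i == 1 and inhibitor is not None:
            rate = f"({rate})/(1 + ({inhibitor}/Ki)**h)"
        reactions.append(Reaction.create(f"R{i}", {s: -1, p: 1}, rate))

    name = f"chain{n}_{cfg.kinetics}_{cfg.feedback}"
    return KineticModel(species, params, reactions, name=name)


def isoenzyme_feedback_model() -> KineticModel:
    """A miniature pathway with two feedback-inhibited isoenzymes.

    Two isoenzymes R1 and R2 (enzyme-concentration parameters ``e1``, ``e2``)
    convert X0 to B; R3 makes the hub metabolite A; the demand side R4
    converts A to the end product T, which drains through R5 and
    allosterically inhibits both isoenzymes with different strengths.  The
    hub A therefore regulates its own supply block through two routes: the
    direct product route via R3 and an indirect route via its demand block
    (A -> T -> isoenzyme inhibition), which splits over R1 and R2 exactly as
    mediator routes split over aspartate-kinase isoenzymes in plant amino
    acid synthesis.  Knock an isoenzyme out by setting ``e1`` or ``e2`` to 0.
    """
    species = [
        Species("X0", "clamped", 1.0),
        Species("B", "variable", 1.0),
        Species("A", "variable", 1.0),
        Species("T", "variable", 1.0),
        Species("X1", "clamped", 0.01),
    ]
    params = {
        "e1": 1.0, "k1": 2.0, "Ki1": 0.5,
        "e2": 1.0, "k2": 4.0, "Ki2": 1.5,
        "k3": 5.0, "k4": 5.0, "k5": 10.0,
        "q": 10.0, "h": 2.0,
    }
    reactions = [
        Reaction.create("R1", {"X0": -1, "B": 1},
                        "e1*k1*(X0 - B/q)/(1 + (T/Ki1)**h)"),
        Reaction.create("R2", {"X0": -1, "B": 1},
                        "e2*k2*(X0 - B/q)/(1 + (T/Ki2)**h)"),
        Reaction.create("R3", {"B": -1, "A": 1}, "k3*(B - A/q)"),
        Reaction.create("R4", {"A": -1, "T": 1}, "k4*(A - T/q)"),
        Reaction.create("R5", {"T": -1, "X1": 1}, "k5*(T - X1/q)"),
    ]
    return KineticModel(species, params, reactions, name="isoenzyme_feedback")


def toy_moiety_model() -> KineticModel:
    """Two pathway branches coupled by a conserved pair M/Mp.

    R1 phosphorylates the moiety while converting A to B, R2 drains B, and
    R3 recycles M back to Mp on an independent branch — so M + Mp is
    conserved (one (1,1) conservation row) and the two branches communicate
    only through the cycle.  Used as the oracle fixture for ratio-variable
    analyses.
    """
    species = [
        Species("A", "clamped", 2.0),
        Species("B", "variable", 1.0),
        Species("C", "clamped", 0.1),
        Species("D", "clamped", 1.0),
        Species("E", "clamped", 0.1),
        Species("M", "variable", 1.0),
        Species("Mp", "variable", 1.0),
    ]
    params = {"k1": 10.0, "k2": 5.0, "k3": 8.0, "q1": 10.0, "q2": 10.0, "q3": 10.0}
    reactions = [
        Reaction.create("R1", {"A": -1, "Mp": -1, "B": 1, "M": 1},
                        "k1*(A*Mp - B*M/q1)"),
        Reaction.create("R2", {"B": -1, "C": 1}, "k2*(B - C/q2)"),
        Reaction.create("R3", {"D": -1, "M": -1, "E": 1, "Mp": 1},
                        "k3*(D*M - E*Mp/q3)"),
    ]
    return KineticModel(species, params, reactions, name="toy_moiety")
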