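# Methods

## Scope and procedure

`gsda` implements generalised supply-demand analysis of kinetic metabolic
models. The procedure for one linking variable `p` (a metabolite
concentration or a moiety ratio) is:

1. Solve the full model's steady state (the *reference* state).
2. Clamp `p` at its reference value; the clamped system partitions into one
   reaction block per reaction stoichiometrically adjacent to `p`, each
   named after that reaction. A block is *supply* if its adjacent reaction
   produces `p` at the reference flux direction, *demand* if it consumes
   it. Membership is stoichiometric connectivity through shared variable
   species of the clamped model; reactions may belong to several blocks.
3. Scan `p` over a log-spaced grid, re-solving the clamped steady state at
   every point (continuation outward from the reference point). The block
   fluxes versus `p` are the rate characteristics.
4. At each converged point, compute the control coefficients of the
   *clamped* system and the elasticities toward `p`, and assemble total and
   partial response coefficients `R^{J_b}_p = Σᵢ C^{J_b}_{vᵢ} ε^{vᵢ}_p`.
5. Optionally compose route shares: the percentage of one block's
   regulation carried through a declared chain of partial responses,
   possibly crossing a mediator metabolite analysed by its own clamping.

Assumptions: deterministic continuous kinetics (ODEs), a unique
asymptotically stable steady state in the scanned region, rate laws that
are differentiable at positive concentrations, and time-scale separation
such that clamped species can be treated as parameters.

## Stoichiometric structure

Conservation analysis is done in exact rational arithmetic (sympy over
`Fraction` stoichiometries): the conservation matrix `G` spans the left
null space of the stoichiometric matrix `N` with `G·N = 0` *exactly*, rows
normalised to smallest-integer form with positive leading entry. Floating
SVD would identify moieties only up to round-off and non-reproducibly. The
link matrix `L` (with `N = L·N_r`) maps the independent species — chosen as
the first maximal independent row set in declaration order — to all
variable species, so every solver iterate satisfies the conserved totals
identically.

## Steady-state solver

The reduced system `N_r·v(s) = 0` is solved by a damped Newton iteration
from the initial guess; if that fails, the reduced ODEs are integrated
(LSODA, suited to stiff branched pathways) over geometrically growing
horizons until the time derivative is small (relative norm < 1e-6), then
Newton-polished. Newton steps are damped (halving, up to 60 times) to keep
all concentrations strictly positive, because rate laws may be undefined
at negative values. Defaults: residual `max|N_r·v| ≤ 1e-9` relative to the
mean `|v|`, at most 100 Newton steps, integration horizon up to 1e9 time
units. Non-convergence is reported in the result object (or raised on
request), never silently; the condition number of the reduced Jacobian is
always attached. The solver has no randomness.

## Coefficients

Elasticities are computed symbolically (closed-form differentiation of the
rate law, compiled once per model and reused across scan points) with a
numeric fallback and cross-check: central differences with relative step
1e-5 in log space. A reaction with zero rate at the evaluation state gets
a NaN elasticity flagged "near equilibrium" — the scaled coefficient
genuinely diverges there — except when the rate is *identically* zero
(e.g. a knocked-out enzyme, where the derivative also vanishes), which is
reported as 0.

Control coefficients use the structural method: unscaled concentration
control `−L (N_r E L)⁻¹ N_r` with `E = ∂v/∂s`, unscaled flux control
`I + E·C_s`, then scaling by fluxes/concentrations. Rows with zero
reference flux are left unscaled and flagged (block fluxes cross zero
inside scans). Inversion is refused when the reduced Jacobian's condition
number exceeds 1e12 — above that the coefficients would be noise.
Summation-theorem residuals (flux rows sum to 1, concentration rows to 0)
are recorded on every call. The connectivity check uses the link-folded
form `C·E·L = 0`: with conservation, perturbing an independent species
drags its cycle partners along, so raw single-species connectivity sums do
not vanish and would be the wrong test.

Responses to a parameter are `Σᵢ C·ε` over the directly sensitive
reactions, with the decomposition retained per reaction. An independent
re-solve oracle (central difference over a multiplicative parameter
perturbation, default relative step 1e-3) is used in tests; the step is
chosen so that O(h²) truncation (~1e-6) stays above steady-state solver
noise (~1e-9 relative) — a much smaller step would measure solver noise,
not the derivative.

## Moiety ratios

Only two-member, coefficient-(1,1) cycles are exposed as ratio variables;
that covers the cofactor pairs this analysis targets (ATP/ADP, NADH/NAD⁺,
acetyl-CoA/CoA), and anything more general raises an error rather than
producing an ill-defined scan. The conserved total is frozen at the
reference state (conservation makes initial-state and steady-state totals
identical). Member reconstruction computes the denominator as `C/(1+φ)`
and the numerator as `C` minus it, so the members sum to the total exactly
in floating point. The ratio elasticity follows from differentiating the
reconstruction: `ε_φ = ε_num/(1+φ) − ε_den·φ/(1+φ)`. Supply/demand
orientation of a block with respect to a ratio uses the stoichiometric
sign of the *numerator* species.

## Scans

Default grid: two decades either side of the reference value, 256 points,
with the reference value inserted as an exact grid point (published
case-study ranges are wider and asymmetric and are passed explicitly).
Continuation runs outward from the reference point in both directions,
seeding each solve with the neighbouring solution — initial guesses are
best near the physiological state. Non-converged points are flagged rows
in the output, never dropped. Block flux is defined as the rate of the
block's adjacent reaction in the clamped steady state (that is what rate
characteristics plot); overlapping membership affects reporting only.
Plots show `|J|` on log-log axes with sign-change markers, since block
fluxes can pass through zero (a block crossing its internal equilibrium).

## Route shares

A route share is the product of two fractions times 100: the fraction of
the primary block response carried by the route's first leg, and the
fraction of the mediator-block response carried by the specific reaction.
The second-stage denominator contains only the partials that pass through
the target block, not the mediator's full response — using the full
response would mix in routes that never reach the block being decomposed.
Routes must partition the primary partials (disjoint, exhaustive stage-1
groups; stage-2 numerators partitioning their denominator), which makes
the shares sum to 100 % identically. Shares are reported signed, with an
absolute-value variant; when all stage fractions share a sign the two
coincide. Mediators with several supply blocks are aggregated
flux-weighted (`d ln ΣJ = Σ (J_b/ΣJ) d ln J_b`). Route groupings are
declared by the analyst (YAML/dict config); automated discovery of
groupings is out of scope.

## Fixture models

The generators in `gsda.fixtures` provide the study conditions for the
self-contained tests:

- `linear_pathway`: X0 →1 S1 →2 P →3 S2 →4 X1 with reversible mass action
  `vᵢ = kᵢ(s − p/qᵢ)`, `k = (10, 5, 5, 10)`, equilibrium constant 10 per
  step, and optional allosteric inhibition of reaction 1 by P (a second
  direct route) or by S2 (an indirect route through the demand block),
  factor `1/(1 + (I/Kᵢ)^h)` with `h = 4`, `Kᵢ = 1`. Boundaries `X0 = 1`,
  `X1 = 1e-4` keep the net drive forward. With purely mass-action (log-
  linear) kinetics the supply/demand response ratio is scale-invariant —
  for these rate constants |R_supply/R_demand| ≈ 0.0175, i.e. the supply
  block holds flux control; the feedback variants steepen the supply
  response past the demand response (ratio ≈ 1.75 for product feedback)
  and shift control to demand. The pair therefore brackets both regimes
  of the supply-demand design principle.
- `toy_moiety_model`: two branches coupled only through a conserved pair
  M/Mp — the minimal system with one (1,1) conservation row, used as the
  oracle for every ratio-variable computation.
- `isoenzyme_feedback_model`: two differently-sensitive, end-product-
  inhibited isoenzymes upstream of a hub metabolite, with enzyme-
  concentration parameters (`e1`, `e2`) for knockouts — the minimal system
  with mediator-crossing regulatory routes.

What the fixtures do *not* emulate: saturable Michaelis-Menten kinetics
with measured parameters, multiple interacting conservation cycles,
branch-point competition for a shared substrate at physiological flux
ratios, and the specific numbers of the published case-study models.
Passing fixture tests therefore demonstrates correctness of the machinery
(theorem closure, oracle agreement, qualitative layouts), not agreement
with any particular organism's kinetics; the case-study tests cover the
latter and require the published SBML files (see `models/README.md`).

## Known limitations

- SBML support covers the ODE core: kinetic laws, global/local parameters,
  boundary/constant species, function definitions, one common compartment
  size. Rules, events, constraints, initial assignments, piecewise math,
  time/delay symbols and multi-compartment variable species raise explicit
  unsupported-feature errors.
- Scans assume the steady-state branch varies continuously with the
  clamped value; bistable regions would follow one branch (the one
  continued from the reference state) without detecting the other.
- Three-or-more-member conserved cycles cannot be scanned as a single
  variable.
- No parameter estimation, stochastic simulation, or time-course analysis
  beyond reaching stationarity.
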