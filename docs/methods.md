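# Methods

## The formalism

A model is a typed graph: physical *entities* (optionally grouped by
`part_of` into a forest, and optionally participating in *processes*) bear
*property instances*, each typed by a property class — one cell of the
domain × category analogy table.  Categories split into states (amount,
momentum), rates (force, flow) and constitutive proportionalities
(resistance, conductance, capacitance, inductance, rate constant, modulus,
coefficient).  *Dependency instances* are occurrences of law classes that
bind property instances to named roles; *sources* prescribe driving
forces/flows as boundary conditions.

The registered law classes and their residual equations (canonical units,
t = time):

| kind             | equation                                        | output |
|------------------|--------------------------------------------------|--------|
| boundary_flow    | d(amount)/dt = Σ inflow − Σ outflow              | state derivative |
| boundary_force   | d(momentum)/dt = Σ force_high − Σ force_low      | state derivative |
| summation        | whole = Σ parts                                  | whole |
| spatial          | derived = a·primary^b                            | derived |
| resistive        | flow = (force_high − force_low)/R                | flow |
| mass_action      | flow = k_f·Π fwd^s − k_r·Π rev^s                 | flow |
| diffusion        | flow = k_d·(amount_src − amount_tgt)             | flow |
| michaelis_menten | flow = V_max·amount/(K_m + amount)               | flow |
| transformer      | force₂ = m·force₁ ; flow₁ = m·flow₂              | two coupled outputs |
| transducer       | same, sides in two distinct domains              | two coupled outputs |
| capacitive       | force = amount/C                                 | force |
| inductive        | flow = momentum/L                                | flow |
| transactor       | target = c·source                                | target |

Sign convention, fixed once and enforced by tests: positive flow runs from
the high force player to the low one (and from the source side to the target
side of amount-driven laws).  Inductive storage is factored as
`flow = momentum/L` plus a separate boundary_force dependency accumulating
the momentum — the standard network-thermodynamics decomposition, and the
only way the inductive storage row is realizable in an explicit ODE
formalism.  Diffusion is driven by an *amount* difference; concentration
gradients are expressible by composing spatial maps.  Conductance is
accepted as a constitutive player and normalized to R = 1/G at compile time.

Role names are this package's concrete vocabulary (the conceptual schema
underdetermines them): boundary_flow distinguishes `inflow`/`outflow`,
boundary_force uses high/low force players, and couplers use side-indexed
roles (`force_player_1`, `flow_player_2`, ...).  The RDF exporter maps all
flow-ish roles to `hasFlowPlayer` and all force-ish roles to
`hasForcePlayer`, so a resistive instance carries exactly one flow-player,
two force-player and one constitutive-proportionality triple.

Michaelis–Menten is deliberately parameterized by two dependency params
(`v_max`, `k_m`) rather than a constitutive property instance: it is a
non-proportional law with a coefficient *pair*, not a single
proportionality.  It is the only sanctioned non-proportional kind; gating
conductances and shear-dependent viscosities are out of scope.

## Domains, units, analogies

Four domains are built in, with canonical units: electrical (V, A, C, Wb),
fluid (Pa, m³/s, m³, Pa·s), chemical (J/mol, mol/s, mol — no momentum row:
there is no accepted chemical inertial analogue, and the taxonomy declares
the cell absent rather than zero), mechanical (N, m/s, m, N·s).
Constitutive units are derived from the defining quotients and verified by a
small symbolic dimension algebra (e.g. mechanical inductance
`(N·s)/(m/s) ≡ kg`).  `register_domain` is the extension hook: a new domain
supplies its full unit row and inherits every law.  Only canonical units and
dimensional checking are supported — no unit conversion.

`analog_of` is the category-preserving bijection between any two domains
restricted to the categories both possess.  Its executable consequence is
tested directly: the electrical RC fixture and its fluid transpose
(`windkessel_discharge`, built by mapping every property class through
`analog_of`) produce bitwise-identical trajectories.

## Compilation

States are the amounts/momenta accumulated by boundary dependencies (ordered
by id; each must carry an initial value).  Causality is fixed per kind —
capacitive → force, inductive/resistive/amount-driven → flow, summation →
whole, spatial/transactor → target, transformer → (force₂, flow₁) — and
every non-state, non-source, non-parameter property must be computed exactly
once (`E_OVERDETERMINED`/`E_UNDERDETERMINED` otherwise).  The algebraic
steps are scheduled per *(dependency, output)* pair — so a transformer's two
outputs can straddle other computations — by lexicographic topological sort
(deterministic; ties broken by dependency id).  Cycles raise
`E_ALGEBRAIC_LOOP` with the offending dependency ids: algebraic loops are
rejected, not solved, because every storage-causal lumped network schedules
explicitly and an implicit nonlinear solver would only mask modelling
errors.  A purely resistive loop cannot even arise under fixed resistive
causality; storage-free cycles appear through feedback kinds (transactors,
couplers) and are detected there.  Transformer causality is fixed (inputs
force₁, flow₂); networks needing the reverse orientation swap their sides in
the model file.

Properties with a set value that are neither states, sources nor
constitutive can be marked `fixed: true` (held-constant boundary values,
e.g. the part volumes of a summation); unset unfixed properties still fail
compilation loudly.

## Numerics

Fixed-step classical RK4, chosen over adaptive solvers for bit-stable,
test-friendly trajectories; the integrator seam (`integrate(sys, t_end,
dt)`) accepts any compiled system, so an adaptive backend can be plugged in
later.  Consequences used by the test suite: global error is O(dt⁴) (the
error ratio per dt halving on the RC problem sits in [12, 20]); linear
constant-force systems (the f = ma fixture) are reproduced to round-off;
a closed two-compartment network conserves total amount to < 1e−12 relative
over 10⁴ steps because the shared flux enters the two derivatives with
exactly opposite signs; the LC oscillator drifts in energy by < 1e−6
relative over ten periods at dt = period/1000.

`steady_state` integrates (default dt = t_max/10⁴) until the max-norm of the
state derivative falls below `tol`; it requires constant sources, returns
every property's converged value, and raises `E_NO_STEADY_STATE` at `t_max`
(the undamped LC case).  For linear relaxations the discrete fixed point
coincides with the exact equilibrium, so the Windkessel steady state matches
Q0·R / C·Q0·R far tighter than the integrator's trajectory accuracy.

Negative amounts are not clamped: the mass-action law raises
`E_NEGATIVE_STATE` below a −1e−9 round-off allowance, surfacing instability
instead of masking it.  Non-finite states raise `E_DIVERGED` with the time.

## Qualitative semantics

The influence graph contains the dynamical properties only; edge signs
follow the causal law forms (force_high→flow +, force_low→flow −,
amount→force +, inflow→amount +, coefficient-signed transactor edges, ...).
Constitutive parameters are excluded as nodes: their influence sign depends
on the operating point (∂flow/∂R = −Δforce/R²), which sign algebra cannot
rank; numeric parameter perturbations remain available through
`check_against_numeric`.

`propagate` computes, for every node, the sign-sum over all *simple* paths
from the perturbed node, by DFS (exponential worst case, negligible at model
scale).  Two candidate semantics were considered for feedback cycles: naive
Kleene iteration marks every node inside a negative feedback loop `?`
(the loop feeds the opposite sign back), which degenerates on the simplest
RC loop; simple-path summation ignores re-entrant loop terms — justified
because in a stable system a negative loop attenuates but cannot invert the
direct effect — and reduces to the same answer on DAGs.  Simple-path
summation was chosen.  It is conservative, not omniscient: a flow that rises
transiently but re-equilibrates to zero (the RC charging current) is
reported `+` against a numeric steady-state `0` — classified as an
*overestimate*, distinct from a contradiction.  The soundness property the
suite enforces is: a propagated `+`/`−` never strictly opposes the numeric
sign; `?` agrees conservatively with anything.  Up/down antisymmetry holds
by construction.

## Fixtures as study conditions

The named fixtures define the conditions everything is tested under:
`rc_circuit(R=2, C=0.5, E0=1, q0=0)` (τ = RC = 1); `windkessel(R=1, C=1,
Q0=1, V0=0)`; `windkessel_discharge` = fluid transpose of the RC model;
`lc_oscillator(L=1, C=1, q0=1)` (period 2π); `mass_action_pair(k_f=2,
k_r=1, A0=1, B0=2)`, whose defaults sit exactly at detailed balance;
`chemo_mech_transducer(m=2, mu0=1, R_load=1)`; `baroreflex_toy(c=−0.5,
P0=1)`; `multiscale_sum([1, 2, 3])`.  Parameters of order one were chosen so
every characteristic time is O(1) and integration horizons stay short; they
are round numbers fixed in the generators, not tuned quantities.
`randomized_network(seed, n_storage, n_resistive)` grows a random
single-domain capacitive tree (a spanning tree of resistive connectors, then
parallel extras up to max(n_resistive, n_storage−1), plus one sourced feed)
— loop-free by construction, hence always compilable, and bit-reproducible
per seed.

What the fixtures emulate — and what they do not: they exercise every law
kind, cross-domain coupling, conservation, and feedback, but they are small
(≤ ~30 properties), single-rate, non-stiff and noise-free.  Passing tests
demonstrate correctness of the formalism and its numerics under those
conditions; they say nothing about stiff physiological parameter regimes,
measurement noise, or structural misspecification of real models.

## Problem sizes

The default suite integrates at most 10⁴ steps per test, uses 200 randomized
seeds for the compiler sweep and 1000 random draws per law-level invariant;
the acceptance script uses 100 randomized networks and the same fixture
horizons.  These sizes make every property decisively measurable (errors are
checked at 1e−6…1e−12, orders of magnitude below the tolerances) while the
whole suite completes in well under a minute.

## Known limitations

- No DAE support, implicit loops, events, stiff detection or sensitivity
  analysis; no parameter fitting.
- Transformer causality is one-directional; no bond-graph causality search.
- The qualitative layer ranks no magnitudes and models no transients
  (steady-state sign semantics only).
- Placeholder `urn:` IRIs in the RDF export are intentionally
  non-resolvable; mapping to a published vocabulary is the user's
  responsibility via `--iri-map`.
- Validation treats a transactor crossing domains as a warning, not an
  error — wild cards are allowed to bridge anything, but the modeller is
  told.
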