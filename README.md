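# opbnet

Executable physical-dependency networks for lumped-parameter biophysics.

Physiological models — hemodynamics, reaction kinetics, muscle mechanics,
electrophysiology — are almost always built from the same small stock of
physical laws: Ohm-type resistive flow, Hooke-type capacitive storage,
inertial (inductive) storage, mass-action and diffusion rate laws,
transformer/transducer couplings, accumulation ("boundary") laws, and
proportional "transactor" wild cards for mechanisms that are unknown or
thermodynamically negligible (e.g. the baroreceptor reflex).  System-dynamics
theory makes these laws domain-portable through the effort/flow analogy:
every biophysical domain has a generalized *force* (voltage, pressure,
chemical potential, mechanical force), *flow* (current, volume flow rate,
molar flux, velocity), *amount* (charge, volume, molar amount, displacement)
and, where inertia exists, *momentum*.

`opbnet` makes that conceptual scheme executable.  It is written for
modellers and knowledge engineers who want to author a model as a typed
network of entities, properties and law instances — rather than as raw
equations — and then validate, simulate, interrogate and semantically export
it:

- **taxonomy** — the four built-in domains (electrical, fluid, chemical,
  mechanical), property categories, cross-domain analogy maps, and canonical
  units with dimensional checking (e.g. `unit(inductance) =
  unit(momentum)/unit(flow)`; mechanical inductance reduces to kg).
- **network** — assemble entities/processes bearing property instances and
  dependency instances that bind properties to named roles; validate role
  signatures, domain rules, and parameter positivity.
- **laws** — the executable law library: `flow = Δforce/R`,
  `force = amount/C`, `flow = momentum/L`, `k_f·Π fwd^s − k_r·Π rev^s`,
  `k_d·Δamount`, Michaelis–Menten, transformer pairs
  (`force₂ = m·force₁`, `flow₁ = m·flow₂`), summation and spatial state maps.
- **compiler** — causality assignment (capacitors output force, inductors
  and resistor-likes output flow, ...), single-assignment checking, algebraic
  scheduling with loop detection, and an explicit ODE right-hand side
  `d(state)/dt = Σ inflow − Σ outflow` (and its force/momentum analogue).
- **simulator** — fixed-step classical RK4 integration with bit-stable
  trajectories recording every property, plus steady-state location.
- **qualitative** — up/down perturbation reasoning: propagate a sign through
  the influence graph without solving anything, and verify the result
  against a numeric steady-state oracle.
- **io_cli** — a versioned YAML model dialect with deterministic round-trip,
  RDF 1.1 Turtle export of the semantic annotation (property classes, role
  players, bearers), and an `opbnet` command-line tool.

## Worked example: two-element Windkessel

The canonical fluid-domain fixture: a heart prescribes a constant inflow
`Q0` into a compliant arterial segment (capacitance `C`) that drains through
a peripheral resistance `R` into a zero-pressure venous sink.

```python
from opbnet import fixtures, compiler, simulator, qualitative

net = fixtures.windkessel(R=1.25, C=2.0, Q0=0.8)
sys = compiler.compile(net)
print(sys.equation_text())

traj = simulator.integrate(sys, t_end=10.0, dt=0.001)
print(f"pressure at t=10: {traj.final('pressure'):.6f}")

ss = simulator.steady_state(sys, t_max=120.0, tol=1e-13)
print(f"steady pressure : {ss['pressure']:.6f}")
print(f"steady volume   : {ss['volume']:.6f}")

report = qualitative.check_against_numeric(net, "inflow")
for row in report.rows:
    print(f"{row.property:16s} {row.qualitative:2s} {row.numeric:2s} {row.status}")
```

Output:

```
# windkessel
d(volume)/dt = + inflow - outflow
pressure = capacitive(cap_dep)
outflow = resistive(res_dep)
inflow = source[constant]
venous_pressure = source[constant]

pressure at t=10: 0.981684
steady pressure : 1.000000
steady volume   : 2.000000
inflow           +  +  agree
outflow          +  +  agree
pressure         +  +  agree
venous_pressure  0  0  agree
volume           +  +  agree
```

The compiled system is the single ODE `dV/dt = Q0 − (V/C)/R`; at t = 10 the
pressure has relaxed to within e^(−t/RC) of its steady value, and the steady
state matches the closed forms `P = Q0·R = 1.0` and `V = C·Q0·R = 2.0`.  The
perturbation report says: raise the inflow and — qualitatively and
numerically — pressure, volume and outflow all rise.

The same models are available as shell commands:

```bash
opbnet fixture --name windkessel --out wk.yaml
opbnet validate wk.yaml
opbnet simulate wk.yaml --t-end 10 --dt 0.001 --out traj.csv
opbnet steady wk.yaml --tol 1e-12
opbnet perturb wk.yaml --property inflow --direction up --check-numeric
opbnet export-rdf wk.yaml --out wk.ttl
```

## Scope notes

Continuum (PDE) physics, non-proportional conductances such as
Hodgkin–Huxley gating (Michaelis–Menten is the one sanctioned
non-proportional kind), implicit/DAE systems, and import of external model
formats (SBML/CellML) are out of scope.  See `docs/methods.md` for the
formal model, numerical choices and limitations.
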