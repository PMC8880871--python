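# Methods

This note documents the models, contracts and numerical choices behind
mdflow: what the engine computes, which knobs matter, what the synthetic
systems do and do not emulate, and where genuinely open design questions
were settled.

## 1. The work-graph model

A work graph is a directed acyclic multigraph whose nodes are *operation
instances* (an `OperationSpec` plus bound inputs) and whose edges are data
dependencies between typed ports. Construction and execution are strictly
separated: building a node performs all wiring checks (port existence,
required bindings, kind compatibility, width broadcasting) and returns
futures; execution happens only when a future is resolved.

**Kinds.** The port type system is nominal and minimal: `boolean`,
`integer`, `real`, `text`, `file_path`, `record` (an opaque structured
payload used for simulation inputs and systems), and `array_of(·)` to a
nesting depth of two. There is no implicit integer→real coercion — a wiring
mistake should fail at build time, not corrupt a run. Two pragmatic
exceptions: plain strings may bind to `file_path` ports (paths are written
as strings), and an empty-array literal has unknown element kind and
unifies with any array, which spares a mandatory annotation in the
degenerate `concatenate_lists([])` case.

**Ensemble widths.** Width broadcasting follows one rule:
`broadcast(1, n) = n`, `broadcast(n, n) = n`, anything else is an error.
Only scalar-to-ensemble replication is implicit; there is no n→m
reshaping. Gather edges (ensemble → array) order members by 0-based member
index; this convention is a choice, not a derivation, and is relied on by
`gather` and by the reduce log.

**Determinism choices.** Node ids are `opname-K` with a per-opname counter,
so identical scripts produce identical graphs, logs and serializations.
Topological order uses Kahn's algorithm with stable insertion-order
tie-breaking, making execution logs reproducible; tests verify the order
against an independent graph library rather than the same code path.

**Serialization.** Graphs serialize to JSON:

```json
{"schema_version": 1,
 "nodes": [{"id": "...", "op": "...", "width": 1,
            "constants": {"port": <json>},
            "ports": {"inputs": {"port": <kind>}, "outputs": {...}},
            "payload": <operation-specific>}],
 "edges": [{"source": ["node", "port"], "sink": ["node", "port"],
            "mode": "map" | "broadcast" | "gather"}]}
```

Port kinds are recorded per node because registry entries for generic
operations (constants, joins) declare placeholder kinds; recording the
concrete kinds keeps futures nominally typed across a round-trip. Operation
payloads (while-loop subgraphs, modify-input overrides, restraint plugins)
serialize through per-operation hooks; wrapped user procedures are recorded
by operation name only and must be re-registered (`wrapped.register(ctx)`)
before loading — procedure code is never serialized.

## 2. Execution

A session owns one graph's run-time state: per-(node, member) output
caches, an executed-node log with completion indices and wall times, a
working-directory root, and a seed. `result()` computes the ancestor set of
the requested node by reverse reachability, orders it topologically, and
executes only the pending entries — minimal execution is an invariant
tested by exact comparison against brute-force ancestor sets on randomized
graphs. Every (node, member) executes at most once per session; failures
are cached too, so a failed node re-raises without re-running, wrapped in
an error naming the node and member.

Working directories are `<root>/<node_id>/<member>/`, never reused;
external tools run there, input files are referenced in place (tools that
write next to their inputs are unsupported by design). Per-(node, member)
seeds derive as `session_seed XOR crc32(node_id:member)`, masked below
2³¹ — reproducible without cross-member correlation; wrapped procedures can
request them via `needs_resources`.

**Coupled co-execution.** Uncoupled operations — everything except
simulation nodes whose plugins declare an ensemble-scope stop or an
ensemble reduction — execute sequentially in member order. Coupled
ensembles run one thread per member in lockstep: a unified
condition-variable barrier releases a step generation when all active
members reach the step boundary, completes a reduce epoch when all
contribute (mean taken in member-index order, delivered identically to
every member), and fails everyone with an epoch-mismatch error when
members disagree on what they are waiting for — including a member calling
reduce after another has finished, or finishing while a reduce is pending.
Reduce epochs are implicit per-member call counters; matching by call count
is the simplest verifiable rule. Threads were chosen over generator
round-robin because `ensemble_reduce` must be an ordinary blocking call
usable from inside plugin code; all numerics are member-local except the
reduce mean, so thread scheduling cannot affect results. Stop signals are
honored at the next step boundary (latency ≤ 1 step). Failure policy is
fail-fast: the first member failure aborts the ensemble with context.

## 3. Control flow

`subgraph(variables={...})` opens a body fragment over named state
variables; reading a variable yields a placeholder future, assigning one
records its end-of-iteration update, and exiting the block freezes the
spec (validated acyclic). `while_loop(spec, condition, max_iteration)`
uses **pre-test** semantics — the condition is evaluated on the initial
state before the first iteration — matching the construct's name; the
alternative (post-test) was genuinely open and is noted here as the road
not taken. Each iteration literally appends fresh body nodes
(`<loop>.itK.<body-node>`) to the graph and executes them, so dynamic
growth is visible in the executed-node log, and loop state is isolated per
loop instance. `max_iteration` is mandatory: with deferred execution a
runaway loop is otherwise undetectable at build time; exhausting it is not
an error (`iterations_run` reports the count).

Conditions are small serializable expressions over the variables
(`var("n") < 4`, `~any_(var("converged"))`). An ensemble-width boolean is
ambiguous as a loop gate, so conditions must pass ensemble variables
through the explicit `any_`/`all_` reductions; anything that does not
reduce to one scalar boolean is rejected. Conditions see end-of-iteration
state only, not values mid-body.

## 4. The toy MD engine

The engine exists to exercise the workflow and plugin contracts with
physics simple enough to test against closed forms. Reduced units
throughout (masses, lengths, times dimensionless; k_B = 1). Systems are
point particles with harmonic bonds `U = ½k(|r|−r0)²`; forces are equal and
opposite along the pair axis. There are no nonbonded interactions,
neighbor lists, periodic boundaries or constraints, and no claim of
chemical realism.

**Integrator.** Velocity Verlet:

```
x(t+dt) = x + v·dt + f/(2m)·dt²
v(t+dt) = v + (f_old + f_new)/(2m)·dt
```

Friction enters as a deterministic damping force `−γ·m·v` (no stochastic
kicks — a full Langevin thermostat would destroy the closed-form restraint
equilibria the tests rely on; it is a documented extension, not an
omission by accident). Because the friction force depends on velocity, the
"new" force evaluation uses the half-updated velocity
`v + f_old·dt/(2m)` — a standard one-pass scheme that is exact for γ = 0,
where the integrator is symplectic: the undamped dimer at dt = 0.001
conserves total energy to |ΔE|/E ≈ 5×10⁻⁷ over 10⁴ steps, halving dt
reduces the drift ~4× (order 2), total momentum is conserved to round-off,
and the separation oscillates with period 2π/√(2k/m) (reduced mass m/2) to
0.01%. Non-finite coordinates raise a numeric-overflow error naming the
step.

**Parameters that matter.** `dt` (default 0.001; stability requires
`dt ≪ 2/ω` with `ω² = k_eff/μ` — the stiff restraints used in the demos
with k ≈ 200 have ω ≈ 20, comfortably resolved), `friction_gamma`
(default 0; 1.0 in relaxation demos, giving an underdamped ζ = γ/2ω ≪ 1),
`output_interval` (frame and reduce cadence), `seed`, and
`init_temperature` (default 0). At `init_temperature > 0` initial
velocities are redrawn from a Maxwell-Boltzmann distribution at that
temperature using `seed`; at 0 the input-file velocities are used verbatim
and the dynamics are fully deterministic. This is the one seed-sensitive
mechanism in the engine — it makes per-member seeds observable (distinct
seeds → distinct trajectories) without touching the in-loop dynamics, and
it is deliberately keyed to `params.seed` alone so identical inputs give
identical trajectories regardless of session.

**Plugins.** A plugin binds to one particle pair and sees only that pair's
positions (the restraint use case; a whole-system view was the open
alternative and can be added without changing the contract). `force` must
be pure — velocity Verlet evaluates it twice per step; `on_step` runs once
per completed step and may reduce or signal stops. The declarative
`RestraintPlugin` (harmonic toward `target`, optional stop when
`|d − target| < stop_tolerance`, optional mean-distance reduce each output
interval) covers the refinement workflows; arbitrary code subclasses
`PairPlugin`. The reduce is a *mean*, not a sum: scale-free in member
count, which is what ensemble-averaged biasing updates consume. An empty
plugin list is bitwise-identical to a plugin-free run (no hidden overhead
on the plugin path).

**File formats.** Simulation input is a JSON document
(`system.{masses, positions, velocities, bonds}`,
`params.{dt, nsteps, friction_gamma, output_interval, seed,
init_temperature}`) with validation errors naming the offending field
path. Trajectories are XYZ frames plus an `energies.jsonl` side file
(step, time, potential, kinetic, total) and a `final_system.json` in the
input schema; members that reduce also write a `reduce.jsonl` audit log
(epoch, contributed value, reduced value) used by the exactness tests.

## 5. The restrained-ensemble demonstration

The demo emulates, at desk scale, refinement of a conformational ensemble
against a measured distance distribution: each of n members draws a target
from a two-component Gaussian mixture (centers 2.5 and 3.5, widths 0.3,
weights 0.6/0.4 — well-separated modes of comparable occupancy, the shape
of a bimodal spin-label distance distribution), restrains a damped dimer
toward it with k_r = 200 ≫ k_b = 1, and stops within 0.02 of the combined
minimum. The stiff restraint bounds the systematic offset between final
distance and target by `(k_b/(k_b+k_r))·|target − r0| ≲ 0.02`, small
against the mixture widths. With 64 members the KS distance of finals
against the mixture is ≈ 0.06–0.13 across seeds, below the 5% asymptotic
critical value 1.358/√64 ≈ 0.170.

What this does and does not show: the synthetic systems have exact
closed-form equilibria, a two-particle geometry, and independent members —
so passing tests demonstrate the *workflow contracts* (fan-out, per-member
targets, stop signals, distribution-level agreement), not force-field
realism, sampling efficiency on rugged landscapes, or the behavior of
coupled biasing schemes on real ensembles. Likewise the engine's
sequential/threaded execution validates co-execution *semantics*, not
parallel performance; MPI- or scheduler-backed execution is out of scope.

## 6. Problem sizes

Defaults were chosen as the smallest sizes at which each property is
sharply testable: 200 random DAGs (≤ 12 nodes) for minimal execution;
10⁴–2×10⁴ integrator steps for conservation, period and equilibrium
checks; 3-member coupled ensembles for barrier semantics; 64 members for
the distribution-level KS comparison (critical value scales as 1/√n, and
64 keeps the test sensitive while the full run stays under a few seconds).

## 7. Known limitations

- The kind system has no user-extensible record schemas; `record` payloads
  are validated by the operations that consume them.
- Wrapped procedures do not serialize; a loaded graph needs the same
  procedures re-registered under the same names.
- `commandline_operation` references input files in place; tools that
  write outputs next to their inputs are unsupported.
- Coupled ensembles require equal step counts and reduce cadences across
  members; ragged reduction is rejected rather than padded.
- The while-loop condition cannot observe mid-body values, only
  end-of-iteration state.
- No if/else graph node: host-language branching after `result()` covers
  conditional logic outside loops.
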