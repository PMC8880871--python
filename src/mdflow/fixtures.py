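"""Seeded synthetic-input generators and executable demo workflows.

The demos reproduce, at desk scale, the canonical usage patterns of
data-flow simulation APIs: an ensemble fan-out over seeds, a convergence
while-loop around an ensemble simulation, and a chain of wrapped
command-line tools feeding a simulation — each both a documentation example
and an integration-test surface.  Everything is deterministic under its
seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Any, Dict, List, Optional

import numpy as np

from .commandline import commandline_operation, fixture_command
from .context import Context
from .control import any_, subgraph, var, while_loop
from .graph import OperationSpec, PortSpec, WorkGraph
from .kinds import INTEGER
from .ops import make_constant
from .toymd import (
    RestraintPlugin,
    SimulationInput,
    make_dimer,
    mdrun,
    modify_input,
    read_input,
    save_input,
)
from .distributions import GaussianMixture  # noqa: F401  (re-export)


# --------------------------------------------------------------------------
# Random DAGs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomDagSpec:
    """Recipe for a random valid DAG of pure no-op operations."""

    n_nodes: int
    edge_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (0 < self.edge_probability < 1):
            raise ValueError("edge_probability must be in (0, 1)")


_NOOP_SPECS: Dict[int, OperationSpec] = {}


def _noop_spec(fan_in: int) -> OperationSpec:
    """A pure integer operation with *fan_in* inputs; returns their sum + 1
    so values are data-dependent and order bugs surface.  Registered in the
    builtin registry so random DAGs survive serialization round-trips."""
    if fan_in not in _NOOP_SPECS:
        from .graph import BUILTIN_REGISTRY

        spec = OperationSpec(
            op_name=f"noop{fan_in}",
            inputs=tuple(PortSpec(f"in{t}", INTEGER, required=True)
                         for t in range(fan_in)),
            outputs=(PortSpec("value", INTEGER),),
            runner=lambda inputs, ctx: {"value": sum(inputs.values()) + 1},
        )
        BUILTIN_REGISTRY.register(spec)
        _NOOP_SPECS[fan_in] = spec
    return _NOOP_SPECS[fan_in]


for _fan_in in range(13):  # eager: serialized random DAGs load anywhere
    _noop_spec(_fan_in)


def generate_random_dag(spec: RandomDagSpec,
                        context: Optional[Context] = None) -> WorkGraph:
    """Build a random valid DAG in *context* (edges only run from earlier to
    later construction indices, guaranteeing acyclicity); deterministic
    under the spec's seed."""
    ctx = context or Context()
    rng = np.random.default_rng(spec.seed)
    handles = []
    for j in range(spec.n_nodes):
        preds = [i for i in range(j) if rng.random() < spec.edge_probability]
        op = _noop_spec(len(preds))
        inputs = {f"in{t}": handles[i].output_future("value")
                  for t, i in enumerate(preds)}
        handles.append(ctx.graph.add_node(op, inputs, context=ctx))
    return ctx.graph


# --------------------------------------------------------------------------
# Demo workflows (figure analogs)
# --------------------------------------------------------------------------


def demo_ensemble_fanout(n_members: int, workdir: Optional[str] = None,
                         seed: int = 0) -> Dict[str, Any]:
    """Ensemble MD from an array of inputs: read one run input, fan it out
    over an array of seeds, and run the batch in one mdrun call.

    Members differ only in ``params.seed``; with a Maxwell-Boltzmann initial
    temperature, distinct seeds produce distinct trajectories and identical
    seeds identical ones.
    """
    with Context(workdir=workdir, seed=seed) as ctx:
        root = ctx.session.workdir_root
        input_path = os.path.join(root, "dimer.json")
        save_input(make_dimer(1.2, 1.0, 1.0, dt=0.001, nsteps=500,
                              output_interval=50, init_temperature=0.5),
                   input_path)
        sim = read_input(input_path, context=ctx)
        ensemble = modify_input(
            sim, {"params.seed": [seed + m for m in range(n_members)]},
            context=ctx,
        )
        md = mdrun(ensemble, context=ctx).run()
        trajectories = md.output.trajectory_file.result()
        if n_members == 1:
            trajectories = [trajectories]
        for path in trajectories:
            assert os.path.exists(path)
        return {
            "trajectories": trajectories,
            "node_id": md.node_id,
            "log": [r.to_json() for r in ctx.session.log],
        }


def demo_convergence_loop(
    n_members: int = 2,
    stop_tolerance: float = 0.05,
    target: float = 1.5,
    max_iteration: int = 10,
    segment_steps: int = 150,
    workdir: Optional[str] = None,
    seed: int = 0,
) -> Dict[str, Any]:
    """A while_loop around an ensemble simulation segment: keep extending
    the trajectories until at least one member's restrained distance has
    converged to its target (or the iteration guard trips).

    The loop state is the ensemble of simulation inputs (each iteration
    restarts from the previous final systems) plus the convergence flags.
    """
    with Context(workdir=workdir, seed=seed) as ctx:
        base = make_dimer(1.0, 1.0, 1.0, dt=0.001, nsteps=segment_steps,
                          friction_gamma=1.0, output_interval=50)
        plugins = [
            [RestraintPlugin(pair=(0, 1), k_restraint=10.0, target=target,
                             stop_tolerance=stop_tolerance)]
            for _ in range(n_members)
        ]
        from .wrappers import function_wrapper
        from .kinds import RECORD

        @function_wrapper(output={"input": RECORD})
        def continue_input(final_system):
            """Next segment's input: previous final system, same params."""
            return SimulationInput(system=final_system, params=base.params).copy()

        sg = subgraph(variables={
            "siminput": (RECORD, base.to_json()),
            "converged": False,
        })
        with sg:
            seed_inputs = modify_input(
                sg.siminput, {"params.seed": [seed + m for m in range(n_members)]}
            ) if n_members > 1 else modify_input(sg.siminput, {})
            md = mdrun(seed_inputs, plugins=plugins)
            sg.siminput = continue_input(final_system=md.output.final_system).output.input
            sg.converged = md.output.converged
        loop = while_loop(sg, ~any_(var("converged")), max_iteration=max_iteration)
        iterations = loop.iterations_run.result()
        converged = loop.final["converged"].result()
        finals = loop.final["siminput"].result()
        if not isinstance(converged, list):
            converged, finals = [converged], [finals]
        from .toymd import pair_distance
        import numpy as _np

        separations = [
            pair_distance(_np.asarray(s.system.positions), 0, 1) for s in finals
        ]
        return {
            "iterations": iterations,
            "converged": converged,
            "final_separations": separations,
            "executed": ctx.session.executed_nodes(),
        }


def demo_tool_chain(workdir: Optional[str] = None, seed: int = 0) -> Dict[str, Any]:
    """A chain of wrapped command-line tools preparing simulation input:
    concatenate two document fragments, copy the result into place, then
    read it and run the dynamics — file futures force the execution order.
    """
    with Context(workdir=workdir, seed=seed) as ctx:
        root = ctx.session.workdir_root
        import json as _json

        full = _json.dumps(make_dimer(1.1, 1.0, 1.0, dt=0.001, nsteps=200,
                                      output_interval=20).to_json())
        half = len(full) // 2
        frag_a = os.path.join(root, "fragment_a.txt")
        frag_b = os.path.join(root, "fragment_b.txt")
        with open(frag_a, "w") as fh:
            fh.write(full[:half])
        with open(frag_b, "w") as fh:
            fh.write(full[half:])

        concat_cmd = fixture_command("concat")
        concat = commandline_operation(
            concat_cmd[0], concat_cmd[1:],
            input_files={"-a": frag_a, "-b": frag_b},
            output_files={"-o": "assembled.json"},
            name="concat", context=ctx,
        )
        copy_cmd = fixture_command("copy")
        copy = commandline_operation(
            copy_cmd[0], copy_cmd[1:],
            input_files={"-i": concat.output.file["-o"]},
            output_files={"-o": "input.json"},
            name="copy", context=ctx,
        )
        sim = read_input(copy.output.file["-o"], context=ctx)
        md = mdrun(sim, context=ctx).run()
        trajectory = md.output.trajectory_file.result()
        order = ctx.session.executed_nodes()
        before_run = len(ctx.session.log)
        md.run()  # re-running the resolved chain executes zero new nodes
        return {
            "trajectory": trajectory,
            "order": order,
            "cache_stable": len(ctx.session.log) == before_run,
        }


def demo_dataflow_tour(seed: int = 0) -> Dict[str, Any]:
    """Exercise the data-flow primitives end to end: constants, array joins,
    negation, the composable concatenate fold, a wrapped user procedure, a
    gathered ensemble, and a counter while_loop."""
    from .ops import concatenate_lists, ensemble_input, gather, join_arrays, logical_not
    from .wrappers import function_wrapper

    with Context(seed=seed) as ctx:
        joined = join_arrays([1, 2], [3, 4], context=ctx)
        catted = concatenate_lists([[1], [2, 3], []], context=ctx)
        negated = logical_not(make_constant(False, context=ctx), context=ctx)

        @function_wrapper(output={"y": INTEGER})
        def double(x):
            return 2 * x

        doubled = double(x=ensemble_input([1, 2, 3], context=ctx), context=ctx)
        gathered = gather(doubled.output.y, context=ctx)

        @function_wrapper(output={"y": INTEGER})
        def increment(x):
            return x + 1

        sg = subgraph(variables={"n": 0})
        with sg:
            sg.n = increment(x=sg.n).output.y
        loop = while_loop(sg, var("n") < 3, max_iteration=10)

        return {
            "joined": joined.result(),
            "concatenated": catted.result(),
            "negated": negated.result(),
            "doubled": doubled.output.y.result(),
            "gathered": gathered.result(),
            "loop_n": loop.final["n"].result(),
            "iterations": loop.iterations_run.result(),
            "ops_executed": sorted({r.op_name for r in ctx.session.log}),
        }
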