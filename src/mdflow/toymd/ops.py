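"""Graph operations over the toy MD engine: the read-input / modify-input /
run triad familiar from molecular simulation toolchains.

``read_input`` parses a run-input file into a typed handle; ``modify_input``
derives new inputs without touching the original (forked trajectories), and
fans out an ensemble when given an array of override values; ``mdrun``
integrates the dynamics with optional in-loop plugins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, List, Mapping, Optional, Sequence, Union

from ..context import Context, get_context
from ..errors import UnknownParameterPathError, UnsupportedPayloadError
from ..graph import BUILTIN_REGISTRY, Future, NodeHandle, OperationSpec, PortSpec
from ..kinds import BOOLEAN, FILE_PATH, INTEGER, RECORD
from .engine import run_ensemble
from .plugins import PairPlugin, RestraintPlugin
from .system import (
    SimulationInput,
    _PARAM_FIELDS,
    _SYSTEM_FIELDS,
    apply_overrides,
    load_input,
    save_input,
)

write_input = save_input


def _as_input_future(value: Any, ctx: Context) -> Any:
    """Accept a NodeHandle (its record output), a Future, or a constant."""
    if isinstance(value, NodeHandle):
        for p in value.spec.outputs:
            if p.kind.tag == "record":
                return value.output_future(p.name)
        raise UnsupportedPayloadError(
            f"node {value.node_id!r} has no simulation-input output"
        )
    return value


def _coerce_sim_input(value: Any) -> SimulationInput:
    if isinstance(value, SimulationInput):
        return value
    if isinstance(value, Mapping):
        return SimulationInput.from_json(dict(value))
    raise UnsupportedPayloadError(
        f"expected a SimulationInput, got {type(value).__name__}"
    )


# ----------------------------------------------------------------- read_input

_READ_INPUT_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="read_input",
    inputs=(PortSpec("path", FILE_PATH, required=True),),
    outputs=(PortSpec("input", RECORD),),
    runner=lambda inputs, ctx: {"input": load_input(str(inputs["path"]))},
))


def read_input(path: Any, context: Optional[Context] = None) -> NodeHandle:
    """Parse a simulation-input file (path or file future) into a handle
    yielding a validated :class:`SimulationInput`.  Pure and cached."""
    ctx = context or get_context()
    return ctx.graph.add_node(_READ_INPUT_SPEC, {"path": path}, context=ctx)


# --------------------------------------------------------------- modify_input


@dataclass
class PerMember:
    """Explicit member-wise override values for ``modify_input`` (needed for
    ``system.*`` paths, whose natural values are already arrays)."""

    values: List[Any]


def _normalize_overrides(overrides: Mapping[str, Any]):
    """Validate paths and split fan-out overrides; returns (doc, width)."""
    width = 1
    doc: Dict[str, Any] = {}
    for path, value in overrides.items():
        parts = path.split(".")
        known = (
            len(parts) == 2
            and (
                (parts[0] == "params" and parts[1] in _PARAM_FIELDS)
                or (parts[0] == "system" and parts[1] in _SYSTEM_FIELDS)
            )
        )
        if not known:
            raise UnknownParameterPathError(f"unknown parameter path {path!r}")
        if isinstance(value, PerMember):
            members = list(value.values)
        elif parts[0] == "params" and isinstance(value, (list, tuple)):
            members = list(value)  # an array of scalars fans out the ensemble
        else:
            doc[path] = {"shared": value}
            continue
        if width != 1 and len(members) != width:
            raise UnsupportedPayloadError(
                f"override {path!r}: fan-out width {len(members)} conflicts "
                f"with {width}"
            )
        width = max(width, len(members))
        doc[path] = {"per_member": members}
    return doc, width


def _member_overrides(doc: Dict[str, Any], member: int) -> Dict[str, Any]:
    out = {}
    for path, entry in doc.items():
        if "shared" in entry:
            out[path] = entry["shared"]
        else:
            out[path] = entry["per_member"][member]
    return out


def _modify_ensemble_runner(handle, inputs_per_member, ctxs, session):
    outs = []
    for member, (inputs, _ctx) in enumerate(zip(inputs_per_member, ctxs)):
        sim = _coerce_sim_input(inputs["input"])
        outs.append({
            "input": apply_overrides(sim, _member_overrides(handle.payload, member))
        })
    return outs


_MODIFY_INPUT_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="modify_input",
    inputs=(PortSpec("input", RECORD, required=True),),
    outputs=(PortSpec("input", RECORD),),
    ensemble_runner=_modify_ensemble_runner,
    payload_to_json=lambda payload: payload,
    payload_from_json=lambda doc, context: doc,
))


def modify_input(
    input: Any,
    overrides: Mapping[str, Any],
    context: Optional[Context] = None,
) -> NodeHandle:
    """Derive a new :class:`SimulationInput` differing only at the given
    dotted parameter paths; the source input is untouched.

    A list of scalars for a ``params.*`` path — or a :class:`PerMember`
    wrapper for any path — fans the node out to a width-n ensemble of
    inputs, one per member value.
    """
    ctx = context or get_context()
    doc, width = _normalize_overrides(overrides)
    return ctx.graph.add_node(
        _MODIFY_INPUT_SPEC,
        {"input": _as_input_future(input, ctx)},
        context=ctx,
        width=width if width > 1 else None,
        payload=doc,
    )


# ---------------------------------------------------------------------- mdrun


def _normalize_plugins(payload, width: int) -> List[List[PairPlugin]]:
    plugins = payload or []
    if plugins and isinstance(plugins[0], (list, tuple)):
        per_member = [list(p) for p in plugins]
        if len(per_member) != width:
            raise UnsupportedPayloadError(
                f"{len(per_member)} per-member plugin lists for width {width}"
            )
        return per_member
    return [list(plugins) for _ in range(width)]


def _mdrun_ensemble_runner(handle, inputs_per_member, ctxs, session):
    sims = [_coerce_sim_input(inp["input"]) for inp in inputs_per_member]
    plugins = _normalize_plugins(handle.payload, handle.width)
    workdirs = [ctx.workdir for ctx in ctxs]
    outs = run_ensemble(sims, plugins, workdirs, node_id=handle.node_id)
    for ctx, out in zip(ctxs, outs):
        ctx.log_extra["steps_run"] = out["steps_run"]
        ctx.log_extra["converged"] = out["converged"]
    return outs


def _plugins_to_json(payload):
    def one(p):
        if hasattr(p, "to_json"):
            return p.to_json()
        raise UnsupportedPayloadError(
            f"plugin {type(p).__name__} is not serializable"
        )

    plugins = payload or []
    if plugins and isinstance(plugins[0], (list, tuple)):
        return {"members": [[one(p) for p in member] for member in plugins]}
    return {"shared": [one(p) for p in plugins]}


def _plugins_from_json(doc, context):
    if "members" in doc:
        return [[RestraintPlugin.from_json(p) for p in member]
                for member in doc["members"]]
    return [RestraintPlugin.from_json(p) for p in doc["shared"]]


_MDRUN_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="mdrun",
    inputs=(PortSpec("input", RECORD, required=True),),
    outputs=(
        PortSpec("trajectory_file", FILE_PATH),
        PortSpec("final_system", RECORD),
        PortSpec("steps_run", INTEGER),
        PortSpec("converged", BOOLEAN),
    ),
    category="simulation",
    deterministic=True,
    ensemble_runner=_mdrun_ensemble_runner,
    payload_to_json=_plugins_to_json,
    payload_from_json=_plugins_from_json,
))


def mdrun(
    input: Any,
    plugins: Sequence = (),
    context: Optional[Context] = None,
) -> NodeHandle:
    """Run velocity-Verlet dynamics on a simulation input (handle, future or
    constant), with optional in-loop plugins.

    *plugins* is either one sequence shared by every ensemble member or a
    sequence of per-member sequences (which itself defines the ensemble
    width).  Outputs: ``trajectory_file``, ``final_system``, ``steps_run``,
    ``converged``.
    """
    ctx = context or get_context()
    plugins = list(plugins)
    width = None
    if plugins and isinstance(plugins[0], (list, tuple)):
        width = len(plugins)
    return ctx.graph.add_node(
        _MDRUN_SPEC,
        {"input": _as_input_future(input, ctx)},
        context=ctx,
        width=width,
        payload=plugins or None,
    )
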