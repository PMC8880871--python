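"""Subgraph fusion and dynamically extending while loops.

A *subgraph* fuses a group of operations with named internal state
variables.  Inside the ``with`` block of a :class:`SubgraphBuilder`, reading
a variable attribute yields a future (a placeholder source in the body
fragment) and assigning one records that variable's end-of-iteration update.

``while_loop(operation, condition, max_iteration)`` repeatedly instantiates
the frozen body — *fresh nodes appended to the executed graph each
iteration*, visible in the executed-node log — propagating each variable's
updated value into the next iteration.  The loop is pre-test: the condition
is evaluated on the current state before each iteration, starting with the
initial values, and ``max_iteration`` is a required safety guard (running
out of it is not an error; ``iterations_run`` reports the count).

Conditions are small serializable expressions over the variables::

    var("n") < 4            # counter gate
    ~any_(var("converged")) # loop until some ensemble member converges

``any_`` / ``all_`` are the explicit reductions required to gate a loop on
an ensemble-width boolean variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional, Tuple, Union

from .context import Context, get_context
from .errors import (
    CycleError,
    KindMismatchError,
    NonBooleanConditionError,
    VariableShadowingError,
)
from .executor import EnsembleValue
from .graph import (
    BUILTIN_REGISTRY,
    Future,
    NodeHandle,
    OperationSpec,
    PortSpec,
    WorkGraph,
    deserialize,
)
from .kinds import BOOLEAN, INTEGER, DataKind, compatible, infer_kind

# --------------------------------------------------------------------------
# Condition expressions
# --------------------------------------------------------------------------

_CMP = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
}


@dataclass(frozen=True)
class ConditionExpr:
    """A boolean reference over subgraph variables: a variable read,
    a comparison against a constant, a negation, or an any/all reduction."""

    op: str
    name: Optional[str] = None
    operand: Any = None
    child: Optional["ConditionExpr"] = None

    def __invert__(self) -> "ConditionExpr":
        return ConditionExpr("not", child=self)

    def _cmp(self, op: str, other: Any) -> "ConditionExpr":
        return ConditionExpr(op, operand=other, child=self)

    def __lt__(self, other):
        return self._cmp("lt", other)

    def __le__(self, other):
        return self._cmp("le", other)

    def __gt__(self, other):
        return self._cmp("gt", other)

    def __ge__(self, other):
        return self._cmp("ge", other)

    def equals(self, other):
        return self._cmp("eq", other)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, state: Mapping[str, Any]) -> Any:
        if self.op == "var":
            if self.name not in state:
                raise NonBooleanConditionError(f"unknown loop variable {self.name!r}")
            value = state[self.name]
            return value.values if isinstance(value, EnsembleValue) else value
        if self.op in _CMP:
            v = self.child.evaluate(state)
            fn = _CMP[self.op]
            if isinstance(v, list):
                return [fn(x, self.operand) for x in v]
            return fn(v, self.operand)
        if self.op == "not":
            v = self.child.evaluate(state)
            if isinstance(v, list):
                return [not x for x in v]
            return not v
        if self.op in ("any", "all"):
            v = self.child.evaluate(state)
            members = v if isinstance(v, list) else [v]
            return any(members) if self.op == "any" else all(members)
        raise NonBooleanConditionError(f"unknown condition op {self.op!r}")

    def test(self, state: Mapping[str, Any]) -> bool:
        value = self.evaluate(state)
        if not isinstance(value, bool):
            raise NonBooleanConditionError(
                "condition does not reduce to a single boolean (ensemble-width "
                "variables must pass through any_()/all_()): got "
                f"{type(value).__name__}"
            )
        return value

    # -- JSON --------------------------------------------------------------
    def to_json(self) -> dict:
        doc: Dict[str, Any] = {"op": self.op}
        if self.name is not None:
            doc["name"] = self.name
        if self.operand is not None:
            doc["operand"] = self.operand
        if self.child is not None:
            doc["child"] = self.child.to_json()
        return doc

    @staticmethod
    def from_json(doc: dict) -> "ConditionExpr":
        return ConditionExpr(
            op=doc["op"],
            name=doc.get("name"),
            operand=doc.get("operand"),
            child=ConditionExpr.from_json(doc["child"]) if "child" in doc else None,
        )


def var(name: str) -> ConditionExpr:
    """Reference a subgraph variable inside a while_loop condition."""
    return ConditionExpr("var", name=name)


def any_(expr: Union[ConditionExpr, str]) -> ConditionExpr:
    """True iff the expression holds for at least one ensemble member."""
    child = var(expr) if isinstance(expr, str) else expr
    return ConditionExpr("any", child=child)


def all_(expr: Union[ConditionExpr, str]) -> ConditionExpr:
    """True iff the expression holds for every ensemble member."""
    child = var(expr) if isinstance(expr, str) else expr
    return ConditionExpr("all", child=child)


# --------------------------------------------------------------------------
# Subgraph
# --------------------------------------------------------------------------


@dataclass
class SubgraphVariable:
    name: str
    kind: DataKind
    initial: Any
    update: Optional[Tuple[str, str]] = None  # (body node id, output port)


_PLACEHOLDER_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="subgraph_variable",
    inputs=(),
    outputs=(PortSpec("value", DataKind("record")),),
    runner=None,
    payload_to_json=lambda payload: payload,
    payload_from_json=lambda doc, context: doc,
))


class SubgraphSpec:
    """A frozen subgraph: variables with initial values and update refs, and
    the acyclic body fragment they parameterize."""

    def __init__(self, variables: Dict[str, SubgraphVariable], body_context: Context):
        self.variables = variables
        self.body_context = body_context
        diags = [d for d in body_context.graph.validate() if d.code == "cycle"]
        if diags:
            raise CycleError("subgraph body is cyclic: " + diags[0].message)

    @property
    def body_graph(self) -> WorkGraph:
        return self.body_context.graph

    def initial_state(self) -> Dict[str, Any]:
        return {name: v.initial for name, v in self.variables.items()}

    def placeholder_id(self, name: str) -> str:
        return f"var.{name}"

    # -- JSON --------------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "variables": {
                name: {
                    "kind": v.kind.to_json(),
                    "initial": v.initial,
                    "update": list(v.update) if v.update else None,
                }
                for name, v in self.variables.items()
            },
            "body": json.loads(self.body_graph.serialize()),
        }

    @staticmethod
    def from_json(doc: dict, context: Context) -> "SubgraphSpec":
        body_context = Context(registry_parent=context.registry)
        deserialize(json.dumps(doc["body"]), body_context)
        variables = {}
        for name, vdoc in doc["variables"].items():
            variables[name] = SubgraphVariable(
                name=name,
                kind=DataKind.from_json(vdoc["kind"]),
                initial=vdoc["initial"],
                update=tuple(vdoc["update"]) if vdoc.get("update") else None,
            )
        return SubgraphSpec(variables, body_context)


class SubgraphBuilder:
    """Builder for a fused subgraph; use as a context manager.

    Within the block, any operation of any module may be instantiated; the
    builder's variable attributes read as futures and assignments record the
    variable's per-iteration update.
    """

    def __init__(self, variables: Mapping[str, Any]):
        object.__setattr__(self, "_vars", {})
        object.__setattr__(self, "_body", Context(registry_parent=get_context().registry))
        object.__setattr__(self, "_placeholders", {})
        object.__setattr__(self, "_updates", {})
        object.__setattr__(self, "_frozen", None)
        object.__setattr__(self, "_building", False)
        for name, init in variables.items():
            if name in self._vars:
                raise VariableShadowingError(f"duplicate variable {name!r}")
            if isinstance(init, tuple) and len(init) == 2 and isinstance(init[0], DataKind):
                kind, value = init
            else:
                kind, value = infer_kind(init), init
            self._vars[name] = SubgraphVariable(name, kind, value)

    def __enter__(self) -> "SubgraphBuilder":
        object.__setattr__(self, "_building", True)
        self._body.__enter__()
        graph = self._body.graph
        for name, v in self._vars.items():
            spec = OperationSpec(
                op_name="subgraph_variable",
                inputs=(),
                outputs=(PortSpec("value", v.kind),),
                payload_to_json=_PLACEHOLDER_SPEC.payload_to_json,
                payload_from_json=_PLACEHOLDER_SPEC.payload_from_json,
            )
            handle = graph.add_node(spec, {}, context=self._body,
                                    node_id=f"var.{name}", payload=name)
            self._placeholders[name] = handle.output_future("value")
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        self._body.__exit__(exc_type, exc, tb)
        object.__setattr__(self, "_building", False)
        if exc_type is None:
            for name, fut in self._updates.items():
                self._vars[name].update = fut.ref
            object.__setattr__(self, "_frozen", SubgraphSpec(dict(self._vars), self._body))

    def __getattr__(self, name: str) -> Future:
        if name.startswith("_"):
            raise AttributeError(name)
        placeholders = object.__getattribute__(self, "_placeholders")
        if name in placeholders:
            return placeholders[name]
        raise AttributeError(f"no subgraph variable {name!r}")

    def __setattr__(self, name: str, value: Any) -> None:
        if name.startswith("_"):
            object.__setattr__(self, name, value)
            return
        if not self._building:
            raise VariableShadowingError(
                "variables may only be updated inside the builder block"
            )
        if name not in self._vars:
            raise VariableShadowingError(
                f"{name!r} is not a declared subgraph variable"
            )
        v = self._vars[name]
        kind = value.kind if isinstance(value, Future) else infer_kind(value)
        if not compatible(kind, v.kind):
            raise KindMismatchError(
                f"update of variable {name!r}: {kind} does not match {v.kind}"
            )
        if not isinstance(value, Future):
            from .ops import make_constant

            value = make_constant(value, context=self._body)
        self._updates[name] = value

    def freeze(self) -> SubgraphSpec:
        if self._frozen is None:
            raise CycleError("subgraph builder was never entered")
        return self._frozen


def subgraph(variables: Mapping[str, Any]) -> SubgraphBuilder:
    """Open a subgraph over named state variables.

    *variables* maps names to initial constants (kinds inferred) or to
    ``(DataKind, initial)`` pairs.
    """
    return SubgraphBuilder(variables)


# --------------------------------------------------------------------------
# while_loop
# --------------------------------------------------------------------------


class WhileLoopHandle:
    """Futures over a while_loop's final variable state and iteration count;
    they resolve only after loop termination."""

    def __init__(self, node: NodeHandle):
        self.node = node

    @property
    def final(self) -> Dict[str, Future]:
        return {
            p.name: self.node.output_future(p.name)
            for p in self.node.spec.outputs
            if p.name != "iterations_run"
        }

    @property
    def iterations_run(self) -> Future:
        return self.node.output_future("iterations_run")


@dataclass
class _WhilePayload:
    spec: SubgraphSpec
    condition: ConditionExpr
    max_iteration: int


def _bind_state(session, loop_id: str, iteration: int, name: str,
                value: Any, kind: DataKind) -> Future:
    """Materialize one state value as a constant (or ensemble) source node."""
    graph = session.graph
    node_id = f"{loop_id}.it{iteration}.var.{name}"
    if isinstance(value, EnsembleValue):
        from .ops import _ENSEMBLE_CONSTANT_SPEC

        spec = OperationSpec(
            op_name="ensemble_constant",
            inputs=(),
            outputs=(PortSpec("value", kind),),
            ensemble_runner=_ENSEMBLE_CONSTANT_SPEC.ensemble_runner,
        )
        handle = graph.add_node(spec, {}, context=session.context,
                                node_id=node_id, width=value.width,
                                payload=list(value.values))
    else:
        spec = OperationSpec(
            op_name="make_constant",
            inputs=(PortSpec("value", kind, required=False),),
            outputs=(PortSpec("value", kind),),
            runner=lambda inputs, ctx: {"value": inputs["value"]},
        )
        handle = graph.add_node(spec, {"value": value}, context=session.context,
                                node_id=node_id)
    return handle.output_future("value")


def _run_iteration(session, loop_node: NodeHandle, payload: _WhilePayload,
                   state: Dict[str, Any], iteration: int) -> Dict[str, Any]:
    """Instantiate the body once, execute it, and return the updated state."""
    sg = payload.spec
    loop_id = loop_node.node_id
    graph = session.graph
    translate: Dict[Tuple[str, str], Future] = {}
    for name, v in sg.variables.items():
        translate[(f"var.{name}", "value")] = _bind_state(
            session, loop_id, iteration, name, state[name], v.kind
        )
    instantiated: List[str] = []
    for body_id in sg.body_graph.topological_order():
        body_node = sg.body_graph.nodes[body_id]
        if body_node.spec.op_name == "subgraph_variable":
            continue
        inputs: Dict[str, Any] = {}
        for pname, bound in body_node.bound_inputs.items():
            if isinstance(bound, Future):
                inputs[pname] = translate[bound.ref]
            else:
                inputs[pname] = bound
        new_id = f"{loop_id}.it{iteration}.{body_id}"
        handle = graph.add_node(
            body_node.spec, inputs, context=session.context,
            node_id=new_id, payload=body_node.payload,
            width=body_node.width if body_node.width > 1 else None,
        )
        for p in body_node.spec.outputs:
            translate[(body_id, p.name)] = handle.output_future(p.name)
        instantiated.append(new_id)
    for nid in instantiated:
        session.ensure_node(nid)
    new_state = dict(state)
    for name, v in sg.variables.items():
        if v.update is not None:
            fut = translate[v.update]
            members = [m[fut.port] for m in session.cache[fut.node_id]]
            new_state[name] = members[0] if len(members) == 1 else EnsembleValue(members)
    return new_state


def _while_runner(handle: NodeHandle, inputs_per_member, ctxs, session):
    payload: _WhilePayload = handle.payload
    state = payload.spec.initial_state()
    iterations = 0
    while iterations < payload.max_iteration and payload.condition.test(state):
        state = _run_iteration(session, handle, payload, state, iterations)
        iterations += 1
    outputs = dict(state)
    outputs["iterations_run"] = iterations
    return [outputs]


BUILTIN_REGISTRY.register(OperationSpec(
    op_name="while_loop",
    inputs=(),
    outputs=(PortSpec("iterations_run", INTEGER),),
    ensemble_runner=_while_runner,
    payload_to_json=lambda p: {
        "subgraph": p.spec.to_json(),
        "condition": p.condition.to_json(),
        "max_iteration": p.max_iteration,
    },
    payload_from_json=lambda doc, context: _WhilePayload(
        spec=SubgraphSpec.from_json(doc["subgraph"], context),
        condition=ConditionExpr.from_json(doc["condition"]),
        max_iteration=doc["max_iteration"],
    ),
))


def while_loop(
    operation: Union[SubgraphBuilder, SubgraphSpec],
    condition: ConditionExpr,
    max_iteration: int,
    context: Optional[Context] = None,
) -> WhileLoopHandle:
    """Gate repeated instantiation of a fused subgraph on a condition.

    Pre-test semantics; state is isolated per loop instance, so two loops
    over the same :class:`SubgraphSpec` never share variables.
    """
    ctx = context or get_context()
    if isinstance(operation, SubgraphBuilder):
        operation = operation.freeze()
    if not isinstance(condition, ConditionExpr):
        raise NonBooleanConditionError("condition must be a ConditionExpr")
    if max_iteration < 0:
        raise ValueError("max_iteration must be >= 0")
    base = BUILTIN_REGISTRY.get("while_loop")
    outputs = [PortSpec(name, v.kind) for name, v in operation.variables.items()]
    outputs.append(PortSpec("iterations_run", INTEGER))
    spec = OperationSpec(
        op_name="while_loop",
        inputs=(),
        outputs=tuple(outputs),
        ensemble_runner=base.ensemble_runner,
        payload_to_json=base.payload_to_json,
        payload_from_json=base.payload_from_json,
    )
    node = ctx.graph.add_node(
        spec, {}, context=ctx,
        payload=_WhilePayload(operation, condition, int(max_iteration)),
    )
    return WhileLoopHandle(node)
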