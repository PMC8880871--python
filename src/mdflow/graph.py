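"""The typed work graph: operations, ports, edges, ensemble widths, futures.

A :class:`WorkGraph` is a directed acyclic graph whose nodes are instances of
declared operations and whose edges are data dependencies between output and
input ports.  Graph construction is independent of execution: adding a node
returns a :class:`NodeHandle` whose outputs are :class:`Future` proxies, and
nothing runs until a future is resolved by a session (see
:mod:`mdflow.executor`).

Every node and edge carries an *ensemble width*: the size of the implicit
parallel dimension.  Passing an ensemble (width n) future into an operation
fans the operation out to n tasks; scalar (width 1) inputs broadcast.  Two
distinct widths > 1 never unify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import kinds as _k
from .errors import (
    CycleError,
    GraphBuildError,
    KindMismatchError,
    MalformedDocumentError,
    MissingRequiredInputError,
    SchemaVersionError,
    UnknownOperationError,
    UnknownPortError,
    UnsupportedPayloadError,
    WidthMismatchError,
)
from .kinds import DataKind, array_of, compatible, conforms, infer_kind

SCHEMA_VERSION = 1

MAP = "map"
BROADCAST = "broadcast"
GATHER = "gather"

CATEGORIES = ("pure", "external_process", "simulation")


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PortSpec:
    """A named, typed input or output port.

    Required ports carry no default; optional ports may.
    """

    name: str
    kind: DataKind
    required: bool = True
    default: Any = None

    def __post_init__(self):
        if not self.name or any(c.isspace() for c in self.name):
            raise ValueError(f"invalid port name {self.name!r}")
        if self.required and self.default is not None:
            raise ValueError(f"required port {self.name!r} must not have a default")


@dataclass(eq=False)
class OperationSpec:
    """Declaration of an operation: name, typed ports, category, runner.

    ``runner(inputs, ctx) -> {port: value}`` executes one ensemble member.
    Operations whose members must be co-executed (or that drive the session
    themselves, like while_loop) provide ``ensemble_runner`` instead:
    ``ensemble_runner(handle, inputs_per_member, ctxs, session) -> [outputs]``.
    """

    op_name: str
    inputs: Tuple[PortSpec, ...]
    outputs: Tuple[PortSpec, ...]
    category: str = "pure"
    deterministic: bool = True
    runner: Optional[Callable] = None
    ensemble_runner: Optional[Callable] = None
    payload_to_json: Optional[Callable] = None
    payload_from_json: Optional[Callable] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.outputs:
            raise ValueError(f"operation {self.op_name!r} declares no outputs")
        for ports in (self.inputs, self.outputs):
            names = [p.name for p in ports]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate port names in {self.op_name!r}")

    def input_port(self, name: str) -> PortSpec:
        for p in self.inputs:
            if p.name == name:
                return p
        raise UnknownPortError(f"operation {self.op_name!r} has no input port {name!r}")

    def output_port(self, name: str) -> PortSpec:
        for p in self.outputs:
            if p.name == name:
                return p
        raise UnknownPortError(f"operation {self.op_name!r} has no output port {name!r}")


class OperationRegistry:
    """Mapping op_name -> OperationSpec, optionally chained to a parent.

    Contexts hold a registry chained to the package-wide builtin registry, so
    user-defined (wrapped) operations do not leak across contexts.
    """

    def __init__(self, parent: Optional["OperationRegistry"] = None):
        self._specs: Dict[str, OperationSpec] = {}
        self._parent = parent

    def register(self, spec: OperationSpec, replace: bool = False) -> OperationSpec:
        if not replace and spec.op_name in self._specs:
            raise GraphBuildError(f"operation {spec.op_name!r} already registered")
        self._specs[spec.op_name] = spec
        return spec

    def __contains__(self, op_name: str) -> bool:
        return op_name in self._specs or (self._parent is not None and op_name in self._parent)

    def get(self, op_name: str) -> OperationSpec:
        if op_name in self._specs:
            return self._specs[op_name]
        if self._parent is not None and op_name in self._parent:
            return self._parent.get(op_name)
        raise UnknownOperationError(f"unknown operation {op_name!r}")

    def unique_name(self, base: str) -> str:
        name, k = base, 1
        while name in self:
            k += 1
            name = f"{base}.{k}"
        return name


#: Package-wide registry of built-in operations.
BUILTIN_REGISTRY = OperationRegistry()


# --------------------------------------------------------------------------
# Width broadcasting
# --------------------------------------------------------------------------


def infer_width(widths: Sequence[int]) -> int:
    """Broadcast a set of ensemble widths: the result is the maximum, and
    every width must be 1 or equal to that maximum."""
    if not widths:
        raise ValueError("infer_width requires at least one width")
    out = max(widths)
    for w in widths:
        if w != 1 and w != out:
            raise WidthMismatchError(f"incompatible ensemble widths {sorted(set(widths))}")
    return out


# --------------------------------------------------------------------------
# Graph elements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DataEdge:
    """A data dependency from (source node, output port) to (sink node,
    input port), with an ensemble mapping mode."""

    source: Tuple[str, str]
    sink: Tuple[str, str]
    mode: str = MAP

    def __post_init__(self):
        if self.mode not in (MAP, BROADCAST, GATHER):
            raise ValueError(f"unknown edge mode {self.mode!r}")


class Future:
    """Proxy for a not-yet-computed output of a node.

    ``result()`` forces resolution of exactly the ancestor subgraph of the
    owning node and localizes the value (a list of per-member values when the
    ensemble width exceeds one).
    """

    __slots__ = ("context", "node_id", "port", "kind", "width")

    def __init__(self, context, node_id: str, port: str, kind: DataKind, width: int):
        self.context = context
        self.node_id = node_id
        self.port = port
        self.kind = kind
        self.width = width

    @property
    def ref(self) -> Tuple[str, str]:
        return (self.node_id, self.port)

    @property
    def resolved(self) -> bool:
        return self.context.session.is_cached(self.node_id)

    def result(self):
        return self.context.session.result_for(self)

    def __repr__(self):
        return f"<Future {self.node_id}.{self.port} [{self.kind}] width={self.width}>"


class _OutputNamespace:
    """Attribute access to a node's output futures; ports named ``file.<key>``
    are grouped under the ``file`` attribute as a key -> Future mapping."""

    def __init__(self, handle: "NodeHandle"):
        object.__setattr__(self, "_handle", handle)

    def __getattr__(self, name: str) -> Any:
        handle: NodeHandle = object.__getattribute__(self, "_handle")
        if name == "file":
            grouped = {
                p.name.split(".", 1)[1]: handle.output_future(p.name)
                for p in handle.spec.outputs
                if p.name.startswith("file.")
            }
            if grouped:
                return grouped
        return handle.output_future(name)

    def __getitem__(self, name: str) -> Future:
        return object.__getattribute__(self, "_handle").output_future(name)


class NodeHandle:
    """A node of the work graph: an operation instance with bound inputs.

    ``handle.output.<port>`` yields the :class:`Future` for that output.
    """

    def __init__(self, graph, context, node_id, spec, bound_inputs, width, payload=None):
        self.graph = graph
        self.context = context
        self.node_id = node_id
        self.spec = spec
        self.bound_inputs: Dict[str, Any] = bound_inputs
        self.width = width
        self.payload = payload
        self._futures: Dict[str, Future] = {}

    @property
    def output(self) -> _OutputNamespace:
        return _OutputNamespace(self)

    def output_future(self, port: str) -> Future:
        if port not in self._futures:
            pspec = self.spec.output_port(port)
            self._futures[port] = Future(self.context, self.node_id, port, pspec.kind, self.width)
        return self._futures[port]

    def run(self) -> "NodeHandle":
        """Resolve all outputs of this node (and its ancestors)."""
        self.context.session.ensure_node(self.node_id)
        return self

    def __repr__(self):
        return f"<Node {self.node_id} ({self.spec.op_name}) width={self.width}>"


@dataclass
class Diagnostic:
    """One validation finding; ``code`` is machine-readable."""

    code: str
    message: str
    nodes: Tuple[str, ...] = ()


class WorkGraph:
    """An insertion-ordered DAG of operation nodes and data edges."""

    def __init__(self):
        self.nodes: Dict[str, NodeHandle] = {}
        self.edges: List[DataEdge] = []
        self._op_counters: Dict[str, int] = {}

    # ------------------------------------------------------------- building

    def new_node_id(self, op_name: str) -> str:
        while True:
            k = self._op_counters.get(op_name, 0)
            self._op_counters[op_name] = k + 1
            node_id = f"{op_name}-{k}"
            if node_id not in self.nodes:
                return node_id

    def add_node(
        self,
        spec: OperationSpec,
        inputs: Mapping[str, Any],
        *,
        context,
        node_id: Optional[str] = None,
        width: Optional[int] = None,
        payload: Any = None,
    ) -> NodeHandle:
        """Append a node binding *inputs* (constants or futures) to ports.

        Creates one data edge per future input, infers the node's ensemble
        width by broadcasting, and preserves acyclicity by construction (a
        new node has no outgoing edges).
        """
        input_names = {p.name for p in spec.inputs}
        for name in inputs:
            if name not in input_names:
                raise UnknownPortError(
                    f"operation {spec.op_name!r} has no input port {name!r}"
                )
        bound: Dict[str, Any] = {}
        for port in spec.inputs:
            if port.name in inputs:
                bound[port.name] = inputs[port.name]
            elif port.default is not None:
                bound[port.name] = port.default
            elif port.required:
                raise MissingRequiredInputError(
                    f"required input {port.name!r} of {spec.op_name!r} is not bound"
                )

        widths = [1] if width is None else [width]
        gather_ports = set()
        for name, value in bound.items():
            pspec = spec.input_port(name)
            if isinstance(value, Future):
                if value.node_id not in self.nodes:
                    raise GraphBuildError(
                        f"future {value!r} does not belong to this graph"
                    )
                if compatible(value.kind, pspec.kind):
                    widths.append(value.width)
                elif (
                    pspec.kind.tag == "array"
                    and value.width > 1
                    and (
                        pspec.kind.element is None
                        or compatible(value.kind, pspec.kind.element)
                    )
                ):
                    gather_ports.add(name)
                    widths.append(1)
                else:
                    raise KindMismatchError(
                        f"cannot bind {value.kind} future to {pspec.kind} port "
                        f"{name!r} of {spec.op_name!r}"
                    )
            else:
                if not conforms(value, pspec.kind):
                    raise KindMismatchError(
                        f"constant {value!r} does not conform to {pspec.kind} port "
                        f"{name!r} of {spec.op_name!r}"
                    )
                widths.append(1)

        node_width = infer_width(widths)
        if width is not None and width != node_width:
            raise WidthMismatchError(
                f"explicit width {width} conflicts with inferred {node_width}"
            )

        if node_id is None:
            node_id = self.new_node_id(spec.op_name)
        elif node_id in self.nodes:
            raise GraphBuildError(f"duplicate node id {node_id!r}")

        handle = NodeHandle(self, context, node_id, spec, bound, node_width, payload)
        self.nodes[node_id] = handle
        for name, value in bound.items():
            if isinstance(value, Future):
                if name in gather_ports:
                    mode = GATHER
                elif value.width == node_width:
                    mode = MAP
                else:
                    mode = BROADCAST
                self.edges.append(DataEdge(value.ref, (node_id, name), mode))
        return handle

    # ------------------------------------------------------------ structure

    def predecessors(self, node_id: str) -> List[str]:
        return [e.source[0] for e in self.edges if e.sink[0] == node_id]

    def in_edges(self, node_id: str) -> List[DataEdge]:
        return [e for e in self.edges if e.sink[0] == node_id]

    def edge_for(self, node_id: str, port: str) -> Optional[DataEdge]:
        for e in self.edges:
            if e.sink == (node_id, port):
                return e
        return None

    def ancestors(self, node_id: str) -> set:
        """All nodes reachable backwards from *node_id* (excluded)."""
        seen: set = set()
        stack = [node_id]
        while stack:
            nid = stack.pop()
            for pred in self.predecessors(nid):
                if pred not in seen:
                    seen.add(pred)
                    stack.append(pred)
        return seen

    def topological_order(self, restrict: Optional[Iterable[str]] = None) -> List[str]:
        """Kahn's algorithm with stable insertion-order tie-breaking.

        With *restrict*, orders only that subset (edges within it).
        """
        universe = list(self.nodes) if restrict is None else [
            n for n in self.nodes if n in set(restrict)
        ]
        uni = set(universe)
        indeg = {n: 0 for n in universe}
        succs: Dict[str, List[str]] = {n: [] for n in universe}
        for e in self.edges:
            s, t = e.source[0], e.sink[0]
            if s in uni and t in uni:
                indeg[t] += 1
                succs[s].append(t)
        order: List[str] = []
        ready = [n for n in universe if indeg[n] == 0]  # insertion order
        while ready:
            n = ready.pop(0)
            order.append(n)
            newly = []
            for t in succs[n]:
                indeg[t] -= 1
                if indeg[t] == 0:
                    newly.append(t)
            # preserve global insertion order among ready nodes
            ready = [x for x in universe if x in set(ready) | set(newly) and x not in set(order)]
        if len(order) != len(universe):
            raise CycleError("graph contains a cycle among: "
                             + ", ".join(sorted(set(universe) - set(order))))
        return order

    def validate(self) -> List[Diagnostic]:
        """Structural diagnostics; empty iff the graph satisfies all
        invariants (existence of endpoints, kind compatibility, width rules,
        acyclicity)."""
        diags: List[Diagnostic] = []
        for e in self.edges:
            for end, label in ((e.source, "source"), (e.sink, "sink")):
                nid, port = end
                if nid not in self.nodes:
                    diags.append(Diagnostic("dangling-edge", f"{label} node {nid!r} missing", (nid,)))
                    continue
                spec = self.nodes[nid].spec
                try:
                    spec.output_port(port) if label == "source" else spec.input_port(port)
                except UnknownPortError:
                    diags.append(Diagnostic("unknown-port", f"{label} port {port!r} on {nid!r}", (nid,)))
        for e in self.edges:
            if e.source[0] in self.nodes and e.sink[0] in self.nodes:
                src = self.nodes[e.source[0]]
                snk = self.nodes[e.sink[0]]
                try:
                    out_k = src.spec.output_port(e.source[1]).kind
                    in_k = snk.spec.input_port(e.sink[1]).kind
                except UnknownPortError:
                    continue
                if e.mode == GATHER:
                    ok = in_k.tag == "array" and (
                        in_k.element is None or compatible(out_k, in_k.element)
                    )
                else:
                    ok = compatible(out_k, in_k)
                if not ok:
                    diags.append(Diagnostic(
                        "kind-mismatch",
                        f"edge {e.source} -> {e.sink}: {out_k} vs {in_k}",
                        (src.node_id, snk.node_id),
                    ))
                if e.mode == MAP and src.width != snk.width:
                    diags.append(Diagnostic(
                        "width-mismatch",
                        f"map edge {e.source} -> {e.sink}: widths {src.width} vs {snk.width}",
                        (src.node_id, snk.node_id),
                    ))
        # cycle detection: iterative DFS, independent of topological_order
        color: Dict[str, int] = {}
        succs: Dict[str, List[str]] = {n: [] for n in self.nodes}
        for e in self.edges:
            if e.source[0] in succs and e.sink[0] in self.nodes:
                succs[e.source[0]].append(e.sink[0])
        for root in self.nodes:
            if color.get(root):
                continue
            stack: List[Tuple[str, int]] = [(root, 0)]
            path: List[str] = []
            while stack:
                node, idx = stack.pop()
                if idx == 0:
                    if color.get(node) == 2:
                        continue
                    color[node] = 1
                    path.append(node)
                if idx < len(succs[node]):
                    stack.append((node, idx + 1))
                    child = succs[node][idx]
                    if color.get(child) == 1:
                        cyc = path[path.index(child):] + [child]
                        diags.append(Diagnostic("cycle", "cycle: " + " -> ".join(cyc), tuple(cyc[:-1])))
                    elif color.get(child) != 2:
                        stack.append((child, 0))
                else:
                    color[node] = 2
                    path.pop()
        return diags

    # -------------------------------------------------------- serialization

    def serialize(self) -> str:
        """JSON document: ``{schema_version, nodes, edges}``.

        Constants must be JSON-representable; operations with non-portable
        payloads must provide ``payload_to_json``.
        """
        nodes_doc = []
        for nid, handle in self.nodes.items():
            constants = {}
            for name, value in handle.bound_inputs.items():
                if not isinstance(value, Future):
                    if hasattr(value, "to_json"):
                        value = value.to_json()
                    try:
                        json.dumps(value)
                    except TypeError as exc:
                        raise UnsupportedPayloadError(
                            f"constant on {nid}.{name} is not JSON-serializable"
                        ) from exc
                    constants[name] = value
            doc = {
                "id": nid,
                "op": handle.spec.op_name,
                "width": handle.width,
                "constants": constants,
                "ports": {
                    "inputs": {p.name: p.kind.to_json() for p in handle.spec.inputs},
                    "outputs": {p.name: p.kind.to_json() for p in handle.spec.outputs},
                },
            }
            if handle.payload is not None:
                if handle.spec.payload_to_json is None:
                    raise UnsupportedPayloadError(
                        f"node {nid!r} carries a payload the operation cannot serialize"
                    )
                doc["payload"] = handle.spec.payload_to_json(handle.payload)
            nodes_doc.append(doc)
        edges_doc = [
            {"source": list(e.source), "sink": list(e.sink), "mode": e.mode}
            for e in self.edges
        ]
        return json.dumps(
            {"schema_version": SCHEMA_VERSION, "nodes": nodes_doc, "edges": edges_doc},
            indent=2,
        )

    def to_dot(self) -> str:
        """Graphviz DOT export (node label = node id, edge label = ports)."""
        lines = ["digraph workgraph {", "  rankdir=LR;"]
        for nid in self.nodes:
            lines.append(f'  "{nid}";')
        for e in self.edges:
            label = f"{e.source[1]}->{e.sink[1]}"
            style = {"map": "solid", "broadcast": "dashed", "gather": "bold"}[e.mode]
            lines.append(
                f'  "{e.source[0]}" -> "{e.sink[0]}" [label="{label}", style={style}];'
            )
        lines.append("}")
        return "\n".join(lines)


def _retype_spec(spec: OperationSpec, ports_doc: dict) -> OperationSpec:
    """Clone a registered spec with the port kinds recorded in a document.

    Registry specs for generic operations (constants, array joins) declare
    placeholder kinds; the document preserves the kinds the graph was built
    with so futures keep their nominal types across a round-trip.
    """
    def rebuild(declared: Tuple[PortSpec, ...], doc: dict) -> Tuple[PortSpec, ...]:
        by_name = {p.name: p for p in declared}
        out = []
        for name, kind_doc in doc.items():
            kind = DataKind.from_json(kind_doc)
            old = by_name.get(name)
            if old is not None:
                out.append(PortSpec(name, kind, old.required, old.default))
            else:
                out.append(PortSpec(name, kind, required=False))
        return tuple(out)

    import dataclasses

    return dataclasses.replace(
        spec,
        inputs=rebuild(spec.inputs, ports_doc.get("inputs", {})),
        outputs=rebuild(spec.outputs, ports_doc.get("outputs", {})),
    )


def deserialize(text: str, context) -> WorkGraph:
    """Rebuild a work graph in *context* from its JSON document.

    Operations must be present in the context's registry; wrapped user
    procedures therefore require re-registration before loading.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedDocumentError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or not {"schema_version", "nodes", "edges"} <= set(doc):
        raise MalformedDocumentError("missing required top-level keys")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"schema version {doc['schema_version']!r} != {SCHEMA_VERSION}"
        )
    graph = context.graph
    by_sink: Dict[Tuple[str, str], dict] = {}
    for e in doc["edges"]:
        by_sink[(e["sink"][0], e["sink"][1])] = e
    for ndoc in doc["nodes"]:
        spec = context.registry.get(ndoc["op"])
        if "ports" in ndoc:
            spec = _retype_spec(spec, ndoc["ports"])
        inputs: Dict[str, Any] = dict(ndoc.get("constants", {}))
        for (sink_node, sink_port), e in by_sink.items():
            if sink_node == ndoc["id"]:
                src_node, src_port = e["source"]
                if src_node not in graph.nodes:
                    raise MalformedDocumentError(
                        f"edge source {src_node!r} precedes its definition"
                    )
                inputs[sink_port] = graph.nodes[src_node].output_future(src_port)
        payload = None
        if "payload" in ndoc:
            if spec.payload_from_json is None:
                raise MalformedDocumentError(
                    f"operation {spec.op_name!r} cannot load a payload"
                )
            payload = spec.payload_from_json(ndoc["payload"], context)
        graph.add_node(
            spec,
            inputs,
            context=context,
            node_id=ndoc["id"],
            width=ndoc["width"] if ndoc["width"] > 1 else None,
            payload=payload,
        )
    return graph
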