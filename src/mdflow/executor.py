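"""Deferred, cached, minimal execution of work graphs.

A :class:`Session` owns the run-time state of one work graph: per-node output
caches, an executed-node log, a working-directory root for external
processes and simulations, and the session seed.  Resolving a future runs
exactly the ancestor subgraph of its node — nothing else — in an order
consistent with the graph's topological order, and every (node, member) is
executed at most once per session lifetime, so trajectories can be forked or
extended without re-running earlier segments.
"""

from __future__ import annotations

import json
import os
import tempfile
import time
import zlib
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

from .errors import OutputKindViolationError, UpstreamFailureError
from .graph import BROADCAST, GATHER, MAP, Future, NodeHandle, WorkGraph
from .kinds import conforms


@dataclass
class ExecutionRecord:
    """One executed (node, member): completion order, timing, extras
    (e.g. the rendered argument list of an external process)."""

    node_id: str
    op_name: str
    member: int
    status: str
    order_index: int
    wall_time: float
    extra: Dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> Dict[str, Any]:
        return {
            "node_id": self.node_id,
            "op_name": self.op_name,
            "member": self.member,
            "status": self.status,
            "order_index": self.order_index,
            "wall_time": self.wall_time,
            **({"extra": self.extra} if self.extra else {}),
        }


@dataclass
class EnsembleValue:
    """A per-member value vector carried through a width-1 port (used by
    while_loop state propagation); localizes to the member list."""

    values: List[Any]

    @property
    def width(self) -> int:
        return len(self.values)


class ExecContext:
    """Per-(node, member) resources handed to operation runners: a stable
    unique working directory, a derived deterministic seed, and log extras."""

    def __init__(self, session: "Session", node_id: str, member: int):
        self.session = session
        self.node_id = node_id
        self.member = member
        self.log_extra: Dict[str, Any] = {}

    @property
    def seed(self) -> int:
        """seed = session_seed XOR crc32(node_id:member), below 2**31."""
        h = zlib.crc32(f"{self.node_id}:{self.member}".encode())
        return (self.session.seed ^ h) & 0x7FFFFFFF

    @property
    def workdir(self) -> str:
        """``<workdir_root>/<node_id>/<member>/`` — created on first use,
        never shared between (node, member) pairs."""
        path = os.path.join(self.session.workdir_root, self.node_id, str(self.member))
        os.makedirs(path, exist_ok=True)
        return path


class Session:
    """Execution state for one work graph."""

    def __init__(self, graph: WorkGraph, context, workdir_root: Optional[str] = None,
                 seed: int = 0):
        self.graph = graph
        self.context = context
        self.seed = int(seed)
        self._workdir_root = workdir_root
        self.cache: Dict[str, List[Dict[str, Any]]] = {}
        self.log: List[ExecutionRecord] = []
        self.failures: Dict[str, UpstreamFailureError] = {}

    @property
    def workdir_root(self) -> str:
        if self._workdir_root is None:
            self._workdir_root = tempfile.mkdtemp(prefix="mdflow-")
        self._workdir_root = os.path.abspath(self._workdir_root)
        os.makedirs(self._workdir_root, exist_ok=True)
        return self._workdir_root

    # -------------------------------------------------------------- queries

    def is_cached(self, node_id: str) -> bool:
        return node_id in self.cache

    def executed_nodes(self) -> List[str]:
        """Node ids in completion order (deduplicated, ensemble-collapsed)."""
        seen, out = set(), []
        for rec in self.log:
            if rec.node_id not in seen:
                seen.add(rec.node_id)
                out.append(rec.node_id)
        return out

    def write_log(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec.to_json()) + "\n")

    # ------------------------------------------------------------ execution

    def result_for(self, future: Future) -> Any:
        """Resolve and localize one future (list of values when width > 1)."""
        self.ensure_node(future.node_id)
        values = [m[future.port] for m in self.cache[future.node_id]]
        values = [v.values if isinstance(v, EnsembleValue) else v for v in values]
        return values[0] if future.width == 1 else values

    def run(self, handle: NodeHandle) -> NodeHandle:
        self.ensure_node(handle.node_id)
        return handle

    def ensure_node(self, node_id: str) -> None:
        """Execute exactly the pending ancestors of *node_id* (and itself)."""
        if node_id in self.cache:
            return
        needed = self.graph.ancestors(node_id) | {node_id}
        for nid in self.graph.topological_order(restrict=needed):
            if nid not in self.cache:
                self._execute(self.graph.nodes[nid])

    def _inputs_for(self, handle: NodeHandle, member: int) -> Dict[str, Any]:
        inputs: Dict[str, Any] = {}
        for name, value in handle.bound_inputs.items():
            if isinstance(value, Future):
                edge = self.graph.edge_for(handle.node_id, name)
                src_cache = self.cache[value.node_id]
                if edge is not None and edge.mode == GATHER:
                    inputs[name] = [m[value.port] for m in src_cache]
                elif edge is not None and edge.mode == BROADCAST:
                    inputs[name] = src_cache[0][value.port]
                else:  # map
                    idx = member if len(src_cache) > 1 else 0
                    inputs[name] = src_cache[idx][value.port]
            else:
                inputs[name] = value
        return inputs

    def _check_outputs(self, handle: NodeHandle, outputs: Dict[str, Any]) -> None:
        for port in handle.spec.outputs:
            if port.name not in outputs:
                raise OutputKindViolationError(
                    f"node {handle.node_id!r} produced no value for output "
                    f"{port.name!r}"
                )
            if isinstance(outputs[port.name], EnsembleValue):
                continue
            if not conforms(outputs[port.name], port.kind):
                raise OutputKindViolationError(
                    f"node {handle.node_id!r} output {port.name!r}: value "
                    f"{outputs[port.name]!r} does not conform to {port.kind}"
                )

    def _execute(self, handle: NodeHandle) -> None:
        nid = handle.node_id
        if nid in self.failures:
            raise self.failures[nid]
        spec = handle.spec
        inputs_per_member = [self._inputs_for(handle, m) for m in range(handle.width)]
        ctxs = [ExecContext(self, nid, m) for m in range(handle.width)]
        t0 = time.perf_counter()
        try:
            if spec.ensemble_runner is not None:
                outs = spec.ensemble_runner(handle, inputs_per_member, ctxs, self)
            else:
                outs = []
                for m in range(handle.width):
                    try:
                        outs.append(spec.runner(inputs_per_member[m], ctxs[m]))
                    except UpstreamFailureError:
                        raise
                    except Exception as exc:  # noqa: BLE001
                        raise UpstreamFailureError(nid, m, exc) from exc
            for out in outs:
                self._check_outputs(handle, out)
        except UpstreamFailureError as err:
            self.failures[nid] = err
            raise
        except Exception as exc:  # noqa: BLE001 - wrapped with node context
            err = UpstreamFailureError(nid, 0, exc)
            self.failures[nid] = err
            raise err from exc
        elapsed = time.perf_counter() - t0
        self.cache[nid] = list(outs)
        for m in range(handle.width):
            self.log.append(ExecutionRecord(
                node_id=nid,
                op_name=spec.op_name,
                member=m,
                status="done",
                order_index=len(self.log),
                wall_time=elapsed / handle.width,
                extra=ctxs[m].log_extra,
            ))
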