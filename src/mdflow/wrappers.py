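"""Turn arbitrary user procedures into graph operations.

``function_wrapper(output={...})`` decorates a plain callable into an
operation factory: calling the factory with input bindings adds a node to
the active graph and returns a handle whose outputs are futures, one per
declared output.  Procedures are assumed uncoupled across ensemble members
and are invoked exactly once per (node, member); results are cached by the
session.

Two assignment styles are supported, mirroring common data-flow APIs:

* single declared output — the procedure simply returns the value;
* multiple outputs (or an explicit ``output`` parameter) — the procedure
  receives an output-assignment handle and sets attributes on it.
"""

from __future__ import annotations

import inspect
from typing import Any, Callable, Dict, Mapping, Optional

from .context import Context, get_context
from .errors import (
    MissingRequiredInputError,
    OutputKindViolationError,
    OutputNeverAssignedError,
    UndeclaredOutputError,
    UnknownPortError,
)
from .graph import NodeHandle, OperationSpec, PortSpec
from .kinds import DataKind, conforms, infer_kind
from .graph import Future

RESERVED_PARAMS = ("output", "resources")


class OutputCollector:
    """The output-assignment handle passed to multi-output procedures."""

    def __init__(self, decl: Mapping[str, DataKind]):
        object.__setattr__(self, "_decl", dict(decl))
        object.__setattr__(self, "_values", {})

    def __setattr__(self, name: str, value: Any) -> None:
        decl = object.__getattribute__(self, "_decl")
        if name not in decl:
            raise UndeclaredOutputError(f"procedure wrote undeclared output {name!r}")
        if not conforms(value, decl[name]):
            raise OutputKindViolationError(
                f"output {name!r}: {value!r} does not conform to {decl[name]}"
            )
        object.__getattribute__(self, "_values")[name] = value

    @property
    def values(self) -> Dict[str, Any]:
        return dict(object.__getattribute__(self, "_values"))


class WrappedFunction:
    """An operation factory produced by :func:`function_wrapper`."""

    def __init__(self, func: Callable, output_decl: Mapping[str, DataKind],
                 needs_resources: bool = False):
        if not output_decl:
            raise ValueError("output declaration must not be empty")
        self.func = func
        self.output_decl = dict(output_decl)
        self.needs_resources = needs_resources
        sig = inspect.signature(func)
        self.takes_collector = "output" in sig.parameters or len(self.output_decl) > 1
        self.params = {
            name: p
            for name, p in sig.parameters.items()
            if name not in RESERVED_PARAMS
            and p.kind is not inspect.Parameter.VAR_KEYWORD
        }
        self.var_keyword = any(
            p.kind is inspect.Parameter.VAR_KEYWORD
            for p in sig.parameters.values()
        )

    # -- execution ---------------------------------------------------------
    def _runner(self, inputs: Dict[str, Any], ctx) -> Dict[str, Any]:
        kwargs = dict(inputs)
        if self.needs_resources:
            kwargs["resources"] = ctx
        if self.takes_collector:
            collector = OutputCollector(self.output_decl)
            kwargs["output"] = collector
            self.func(**kwargs)
            outputs = collector.values
        else:
            (name,) = self.output_decl
            value = self.func(**kwargs)
            if not conforms(value, self.output_decl[name]):
                raise OutputKindViolationError(
                    f"output {name!r}: {value!r} does not conform to "
                    f"{self.output_decl[name]}"
                )
            outputs = {name: value}
        missing = set(self.output_decl) - set(outputs)
        if missing:
            raise OutputNeverAssignedError(
                f"declared outputs never assigned: {sorted(missing)}"
            )
        return outputs

    # -- graph building ----------------------------------------------------
    def _op_name(self, ctx: Context) -> str:
        # one registered name per (wrapped function, registry), stored on the
        # registry so lifetimes stay aligned
        names = ctx.registry.__dict__.setdefault("_wrapped_names", {})
        if self not in names:
            name = ctx.registry.unique_name(self.func.__name__)
            ctx.registry.register(OperationSpec(
                op_name=name,
                inputs=tuple(
                    PortSpec(p, DataKind("record"), required=False)
                    for p in self.params
                ),
                outputs=tuple(
                    PortSpec(n, k) for n, k in self.output_decl.items()
                ),
                runner=self._runner,
            ))
            names[self] = name
        return names[self]

    def register(self, context: Optional[Context] = None) -> str:
        """Ensure this wrapped operation is registered in a context's
        registry (needed before deserializing graphs that reference it);
        returns the registered op name."""
        return self._op_name(context or get_context())

    def __call__(self, context: Optional[Context] = None, **inputs) -> NodeHandle:
        ctx = context or get_context()
        for name in inputs:
            if name not in self.params and not self.var_keyword:
                raise UnknownPortError(
                    f"{self.func.__name__!r} has no input parameter {name!r}"
                )
        for name, p in self.params.items():
            if name not in inputs and p.default is inspect.Parameter.empty:
                raise MissingRequiredInputError(
                    f"parameter {name!r} of {self.func.__name__!r} is not bound"
                )
        # input kinds are inferred from the bound values at build time
        in_ports = []
        for name, value in inputs.items():
            kind = value.kind if isinstance(value, Future) else infer_kind(value)
            in_ports.append(PortSpec(name, kind, required=False))
        spec = OperationSpec(
            op_name=self._op_name(ctx),
            inputs=tuple(in_ports),
            outputs=tuple(PortSpec(n, k) for n, k in self.output_decl.items()),
            runner=self._runner,
        )
        return ctx.graph.add_node(spec, inputs, context=ctx)


def function_wrapper(output: Mapping[str, DataKind], *,
                     needs_resources: bool = False):
    """Decorator factory: declare output names and kinds, get back an
    operation factory for the decorated procedure.

    ``needs_resources=True`` passes the per-(node, member) execution context
    (working directory, derived seed) as a ``resources`` keyword.
    """

    def decorate(func: Callable) -> WrappedFunction:
        return WrappedFunction(func, output, needs_resources=needs_resources)

    return decorate
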