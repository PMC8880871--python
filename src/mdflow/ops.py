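"""Typing, data-topology and logic primitives.

These are the simplest graph operations: constants, array joining, boolean
negation, and the composable ``concatenate_lists`` helper, which is not an
operation itself but a fold that *builds* ``join_arrays`` nodes.
"""

from __future__ import annotations

from typing import Any, Optional, Sequence

from .context import Context, get_context
from .errors import KindMismatchError, UnsupportedPayloadError
from .graph import BUILTIN_REGISTRY, Future, NodeHandle, OperationSpec, PortSpec
from .kinds import BOOLEAN, DataKind, array_of, compatible, infer_kind

# --------------------------------------------------------------------------
# make_constant
# --------------------------------------------------------------------------

_CONSTANT_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="make_constant",
    inputs=(PortSpec("value", DataKind("record"), required=True),),
    outputs=(PortSpec("value", DataKind("record")),),
    runner=lambda inputs, ctx: {"value": inputs["value"]},
))


def _typed_identity_spec(base: OperationSpec, kind: DataKind) -> OperationSpec:
    """A per-kind view of an identity-like spec (nominal typing needs the
    output future to carry the payload's kind, not ``record``)."""
    return OperationSpec(
        op_name=base.op_name,
        inputs=(PortSpec("value", kind, required=True),),
        outputs=(PortSpec("value", kind),),
        category=base.category,
        runner=base.runner,
    )


def make_constant(value: Any, context: Optional[Context] = None) -> Future:
    """Lift a constant payload into the graph; resolving the returned future
    yields the value unchanged.  Raises :class:`UnsupportedPayloadError` for
    heterogeneous arrays or unknown scalar types."""
    ctx = context or get_context()
    kind = infer_kind(value)
    spec = _typed_identity_spec(_CONSTANT_SPEC, kind)
    handle = ctx.graph.add_node(spec, {"value": value}, context=ctx)
    return handle.output.value


_ENSEMBLE_CONSTANT_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="ensemble_constant",
    inputs=(),
    outputs=(PortSpec("value", DataKind("record")),),
    runner=None,  # ensemble_runner below
    ensemble_runner=lambda handle, inputs, ctxs, session: [
        {"value": v} for v in handle.payload
    ],
    payload_to_json=lambda payload: list(payload),
    payload_from_json=lambda doc, context: list(doc),
))


def ensemble_input(values: Sequence[Any], context: Optional[Context] = None) -> Future:
    """Lift a sequence of per-member payloads into a width-``len(values)``
    ensemble future (the fan-out entry point for ensemble workflows)."""
    ctx = context or get_context()
    values = list(values)
    if not values:
        raise UnsupportedPayloadError("an ensemble needs at least one member")
    kind = infer_kind(values[0])
    for v in values[1:]:
        if not compatible(kind, infer_kind(v)):
            raise UnsupportedPayloadError("ensemble members differ in kind")
    spec = OperationSpec(
        op_name="ensemble_constant",
        inputs=(),
        outputs=(PortSpec("value", kind),),
        ensemble_runner=_ENSEMBLE_CONSTANT_SPEC.ensemble_runner,
        payload_to_json=_ENSEMBLE_CONSTANT_SPEC.payload_to_json,
        payload_from_json=_ENSEMBLE_CONSTANT_SPEC.payload_from_json,
    )
    handle = ctx.graph.add_node(spec, {}, context=ctx, width=len(values),
                                payload=values)
    return handle.output.value


# --------------------------------------------------------------------------
# join_arrays / logical_not / gather
# --------------------------------------------------------------------------

_JOIN_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="join_arrays",
    inputs=(
        PortSpec("front", DataKind("array"), required=True),
        PortSpec("back", DataKind("array"), required=True),
    ),
    outputs=(PortSpec("value", DataKind("array")),),
    runner=lambda inputs, ctx: {"value": list(inputs["front"]) + list(inputs["back"])},
))


def _array_kind_of(value: Any) -> DataKind:
    kind = value.kind if isinstance(value, Future) else infer_kind(value)
    if kind.tag != "array":
        raise KindMismatchError(f"expected an array, got {kind}")
    return kind


def join_arrays(front: Any, back: Any, context: Optional[Context] = None) -> Future:
    """Concatenate two arrays of the same element kind."""
    ctx = context or get_context()
    fk, bk = _array_kind_of(front), _array_kind_of(back)
    if not compatible(fk, bk):
        raise KindMismatchError(f"element kind mismatch: {fk} vs {bk}")
    out_kind = fk if fk.element is not None else bk
    spec = OperationSpec(
        op_name="join_arrays",
        inputs=(
            PortSpec("front", fk, required=True),
            PortSpec("back", bk, required=True),
        ),
        outputs=(PortSpec("value", out_kind),),
        runner=_JOIN_SPEC.runner,
    )
    handle = ctx.graph.add_node(spec, {"front": front, "back": back}, context=ctx)
    return handle.output.value


_NOT_SPEC = BUILTIN_REGISTRY.register(OperationSpec(
    op_name="logical_not",
    inputs=(PortSpec("value", BOOLEAN, required=True),),
    outputs=(PortSpec("value", BOOLEAN),),
    runner=lambda inputs, ctx: {"value": not inputs["value"]},
))


def logical_not(value: Any, context: Optional[Context] = None) -> Future:
    """Boolean negation, member-wise over ensembles; an involution."""
    ctx = context or get_context()
    kind = value.kind if isinstance(value, Future) else infer_kind(value)
    if not compatible(kind, BOOLEAN):
        raise KindMismatchError(f"logical_not expects boolean, got {kind}")
    handle = ctx.graph.add_node(_NOT_SPEC, {"value": value}, context=ctx)
    return handle.output.value


def gather(future: Future, context: Optional[Context] = None) -> Future:
    """Collect a width-n ensemble future into one width-1 array future,
    ordered by ensemble member index (0-based)."""
    ctx = context or get_context()
    spec = OperationSpec(
        op_name="gather_members",
        inputs=(PortSpec("values", array_of(future.kind), required=True),),
        outputs=(PortSpec("value", array_of(future.kind)),),
        runner=lambda inputs, _ctx: {"value": list(inputs["values"])},
    )
    handle = ctx.graph.add_node(spec, {"values": future}, context=ctx)
    return handle.output.value


BUILTIN_REGISTRY.register(OperationSpec(
    op_name="gather_members",
    inputs=(PortSpec("values", DataKind("array"), required=True),),
    outputs=(PortSpec("value", DataKind("array")),),
    runner=lambda inputs, _ctx: {"value": list(inputs["values"])},
))


# --------------------------------------------------------------------------
# concatenate_lists — composability: a fold of join_arrays nodes
# --------------------------------------------------------------------------


def concatenate_lists(sublists: Sequence[Any] = (),
                      context: Optional[Context] = None) -> Future:
    """Concatenate a sequence of arrays by *constructing* a left fold of
    ``join_arrays`` nodes starting from the empty array.

    An empty sequence yields an empty array of unknown element kind, which
    unifies with any array kind downstream.
    """
    ctx = context or get_context()
    acc = make_constant([], context=ctx)
    for sub in sublists:
        acc = join_arrays(acc, sub, context=ctx)
    return acc
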