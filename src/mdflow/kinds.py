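"""The minimal nominal data-kind system attached to operation ports.

Scalar tags: ``boolean``, ``integer``, ``real``, ``text``, ``file_path`` and
``record`` (an opaque structured payload used for simulation inputs and
systems).  ``array`` wraps an element kind, to a nesting depth of at most two.
Kinds are compared nominally — there is no implicit integer→real coercion —
so wiring mistakes fail at graph-build time, not at run time.
"""

from __future__ import annotations

import numbers
import os
from dataclasses import dataclass
from typing import Any, Optional

import numpy as np

from .errors import UnsupportedPayloadError

_SCALAR_TAGS = ("boolean", "integer", "real", "text", "file_path", "record")
_MAX_ARRAY_DEPTH = 2


@dataclass(frozen=True)
class DataKind:
    """A port/data kind: a tag, plus an element kind for arrays.

    An array with ``element=None`` has *unknown* element kind (the kind of an
    empty literal array); it unifies with any other array kind.
    """

    tag: str
    element: Optional["DataKind"] = None

    def __post_init__(self):
        if self.tag not in _SCALAR_TAGS + ("array",):
            raise ValueError(f"unknown kind tag {self.tag!r}")
        if self.tag != "array" and self.element is not None:
            raise ValueError("only array kinds carry an element kind")

    @property
    def depth(self) -> int:
        if self.tag != "array":
            return 0
        return 1 + (self.element.depth if self.element is not None else 0)

    def __str__(self) -> str:
        if self.tag == "array":
            return f"array_of({self.element if self.element else '?'})"
        return self.tag

    # -- JSON round-trip ---------------------------------------------------
    def to_json(self):
        if self.tag == "array":
            return {"array_of": self.element.to_json() if self.element else None}
        return self.tag

    @staticmethod
    def from_json(doc) -> "DataKind":
        if isinstance(doc, str):
            return DataKind(doc)
        if isinstance(doc, dict) and set(doc) == {"array_of"}:
            elem = doc["array_of"]
            return array_of(DataKind.from_json(elem)) if elem is not None else DataKind("array")
        raise ValueError(f"not a kind document: {doc!r}")


BOOLEAN = DataKind("boolean")
INTEGER = DataKind("integer")
REAL = DataKind("real")
TEXT = DataKind("text")
FILE_PATH = DataKind("file_path")
RECORD = DataKind("record")


def array_of(element: Optional[DataKind]) -> DataKind:
    """Array kind over *element*; nesting depth is capped at two."""
    kind = DataKind("array", element)
    if kind.depth > _MAX_ARRAY_DEPTH:
        raise ValueError("array nesting depth exceeds 2")
    return kind


def compatible(a: DataKind, b: DataKind) -> bool:
    """Nominal compatibility: tags must match recursively; an unknown array
    element unifies with anything."""
    if a.tag != b.tag:
        return False
    if a.tag != "array":
        return True
    if a.element is None or b.element is None:
        return True
    return compatible(a.element, b.element)


def infer_kind(value: Any) -> DataKind:
    """Infer the kind of a constant payload.

    Raises :class:`UnsupportedPayloadError` for heterogeneous arrays or
    unknown scalar types.
    """
    if isinstance(value, (bool, np.bool_)):
        return BOOLEAN
    if isinstance(value, (int, np.integer)):
        return INTEGER
    if isinstance(value, (float, np.floating)):
        return REAL
    if isinstance(value, os.PathLike):
        return FILE_PATH
    if isinstance(value, str):
        return TEXT
    if isinstance(value, (list, tuple)):
        elem: Optional[DataKind] = None
        for item in value:
            k = infer_kind(item)
            if elem is None:
                elem = k
            elif not compatible(elem, k):
                raise UnsupportedPayloadError(
                    f"heterogeneous array: {elem} vs {k}"
                )
            elif elem.tag == "array" and elem.element is None:
                elem = k  # refine unknown element
        try:
            return array_of(elem)
        except ValueError as exc:
            raise UnsupportedPayloadError(str(exc)) from exc
    if isinstance(value, np.ndarray):
        return infer_kind(value.tolist())
    if isinstance(value, dict) or hasattr(value, "__dataclass_fields__"):
        return RECORD
    raise UnsupportedPayloadError(f"cannot infer data kind of {type(value).__name__}")


def conforms(value: Any, kind: DataKind) -> bool:
    """Whether a constant payload may be bound to a port of *kind*.

    Strings conform to ``file_path`` ports (paths are written as strings);
    everything else is nominal.
    """
    if kind.tag == "file_path" and isinstance(value, (str, os.PathLike)):
        return True
    if kind.tag == "record":
        return True
    try:
        return compatible(infer_kind(value), kind)
    except UnsupportedPayloadError:
        return False
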