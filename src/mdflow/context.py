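"""Build/run contexts.

A :class:`Context` bundles one work graph, one operation registry (chained to
the package builtins, so user-wrapped operations stay local), and one
execution session.  Operations add nodes to the *active* context, which is the
innermost ``with Context(): ...`` block, or a process-wide default.
"""

from __future__ import annotations

from typing import List, Optional

from .executor import Session
from .graph import BUILTIN_REGISTRY, OperationRegistry, WorkGraph


class Context:
    def __init__(self, workdir: Optional[str] = None, seed: int = 0,
                 registry_parent: Optional[OperationRegistry] = None):
        self.registry = OperationRegistry(parent=registry_parent or BUILTIN_REGISTRY)
        self.graph = WorkGraph()
        self.session = Session(self.graph, self, workdir_root=workdir, seed=seed)

    def __enter__(self) -> "Context":
        _STACK.append(self)
        return self

    def __exit__(self, *exc) -> None:
        _STACK.remove(self)


_STACK: List[Context] = []


def get_context() -> Context:
    """The active context (creating the process-wide default if needed)."""
    if not _STACK:
        _STACK.append(Context())
    return _STACK[0] if len(_STACK) == 1 else _STACK[-1]
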