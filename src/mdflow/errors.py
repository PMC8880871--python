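"""Exception hierarchy for work-graph construction and execution.

Construction-time errors (wiring mistakes) derive from :class:`GraphBuildError`;
run-time errors derive from :class:`ExecutionError`.  Nonzero exit codes of
wrapped command-line tools are *data*, never exceptions.
"""


class MdflowError(Exception):
    """Base class for all package errors."""


# ---------------------------------------------------------------- build time


class GraphBuildError(MdflowError):
    """A work graph could not be constructed as requested."""


class UnknownPortError(GraphBuildError):
    pass


class MissingRequiredInputError(GraphBuildError):
    pass


class KindMismatchError(GraphBuildError):
    """A bound value or future does not match the port's declared kind."""


class WidthMismatchError(GraphBuildError):
    """Two ensemble widths > 1 disagree; only 1 -> n broadcast is implicit."""


class CycleError(GraphBuildError):
    """The graph contains (or an operation would create) a dependency cycle."""


class UnsupportedPayloadError(GraphBuildError):
    """A constant value whose data kind cannot be inferred."""


class UnknownOperationError(GraphBuildError):
    """A serialized document references an operation name not in the registry."""


class MalformedDocumentError(GraphBuildError):
    pass


class SchemaVersionError(MalformedDocumentError):
    pass


class UnknownParameterPathError(GraphBuildError):
    """modify_input was given a path that does not exist in the input schema."""


class VariableShadowingError(GraphBuildError):
    pass


class NonBooleanConditionError(GraphBuildError):
    """A while_loop condition does not evaluate to a single boolean."""


# ----------------------------------------------------------------- run time


class ExecutionError(MdflowError):
    """An operation failed while the executor was resolving a future."""


class UpstreamFailureError(ExecutionError):
    """Resolution failed because an ancestor node failed.

    Carries the failing node and ensemble member for diagnosis.
    """

    def __init__(self, node_id, member, cause):
        self.node_id = node_id
        self.member = member
        self.cause = cause
        super().__init__(f"node {node_id!r} (member {member}) failed: {cause}")


class OutputContractError(ExecutionError):
    """A procedure violated its declared-output contract."""


class UndeclaredOutputError(OutputContractError):
    pass


class OutputNeverAssignedError(OutputContractError):
    pass


class OutputKindViolationError(OutputContractError):
    pass


class ExecutableNotFoundError(ExecutionError):
    pass


class SpawnFailureError(ExecutionError):
    pass


class MissingDeclaredOutputError(ExecutionError):
    """A wrapped command exited 0 but did not create a declared output file."""


class InvariantViolationError(MdflowError):
    """A domain object violates its structural invariants (names the field)."""


class MalformedInputError(InvariantViolationError):
    pass


class DegenerateGeometryError(ExecutionError):
    """Coincident particles: a bonded or restrained pair at zero separation."""


class NumericOverflowError(ExecutionError):
    """Non-finite coordinates, typically from a too-large time step."""


class ReduceEpochMismatchError(ExecutionError):
    """Members of a coupled ensemble called ensemble_reduce unequal numbers
    of times (or some member never reached the barrier)."""


class PluginError(ExecutionError):
    """A plugin raised inside the integration loop; carries context."""

    def __init__(self, node_id, member, step, cause):
        self.node_id = node_id
        self.member = member
        self.step = step
        self.cause = cause
        super().__init__(
            f"plugin failed in node {node_id!r}, member {member}, step {step}: {cause}"
        )
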