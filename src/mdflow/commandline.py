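"""Wrap external command-line executables as graph operations.

:func:`cli` is the raw primitive — a thin subprocess wrapper that runs a
child process to completion in a fresh working directory and captures its
exit status and streams.  A nonzero return code is *data* (downstream logic
may branch on it), never an exception.

:func:`commandline_operation` builds the data-flow face around ``cli``: file
inputs may be futures (so tool chains sequence correctly), declared output
files become ``file.<flag>`` output ports, and passing an array of values for
any input fans the command out across an ensemble.  It is implemented with
:func:`mdflow.wrappers.function_wrapper`, demonstrating that the command
wrapper is itself an ordinary wrapped operation.

No shell interpretation is performed: argument lists, not shell lines.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import sys
import tempfile
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Optional, Sequence

from .context import Context, get_context
from .errors import (
    ExecutableNotFoundError,
    MissingDeclaredOutputError,
    SpawnFailureError,
)
from .graph import Future, NodeHandle
from .kinds import FILE_PATH, INTEGER, TEXT
from .ops import ensemble_input
from .wrappers import function_wrapper


@dataclass
class CommandResult:
    """Captured outcome of one child process."""

    returncode: int
    stdout: str
    stderr: str
    file: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> Dict[str, Any]:
        return {
            "returncode": self.returncode,
            "stdout": self.stdout,
            "stderr": self.stderr,
            "file": dict(self.file),
        }


def _resolve_executable(name: str) -> str:
    if os.path.sep in name or (os.path.altsep and os.path.altsep in name):
        if os.path.isfile(name) and os.access(name, os.X_OK):
            return name
        raise ExecutableNotFoundError(f"no executable at {name!r}")
    found = shutil.which(name)
    if found is None:
        raise ExecutableNotFoundError(f"executable {name!r} not found on PATH")
    return found


def cli(command: Sequence[str], stdin: Optional[str] = None,
        cwd: Optional[str] = None) -> CommandResult:
    """Run *command* to completion; capture returncode/stdout/stderr.

    The child runs in *cwd* (a fresh unique temporary directory when not
    given).  stdout/stderr are decoded as UTF-8 with replacement.
    """
    command = [str(c) for c in command]
    if not command:
        raise ExecutableNotFoundError("empty command")
    exe = _resolve_executable(command[0])
    if cwd is None:
        cwd = tempfile.mkdtemp(prefix="mdflow-cli-")
    try:
        proc = subprocess.run(
            [exe] + command[1:],
            input=stdin.encode() if stdin is not None else None,
            capture_output=True,
            cwd=cwd,
        )
    except OSError as exc:
        raise SpawnFailureError(f"could not spawn {exe!r}: {exc}") from exc
    return CommandResult(
        returncode=proc.returncode,
        stdout=proc.stdout.decode("utf-8", errors="replace"),
        stderr=proc.stderr.decode("utf-8", errors="replace"),
    )


def _maybe_ensemble(value: Any, ctx: Context) -> Any:
    """Fan-out rule: a plain list/tuple input becomes a width-n ensemble."""
    if isinstance(value, (list, tuple)):
        return ensemble_input(list(value), context=ctx)
    return value


def commandline_operation(
    executable: str,
    arguments: Sequence[str] = (),
    input_files: Optional[Mapping[str, Any]] = None,
    output_files: Optional[Mapping[str, str]] = None,
    stdin: Optional[Any] = None,
    name: Optional[str] = None,
    context: Optional[Context] = None,
) -> NodeHandle:
    """Wrap one invocation of an external tool as a graph node.

    *input_files* maps flag text to a path, a file-path future, or an array
    of either (ensemble fan-out); a ``None`` value renders the bare flag.
    *output_files* maps flag text to a path **relative** to the task's
    working directory; each becomes a ``file.<flag>`` output port holding the
    absolute path, checked for existence when the tool exits 0.

    Outputs: ``returncode``, ``stdout``, ``stderr``, ``file.<flag>``.
    Flags render in insertion order after *arguments*.
    """
    ctx = context or get_context()
    input_files = dict(input_files or {})
    output_files = dict(output_files or {})
    for flag, rel in output_files.items():
        if rel is not None and os.path.isabs(str(rel)):
            raise ValueError(
                f"declared output {flag!r} must be a relative path, got {rel!r}"
            )
    arguments = [str(a) for a in arguments]
    executable = str(executable)

    output_decl = {"returncode": INTEGER, "stdout": TEXT, "stderr": TEXT}
    for flag in output_files:
        output_decl[f"file.{flag}"] = FILE_PATH

    in_port = {flag: f"infile.{flag}" for flag in input_files}

    def _cmd_tool(output=None, resources=None, **bound):
        workdir = resources.workdir
        argv = [executable] + list(arguments)
        for flag in input_files:
            value = bound.get(in_port[flag])
            argv.append(flag)
            if value is not None:
                argv.append(str(value))
        for flag, rel in output_files.items():
            argv.append(flag)
            if rel is not None:
                argv.append(str(rel))
        resources.log_extra["argv"] = list(argv)
        result = cli(argv, stdin=bound.get("stdin_text"), cwd=workdir)
        output.returncode = result.returncode
        output.stdout = result.stdout
        output.stderr = result.stderr
        for flag, rel in output_files.items():
            path = os.path.abspath(os.path.join(workdir, str(rel)))
            if result.returncode == 0 and not os.path.exists(path):
                raise MissingDeclaredOutputError(
                    f"{executable} exited 0 but declared output {flag!r} "
                    f"({rel!r}) was not created"
                )
            setattr(output, f"file.{flag}", path)

    _cmd_tool.__name__ = "cmdline." + (name or os.path.basename(executable))
    factory = function_wrapper(output_decl, needs_resources=True)(_cmd_tool)

    bindings: Dict[str, Any] = {}
    for flag, value in input_files.items():
        if value is not None:
            bindings[in_port[flag]] = _maybe_ensemble(value, ctx)
    if stdin is not None:
        bindings["stdin_text"] = _maybe_ensemble(stdin, ctx)
    return factory(context=ctx, **bindings)


def fixture_command(name: str) -> list:
    """Command prefix for a bundled fixture tool (emit, copy, fail, concat).

    Returned as ``[python, script_path]`` so the fixtures stay portable text
    files with documented contracts, independent of platform tool behavior.
    """
    script = os.path.join(os.path.dirname(__file__), "fixture_scripts", f"{name}.py")
    if not os.path.isfile(script):
        raise FileNotFoundError(f"no fixture tool named {name!r}")
    return [sys.executable, script]
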