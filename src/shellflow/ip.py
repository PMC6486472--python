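"""Information packets and engine exception types.

In flow-based programming the unit of exchange between processes is the
*information packet* (IP).  Here a packet is either a file — represented by
:class:`FileIP`, a workflow-relative path plus the provenance record that
travelled with it — or a bare parameter value (a string), which is never
persisted to disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .audit import AuditInfo


class WorkflowError(Exception):
    """Base class for all engine errors."""


class DefinitionError(WorkflowError):
    """Raised for errors while defining a workflow (bad pattern, duplicate
    process name, illegal connection, non-positive task cap, ...)."""


class ValidationError(WorkflowError):
    """Raised when a workflow fails pre-run validation (unconnected in-port,
    cyclic dependency graph, unknown run target, ...)."""


class TemplateError(DefinitionError):
    """Raised for malformed placeholder patterns or unresolvable references."""

    def __init__(self, message: str, column: Optional[int] = None):
        if column is not None:
            message = f"{message} (column {column})"
        super().__init__(message)
        self.column = column


class TaskError(WorkflowError):
    """A shell command failed, or a declared output was not produced.

    Carries enough context to debug the failure: the process name, the fully
    resolved command, the exit code and captured standard error.  The task's
    sandbox directory is retained on disk for inspection.
    """

    def __init__(self, process_name: str, command: str, returncode: int,
                 stderr: str = "", message: Optional[str] = None):
        self.process_name = process_name
        self.command = command
        self.returncode = returncode
        self.stderr = stderr
        msg = message or (
            f"process {process_name!r}: command failed with exit code "
            f"{returncode}: {command}"
            + (f"\nstderr: {stderr.strip()}" if stderr.strip() else "")
        )
        super().__init__(msg)


@dataclass
class FileIP:
    """A file information packet: a path plus its audit attachment.

    ``path`` is always relative to the workflow's working directory, which is
    also the form recorded in audit logs and (with a ``../`` prefix) in
    resolved commands.  The audit sidecar for the file lives at
    ``path + ".audit.json"``.
    """

    path: str
    audit: Optional["AuditInfo"] = None
    streamed: bool = field(default=False)

    @property
    def audit_path(self) -> str:
        return self.path + ".audit.json"

    def sandbox_path(self, sandbox: str) -> str:
        """The same file inside a task sandbox (same relative path, hence the
        same basename)."""
        return os.path.join(sandbox, self.path)


@dataclass(frozen=True)
class ParamIP:
    """A parameter information packet: a named string value, RAM-only."""

    name: str
    value: str
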