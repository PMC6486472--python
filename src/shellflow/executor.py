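"""Single-task execution: cache check, sandbox, shell run, atomic finalize.

Every task runs inside its own *sandbox*, a temporary directory created
directly under the workflow's working directory.  The resolved command is
executed from inside the sandbox through Bash in fail-on-error pipe mode, so
input files one level up are reachable via their ``../``-prefixed paths.  On
success, every file found in the sandbox — declared on the command line or
not (think of an indexing tool that drops half a dozen companion files next
to its declared output) — is moved into the final area with atomic renames,
audit sidecar first, then the data file.  A crashed or killed run therefore
never leaves a final-area file without its complete provenance record, and
half-finished work stays quarantined in the sandbox.

Caching is presence-based: a task is skipped when every declared output and
its ``.audit.json`` sidecar already exist.  Streamed (FIFO) outputs have no
persistent content and are never cached; neither is a task that consumes one.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import threading
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Optional, Union

from . import audit as audit_mod
from .ip import FileIP, TaskError

SANDBOX_PREFIX = "_tmp."
FIFO_SUFFIX = ".fifo"

_BASH_ARGS = ["bash", "-o", "pipefail", "-e", "-c"]


@dataclass
class Task:
    """One concrete command invocation with resolved paths and parameters."""

    id: str
    process_name: str
    command: str
    inputs: Dict[str, Union[FileIP, List[FileIP]]]
    outputs: Dict[str, FileIP]
    params: Dict[str, str]
    work_dir: Path
    digest: str
    tags: Dict[str, str] = field(default_factory=dict)
    start_ns: int = 0
    finish_ns: int = 0
    cached: bool = False

    @property
    def sandbox(self) -> Path:
        """Deterministically named sandbox, a direct child of the workflow
        directory, so an aborted attempt is found and wiped on retry."""
        return self.work_dir / f"{SANDBOX_PREFIX}{self.digest}"

    def iter_input_ips(self) -> Iterator[FileIP]:
        for value in self.inputs.values():
            if isinstance(value, FileIP):
                yield value
            else:
                yield from value

    def streamed_outputs(self) -> Dict[str, FileIP]:
        return {k: v for k, v in self.outputs.items() if v.streamed}

    def input_paths(self) -> List[str]:
        return [ip.path for ip in self.iter_input_ips()]

    def output_paths(self) -> List[str]:
        return [ip.path for ip in self.outputs.values()]


class RunContext:
    """Shared state of one workflow run.

    Holds the concurrency cap on external commands (a semaphore — engine
    bookkeeping threads are unbounded), the abort flag raised on the first
    command failure, the append-only event log, and an instrumented counter
    of simultaneously live commands.
    """

    def __init__(self, work_dir: Union[str, Path], max_tasks: int):
        self.work_dir = Path(work_dir)
        self.max_tasks = max_tasks
        self.semaphore = threading.BoundedSemaphore(max_tasks)
        self.abort = threading.Event()
        self.failures: List[BaseException] = []
        self.events: List[dict] = []
        self.fifos: List[Path] = []
        self.channels: Dict[object, object] = {}
        self._lock = threading.Lock()
        self._live = 0
        self.max_live = 0

    def record(self, **event) -> None:
        with self._lock:
            self.events.append(event)

    def fail(self, exc: BaseException) -> None:
        with self._lock:
            self.failures.append(exc)
        self.abort.set()

    def add_fifo(self, path: Path) -> None:
        with self._lock:
            self.fifos.append(path)

    @contextmanager
    def command_slot(self):
        """Acquire one of the ``max_tasks`` external-command slots."""
        with self.semaphore:
            with self._lock:
                self._live += 1
                self.max_live = max(self.max_live, self._live)
            try:
                yield
            finally:
                with self._lock:
                    self._live -= 1


def should_skip(task: Task) -> bool:
    """True iff the task is a cache hit.

    Every declared output's final file *and* its audit sidecar must exist —
    an output without its sidecar is treated as unfinished and re-executed.
    Tasks producing or consuming a stream are never skipped.
    """
    if task.streamed_outputs():
        return False
    if any(ip.streamed for ip in task.iter_input_ips()):
        return False
    if not task.outputs:
        return False
    for ip in task.outputs.values():
        final = task.work_dir / ip.path
        sidecar = task.work_dir / ip.audit_path
        if not (final.exists() and sidecar.exists()):
            return False
    return True


def load_cached(task: Task, ctx: RunContext) -> None:
    """Attach the stored provenance of a cache-hit task to its outputs.

    Task IDs are reused from the existing audit logs, so converters see the
    same identity across runs.
    """
    for ip in task.outputs.values():
        ip.audit = audit_mod.load_audit(task.work_dir / ip.path)
    task.cached = True
    first = next(iter(task.outputs.values()))
    ctx.record(event="cached", process=task.process_name,
               task_id=first.audit.id if first.audit else task.id,
               command=task.command, start_ns=0, finish_ns=0,
               inputs=task.input_paths(), outputs=task.output_paths())


def execute(task: Task, ctx: RunContext,
            on_stream: Optional[Callable[[str, FileIP], None]] = None) -> Task:
    """Run one task to completion and finalize its outputs atomically.

    Streamed outputs are materialized as named pipes at their final paths
    before the command starts; *on_stream* is called for each so the engine
    can hand the packet to the consumer immediately — producer and consumer
    then run concurrently.  A nonzero exit raises :class:`TaskError`, keeps
    the sandbox on disk for inspection and moves no files.
    """
    sandbox = task.sandbox
    if sandbox.exists():
        shutil.rmtree(sandbox)
    sandbox.mkdir(parents=True)

    streamed = task.streamed_outputs()
    with ctx.command_slot():
        for port, ip in streamed.items():
            fifo = ctx.work_dir / ip.path
            if fifo.exists():
                fifo.unlink()
            os.mkfifo(fifo)
            ctx.add_fifo(fifo)
            # Attach provenance before the run: the stream has no persistent
            # content, so its record is the command about to produce it.
            ip.audit = audit_mod.build_audit(task)
            ip.audit.tags["stream"] = "true"
            if on_stream is not None:
                on_stream(port, ip)
        task.start_ns = time.time_ns()
        proc = subprocess.run(
            _BASH_ARGS + [task.command], cwd=sandbox,
            stdout=subprocess.PIPE, stderr=subprocess.PIPE, text=True)
        task.finish_ns = time.time_ns()

    if proc.returncode != 0:
        ctx.record(event="failed", process=task.process_name, task_id=task.id,
                   command=task.command, start_ns=task.start_ns,
                   finish_ns=task.finish_ns, inputs=task.input_paths(),
                   outputs=task.output_paths())
        raise TaskError(task.process_name, task.command, proc.returncode,
                        proc.stderr)

    _finalize(task, ctx, streamed)
    ctx.record(event="exec", process=task.process_name, task_id=task.id,
               command=task.command, start_ns=task.start_ns,
               finish_ns=task.finish_ns, inputs=task.input_paths(),
               outputs=task.output_paths())
    return task


def _finalize(task: Task, ctx: RunContext, streamed: Dict[str, FileIP]) -> None:
    """Move everything the command created into the final area.

    The task's audit record is written for every produced file (declared or
    undeclared) inside the sandbox first; each sidecar is then renamed into
    place *before* its data file, so a kill between the two renames can never
    leave data without provenance.
    """
    sandbox = task.sandbox
    record = audit_mod.build_audit(task)
    for ip in task.outputs.values():
        if not ip.streamed:
            ip.audit = record

    declared = {ip.path for ip in task.outputs.values() if not ip.streamed}
    produced = sorted(
        str(p.relative_to(sandbox)) for p in sandbox.rglob("*") if p.is_file())
    missing = declared - set(produced)
    if missing:
        raise TaskError(
            task.process_name, task.command, 0,
            message=(f"process {task.process_name!r}: command exited 0 but did "
                     f"not produce declared output(s): {sorted(missing)}"))

    for rel in produced:
        audit_mod.write_audit(record, sandbox / rel)
    for rel in produced:
        final = ctx.work_dir / rel
        final.parent.mkdir(parents=True, exist_ok=True)
        _move(sandbox / (rel + audit_mod.AUDIT_SUFFIX),
              ctx.work_dir / (rel + audit_mod.AUDIT_SUFFIX))
        _move(sandbox / rel, final)
    shutil.rmtree(sandbox)

    # Streams leave no data behind; record their provenance beside the FIFO.
    for ip in streamed.values():
        audit_mod.write_audit(ip.audit, ctx.work_dir / ip.path)


def _move(src: Path, dst: Path) -> None:
    """Atomic rename; cross-device fallback is copy, rename, delete."""
    try:
        os.replace(src, dst)
    except OSError:
        tmp = dst.with_name(dst.name + ".partial")
        shutil.copy2(src, tmp)
        os.replace(tmp, dst)
        os.unlink(src)
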