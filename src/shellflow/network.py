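"""Workflow networks: processes, ports, connections and the scheduler.

The engine follows flow-based programming: a workflow is a network of
independent processes that exchange information packets over channels
attached to *named ports*.  The network is defined separately from the
processes (``in_port.From(out_port)``), so components stay self-contained
and reconnectable.  At run time every process runs concurrently and forms
tasks *dynamically* as packets arrive — push-based dataflow — which allows a
downstream task to be parametrized with a value computed earlier in the same
run (e.g. a tuned hyperparameter), something pull-based schedulers that plan
all tasks up front cannot express.

Task formation uses zip semantics: one packet is taken from each connected
in-port per task, and a process closes down after ``min`` over its ports of
the available packet counts.  Fan-out is built explicitly with parameter
sources; fan-in (reduce) with a *collecting* in-port that gathers every
packet from its upstream into a single task.  An out-port connected to
several in-ports broadcasts each packet to all of them.
"""

from __future__ import annotations

import queue
import threading
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from . import audit as audit_mod
from . import executor, template
from .executor import FIFO_SUFFIX, RunContext, Task
from .ip import DefinitionError, FileIP, TaskError, ValidationError

_CLOSE = object()  # end-of-stream sentinel on channels
_DONE = object()   # end-of-tasks sentinel on the in-flight queue

FILE, PARAM = "file", "param"


class _PortBase:
    kind: str
    direction: str

    def __init__(self, proc: "_Node", name: str):
        self.proc = proc
        self.name = name

    def __repr__(self):
        return (f"<{type(self).__name__} {self.proc.name!r}.{self.name!r}>")


class _OutBase(_PortBase):
    direction = "out"

    def __init__(self, proc, name):
        super().__init__(proc, name)
        self.targets: List["_InBase"] = []

    def send(self, ctx: RunContext, packet) -> None:
        for target in self.targets:
            ch = ctx.channels.get(target)
            if ch is not None:
                ch.put(packet)

    def close(self, ctx: RunContext) -> None:
        self.send(ctx, _CLOSE)


class _InBase(_PortBase):
    direction = "in"

    def __init__(self, proc, name):
        super().__init__(proc, name)
        self.source: Optional[_OutBase] = None

    def From(self, out_port: "_OutBase") -> None:
        """Connect this in-port to *out_port* (``InPort.From(OutPort)``)."""
        self.proc.wf.connect(self, out_port)


class OutPort(_OutBase):
    """File out-port; emits :class:`FileIP` packets."""

    kind = FILE

    def __init__(self, proc, name):
        super().__init__(proc, name)
        self.streamed = False


class InPort(_InBase):
    """File in-port; consumes one packet per task, or all packets as a
    single task when switched to collecting mode."""

    kind = FILE

    def __init__(self, proc, name):
        super().__init__(proc, name)
        self.collect = False

    def collect_all(self) -> "InPort":
        """Gather every upstream packet into one task (explicit fan-in)."""
        self.collect = True
        return self


class ParamOutPort(_OutBase):
    """Parameter out-port; emits string values, RAM-only (never persisted).

    On a shell process it is derived from an out-port: after each task the
    finalized file's (whitespace-stripped) content is emitted as the value —
    the mechanism behind dynamic downstream parametrization.
    """

    kind = PARAM

    def __init__(self, proc, name, source_port: Optional[str] = None):
        super().__init__(proc, name)
        self.source_port = source_port


class ParamInPort(_InBase):
    kind = PARAM


class _TaskRun:
    """Handle for one in-flight task, completed by a runner thread."""

    __slots__ = ("task", "done", "error", "skipped")

    def __init__(self, task: Task):
        self.task = task
        self.done = threading.Event()
        self.error: Optional[BaseException] = None
        self.skipped = False


class _Node:
    """Common base of shell processes and lightweight source nodes."""

    def __init__(self, wf: "Workflow", name: str):
        self.wf = wf
        self.name = name
        self.in_ports: Dict[str, InPort] = {}
        self.out_ports: Dict[str, OutPort] = {}
        self.param_in_ports: Dict[str, ParamInPort] = {}
        self.param_out_ports: Dict[str, ParamOutPort] = {}

    # -- port accessors -----------------------------------------------------
    def in_port(self, name: str) -> InPort:
        return self._get(self.in_ports, name, "in-port")

    def out_port(self, name: str) -> OutPort:
        return self._get(self.out_ports, name, "out-port")

    def param_in(self, name: str) -> ParamInPort:
        return self._get(self.param_in_ports, name, "parameter in-port")

    def param_out(self, name: str) -> ParamOutPort:
        return self._get(self.param_out_ports, name, "parameter out-port")

    def _get(self, ports, name, what):
        try:
            return ports[name]
        except KeyError:
            raise DefinitionError(
                f"process {self.name!r} has no {what} named {name!r}; "
                f"available: {sorted(ports)}") from None

    def all_out_ports(self) -> List[_OutBase]:
        return list(self.out_ports.values()) + list(self.param_out_ports.values())

    def connected_in_ports(self) -> List[_InBase]:
        return list(self.in_ports.values()) + list(self.param_in_ports.values())

    def _threads(self, ctx: RunContext) -> List[threading.Thread]:
        raise NotImplementedError


class Process(_Node):
    """A workflow component: a named shell command pattern with ports.

    Ports are exactly the distinct placeholder names parsed from the command
    pattern: ``{i:name}`` file in-ports, ``{o:name}`` file out-ports and
    ``{p:name}`` parameter in-ports.  A repeated placeholder yields a single
    port.
    """

    def __init__(self, wf: "Workflow", name: str, command_pattern: str):
        super().__init__(wf, name)
        self.command_pattern = command_pattern
        self.path_formatters: Dict[str, template.PathFormatter] = {}
        self.prepend = ""
        for ph in template.parse_pattern(command_pattern):
            if ph.kind == "i":
                self.in_ports.setdefault(ph.name, InPort(self, ph.name))
            elif ph.kind == "o":
                self.out_ports.setdefault(ph.name, OutPort(self, ph.name))
            else:
                self.param_in_ports.setdefault(ph.name, ParamInPort(self, ph.name))

    # -- definition API -----------------------------------------------------
    def set_out(self, port: str,
                pattern: Union[str, Callable[[Mapping[str, str], Mapping[str, str]], str]]
                ) -> None:
        """Register the output path pattern for *port*.

        Patterns support literals, ``{i:port}``, ``{p:param}`` and the trim
        modifier ``{i:port|%.suffix}``; a callable ``f(inputs, params)`` may
        be given instead as an escape hatch.
        """
        self.out_port(port)  # raises if unknown
        if callable(pattern):
            fmt = template.PathFormatter(func=pattern)
        else:
            fmt = template.PathFormatter(pattern=pattern)
            for ref in fmt.references():
                if ref.kind == "i" and ref.name not in self.in_ports:
                    raise DefinitionError(
                        f"path pattern for {self.name!r}.{port!r} references "
                        f"nonexistent in-port {ref.name!r}")
                if ref.kind == "p" and ref.name not in self.param_in_ports:
                    raise DefinitionError(
                        f"path pattern for {self.name!r}.{port!r} references "
                        f"nonexistent parameter {ref.name!r}")
        self.path_formatters[port] = fmt

    def stream_out(self, port: str) -> None:
        """Turn *port* into a streamed output (a Unix named pipe).

        The producer and its single consumer then run concurrently, passing
        data through memory; nothing is persisted at the port's path and the
        result is never cached.
        """
        self.out_port(port).streamed = True

    def add_param_out(self, name: str, from_port: str) -> ParamOutPort:
        """Expose the content of out-port *from_port* as a parameter stream."""
        self.out_port(from_port)
        if name in self.param_out_ports:
            raise DefinitionError(
                f"process {self.name!r} already has parameter out-port {name!r}")
        p = ParamOutPort(self, name, source_port=from_port)
        self.param_out_ports[name] = p
        return p

    def set_prepend(self, text: str) -> None:
        """Text prefixed to every executed command (e.g. a resource-manager
        allocation call such as ``salloc -n 1``)."""
        self.prepend = text

    # -- scheduling ---------------------------------------------------------
    def _threads(self, ctx: RunContext) -> List[threading.Thread]:
        flight: "queue.Queue" = queue.Queue(maxsize=max(2 * ctx.max_tasks, 4))
        former = threading.Thread(
            target=self._former, args=(ctx, flight),
            name=f"former:{self.name}", daemon=True)
        emitter = threading.Thread(
            target=self._emitter, args=(ctx, flight),
            name=f"emitter:{self.name}", daemon=True)
        return [former, emitter]

    def _bundles(self, ctx: RunContext):
        """Yield one (files, params) input bundle per task (zip semantics)."""
        fports = [self.in_ports[k] for k in sorted(self.in_ports)]
        pports = [self.param_in_ports[k] for k in sorted(self.param_in_ports)]
        if not fports and not pports:
            yield {}, {}
            return
        collected = False
        while True:
            files: Dict[str, Union[FileIP, List[FileIP]]] = {}
            params: Dict[str, str] = {}
            for p in fports:
                ch = ctx.channels[p]
                if p.collect:
                    if collected:
                        return
                    items: List[FileIP] = []
                    while (x := ch.get()) is not _CLOSE:
                        items.append(x)
                    if not items:
                        return
                    files[p.name] = items
                else:
                    x = ch.get()
                    if x is _CLOSE:
                        return
                    files[p.name] = x
            for p in pports:
                x = ctx.channels[p].get()
                if x is _CLOSE:
                    return
                params[p.name] = x
            if any(p.collect for p in fports):
                collected = True
            yield files, params

    def form_task(self, ctx: RunContext,
                  files: Mapping[str, Union[FileIP, List[FileIP]]],
                  params: Mapping[str, str]) -> Task:
        """Combine one input bundle into a concrete task: resolve output
        paths (explicit formatter or automatic signature path) and the
        shell command."""
        input_paths: Dict[str, Union[str, List[str]]] = {}
        first_paths: Dict[str, str] = {}
        for name, v in files.items():
            if isinstance(v, list):
                input_paths[name] = [ip.path for ip in v]
                first_paths[name] = v[0].path
            else:
                input_paths[name] = v.path
                first_paths[name] = v.path
        outputs: Dict[str, FileIP] = {}
        for name in sorted(self.out_ports):
            port = self.out_ports[name]
            fmt = self.path_formatters.get(name)
            if fmt is not None:
                path = fmt.format(first_paths, params)
            else:
                path = template.default_path(
                    self.name, name, self.command_pattern, params, input_paths)
            if port.streamed:
                path += FIFO_SUFFIX
            outputs[name] = FileIP(path=path, streamed=port.streamed)
        cmd_outputs = {name: ("../" + ip.path if ip.streamed else ip.path)
                       for name, ip in outputs.items()}
        command = template.format_command(
            self.command_pattern, input_paths, cmd_outputs, params, self.prepend)
        digest = template.signature_digest(
            self.name + "\x00" + self.command_pattern, params, input_paths)
        return Task(id=audit_mod.new_id(), process_name=self.name,
                    command=command, inputs=dict(files), outputs=outputs,
                    params=dict(params), work_dir=ctx.work_dir, digest=digest)

    def _former(self, ctx: RunContext, flight: "queue.Queue") -> None:
        try:
            for files, params in self._bundles(ctx):
                if ctx.abort.is_set():
                    break
                task = self.form_task(ctx, files, params)
                tr = _TaskRun(task)
                flight.put(tr)  # bounds in-flight tasks per process
                threading.Thread(target=self._runner, args=(ctx, tr),
                                 name=f"task:{self.name}", daemon=True).start()
        except BaseException as exc:  # noqa: BLE001 - forwarded to the run
            ctx.fail(exc)
        finally:
            flight.put(_DONE)

    def _runner(self, ctx: RunContext, tr: _TaskRun) -> None:
        try:
            if ctx.abort.is_set():
                tr.skipped = True
            elif executor.should_skip(tr.task):
                executor.load_cached(tr.task, ctx)
            else:
                def on_stream(port_name: str, ip: FileIP) -> None:
                    self.out_ports[port_name].send(ctx, ip)
                executor.execute(tr.task, ctx, on_stream=on_stream)
        except BaseException as exc:  # noqa: BLE001
            tr.error = exc
            ctx.fail(exc)
        finally:
            tr.done.set()

    def _emitter(self, ctx: RunContext, flight: "queue.Queue") -> None:
        try:
            while (tr := flight.get()) is not _DONE:
                tr.done.wait()
                if tr.error is not None or tr.skipped:
                    continue
                for name, ip in tr.task.outputs.items():
                    if not ip.streamed:  # streams were emitted at task start
                        self.out_ports[name].send(ctx, ip)
                for pout in self.param_out_ports.values():
                    src = tr.task.outputs[pout.source_port]
                    value = (ctx.work_dir / src.path).read_text().strip()
                    pout.send(ctx, value)
        except BaseException as exc:  # noqa: BLE001
            ctx.fail(exc)
        finally:
            for port in self.all_out_ports():
                port.close(ctx)


class ParamSource(_Node):
    """Lightweight node that emits a fixed sequence of parameter values on a
    parameter out-port — the explicit fan-out construct for sweeps."""

    def __init__(self, wf: "Workflow", name: str, values: Sequence, port: str = "out"):
        super().__init__(wf, name)
        self.values = [str(v) for v in values]
        self.param_out_ports[port] = ParamOutPort(self, port)

    def _threads(self, ctx: RunContext) -> List[threading.Thread]:
        def emit():
            port = next(iter(self.param_out_ports.values()))
            try:
                for v in self.values:
                    if ctx.abort.is_set():
                        break
                    port.send(ctx, v)
            finally:
                port.close(ctx)
        return [threading.Thread(target=emit, name=f"source:{self.name}",
                                 daemon=True)]


class FileSource(_Node):
    """Lightweight node that injects existing files into the network.

    Each path (relative to the working directory) is emitted as a packet
    with its stored audit tree attached, which is how a chain of processing
    split across separate workflow scripts keeps its full provenance: audits
    of earlier runs are loaded and merged into the new run's records.  A
    file without a sidecar gets an external-input stub.
    """

    def __init__(self, wf: "Workflow", name: str, paths: Sequence[str],
                 port: str = "out"):
        super().__init__(wf, name)
        self.paths = [str(p) for p in paths]
        self.out_ports[port] = OutPort(self, port)

    def _threads(self, ctx: RunContext) -> List[threading.Thread]:
        def emit():
            port = next(iter(self.out_ports.values()))
            try:
                for p in self.paths:
                    if ctx.abort.is_set():
                        break
                    ip = FileIP(path=p, audit=audit_mod.load_audit(ctx.work_dir / p))
                    port.send(ctx, ip)
            finally:
                port.close(ctx)
        return [threading.Thread(target=emit, name=f"source:{self.name}",
                                 daemon=True)]


@dataclass
class RunReport:
    """Outcome of one workflow run: the append-only task event log plus the
    high-water mark of simultaneously live external commands."""

    events: List[dict]
    max_concurrent_commands: int = 0

    @property
    def commands_executed(self) -> int:
        return sum(1 for e in self.events if e["event"] == "exec")

    @property
    def cached_tasks(self) -> int:
        return sum(1 for e in self.events if e["event"] == "cached")

    @property
    def processes_executed(self) -> Set[str]:
        return {e["process"] for e in self.events if e["event"] == "exec"}

    @property
    def processes_run(self) -> Set[str]:
        return {e["process"] for e in self.events
                if e["event"] in ("exec", "cached")}

    def tasks_for(self, process_name: str) -> int:
        return sum(1 for e in self.events
                   if e["process"] == process_name
                   and e["event"] in ("exec", "cached"))


class Workflow:
    """A named process network with a run policy.

    ``max_tasks`` caps the number of *external shell commands* running at
    any instant (engine bookkeeping threads are unbounded).  All file paths
    are kept relative to ``work_dir``, which is where outputs, audit
    sidecars and task sandboxes live.
    """

    def __init__(self, name: str, max_tasks: int,
                 work_dir: Union[str, Path] = "."):
        if not isinstance(max_tasks, int) or max_tasks < 1:
            raise DefinitionError(
                f"max_tasks must be a positive integer, got {max_tasks!r}")
        self.name = name
        self.max_tasks = max_tasks
        self.work_dir = Path(work_dir)
        self.procs: Dict[str, _Node] = {}
        self.connections: List[Tuple[_OutBase, _InBase]] = []
        self.run_log: List[dict] = []

    # -- definition ---------------------------------------------------------
    def _register(self, node: _Node) -> _Node:
        if node.name in self.procs:
            raise DefinitionError(f"duplicate process name {node.name!r}")
        self.procs[node.name] = node
        return node

    def new_proc(self, name: str, command_pattern: str) -> Process:
        """Create and register a process from a shell command pattern."""
        if name in self.procs:
            raise DefinitionError(f"duplicate process name {name!r}")
        return self._register(Process(self, name, command_pattern))

    def new_param_source(self, name: str, values: Sequence,
                         port: str = "out") -> ParamSource:
        return self._register(ParamSource(self, name, values, port))

    def new_file_source(self, name: str, paths: Sequence[str],
                        port: str = "out") -> FileSource:
        return self._register(FileSource(self, name, paths, port))

    def proc(self, name: str) -> _Node:
        try:
            return self.procs[name]
        except KeyError:
            raise DefinitionError(f"no process named {name!r}") from None

    def connect(self, in_port: _InBase, out_port: _OutBase) -> None:
        """Register the dependency edge ``out_port -> in_port``.

        Only complementary kinds may be paired (file-out to file-in,
        param-out to param-in); an in-port accepts exactly one upstream,
        while an out-port may feed many in-ports (broadcast).
        """
        if not isinstance(in_port, _InBase) or not isinstance(out_port, _OutBase):
            raise DefinitionError(
                f"connect expects (in-port, out-port), got "
                f"({in_port!r}, {out_port!r})")
        if in_port.kind != out_port.kind:
            raise DefinitionError(
                f"cannot connect {out_port.kind}-out {out_port!r} to "
                f"{in_port.kind}-in {in_port!r}: kind mismatch")
        if in_port.proc.wf is not self or out_port.proc.wf is not self:
            raise DefinitionError("ports belong to a different workflow")
        if in_port.source is not None:
            raise DefinitionError(
                f"{in_port!r} is already connected to {in_port.source!r}; "
                f"an in-port has exactly one upstream out-port")
        in_port.source = out_port
        out_port.targets.append(in_port)
        self.connections.append((out_port, in_port))

    # -- structure ----------------------------------------------------------
    def graph(self) -> "nx.DiGraph":
        """Process-level dependency graph (file and parameter edges)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.procs)
        for out_port, in_port in self.connections:
            g.add_edge(out_port.proc.name, in_port.proc.name)
        return g

    def validate(self, included: Optional[Iterable[str]] = None) -> None:
        """Check the network before execution: every in-port of an included
        process connected to an included producer, dependency graph acyclic,
        streamed ports single-consumer (and a task cap that allows producer
        and consumer to run at once)."""
        names = set(included) if included is not None else set(self.procs)
        streamed = False
        for name in sorted(names):
            node = self.procs[name]
            for p in node.connected_in_ports():
                if p.source is None:
                    raise ValidationError(f"{p!r} is not connected")
                if p.source.proc.name not in names:
                    raise ValidationError(
                        f"{p!r} is fed by {p.source!r}, which is outside the "
                        f"set of processes being run")
            for port in node.out_ports.values():
                if port.streamed:
                    streamed = True
                    if len(port.targets) != 1:
                        raise ValidationError(
                            f"streamed port {port!r} must have exactly one "
                            f"consumer (a named pipe has a single reader), "
                            f"has {len(port.targets)}")
        sub = self.graph().subgraph(names)
        if not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            raise ValidationError(f"dependency graph contains a cycle: {cycle}")
        if streamed and self.max_tasks < 2:
            raise ValidationError(
                "streaming requires max_tasks >= 2 so producer and consumer "
                "can run concurrently")

    # -- execution ----------------------------------------------------------
    def run(self) -> RunReport:
        """Run the whole network; see :meth:`run_to` for partial runs."""
        return self._run(set(self.procs))

    def run_to(self, *targets: str) -> RunReport:
        """Run all processes upstream of, and including, *targets*.

        Processes downstream of the targets are skipped entirely — useful
        when iterating on the middle of a long pipeline.
        """
        for t in targets:
            if t not in self.procs:
                raise ValidationError(f"unknown run target {t!r}")
        g = self.graph()
        closure: Set[str] = set()
        for t in targets:
            closure |= nx.ancestors(g, t)
            closure.add(t)
        return self._run(closure)

    def _run(self, included: Set[str]) -> RunReport:
        self.validate(included)
        self.work_dir.mkdir(parents=True, exist_ok=True)
        ctx = RunContext(self.work_dir, self.max_tasks)
        for out_port, in_port in self.connections:
            if (in_port.proc.name in included
                    and out_port.proc.name in included):
                ctx.channels[in_port] = queue.SimpleQueue()
        threads: List[threading.Thread] = []
        for name in self.procs:  # definition order
            if name in included:
                threads.extend(self.procs[name]._threads(ctx))
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        for fifo in ctx.fifos:
            try:
                fifo.unlink()
            except FileNotFoundError:
                pass
        self.run_log.extend(ctx.events)
        if ctx.failures:
            raise ctx.failures[0]
        return RunReport(events=ctx.events,
                         max_concurrent_commands=ctx.max_live)


def new_workflow(name: str, max_tasks: int,
                 work_dir: Union[str, Path] = ".") -> Workflow:
    """Create an empty workflow bound to a working directory."""
    return Workflow(name, max_tasks, work_dir)
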