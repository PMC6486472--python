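# Methods

This note documents the execution model shellflow implements, the design
choices made where the design was genuinely open, and what the bundled demo
workflows do and do not show about real pipelines.

## Execution model

A workflow is a directed network of processes exchanging information
packets over channels bound to named ports. Two packet kinds exist: file
packets (a working-directory-relative path plus its provenance record) and
parameter packets (bare strings, RAM-only). Connections pair complementary
kinds only — file-out to file-in, param-out to param-in — and an in-port
has exactly one upstream producer, while an out-port broadcasts every
packet to all of its consumers. The process graph must be acyclic; this is
checked before any task runs, together with port connectedness.

Scheduling is push-based dataflow. Each process runs concurrently (a
task-forming thread and an ordered emitter thread; each task gets its own
runner thread) and forms tasks continually as packets arrive, so the
number of tasks need not be known up front and a downstream process can be
parametrized with a value computed during the run. Task formation is a
positional zip: one packet from each connected in-port per task, closing
down after `min` over ports of the packet counts. The alternatives —
cross-product combination, or merging multiple producers into one in-port —
are deliberately not offered: fan-out is written explicitly with parameter
sources (as the sweep demo does), which keeps pairing semantics
unambiguous. Fan-in is explicit too: an in-port switched to *collecting*
mode gathers every packet from its upstream into a single task, which is
the reduce step a select-best stage needs.

Output packets of a process are emitted in task-formation order even when
tasks finish out of order, so positional pairing stays deterministic
downstream. Channels are unbounded FIFOs; the in-flight tasks of each
process are bounded (2 × `max_tasks`), which is where back-pressure comes
from.

`max_tasks` caps the number of *external shell commands* live at any
instant, via a counting semaphore acquired only around command execution;
engine bookkeeping threads are unbounded and cheap. The instrumented
high-water mark of live commands is reported on every run.

Dynamic parametrization is implemented by deriving a parameter out-port
from a file out-port: after each task finalizes, the file's
whitespace-stripped content is emitted as a parameter value. Cached tasks
emit the same way, from the cached file.

## Tasks, sandboxes, atomicity

A task is one concrete command invocation: the pattern resolved against
specific input paths and parameter values. Commands run through
`bash -o pipefail -e -c`, from inside a sandbox directory
`_tmp.<12-hex digest>` created directly under the workflow directory; the
digest is a SHA-256 prefix of the task signature (process name, command
pattern, sorted parameters, sorted input paths), so a crashed task's
sandbox is found and wiped on retry. Inputs are referenced as `../<path>`;
declared outputs are written to their relative paths inside the sandbox.

On exit 0, every file found in the sandbox — declared or not — is moved to
the final area. Undeclared-output capture matters for tools that drop
companion files next to their declared output (a FASTA indexer producing
`.bwt/.pac/.ann/.amb/.sa` files is the canonical case). The move order is
the atomicity mechanism: each file's audit sidecar is written inside the
sandbox first and renamed into place *before* its data file, both with
`os.replace` (atomic on one filesystem; the cross-device fallback is
copy-then-rename-then-delete). A kill at any instant therefore leaves
either no trace of an output or a complete file-plus-sidecar pair, never a
finalized file without provenance — undeclared files included, which is why
they get sidecars too. A failing command (nonzero exit) moves nothing and
keeps its sandbox for inspection; the run stops launching new tasks, lets
in-flight commands finish, then raises with the process name, resolved
command, exit code and captured stderr. In-flight commands are not killed:
whether to cancel them was an open choice, and letting them finish keeps
their sandboxes self-consistent.

Caching is presence-based: a task is skipped iff every declared output and
its `.audit.json` sidecar exist. No checksums are kept — content
verification is out of scope — so editing an output by hand does not
invalidate it; deleting either the file or its sidecar does. Cache hits
reload the stored audit, reusing the original task IDs.

## File naming

Explicit output paths come from a small pattern language: literals,
`{i:port}`, `{p:param}`, and a trim modifier `{i:port|%.suffix}` that
removes the suffix when present and otherwise leaves the path unchanged
with a logged warning (failing hard on a mismatched trim would make
components brittle against upstream renames). A caller-supplied function
is accepted as an escape hatch. Without an explicit pattern the path is
`<process>.<12-hex signature digest>.<port>`; the digest guarantees that
different parameters or inputs never collide while identical signatures
reuse the cache. Process names are sanitized (`[^A-Za-z0-9_.-]` → `_`)
before entering a path, since display names may contain spaces. For a
collecting in-port, `{i:port}` in a path pattern refers to the first
collected path; sweep-style reduce stages normally use static names.

## Provenance

Audit records carry fixed JSON fields `ID`, `ProcessName`, `Command`,
`Params`, `Tags`, `StartTime` (RFC 3339, nanosecond precision),
`ExecTimeNS`, `Upstream`. `Upstream` maps each input path (as referenced
by the command, `../` stripped) to the producing task's full record, giving
every output its complete command history. IDs are random 128-bit hex
tokens; a task reached along several paths keeps one ID, which converters
use for deduplication. Serialization is deterministic (fixed field order,
sorted keys), so write → load → write is byte-stable.

When a workflow consumes a file produced by an earlier run or another
script (via a file source), the existing sidecar is loaded and merged into
the new records, so provenance chains across scripts. A file with no
sidecar becomes a stub entry tagged `external=true` — a warning, not an
error, since data commonly originates outside the engine ("follow the
data" has that limit by construction).

`audit2bash` emits the unique tasks in dependency order, each wrapped in a
scratch-subdirectory block that mirrors sandboxed execution (so the
recorded `../` prefixes resolve); for deterministic commands the script
reproduces the target file byte-identically. The HTML/TeX reports render a
header (engine version, total execution time), a Gantt-style timeline
ordered by start time (ID order breaks ties), and one color-keyed table
per unique task; the TeX output is a standalone document left to an
external `pdflatex`.

## Streaming

`proc.stream_out(port)` materializes that output as a named pipe at
`<formatted path>.fifo`. The packet is handed to the consumer when the
producer *starts*, so both run concurrently and data flows through memory;
the FIFO is removed at the end of the run and its provenance (tagged
`stream=true`) is written beside the FIFO path and embedded in the
consumer's record. Streams have no persistent content, so they are never
cached, and a task consuming a stream is never cache-skipped (a skipped
reader would leave the pipe without a consumer). Validation enforces
exactly one consumer per streamed port (a FIFO has one reader) and
`max_tasks ≥ 2` (producer and consumer must hold command slots
simultaneously). The producer's record attaches before execution, so a
consumer that finalizes first may record the producer's execution time as
not-yet-final; at most the timing field is affected, never the command
chain.

## Demo workflows: what they emulate

The fixtures use only POSIX text tools, so they exercise the engine, not
any scientific tool stack. The reverse-complement chain reproduces the
canonical three-process demo and its exact file contents. The sweep demo
mirrors the shape of a hyperparameter search — per training-set size, a
15-cost × 10-fold sweep (the reference grid: 0.0001–5 over sizes
500–8,000), a collecting select-best stage, and a final training task
receiving the selected cost over a parameter connection — with the learner
replaced by the deterministic stand-in *error = (cost − 0.25)² +
fold/1000*, chosen so the argmin is unique and the selected value
verifiable. Random DAGs (≤ 12 echo/cat processes, seeded) drive the
scheduling-soundness checks; a sleep chain drives the kill/resume
atomicity checks. Problem sizes in the test suite (100 DAGs, 50 kill
points, 20 one-second sleepers under a cap of 4) keep the whole suite in
the low minutes on one CPU.

Passing these fixtures shows the engine's contracts hold — ordering,
atomicity, caching, provenance, fan-out counts — under realistic
concurrency. It does not show anything about the behaviour of real
bioinformatics tools (multi-gigabyte I/O, long runtimes, tools that write
outside their working directory), nor about distributed execution.

## Known limitations

- One machine, one Python process; HPC integration is limited to the
  prepend hook (e.g. `salloc -n 1` before a command).
- Presence-based caching cannot detect stale or hand-edited outputs.
- Two processes declaring the same explicit output path are not detected
  statically; the second finalization overwrites the first.
- Streamed ports with more than one task emit packets in completion order,
  not formation order (single-task streaming is the intended use).
- Audit logs follow this engine's JSON dialect; no W3C PROV/JSON-LD
  export, and no CWL interoperability.
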