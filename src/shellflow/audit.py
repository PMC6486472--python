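"""Per-output hierarchical provenance records.

Every file a workflow finalizes gets a sidecar ``<file>.audit.json`` holding
the complete chain of shell commands that produced it.  The record is
*data-centric*: provenance travels with each file rather than with a
workflow run, so the trace survives across runs, scripts and users.  Each
level of the tree describes one task; its ``Upstream`` field maps the input
file paths the task consumed to the audit records of the tasks that produced
them.  Task IDs are random 128-bit tokens, globally unique per execution and
reused verbatim on cache hits, which lets converters deduplicate a task that
reaches the root along several paths (a "diamond").

The module also converts audit trees into executable Bash replay scripts and
into HTML/TeX reports with a Gantt-style execution timeline.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

logger = logging.getLogger(__name__)

AUDIT_SUFFIX = ".audit.json"

#: Fixed JSON field names of the audit dialect.
_FIELDS = ("ID", "ProcessName", "Command", "Params", "Tags", "StartTime",
           "ExecTimeNS", "Upstream")


def new_id() -> str:
    """Random 128-bit token rendered as 32 hex characters."""
    return uuid.uuid4().hex


@dataclass
class AuditInfo:
    """One task's provenance record, with its upstream tree.

    ``start_time_ns`` is nanoseconds since the Unix epoch (UTC); it is
    serialized as an RFC 3339 timestamp with nanosecond precision.
    ``exec_time_ns`` is the wall-clock execution time in nanoseconds.
    """

    id: str
    process_name: str
    command: str
    params: Dict[str, str] = field(default_factory=dict)
    tags: Dict[str, str] = field(default_factory=dict)
    start_time_ns: int = 0
    exec_time_ns: int = 0
    upstream: Dict[str, "AuditInfo"] = field(default_factory=dict)

    @property
    def external(self) -> bool:
        return self.tags.get("external") == "true"


def format_rfc3339_ns(ns: int) -> str:
    secs, frac = divmod(ns, 10 ** 9)
    dt = datetime.fromtimestamp(secs, tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S") + f".{frac:09d}Z"


def parse_rfc3339_ns(text: str) -> int:
    base, _, rest = text.partition(".")
    frac = rest.rstrip("Z")
    dt = datetime.strptime(base, "%Y-%m-%dT%H:%M:%S").replace(tzinfo=timezone.utc)
    ns = int(dt.timestamp()) * 10 ** 9
    if frac:
        ns += int(frac.ljust(9, "0")[:9])
    return ns


def to_dict(audit: AuditInfo) -> dict:
    return {
        "ID": audit.id,
        "ProcessName": audit.process_name,
        "Command": audit.command,
        "Params": {k: audit.params[k] for k in sorted(audit.params)},
        "Tags": {k: audit.tags[k] for k in sorted(audit.tags)},
        "StartTime": format_rfc3339_ns(audit.start_time_ns),
        "ExecTimeNS": audit.exec_time_ns,
        "Upstream": {k: to_dict(audit.upstream[k]) for k in sorted(audit.upstream)},
    }


def from_dict(data: dict) -> AuditInfo:
    return AuditInfo(
        id=data.get("ID", ""),
        process_name=data.get("ProcessName", ""),
        command=data.get("Command", ""),
        params=dict(data.get("Params", {})),
        tags=dict(data.get("Tags", {})),
        start_time_ns=parse_rfc3339_ns(data["StartTime"]) if data.get("StartTime") else 0,
        exec_time_ns=int(data.get("ExecTimeNS", 0)),
        upstream={k: from_dict(v) for k, v in data.get("Upstream", {}).items()},
    )


def dumps(audit: AuditInfo) -> str:
    """Serialize deterministically (fixed field order, sorted upstream keys)."""
    return json.dumps(to_dict(audit), indent=2) + "\n"


def external_stub(path: str) -> AuditInfo:
    """Provenance stub for a file created outside any workflow run."""
    return AuditInfo(id=new_id(), process_name="", command="",
                     tags={"external": "true"})


def write_audit(audit: AuditInfo, file_path: Union[str, Path]) -> Path:
    """Write the sidecar ``<file_path>.audit.json`` next to *file_path*."""
    out = Path(str(file_path) + AUDIT_SUFFIX)
    out.write_text(dumps(audit), encoding="utf-8")
    return out


def read_audit(audit_path: Union[str, Path]) -> AuditInfo:
    """Parse an audit JSON file given the path of the sidecar itself."""
    with open(audit_path, encoding="utf-8") as fh:
        return from_dict(json.load(fh))


def load_audit(file_path: Union[str, Path]) -> AuditInfo:
    """Load the audit tree attached to data file *file_path*.

    A missing or corrupt sidecar yields a warning and an external stub, so
    externally created inputs do not fail the run — their provenance is
    simply marked unknown.
    """
    sidecar = Path(str(file_path) + AUDIT_SUFFIX)
    try:
        return read_audit(sidecar)
    except FileNotFoundError:
        logger.warning("no audit log found for %s; treating as external input",
                       file_path)
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        logger.warning("corrupt audit log %s (%s); treating as external input",
                       sidecar, exc)
    return external_stub(str(file_path))


def build_audit(task) -> AuditInfo:
    """Build the provenance record for a finished task.

    The upstream map is populated from the audit attachments of the task's
    input packets, keyed by the (``../``-stripped) final input paths exactly
    as referenced by the resolved command.
    """
    upstream: Dict[str, AuditInfo] = {}
    for ip in task.iter_input_ips():
        upstream[ip.path] = ip.audit if ip.audit is not None else external_stub(ip.path)
    return AuditInfo(
        id=task.id,
        process_name=task.process_name,
        command=task.command,
        params=dict(task.params),
        tags=dict(task.tags),
        start_time_ns=task.start_ns,
        exec_time_ns=max(task.finish_ns - task.start_ns, 0),
        upstream=upstream,
    )


def unique_tasks(audit: AuditInfo) -> List[AuditInfo]:
    """All distinct tasks of the tree in a dependency-respecting order.

    Depth-first post-order with sorted upstream keys: every producer precedes
    its consumers, duplicated subtrees (shared IDs) appear once, and the
    order is deterministic.  External stubs are excluded.
    """
    seen = set()
    ordered: List[AuditInfo] = []

    def visit(node: AuditInfo) -> None:
        if node.id in seen:
            return
        seen.add(node.id)
        for key in sorted(node.upstream):
            visit(node.upstream[key])
        if not node.external:
            ordered.append(node)

    visit(audit)
    return ordered


def audit2bash(audit: AuditInfo, target: str = "") -> str:
    """Convert an audit tree into an executable Bash replay script.

    Commands are emitted in topological order, each unique task exactly once.
    Each command runs inside a scratch subdirectory of the current directory
    (mirroring the engine's sandboxes, so the ``../`` input prefixes resolve)
    and its outputs are then moved up.  For deterministic commands, running
    the script in a clean directory reproduces the target file byte for byte.
    """
    tasks = unique_tasks(audit)
    lines = [
        "#!/usr/bin/env bash",
        "# Replay script generated by shellflow"
        + (f" for: {target}" if target else ""),
        "# Each task runs in a scratch subdirectory; outputs are moved into",
        "# the current directory afterwards, mirroring sandboxed execution.",
        "set -euo pipefail",
        "",
    ]
    for task in tasks:
        scratch = f"_replay_{task.id[:12]}"
        lines += [
            f"# task {task.id} ({task.process_name})",
            f'mkdir -p "{scratch}"',
            f'( cd "{scratch}" && {task.command} )',
            f'find "{scratch}" -mindepth 1 -maxdepth 1 -exec mv -f -t . {{}} +',
            f'rmdir "{scratch}"',
            "",
        ]
    return "\n".join(lines)


_PALETTE = ["4E79A7", "F28E2B", "E15759", "76B7B2", "59A14F",
            "EDC948", "B07AA1", "FF9DA7", "9C755F", "BAB0AC"]


def _timeline(tasks: List[AuditInfo]):
    """Relative (offset, width) fractions per task for the Gantt bars."""
    if not tasks:
        return 0, []
    t0 = min(t.start_time_ns for t in tasks)
    t1 = max(t.start_time_ns + t.exec_time_ns for t in tasks)
    span = max(t1 - t0, 1)
    bars = []
    for t in tasks:
        offset = (t.start_time_ns - t0) / span
        width = max(t.exec_time_ns / span, 0.005)
        bars.append((offset, min(width, 1.0 - offset)))
    return span, bars


def _fmt_duration(ns: int) -> str:
    if ns >= 10 ** 9:
        return f"{ns / 10 ** 9:.3f} s"
    if ns >= 10 ** 6:
        return f"{ns / 10 ** 6:.3f} ms"
    return f"{ns} ns"


def audit2report(audit: AuditInfo, format: str = "html", target: str = "") -> str:
    """Render an audit tree as a human-readable report.

    The report contains a header with the engine version and the total
    execution time, an execution timeline in Gantt-chart style ordered by
    task start time (ID-sorted for equal starts), and one metadata table per
    unique task, color-keyed consistently with the timeline.
    ``format`` is ``"html"`` or ``"tex"`` (a standalone document compilable
    with an external pdflatex).
    """
    from . import __version__

    tasks = sorted(unique_tasks(audit), key=lambda t: (t.start_time_ns, t.id))
    span, bars = _timeline(tasks)
    colors = [_PALETTE[i % len(_PALETTE)] for i in range(len(tasks))]
    total = _fmt_duration(span if tasks else 0)

    if format == "html":
        return _report_html(tasks, bars, colors, total, target, __version__)
    if format == "tex":
        return _report_tex(tasks, bars, colors, total, target, __version__)
    raise ValueError(f"unknown report format {format!r}")


def _esc_html(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def _report_html(tasks, bars, colors, total, target, version) -> str:
    out = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>Audit report</title>",
        "<style>body{font-family:sans-serif;max-width:60em;margin:2em auto}"
        ".bar{height:14px;border-radius:2px}"
        "table{border-collapse:collapse;margin:1em 0}"
        "td,th{border:1px solid #ccc;padding:2px 8px;text-align:left}"
        "td.cmd{font-family:monospace}</style></head><body>",
        f"<h1>Audit report{': ' + _esc_html(target) if target else ''}</h1>",
        f"<p>Generated by shellflow {version}. Total execution time: {total}.</p>",
        "<h2>Execution timeline</h2>",
    ]
    for i, (task, (off, width)) in enumerate(zip(tasks, bars)):
        out.append(
            f"<div title='{_esc_html(task.process_name)}' style='margin:2px 0'>"
            f"<span style='display:inline-block;width:12em'>"
            f"{_esc_html(task.process_name)}</span>"
            f"<span class='bar' style='display:inline-block;"
            f"margin-left:{off * 70:.2f}%;width:{width * 70:.2f}%;"
            f"background:#{colors[i]}'>&nbsp;</span></div>")
    out.append("<h2>Tasks</h2>")
    for i, task in enumerate(tasks):
        out.append(f"<h3 style='color:#{colors[i]}'>{_esc_html(task.process_name)}</h3>")
        rows = [
            ("ID", task.id),
            ("Process", task.process_name),
            ("Command", task.command),
            ("Parameters", ", ".join(f"{k}={v}" for k, v in sorted(task.params.items())) or "-"),
            ("Tags", ", ".join(f"{k}={v}" for k, v in sorted(task.tags.items())) or "-"),
            ("Start time", format_rfc3339_ns(task.start_time_ns)),
            ("Execution time", _fmt_duration(task.exec_time_ns)),
        ]
        out.append("<table>")
        for key, value in rows:
            cls = " class='cmd'" if key == "Command" else ""
            out.append(f"<tr><th>{key}</th><td{cls}>{_esc_html(str(value))}</td></tr>")
        out.append("</table>")
    out.append("</body></html>")
    return "\n".join(out) + "\n"


def _esc_tex(text: str) -> str:
    return "\\detokenize{" + text.replace("{", "(").replace("}", ")") + "}"


def _report_tex(tasks, bars, colors, total, target, version) -> str:
    out = [
        "\\documentclass{article}",
        "\\usepackage[margin=2.5cm]{geometry}",
        "\\usepackage{xcolor}",
        "\\usepackage{longtable}",
        "\\begin{document}",
        f"\\section*{{Audit report{': ' + _esc_tex(target) if target else ''}}}",
        f"Generated by shellflow {version}. Total execution time: {total}.",
        "",
        "\\subsection*{Execution timeline}",
        "\\begin{longtable}{l l}",
    ]
    for i, c in enumerate(colors):
        out.insert(4, f"\\definecolor{{task{i}}}{{HTML}}{{{c}}}")
    for i, (task, (off, width)) in enumerate(zip(tasks, bars)):
        bar = (f"\\hspace{{{off * 10:.2f}cm}}"
               f"\\textcolor{{task{i}}}{{\\rule{{{max(width * 10, 0.05):.2f}cm}}{{8pt}}}}")
        out.append(f"{_esc_tex(task.process_name)} & {bar} \\\\")
    out.append("\\end{longtable}")
    out.append("\\subsection*{Tasks}")
    for i, task in enumerate(tasks):
        out += [
            f"\\subsubsection*{{\\textcolor{{task{i}}}{{\\rule{{8pt}}{{8pt}}}} "
            f"{_esc_tex(task.process_name)}}}",
            "\\begin{longtable}{l p{11cm}}",
            f"ID & {_esc_tex(task.id)} \\\\",
            f"Command & \\texttt{{{_esc_tex(task.command)}}} \\\\",
            "Parameters & " + (_esc_tex(", ".join(
                f"{k}={v}" for k, v in sorted(task.params.items()))) or "--") + " \\\\",
            f"Start time & {_esc_tex(format_rfc3339_ns(task.start_time_ns))} \\\\",
            f"Execution time & {_esc_tex(_fmt_duration(task.exec_time_ns))} \\\\",
            "\\end{longtable}",
        ]
    out.append("\\end{document}")
    return "\n".join(out) + "\n"
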