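"""DOT (graphviz) export of a workflow's process network.

One box node per process; one directed edge per connection, with the
out-port name on the edge tail and the in-port name on the edge head.  File
dependencies are drawn solid, parameter dependencies dashed (parameters are
RAM-only and never persisted to file).  Emission order is deterministic —
processes and edges sorted by name — so the output is diffable.  Rendering
to images is delegated to the external ``dot`` tool.
"""

from __future__ import annotations

from .network import PARAM, Workflow


def _q(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(wf: Workflow) -> str:
    """Emit the DOT description of *wf*'s process network."""
    wf.validate()
    lines = [
        f"digraph {_q(wf.name)} {{",
        "  rankdir=LR;",
        "  node [shape=box, style=\"rounded\"];",
    ]
    for name in sorted(wf.procs):
        lines.append(f"  {_q(name)};")
    edges = sorted(
        (out_port.proc.name, in_port.proc.name, out_port.name, in_port.name,
         out_port.kind)
        for out_port, in_port in wf.connections)
    for src, dst, tail, head, kind in edges:
        style = "dashed" if kind == PARAM else "solid"
        lines.append(
            f"  {_q(src)} -> {_q(dst)} "
            f"[taillabel={_q(tail)}, headlabel={_q(head)}, style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
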