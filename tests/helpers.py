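"""Shared oracles for the engine tests.

These checks are deliberately independent of the engine internals: they look
only at the filesystem and at the run event log.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

AUDIT_SUFFIX = ".audit.json"


def data_files(work_dir) -> List[Path]:
    """All finalized data files: everything outside task sandboxes that is
    neither an audit sidecar nor a FIFO."""
    out = []
    for f in Path(work_dir).rglob("*"):
        if not f.is_file():
            continue
        if any(part.startswith("_tmp.") for part in f.relative_to(work_dir).parts):
            continue
        if f.name.endswith(AUDIT_SUFFIX) or f.name.endswith(".fifo"):
            continue
        out.append(f)
    return out


def orphan_files(work_dir) -> List[Path]:
    """Finalized data files lacking a complete (parseable) audit sidecar."""
    orphans = []
    for f in data_files(work_dir):
        sidecar = f.with_name(f.name + AUDIT_SUFFIX)
        if not sidecar.exists():
            orphans.append(f)
            continue
        try:
            json.loads(sidecar.read_text())
        except json.JSONDecodeError:
            orphans.append(f)
    return orphans


def soundness_violations(events) -> List[tuple]:
    """Task-ordering oracle on the run log.

    For every executed task and every input it consumed, the producer of
    that input must have finished before the consumer started (topological
    order respected by the actual timestamps).  Streamed inputs are exempt —
    overlap is their purpose.
    """
    finished_at = {}
    for e in events:
        if e["event"] != "exec":
            continue
        for path in e["outputs"]:
            finished_at[path] = e["finish_ns"]
    violations = []
    for e in events:
        if e["event"] != "exec":
            continue
        for path in e["inputs"]:
            if path.endswith(".fifo"):
                continue
            if path in finished_at and e["start_ns"] < finished_at[path]:
                violations.append((path, e["process"]))
    return violations
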