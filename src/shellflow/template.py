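"""Command-pattern and output-path templating.

A process is declared with a shell command *pattern* in which concrete file
names are replaced by placeholders::

    cat {i:in} | rev > {o:rev}

``{i:NAME}`` marks an input file (an in-port), ``{o:NAME}`` an output file
(an out-port) and ``{p:NAME}`` a parameter value.  Port names follow the
identifier grammar ``[A-Za-z0-9_]+``.  Braces that do not open a
``WORD:``-shaped token are treated as literal text, so constructs such as
``awk '{print $1}'`` pass through untouched.

Output *path* patterns (see :func:`compile_formatter`) use the same
placeholder syntax and additionally accept a trim modifier on input
references, ``{i:port|%.suffix}``, which removes ``.suffix`` from the end of
the input path when present.  Modifiers are only legal in path patterns,
never in command patterns.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .ip import TemplateError

logger = logging.getLogger(__name__)

KINDS = ("i", "o", "p")

_IDENT = re.compile(r"[A-Za-z0-9_]+\Z")
_PH_OPEN = re.compile(r"\{([A-Za-z0-9_]*):")


@dataclass(frozen=True)
class Placeholder:
    """One ``{kind:name}`` token found in a pattern."""

    kind: str  # "i", "o" or "p"
    name: str
    trim: Optional[str] = None  # suffix to trim, without the leading "%"
    column: int = 0


# A scanned pattern is a list of segments: ("lit", text) or a Placeholder.
Segment = Union[Tuple[str, str], Placeholder]


def scan_pattern(text: str, allow_modifier: bool = False) -> List[Segment]:
    """Split *text* into literal segments and placeholders.

    Raises :class:`TemplateError` (with the column offset of the offending
    token) on an unknown kind letter, an empty or malformed name, an
    unterminated placeholder, or a modifier where none is allowed.
    """
    segments: List[Segment] = []
    i, n = 0, len(text)
    while i < n:
        j = text.find("{", i)
        if j < 0:
            if i < n:
                segments.append(("lit", text[i:]))
            break
        m = _PH_OPEN.match(text, j)
        if not m:
            # Literal brace (e.g. shell/awk syntax); not a placeholder.
            segments.append(("lit", text[i:j + 1]))
            i = j + 1
            continue
        if j > i:
            segments.append(("lit", text[i:j]))
        kind = m.group(1)
        if kind not in KINDS:
            raise TemplateError(
                f"unknown placeholder kind {kind!r}, expected one of i/o/p",
                column=j)
        close = text.find("}", m.end())
        if close < 0:
            raise TemplateError("unbalanced braces: '{' never closed", column=j)
        body = text[m.end():close]
        trim: Optional[str] = None
        if "|" in body:
            name, mod = body.split("|", 1)
            if not allow_modifier:
                raise TemplateError(
                    "modifiers are only allowed in output path patterns",
                    column=j)
            if not mod.startswith("%") or len(mod) < 2:
                raise TemplateError(
                    f"malformed modifier {mod!r}, expected '%SUFFIX'", column=j)
            trim = mod[1:]
        else:
            name = body
        if not name:
            raise TemplateError("empty placeholder name", column=j)
        if not _IDENT.match(name):
            raise TemplateError(
                f"invalid placeholder name {name!r}", column=j)
        segments.append(Placeholder(kind=kind, name=name, trim=trim, column=j))
        i = close + 1
    return segments


def parse_pattern(text: str, allow_modifier: bool = False) -> List[Placeholder]:
    """Return the placeholders of *text* in order of appearance.

    Duplicates are preserved; literal text is ignored.
    """
    return [s for s in scan_pattern(text, allow_modifier) if isinstance(s, Placeholder)]


def reassemble(segments: Iterable[Segment]) -> str:
    """Inverse of :func:`scan_pattern` (modulo literal-brace merging)."""
    parts = []
    for seg in segments:
        if isinstance(seg, Placeholder):
            mod = f"|%{seg.trim}" if seg.trim else ""
            parts.append("{%s:%s%s}" % (seg.kind, seg.name, mod))
        else:
            parts.append(seg[1])
    return "".join(parts)


def trim_suffix(path: str, suffix: str) -> str:
    """Remove *suffix* from the end of *path* if present; otherwise return
    *path* unchanged with a logged warning."""
    if suffix and path.endswith(suffix) and len(path) > len(suffix):
        return path[:-len(suffix)]
    logger.warning("trim modifier %%%s does not match end of %r; path left "
                   "unchanged", suffix, path)
    return path


class PathFormatter:
    """Compiled output-path pattern for one out-port.

    Built either from a pattern string (literals, ``{i:port}``, ``{p:param}``
    and the trim modifier ``{i:port|%.suffix}``) or from a caller-supplied
    function ``f(inputs, params) -> str`` as an escape hatch for naming
    schemes the mini-language cannot express.
    """

    def __init__(self,
                 pattern: Optional[str] = None,
                 func: Optional[Callable[[Mapping[str, str], Mapping[str, str]], str]] = None):
        if (pattern is None) == (func is None):
            raise TemplateError("provide exactly one of pattern or function")
        self.pattern = pattern
        self.func = func
        self.segments: List[Segment] = []
        if pattern is not None:
            self.segments = scan_pattern(pattern, allow_modifier=True)
            for seg in self.segments:
                if isinstance(seg, Placeholder) and seg.kind == "o":
                    raise TemplateError(
                        "output placeholders cannot appear in a path pattern",
                        column=seg.column)

    def references(self) -> List[Placeholder]:
        return [s for s in self.segments if isinstance(s, Placeholder)]

    def format(self, inputs: Mapping[str, str], params: Mapping[str, str]) -> str:
        """Resolve the formatter into a concrete path.

        Deterministic: the same inputs and params always yield the same path.
        """
        if self.func is not None:
            return self.func(dict(inputs), dict(params))
        parts = []
        for seg in self.segments:
            if not isinstance(seg, Placeholder):
                parts.append(seg[1])
            elif seg.kind == "i":
                if seg.name not in inputs:
                    raise TemplateError(
                        f"path pattern references unknown in-port {seg.name!r}")
                value = inputs[seg.name]
                parts.append(trim_suffix(value, seg.trim) if seg.trim else value)
            else:  # "p"
                if seg.name not in params:
                    raise TemplateError(
                        f"path pattern references unknown parameter {seg.name!r}")
                parts.append(params[seg.name])
        return "".join(parts)


def format_path(formatter: PathFormatter, inputs: Mapping[str, str],
                params: Mapping[str, str]) -> str:
    """Functional form of :meth:`PathFormatter.format`."""
    return formatter.format(inputs, params)


_UNSAFE = re.compile(r"[^A-Za-z0-9_.-]+")


def default_path(process_name: str, port_name: str, command_pattern: str,
                 params: Mapping[str, str],
                 input_paths: Mapping[str, Union[str, Sequence[str]]]) -> str:
    """Automatic output path for a port with no explicit formatter.

    The path is ``<process-name>.<12-hex digest>.<port-name>`` where the
    digest is taken over the task's canonical signature: the command pattern,
    the sorted ``name=value`` parameter pairs and the sorted
    ``in-port=final-input-path`` pairs.  Two tasks with different parameters
    or input data therefore never clash, while two tasks with the same
    signature reuse the same cached path.
    """
    digest = signature_digest(command_pattern, params, input_paths)
    safe_name = _UNSAFE.sub("_", process_name)
    return f"{safe_name}.{digest}.{port_name}"


def signature_digest(command_pattern: str, params: Mapping[str, str],
                     input_paths: Mapping[str, Union[str, Sequence[str]]],
                     width: int = 12) -> str:
    """12 hex chars of SHA-256 over the canonical UTF-8 task signature."""
    parts = [command_pattern]
    parts += [f"p:{k}={params[k]}" for k in sorted(params)]
    for k in sorted(input_paths):
        v = input_paths[k]
        if not isinstance(v, str):
            v = ",".join(v)
        parts.append(f"i:{k}={v}")
    sig = "\n".join(parts)
    return hashlib.sha256(sig.encode("utf-8")).hexdigest()[:width]


def format_command(pattern: str,
                   inputs: Mapping[str, Union[str, Sequence[str]]],
                   outputs: Mapping[str, str],
                   params: Mapping[str, str],
                   prepend: str = "") -> str:
    """Resolve a command pattern into concrete shell text.

    Input placeholders become the final (working-directory-relative) input
    path prefixed with ``../``, because the command runs from inside a task
    sandbox one level below the working directory.  A collected (multi-packet)
    input expands to all its paths, space-separated, each with the ``../``
    prefix.  Output placeholders are substituted verbatim with the
    sandbox-relative path the caller resolved (or the ``../``-prefixed FIFO
    path for streamed ports).  Parameter placeholders become their values.
    If *prepend* is non-empty it is prefixed with a single space separator.
    """
    parts = []
    for seg in scan_pattern(pattern, allow_modifier=False):
        if not isinstance(seg, Placeholder):
            parts.append(seg[1])
        elif seg.kind == "i":
            if seg.name not in inputs:
                raise TemplateError(
                    f"unresolved input placeholder {{i:{seg.name}}}",
                    column=seg.column)
            v = inputs[seg.name]
            if isinstance(v, str):
                parts.append("../" + v)
            else:
                parts.append(" ".join("../" + p for p in v))
        elif seg.kind == "o":
            if seg.name not in outputs:
                raise TemplateError(
                    f"unresolved output placeholder {{o:{seg.name}}}",
                    column=seg.column)
            parts.append(outputs[seg.name])
        else:
            if seg.name not in params:
                raise TemplateError(
                    f"unresolved parameter placeholder {{p:{seg.name}}}",
                    column=seg.column)
            parts.append(params[seg.name])
    command = "".join(parts)
    if prepend:
        command = prepend + " " + command
    return command
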