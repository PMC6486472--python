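# shellflow

A flow-based workflow engine for shell-command pipelines, written as a plain
Python library. It is aimed at bioinformatics, cheminformatics and machine
learning pipelines whose structure is too dynamic for file-name-driven,
pull-based workflow tools: nested parameter sweeps, cross-validation fold
generation, and downstream steps parametrized with values that only exist
once part of the workflow has already run.

## The model

A workflow is a network of independent **processes**, each wrapping a shell
command *pattern* in which concrete file names are replaced by placeholders:

```
cat {i:in} | rev > {o:rev}
```

`{i:NAME}` declares a file in-port, `{o:NAME}` a file out-port and
`{p:NAME}` a parameter in-port. Following flow-based programming (FBP), the
network is defined *separately* from the processes, by connecting port
objects (`in_port.From(out_port)`), so components stay self-contained and
freely reconnectable. At run time every process runs concurrently and forms
**tasks** dynamically as information packets arrive (push-based dataflow):
one packet per connected port per task (zip semantics), with explicit
parameter sources for fan-out and collecting in-ports for fan-in.

Around that core the engine provides:

- **Atomic writes** — each task runs in a sandbox directory directly under
  the workflow directory; on success everything the command created
  (declared on the command line or not) is moved into place with atomic
  renames, so finished and half-finished files can never be confused.
- **Caching** — a task whose declared outputs and audit sidecars already
  exist is skipped; automatic output naming embeds a signature digest so
  tasks with different inputs or parameters never clash.
- **Per-file provenance** — every output gets a hierarchical audit log
  `<file>.audit.json` holding the full chain of commands that produced it,
  merged across runs and scripts, convertible to Bash replay scripts and
  HTML/TeX timeline reports.
- **Partial runs** — `wf.run_to("Some Process")` runs only the upstream
  closure of a process, skipping everything downstream.
- **Streaming** — an out-port can be turned into a Unix named pipe, so
  producer and consumer run concurrently and the intermediate never touches
  disk.

## Worked example

The classic three-step demo computes the reverse base complement of a DNA
string with standard UNIX tools:

```python
from shellflow import Workflow

wf = Workflow("DNA Base Complement Workflow", max_tasks=4)

make_dna = wf.new_proc("Make DNA", "echo AAAGCCCGTGGGGGACCTGTTC > {o:dna}")
make_dna.set_out("dna", "dna.txt")

compl = wf.new_proc("Base Complement", "cat {i:in} | tr ATCG TAGC > {o:complement}")
compl.set_out("complement", "{i:in|%.txt}.compl.txt")   # %.txt trims ".txt"

rev = wf.new_proc("Reverse", "cat {i:in} | rev > {o:rev}")
rev.set_out("rev", "{i:in|%.txt}.rev.txt")

compl.in_port("in").From(make_dna.out_port("dna"))
rev.in_port("in").From(compl.out_port("complement"))

report = wf.run()
print("commands executed:", report.commands_executed)
```

Running this prints `commands executed: 3` and leaves six files behind —
three outputs, each with its audit sidecar:

```
dna.txt                       dna.txt.audit.json
dna.compl.txt                 dna.compl.txt.audit.json
dna.compl.rev.txt             dna.compl.rev.txt.audit.json
```

`dna.txt` contains `AAAGCCCGTGGGGGACCTGTTC` and `dna.compl.rev.txt`
contains `GAACAGGTCCCCCACGGGCTTT`, its reverse base complement. Running the
script again executes 0 commands: every task is a cache hit. The final
audit log nests the whole chain — note the `../` input prefixes, recording
that commands execute inside a sandbox one level below the workflow
directory, and the execution times in nanoseconds:

```json
{
  "ID": "77a849408bec475b83cc21226ffa1c11",
  "ProcessName": "Reverse",
  "Command": "cat ../dna.compl.txt | rev > dna.compl.rev.txt",
  "StartTime": "2026-09-19T23:25:06.485349986Z",
  "ExecTimeNS": 5607241,
  "Upstream": {
    "dna.compl.txt": {
      "ProcessName": "Base Complement",
      "Command": "cat ../dna.txt | tr ATCG TAGC > dna.compl.txt",
      "Upstream": { "dna.txt": { "ProcessName": "Make DNA", "..." : "..." } }
    }
  }
}
```

The `shellflow` helper converts audit logs and plots workflows:

```sh
shellflow audit2bash dna.compl.rev.txt.audit.json -o replay.sh   # Bash replay
shellflow audit2html dna.compl.rev.txt.audit.json -o report.html # timeline report
shellflow audit2tex  dna.compl.rev.txt.audit.json -o report.tex  # for pdflatex
shellflow plot revcomp -o wf.dot                                 # graphviz DOT
```

`replay.sh`, executed in an empty directory, regenerates
`dna.compl.rev.txt` byte for byte from its three recorded commands.

Demo workflows (also addressable by name from `shellflow plot`) live in
`shellflow.fixtures`: the chain above (`revcomp`), a 15-cost × 10-fold
parameter sweep with a dynamically parametrized final training step
(`sweep`), a streaming producer/consumer pair (`stream`) and seeded random
DAGs (`random-dag`).

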