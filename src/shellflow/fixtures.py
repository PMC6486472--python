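"""Self-contained demo workflows and randomized test networks.

Everything here uses only standard UNIX text tools (echo, cat, tr, rev,
awk, sort, seq, wc, sleep, touch), so every part of the engine can be
exercised without downloads or domain software.  The sweep demo mirrors the
shape of a hyperparameter-tuning pipeline — a cost x fold parameter sweep, a
per-size selection of the best cost, and a final training step parametrized
by the selected value at run time — with a deterministic arithmetic stand-in
for the learner so the selection has a unique argmin.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Sequence, Union

from .network import Workflow

DNA_STRING = "AAAGCCCGTGGGGGACCTGTTC"

#: Cost grid and training-set sizes of the reference sweep design:
#: 15 cost values in a 10-fold cross-validated sweep, at 5 training sizes.
SWEEP_COSTS = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5,
               0.75, 1, 2, 3, 4, 5)
SWEEP_SIZES = (500, 1000, 2000, 4000, 8000)
SWEEP_FOLDS = 10


def make_revcomp_demo(work_dir: Union[str, Path] = ".") -> Workflow:
    """Three-process chain computing the reverse base complement of a DNA
    string: write the string, complement each base (A<->T, C<->G), reverse
    it.  Produces dna.txt, dna.compl.txt and dna.compl.rev.txt, each with an
    audit sidecar."""
    wf = Workflow("DNA Base Complement Workflow", max_tasks=4,
                  work_dir=work_dir)

    make_dna = wf.new_proc("Make DNA", f"echo {DNA_STRING} > {{o:dna}}")
    make_dna.set_out("dna", "dna.txt")

    complement = wf.new_proc("Base Complement",
                             "cat {i:in} | tr ATCG TAGC > {o:complement}")
    complement.set_out("complement", "{i:in|%.txt}.compl.txt")

    reverse = wf.new_proc("Reverse", "cat {i:in} | rev > {o:rev}")
    reverse.set_out("rev", "{i:in|%.txt}.rev.txt")

    complement.in_port("in").From(make_dna.out_port("dna"))
    reverse.in_port("in").From(complement.out_port("complement"))
    return wf


def make_sweep_demo(work_dir: Union[str, Path] = ".",
                    sizes: Sequence = SWEEP_SIZES,
                    costs: Sequence = SWEEP_COSTS,
                    folds: int = SWEEP_FOLDS) -> Workflow:
    """Parameter-sweep workflow with dynamic downstream parametrization.

    Per training-set size: ``len(costs) * folds`` sweep tasks evaluate a toy
    learner (validation error ``(cost - 0.25)^2 + fold/1000``, so the best
    cost is unique), a collecting select-best stage picks the cost with the
    lowest error, and a final training task receives that cost over a
    parameter connection — its value exists only once the sweep has run.
    """
    if not sizes or not costs or not folds:
        raise ValueError("sizes, costs and folds must be non-empty")
    wf = Workflow("Parameter Sweep Workflow", max_tasks=8, work_dir=work_dir)
    for size in sizes:
        combos = [(c, f) for c in costs for f in range(1, folds + 1)]
        cost_src = wf.new_param_source(f"Costs (size {size})",
                                       [c for c, _ in combos])
        fold_src = wf.new_param_source(f"Folds (size {size})",
                                       [f for _, f in combos])

        sweep = wf.new_proc(
            f"Train Validate (size {size})",
            "awk -v c={p:cost} -v f={p:fold} "
            "'BEGIN{printf \"%s,%.6f\\n\", c, (c-0.25)*(c-0.25)+f/1000}'"
            " > {o:eval}")
        sweep.set_out("eval", f"sweep_s{size}_c{{p:cost}}_f{{p:fold}}.csv")
        sweep.param_in("cost").From(cost_src.param_out("out"))
        sweep.param_in("fold").From(fold_src.param_out("out"))

        select = wf.new_proc(
            f"Select Best (size {size})",
            "sort -t, -g -k2 {i:evals} | head -n 1 | cut -d, -f1 > {o:best}")
        select.in_port("evals").collect_all()
        select.set_out("best", f"best_cost_s{size}.txt")
        select.add_param_out("bestcost", "best")
        select.in_port("evals").From(sweep.out_port("eval"))

        final = wf.new_proc(
            f"Final Train (size {size})",
            f'echo "model size={size} cost={{p:cost}}" > {{o:model}}')
        final.set_out("model", f"model_s{size}.txt")
        final.param_in("cost").From(select.param_out("bestcost"))
    return wf


def make_random_dag(work_dir: Union[str, Path], n_procs: int,
                    seed: int) -> Workflow:
    """Seeded random DAG of echo/cat processes for scheduler property tests.

    Process ``i`` depends on a random subset (at most 3) of the processes
    before it; parentless processes are sources.  The same ``(n_procs,
    seed)`` always yields an identical network.
    """
    if n_procs < 1:
        raise ValueError("n_procs must be >= 1")
    rng = random.Random(seed)
    wf = Workflow(f"Random DAG {n_procs}/{seed}", max_tasks=4,
                  work_dir=work_dir)
    procs = []
    for i in range(n_procs):
        k = rng.randint(0, min(i, 3))
        parents = sorted(rng.sample(range(i), k))
        if not parents:
            proc = wf.new_proc(f"p{i:02d}", f"echo data{i} > {{o:out}}")
        else:
            ins = " ".join(f"{{i:in{j}}}" for j in range(len(parents)))
            proc = wf.new_proc(f"p{i:02d}", f"cat {ins} > {{o:out}}")
        proc.set_out("out", f"node{i:02d}.txt")
        for j, parent in enumerate(parents):
            proc.in_port(f"in{j}").From(procs[parent].out_port("out"))
        procs.append(proc)
    return wf


def make_atomic_chain(work_dir: Union[str, Path] = ".", n_steps: int = 4,
                      delay: float = 0.08) -> Workflow:
    """Linear chain of slow steps, used to probe crash atomicity.

    Each step sleeps briefly and appends its own marker to the accumulated
    file, so a run killed at an arbitrary instant leaves work half done and
    a resumed run must pick up exactly where the finished files end.
    """
    wf = Workflow("Atomic Chain Workflow", max_tasks=2, work_dir=work_dir)
    prev = wf.new_proc("step00", f"sleep {delay} && echo seed > {{o:out}}")
    prev.set_out("out", "step00.txt")
    for i in range(1, n_steps):
        proc = wf.new_proc(
            f"step{i:02d}",
            f"sleep {delay} && (cat {{i:in}}; echo step{i}) > {{o:out}}")
        proc.set_out("out", f"step{i:02d}.txt")
        proc.in_port("in").From(prev.out_port("out"))
        prev = proc
    return wf


def make_stream_pair(work_dir: Union[str, Path] = ".", n: int = 5,
                     streamed: bool = True) -> Workflow:
    """Producer/consumer pair for streaming checks: ``seq`` feeds ``wc -l``
    through a named pipe (or a regular file when ``streamed`` is off)."""
    wf = Workflow("Stream Pair Workflow", max_tasks=4, work_dir=work_dir)
    producer = wf.new_proc("Produce Numbers", f"seq 1 {n} > {{o:s}}")
    producer.set_out("s", "numbers.txt")
    if streamed:
        producer.stream_out("s")
    consumer = wf.new_proc("Count Lines", "wc -l < {i:s} > {o:n}")
    consumer.set_out("n", "count.txt")
    consumer.in_port("s").From(producer.out_port("s"))
    return wf


#: Demo workflows addressable by name from the command line.
DEMOS = {
    "revcomp": make_revcomp_demo,
    "sweep": make_sweep_demo,
    "random-dag": lambda work_dir: make_random_dag(work_dir, 12, 7),
    "stream": make_stream_pair,
}
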