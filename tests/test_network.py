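"""Workflow definition, connections, zip task formation and scheduling."""

import re

import pytest

import helpers
from shellflow import Workflow, new_workflow
from shellflow.fixtures import make_random_dag, make_revcomp_demo
from shellflow.ip import DefinitionError, TaskError, ValidationError


class TestWorkflowInit:
    def test_empty_workflow(self):
        wf = new_workflow("wf", 4)
        assert wf.procs == {} and wf.max_tasks == 4

    @pytest.mark.parametrize("max_tasks", [0, -1, 1.5])
    def test_nonpositive_task_cap_rejected(self, max_tasks):
        with pytest.raises(DefinitionError):
            new_workflow("wf", max_tasks)


class TestPortCreation:
    @pytest.mark.parametrize("pattern", [
        "echo AAAGCCCGTGGGGGACCTGTTC > {o:dna}",
        "cat {i:in} > {o:out}",
        "f {i:a} {i:a} {o:b}",
        "train -c {p:cost} {i:d} > {o:m} 2> {o:log}",
    ])
    def test_ports_are_distinct_placeholder_names(self, pattern, tmp_path):
        # oracle: independent regex scan for distinct (kind, name) pairs
        pairs = set(re.findall(r"\{([iop]):([A-Za-z0-9_]+)\}", pattern))
        wf = Workflow("wf", 1, tmp_path)
        proc = wf.new_proc("p", pattern)
        assert set(proc.in_ports) == {n for k, n in pairs if k == "i"}
        assert set(proc.out_ports) == {n for k, n in pairs if k == "o"}
        assert set(proc.param_in_ports) == {n for k, n in pairs if k == "p"}

    def test_duplicate_process_name_rejected(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        wf.new_proc("p", "echo > {o:x}")
        with pytest.raises(DefinitionError, match="duplicate"):
            wf.new_proc("p", "echo > {o:y}")

    def test_malformed_pattern_names_offending_token(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        with pytest.raises(DefinitionError, match="x"):
            wf.new_proc("p", "cmd {x:bad}")


class TestConnections:
    def test_kind_mismatch_rejected(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        a = wf.new_proc("a", "echo > {o:out}")
        b = wf.new_proc("b", "run -c {p:c} > {o:out}")
        with pytest.raises(DefinitionError, match="kind mismatch"):
            b.param_in("c").From(a.out_port("out"))

    def test_double_connecting_in_port_rejected(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        a = wf.new_proc("a", "echo > {o:out}")
        b = wf.new_proc("b", "echo > {o:out}")
        c = wf.new_proc("c", "cat {i:in} > {o:out}")
        c.in_port("in").From(a.out_port("out"))
        with pytest.raises(DefinitionError, match="already connected"):
            c.in_port("in").From(b.out_port("out"))

    def test_broadcast_delivers_every_packet_to_each_consumer(self, tmp_path):
        # 1 producer emitting 3 packets, 2 consumers: each runs 3 tasks
        wf = Workflow("wf", 4, tmp_path)
        vals = wf.new_param_source("vals", [1, 2, 3])
        prod = wf.new_proc("prod", "echo {p:v} > {o:out}")
        prod.set_out("out", "v{p:v}.txt")
        prod.param_in("v").From(vals.param_out("out"))
        for name in ("left", "right"):
            cons = wf.new_proc(name, "cat {i:in} > {o:out}")
            cons.set_out("out", name + "_{i:in}")
            cons.in_port("in").From(prod.out_port("out"))
        report = wf.run()
        assert report.tasks_for("prod") == 3
        assert report.tasks_for("left") == 3
        assert report.tasks_for("right") == 3


class TestZipSemantics:
    def _sweep(self, tmp_path, a_vals, b_vals):
        wf = Workflow("wf", 4, tmp_path)
        src_a = wf.new_param_source("A", a_vals)
        src_b = wf.new_param_source("B", b_vals)
        proc = wf.new_proc("pair", "echo {p:a}-{p:b} > {o:out}")
        proc.set_out("out", "pair_{p:a}_{p:b}.txt")
        proc.param_in("a").From(src_a.param_out("out"))
        proc.param_in("b").From(src_b.param_out("out"))
        return wf, proc

    def test_equal_streams_pair_positionally(self, tmp_path):
        wf, _ = self._sweep(tmp_path, [1, 2, 3], ["x", "y", "z"])
        report = wf.run()
        assert report.tasks_for("pair") == 3
        assert {(tmp_path / f"pair_{a}_{b}.txt").exists()
                for a, b in [(1, "x"), (2, "y"), (3, "z")]} == {True}

    def test_unequal_streams_stop_at_min(self, tmp_path):
        wf, _ = self._sweep(tmp_path, [1, 2, 3], ["x", "y"])
        report = wf.run()
        assert report.tasks_for("pair") == 2

    def test_single_port_identity(self, tmp_path):
        wf = Workflow("wf", 2, tmp_path)
        src = wf.new_param_source("S", [1, 2, 3])
        proc = wf.new_proc("p", "echo {p:v} > {o:out}")
        proc.set_out("out", "o{p:v}.txt")
        proc.param_in("v").From(src.param_out("out"))
        assert wf.run().tasks_for("p") == 3


class TestValidation:
    def test_unconnected_in_port_fails_before_execution(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        wf.new_proc("a", "echo > {o:out}").set_out("out", "a.txt")
        wf.new_proc("b", "cat {i:in} > {o:out}").set_out("out", "b.txt")
        with pytest.raises(ValidationError, match="not connected"):
            wf.run()
        assert not (tmp_path / "a.txt").exists()

    def test_cycle_rejected(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        a = wf.new_proc("a", "cat {i:x} > {o:y}")
        b = wf.new_proc("b", "cat {i:x} > {o:y}")
        a.set_out("y", "a.txt")
        b.set_out("y", "b.txt")
        b.in_port("x").From(a.out_port("y"))
        a.in_port("x").From(b.out_port("y"))
        with pytest.raises(ValidationError, match="cycle"):
            wf.run()


class TestRunTo:
    def test_mid_chain_target_skips_downstream(self, tmp_path):
        wf = make_revcomp_demo(tmp_path)
        report = wf.run_to("Base Complement")
        assert report.processes_run == {"Make DNA", "Base Complement"}
        assert not (tmp_path / "dna.compl.rev.txt").exists()

    def test_sink_target_equals_full_run(self, tmp_path):
        wf = make_revcomp_demo(tmp_path)
        report = wf.run_to("Reverse")
        assert report.processes_run == {"Make DNA", "Base Complement",
                                        "Reverse"}

    def test_diamond_branch_closure(self, tmp_path):
        wf = Workflow("wf", 2, tmp_path)
        root = wf.new_proc("root", "echo r > {o:out}")
        root.set_out("out", "root.txt")
        for name in ("b1", "b2"):
            br = wf.new_proc(name, "cat {i:in} > {o:out}")
            br.set_out("out", name + ".txt")
            br.in_port("in").From(root.out_port("out"))
        report = wf.run_to("b1")
        # oracle: reverse reachability of b1 is {root, b1}
        assert report.processes_run == {"root", "b1"}

    def test_unknown_target_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="nope"):
            make_revcomp_demo(tmp_path).run_to("nope")


class TestFailure:
    def test_nonzero_exit_reports_context_and_moves_nothing(self, tmp_path):
        wf = Workflow("wf", 1, tmp_path)
        proc = wf.new_proc("boom", "echo x > {o:out}; exit 3")
        proc.set_out("out", "out.txt")
        with pytest.raises(TaskError) as err:
            wf.run()
        assert err.value.process_name == "boom"
        assert err.value.returncode == 3
        assert "exit 3" in err.value.command
        assert not (tmp_path / "out.txt").exists()

    def test_downstream_of_failed_task_never_runs(self, tmp_path):
        wf = Workflow("wf", 2, tmp_path)
        bad = wf.new_proc("bad", "exit 1; echo > {o:out}")
        bad.set_out("out", "bad.txt")
        after = wf.new_proc("after", "cat {i:in} > {o:out}")
        after.set_out("out", "after.txt")
        after.in_port("in").From(bad.out_port("out"))
        with pytest.raises(TaskError):
            wf.run()
        assert not (tmp_path / "after.txt").exists()


def test_random_dags_respect_dependency_order(tmp_path):
    """Every task starts only after all its producers have finished."""
    for seed in range(10):
        d = tmp_path / f"dag{seed}"
        wf = make_random_dag(d, n_procs=3 + seed % 10, seed=seed)
        report = wf.run()
        assert helpers.soundness_violations(report.events) == []
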