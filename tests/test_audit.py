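"""Provenance records: structure, persistence, merging and converters."""

import json
import subprocess

import pytest

from shellflow import (AuditInfo, Workflow, audit2bash, audit2report,
                       load_audit, read_audit, write_audit)
from shellflow.audit import dumps, from_dict, new_id, to_dict, unique_tasks
from shellflow.fixtures import make_revcomp_demo


@pytest.fixture
def revcomp_run(tmp_path):
    wf = make_revcomp_demo(tmp_path)
    wf.run()
    return tmp_path


class TestHierarchy:
    def test_final_audit_nests_full_chain(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        assert tree.process_name == "Reverse"
        assert set(tree.upstream) == {"dna.compl.txt"}
        compl = tree.upstream["dna.compl.txt"]
        assert compl.process_name == "Base Complement"
        assert set(compl.upstream) == {"dna.txt"}
        assert compl.upstream["dna.txt"].process_name == "Make DNA"
        assert compl.upstream["dna.txt"].upstream == {}

    def test_upstream_keys_match_command_inputs(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        # the command references the input with a ../ prefix; the upstream
        # key is the same path stripped of it
        assert "../dna.compl.txt" in tree.command
        assert "dna.compl.txt" in tree.upstream

    def test_execution_time_is_nanoseconds(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.txt.audit.json")
        assert isinstance(tree.exec_time_ns, int)
        assert 0 < tree.exec_time_ns < 60 * 10 ** 9

    def test_shared_upstream_task_keeps_one_id(self, tmp_path):
        # diamond: two branch files produced from one root, joined downstream
        wf = Workflow("wf", 2, tmp_path)
        root = wf.new_proc("root", "echo r > {o:out}")
        root.set_out("out", "root.txt")
        join = wf.new_proc("join", "cat {i:a} {i:b} > {o:out}")
        join.set_out("out", "join.txt")
        for name, port in (("b1", "a"), ("b2", "b")):
            br = wf.new_proc(name, "cat {i:in} > {o:out}")
            br.set_out("out", name + ".txt")
            br.in_port("in").From(root.out_port("out"))
            join.in_port(port).From(br.out_port("out"))
        wf.run()
        tree = read_audit(tmp_path / "join.txt.audit.json")
        root_ids = {tree.upstream[k].upstream["root.txt"].id
                    for k in ("b1.txt", "b2.txt")}
        assert len(root_ids) == 1


class TestSerialization:
    def test_write_load_roundtrip_is_byte_stable(self, revcomp_run):
        sidecar = revcomp_run / "dna.compl.rev.txt.audit.json"
        original = sidecar.read_text()
        assert dumps(from_dict(json.loads(original))) == original

    def test_structural_roundtrip(self, tmp_path):
        tree = AuditInfo(id=new_id(), process_name="p", command="echo",
                         params={"c": "1"}, tags={"t": "v"},
                         start_time_ns=1_600_000_000_123_456_789,
                         exec_time_ns=42,
                         upstream={"f.txt": AuditInfo(id=new_id(),
                                                      process_name="q",
                                                      command="touch f.txt")})
        write_audit(tree, tmp_path / "f2.txt")
        loaded = load_audit(tmp_path / "f2.txt")
        assert to_dict(loaded) == to_dict(tree)

    def test_missing_sidecar_yields_external_stub(self, tmp_path, caplog):
        stub = load_audit(tmp_path / "nothing.txt")
        assert stub.external and stub.upstream == {}

    def test_fixed_json_field_names(self, revcomp_run):
        data = json.loads((revcomp_run / "dna.txt.audit.json").read_text())
        assert set(data) == {"ID", "ProcessName", "Command", "Params", "Tags",
                             "StartTime", "ExecTimeNS", "Upstream"}


class TestCrossRunMerging:
    def test_chain_split_across_two_scripts_keeps_full_trace(self, tmp_path):
        first = Workflow("first", 1, tmp_path)
        first.new_proc("origin", "echo hello > {o:out}").set_out("out", "a.txt")
        first.run()

        second = Workflow("second", 1, tmp_path)
        src = second.new_file_source("load", ["a.txt"])
        up = second.new_proc("shout", "tr a-z A-Z < {i:in} > {o:out}")
        up.set_out("out", "b.txt")
        up.in_port("in").From(src.out_port("out"))
        second.run()

        tree = read_audit(tmp_path / "b.txt.audit.json")
        assert tree.upstream["a.txt"].command == "echo hello > a.txt"

    def test_externally_created_input_flagged_external(self, tmp_path):
        (tmp_path / "raw.txt").write_text("payload\n")
        wf = Workflow("wf", 1, tmp_path)
        src = wf.new_file_source("load", ["raw.txt"])
        proc = wf.new_proc("copy", "cat {i:in} > {o:out}")
        proc.set_out("out", "copy.txt")
        proc.in_port("in").From(src.out_port("out"))
        wf.run()
        tree = read_audit(tmp_path / "copy.txt.audit.json")
        assert tree.upstream["raw.txt"].external


class TestBashConversion:
    def test_three_process_chain_gives_three_commands(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        script = audit2bash(tree)
        assert script.count("mkdir -p") == 3

    def test_replay_reproduces_target_byte_identically(self, revcomp_run,
                                                       tmp_path_factory):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        clean = tmp_path_factory.mktemp("replay")
        (clean / "replay.sh").write_text(audit2bash(tree))
        subprocess.run(["bash", "replay.sh"], cwd=clean, check=True)
        assert ((clean / "dna.compl.rev.txt").read_bytes()
                == (revcomp_run / "dna.compl.rev.txt").read_bytes())
        assert (clean / "dna.compl.rev.txt").read_text().strip() == \
            "GAACAGGTCCCCCACGGGCTTT"

    def test_duplicate_subtrees_emitted_once(self):
        root = AuditInfo(id="rootid", process_name="root",
                         command="echo r > root.txt")
        tree = AuditInfo(id="joinid", process_name="join", command="cat",
                         upstream={"a": AuditInfo(id="b1", process_name="b1",
                                                  command="c1",
                                                  upstream={"r": root}),
                                   "b": AuditInfo(id="b2", process_name="b2",
                                                  command="c2",
                                                  upstream={"r": root})})
        script = audit2bash(tree)
        assert script.count("echo r > root.txt") == 1

    def test_single_task_audit_gives_single_command(self):
        tree = AuditInfo(id=new_id(), process_name="only",
                         command="echo hi > hi.txt")
        assert audit2bash(tree).count("mkdir -p") == 1


class TestReports:
    def _tree(self, starts):
        ups = {f"f{i}.txt": AuditInfo(id=f"id{i:02d}", process_name=f"p{i}",
                                      command=f"c{i}", start_time_ns=s,
                                      exec_time_ns=10)
               for i, s in enumerate(starts)}
        return AuditInfo(id="rootid", process_name="final", command="cf",
                         start_time_ns=max(starts) + 20, exec_time_ns=5,
                         upstream=ups)

    @pytest.mark.parametrize("fmt, marker", [("html", "<html"),
                                             ("tex", "\\documentclass")])
    def test_report_has_header_and_all_tasks(self, revcomp_run, fmt, marker):
        from shellflow import __version__
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        doc = audit2report(tree, format=fmt)
        assert marker in doc and __version__ in doc
        for name in ("Make DNA", "Base Complement", "Reverse"):
            assert name in doc

    def test_tasks_ordered_by_start_time(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        doc = audit2report(tree, format="html")
        assert (doc.index("Make DNA") < doc.index("Base Complement")
                < doc.index("Reverse"))

    def test_equal_start_times_rendered_in_id_order(self):
        doc = audit2report(self._tree([100, 100, 100]), format="html")
        assert doc.index(">p0<") < doc.index(">p1<") < doc.index(">p2<")

    def test_single_task_timeline_has_one_bar(self):
        tree = AuditInfo(id="x", process_name="solo", command="c",
                         start_time_ns=100, exec_time_ns=50)
        doc = audit2report(tree, format="html")
        assert doc.count("class='bar'") == 1

    def test_unique_tasks_topological_and_deduplicated(self, revcomp_run):
        tree = read_audit(revcomp_run / "dna.compl.rev.txt.audit.json")
        tasks = unique_tasks(tree)
        names = [t.process_name for t in tasks]
        assert names == ["Make DNA", "Base Complement", "Reverse"]
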