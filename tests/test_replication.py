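"""Bundle export, script reconstruction, environment verification, replication."""

import subprocess

import pytest

from provfs import (
    Mount,
    TracedRunner,
    dumps_bundle,
    export_bundle,
    load_bundle,
    reconstruct_script,
    replicate,
    save_bundle,
    verify_environment,
)
from provfs.replication import BundleError, MISSING_EXECUTABLE, VERSION_MISMATCH
from provfs.synthetic import gen_pipeline, materialize_pipeline


def record(tmp_path, pipeline, subdir="data"):
    data, bindir = tmp_path / subdir, tmp_path / f"{subdir}-bin"
    data.mkdir()
    materialize_pipeline(pipeline, data, bindir)
    mount = Mount(data)
    run = TracedRunner(mount).run_pipeline(pipeline, bindir)
    return mount, run, data, bindir


def external_input_map(bundle, data):
    return {e["path"]: str(data / e["path"]) for e in bundle["external_inputs"]}


class TestExport:
    def test_bundle_counts_match_fixture_topology(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        pl = ctx["pipeline"]
        # stages in the target's closure + the driver shell
        assert len(b["processes"]) == len(pl.closure_stages) + 1
        assert len(b["files"]) == len(pl.closure_files)
        assert b["target"]["path"] == pl.target
        assert b["target"]["content_checksum"] == pl.expected_target_sha256

    def test_external_target_bundle_has_no_processes(self, tmp_path):
        root = tmp_path / "r"
        root.mkdir()
        m = Mount(root)
        m.write_file("ext.dat", b"payload")  # written by the test process...
        fv = m.store.ensure_version("untouched.dat")  # ...but this one never written
        b = export_bundle(fv.file_key, m.store)
        assert b["processes"] == []
        assert len(b["external_inputs"]) == 1
        with pytest.raises(BundleError, match="external origin"):
            reconstruct_script(b)
        m.store.close()

    def test_bundle_round_trip_byte_identical(self, recorded_pipeline, tmp_path):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        p1, p2 = tmp_path / "b1.json", tmp_path / "b2.json"
        save_bundle(b, p1)
        save_bundle(load_bundle(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert dumps_bundle(load_bundle(p2)) == dumps_bundle(b)

    def test_bad_schema_version_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"schema_version": 99}')
        with pytest.raises(BundleError, match="schema"):
            load_bundle(p)


class TestScriptReconstruction:
    def test_script_reproduces_target_without_driver(self, recorded_pipeline):
        """The original driver script never existed on disk; reconstruction
        from provenance alone must reproduce the target byte-for-byte."""
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        script = reconstruct_script(b)
        fresh = ctx["tmp"] / "fresh"
        fresh.mkdir()
        for rel, src in external_input_map(b, ctx["data"]).items():
            dst = fresh / rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            dst.write_bytes(open(src, "rb").read())
        sp = ctx["tmp"] / "repro.sh"
        sp.write_text(script)
        subprocess.run(["/bin/sh", str(sp)], cwd=fresh, check=True)
        assert (fresh / ctx["pipeline"].target).read_bytes() == ctx["pipeline"].expected_target

    def test_wrapper_driver_not_reinvoked(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        script = reconstruct_script(b)
        assert "driver.sh" not in script  # shell wrapper excluded
        # one command line per closure stage
        cmds = [l for l in script.splitlines()
                if l and not l.startswith(("#", "set", "export", "mkdir"))]
        assert len(cmds) == len(ctx["pipeline"].closure_stages)

    @pytest.mark.parametrize("seed", [2, 9])
    def test_branching_pipelines_replicate_in_any_valid_order(self, tmp_path, seed):
        pl = gen_pipeline(6, branching=3, seed=seed)
        mount, run, data, _ = record(tmp_path, pl)
        b = export_bundle(run["target_file_key"], mount.store)
        rep = replicate(b, tmp_path / "w", inputs=external_input_map(b, data))
        assert rep.target_match
        mount.store.close()


class TestVerifyEnvironment:
    def test_identical_environment_zero_mismatches(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        assert verify_environment(b) == []

    def test_tampered_tools_reported_exactly(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        used = sorted({p["exe_path"] for p in b["processes"]
                       if p["exe_path"].startswith(str(ctx["bindir"]))})
        k = min(2, len(used))
        for exe in used[:k]:
            with open(exe, "a") as fh:
                fh.write("# different build\n")
        mismatches = verify_environment(b)
        assert {m.exe_path for m in mismatches} == set(used[:k])
        assert all(m.status == VERSION_MISMATCH for m in mismatches)

    def test_missing_tool_reported_not_raised(self, recorded_pipeline):
        import os

        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        victim = next(p["exe_path"] for p in b["processes"]
                      if p["exe_path"].startswith(str(ctx["bindir"])))
        os.remove(victim)
        report = verify_environment(b)
        assert any(m.exe_path == victim and m.status == MISSING_EXECUTABLE
                   for m in report)


class TestReplicate:
    def test_identical_environment_target_matches(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        rep = replicate(b, ctx["tmp"] / "replica",
                        inputs=external_input_map(b, ctx["data"]))
        assert rep.target_match
        assert rep.mismatches == []
        assert rep.produced_checksum == ctx["pipeline"].expected_target_sha256
        assert all(s == "ok" for s in rep.process_status.values())

    def test_output_altering_wrapper_detected_and_mismatched(self, tmp_path):
        pl = gen_pipeline(3, branching=2, seed=21)
        mount, run, data, bindir = record(tmp_path, pl)
        b = export_bundle(run["target_file_key"], mount.store)
        # replace a tool used in the closure by a behavior-altering build
        used = sorted({p["exe_path"] for p in b["processes"]
                       if p["exe_path"].startswith(str(bindir))})
        victim = used[0]
        altered = '#!/bin/sh\nexec sort -r "$@"\n' if victim.endswith("t_sort") \
            else '#!/bin/sh\ncat "$@"; echo EXTRA\n'
        open(victim, "w").write(altered)
        rep = replicate(b, tmp_path / "w", inputs=external_input_map(b, data))
        assert victim in {m.exe_path for m in rep.mismatches}
        assert not rep.target_match
        mount.store.close()

    def test_benign_rebuild_warns_but_output_matches(self, tmp_path):
        pl = gen_pipeline(3, branching=2, seed=22)
        mount, run, data, bindir = record(tmp_path, pl)
        b = export_bundle(run["target_file_key"], mount.store)
        used = sorted({p["exe_path"] for p in b["processes"]
                       if p["exe_path"].startswith(str(bindir))})
        with open(used[0], "a") as fh:
            fh.write("# recompiled with identical behavior\n")
        rep = replicate(b, tmp_path / "w", inputs=external_input_map(b, data))
        assert rep.target_match  # bytes identical despite the version warning
        assert {m.exe_path for m in rep.mismatches} == {used[0]}
        mount.store.close()

    def test_missing_external_input_fails_before_execution(self, recorded_pipeline):
        ctx = recorded_pipeline
        b = export_bundle(ctx["run"]["target_file_key"], ctx["store"])
        with pytest.raises(BundleError, match="external input"):
            replicate(b, ctx["tmp"] / "w2")  # no inputs supplied

    def test_failing_process_halts_with_exec_failed(self, tmp_path):
        pl = gen_pipeline(3, branching=1, seed=23)
        mount, run, data, bindir = record(tmp_path, pl)
        b = export_bundle(run["target_file_key"], mount.store)
        used = sorted({p["exe_path"] for p in b["processes"]
                       if p["exe_path"].startswith(str(bindir))})
        open(used[0], "w").write("#!/bin/sh\nexit 9\n")
        rep = replicate(b, tmp_path / "w", inputs=external_input_map(b, data))
        assert "exec_failed" in rep.process_status.values()
        assert not rep.target_match
        mount.store.close()
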