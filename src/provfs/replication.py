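"""Workflow replication: export, script reconstruction, verification, re-run.

A target file's provenance is exported as a self-contained JSON bundle:
the lineage graph, full process records (command line, working directory,
executable path and checksum), external inputs with content checksums, and
the target's checksum. On another system the bundle alone suffices to:

* reconstruct an executable shell script for the workflow, even when the
  original driver script was never copied;
* verify the software environment by checksumming every recorded executable
  and reporting mismatches or missing tools;
* re-execute the workflow in a clean directory and verify the produced
  target byte-for-byte (checksum equality).

Shell-interpreter processes whose children were captured are treated as
wrappers: their children are re-invoked, the wrapper itself is not, which
prevents double execution. Redirections are not part of a recorded command
line, so the reconstructor infers at most one unnamed input and one unnamed
output per process (a file the process read/wrote whose path does not appear
among its arguments) and emits ``<``/``>`` accordingly.
"""

from __future__ import annotations

import heapq
import json
import os
import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from .lineage import ProvenanceGraph, trace
from .procinfo import checksum_file
from .store import ProvenanceStore

BUNDLE_SCHEMA_VERSION = 1

OK = "ok"
VERSION_MISMATCH = "version_mismatch"
EXEC_FAILED = "exec_failed"
MISSING_EXECUTABLE = "missing_executable"


class BundleError(ValueError):
    pass


@dataclass(frozen=True)
class Mismatch:
    exe_path: str
    expected: str | None
    found: str | None
    status: str  # version_mismatch | missing_executable


@dataclass
class ReplicationReport:
    process_status: dict[str, str] = field(default_factory=dict)
    mismatches: list[Mismatch] = field(default_factory=list)
    target_match: bool = False
    produced_checksum: str | None = None
    target_path: str | None = None
    input_warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.target_match and all(s == OK for s in self.process_status.values())


# --------------------------------------------------------------------------
# Export / import
# --------------------------------------------------------------------------


def export_bundle(target: str, store: ProvenanceStore) -> dict:
    """Export the full provenance of ``target`` (file key) as a plain dict.

    The bundle is self-contained: every process and file referenced by the
    graph is embedded, with no references into the live database.
    """
    g = trace(target, store)
    tfv = store.get_file(target)

    processes = []
    for pk in sorted(g.proc_nodes):
        p = store.get_process(pk)
        processes.append(
            {
                "proc_key": p.proc_key,
                "pid": p.pid,
                "start_time": p.start_time,
                "parent_key": p.parent_key,
                "exe_path": p.exe_path,
                "exe_checksum": p.exe_checksum,
                "checksum_algo": p.checksum_algo,
                "cmdline": list(p.cmdline),
                "cwd": p.cwd,
            }
        )
    files = []
    for fk in sorted(g.file_nodes):
        f = store.get_file(fk)
        files.append(
            {
                "file_key": f.file_key,
                "path": f.path,
                "version_no": f.version_no,
                "created_time": f.created_time,
                "origin": f.origin,
                "content_checksum": f.content_checksum,
            }
        )
    written = {f for (_, f) in g.write_edges}
    external = [f for f in files if f["file_key"] not in written]

    return {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "session": {
            "session_id": store.session_id,
            "source_root": store.source_root,
        },
        "target": {
            "file_key": tfv.file_key,
            "path": tfv.path,
            "version_no": tfv.version_no,
            "content_checksum": tfv.content_checksum,
        },
        "processes": processes,
        "files": files,
        "read_edges": sorted([f, p, t] for (f, p), t in g.read_edges.items()),
        "write_edges": sorted([p, f, t] for (p, f), t in g.write_edges.items()),
        "spawn_edges": sorted(list(e) for e in g.spawn_edges),
        "external_inputs": [
            {"path": f["path"], "file_key": f["file_key"],
             "content_checksum": f["content_checksum"]}
            for f in external
        ],
    }


def dumps_bundle(bundle: dict) -> str:
    """Canonical serialization: identical bundles yield identical bytes."""
    return json.dumps(bundle, indent=2, sort_keys=True) + "\n"


def save_bundle(bundle: dict, path: str | os.PathLike) -> None:
    Path(path).write_text(dumps_bundle(bundle), encoding="utf-8")


def load_bundle(path: str | os.PathLike) -> dict:
    bundle = json.loads(Path(path).read_text(encoding="utf-8"))
    version = bundle.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise BundleError(f"unsupported bundle schema version: {version!r}")
    return bundle


def bundle_graph(bundle: dict) -> ProvenanceGraph:
    """Rebuild the in-memory graph from a bundle (for visualization)."""
    g = ProvenanceGraph(target=bundle["target"]["file_key"])
    g.file_nodes = {f["file_key"] for f in bundle["files"]}
    g.proc_nodes = {p["proc_key"] for p in bundle["processes"]}
    g.read_edges = {(f, p): t for f, p, t in bundle["read_edges"]}
    g.write_edges = {(p, f): t for p, f, t in bundle["write_edges"]}
    g.spawn_edges = {tuple(e) for e in bundle["spawn_edges"]}
    return g


# --------------------------------------------------------------------------
# Script reconstruction
# --------------------------------------------------------------------------


def _leaf_processes(bundle: dict) -> list[dict]:
    """Processes with no captured children (wrappers are not re-invoked)."""
    parents = {p for p, _ in (tuple(e) for e in bundle["spawn_edges"])}
    return [p for p in bundle["processes"] if p["proc_key"] not in parents]


def _ordered_leaves(bundle: dict) -> list[dict]:
    """Dependency order (writer before reader), start time as tie-break."""
    leaves = _leaf_processes(bundle)
    by_key = {p["proc_key"]: p for p in leaves}
    writers: dict[str, set[str]] = {}
    for pk, fk, _t in bundle["write_edges"]:
        writers.setdefault(fk, set()).add(pk)
    deps: dict[str, set[str]] = {p["proc_key"]: set() for p in leaves}
    for fk, pk, rt in bundle["read_edges"]:
        if pk not in deps:
            continue
        for wk in writers.get(fk, ()):  # only writes before the read count
            wt = next(
                (t for (p2, f2, t) in bundle["write_edges"] if p2 == wk and f2 == fk),
                None,
            )
            if wk in by_key and wk != pk and wt is not None and wt < rt:
                deps[pk].add(wk)

    indeg = {k: len(v) for k, v in deps.items()}
    rdeps: dict[str, set[str]] = {k: set() for k in deps}
    for k, vs in deps.items():
        for v in vs:
            rdeps[v].add(k)
    heap = [
        (by_key[k]["start_time"], k) for k, d in indeg.items() if d == 0
    ]
    heapq.heapify(heap)
    order = []
    while heap:
        _, k = heapq.heappop(heap)
        order.append(by_key[k])
        for m in sorted(rdeps[k]):
            indeg[m] -= 1
            if indeg[m] == 0:
                heapq.heappush(heap, (by_key[m]["start_time"], m))
    if len(order) != len(leaves):
        raise BundleError("cyclic dependency among recorded processes")
    return order


def _invocation(bundle: dict, proc: dict) -> tuple[list[str], str | None, str | None]:
    """(argv, inferred stdin path, inferred stdout path) for one process."""
    pk = proc["proc_key"]
    files_by_key = {f["file_key"]: f for f in bundle["files"]}
    reads = [files_by_key[fk]["path"] for fk, p, _ in bundle["read_edges"] if p == pk]
    writes = [files_by_key[fk]["path"] for p, fk, _ in bundle["write_edges"] if p == pk]
    argv = list(proc["cmdline"])
    tokens = set(argv)
    unnamed_in = sorted({p for p in reads if p not in tokens and os.path.basename(p) not in tokens})
    unnamed_out = sorted({p for p in writes if p not in tokens and os.path.basename(p) not in tokens})
    stdin = unnamed_in[0] if len(unnamed_in) == 1 else None
    stdout = unnamed_out[0] if len(unnamed_out) == 1 else None
    if len(unnamed_in) > 1 or len(unnamed_out) > 1:
        raise BundleError(
            f"process {pk} has ambiguous redirections: "
            f"inputs {unnamed_in}, outputs {unnamed_out}"
        )
    return argv, stdin, stdout


def reconstruct_script(bundle: dict) -> str:
    """Reconstruct a POSIX shell script that reproduces the target.

    Leaf processes are invoked with their recorded command lines and working
    directories in dependency order; executing the script in a directory
    containing the external inputs reproduces the target byte-for-byte.
    """
    if not bundle["processes"]:
        raise BundleError(
            "target is of external origin: no recorded process produced it"
        )
    order = _ordered_leaves(bundle)
    lines = [
        "#!/bin/sh",
        "# reconstructed from recorded provenance",
        "set -e",
        "export LC_ALL=C",
    ]
    outdirs = sorted(
        {
            os.path.dirname(f["path"])
            for f in bundle["files"]
            if os.path.dirname(f["path"])
        }
    )
    for d in outdirs:
        lines.append(f"mkdir -p {shlex.quote(d)}")
    for proc in order:
        argv, stdin, stdout = _invocation(bundle, proc)
        cmd = shlex.join(argv)
        if stdin:
            cmd += f" < {shlex.quote(stdin)}"
        if stdout:
            cmd += f" > {shlex.quote(stdout)}"
        cwd = proc.get("cwd") or "."
        if cwd not in (".", ""):
            cmd = f"(cd {shlex.quote(cwd)} && {cmd})"
        lines.append(cmd)
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Environment verification and replication
# --------------------------------------------------------------------------


def verify_environment(bundle: dict) -> list[Mismatch]:
    """Checksum every recorded executable in the current environment.

    Lookup order: recorded absolute path, then the current search path.
    Identical environments yield an empty report; missing executables are
    report entries, never exceptions.
    """
    seen: dict[str, Mismatch | None] = {}
    for proc in bundle["processes"]:
        exe = proc.get("exe_path")
        expected = proc.get("exe_checksum")
        if not exe or exe in seen:
            continue
        candidate = exe if os.path.isfile(exe) else shutil.which(os.path.basename(exe))
        if candidate is None:
            seen[exe] = Mismatch(exe, expected, None, MISSING_EXECUTABLE)
            continue
        try:
            found = checksum_file(candidate)
        except OSError:
            seen[exe] = Mismatch(exe, expected, None, MISSING_EXECUTABLE)
            continue
        if expected is not None and found != expected:
            seen[exe] = Mismatch(exe, expected, found, VERSION_MISMATCH)
        else:
            seen[exe] = None
    return [m for m in seen.values() if m is not None]


def replicate(
    bundle: dict,
    workdir: str | os.PathLike,
    *,
    inputs: dict[str, str] | None = None,
    timeout: float | None = 300.0,
) -> ReplicationReport:
    """Re-execute the recorded workflow in ``workdir`` and verify the result.

    External inputs must be present at their recorded relative paths or
    supplied via ``inputs`` (relative path -> source file to copy in).
    Version mismatches are warnings, not errors: execution proceeds and the
    report records both the mismatches and whether the target matched. A
    nonzero process exit halts replication at that process.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    report = ReplicationReport(target_path=bundle["target"]["path"])
    report.mismatches = verify_environment(bundle)
    mismatched_exes = {m.exe_path for m in report.mismatches}
    missing_exes = {
        m.exe_path for m in report.mismatches if m.status == MISSING_EXECUTABLE
    }

    for ext in bundle["external_inputs"]:
        rel = ext["path"]
        dest = workdir / rel
        if inputs and rel in inputs:
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(inputs[rel], dest)
        if not dest.is_file():
            raise BundleError(f"external input missing: {rel}")
        if ext.get("content_checksum"):
            found = checksum_file(dest)
            if found != ext["content_checksum"]:
                report.input_warnings.append(
                    f"external input {rel} differs from recorded checksum"
                )

    for f in bundle["files"]:
        d = os.path.dirname(f["path"])
        if d:
            (workdir / d).mkdir(parents=True, exist_ok=True)

    order = _ordered_leaves(bundle)
    env = {"PATH": os.environ.get("PATH", "/usr/bin:/bin"), "LC_ALL": "C"}
    for proc in order:
        pk = proc["proc_key"]
        exe = proc.get("exe_path") or ""
        if exe in missing_exes:
            report.process_status[pk] = MISSING_EXECUTABLE
            break
        argv, stdin, stdout = _invocation(bundle, proc)
        cwd = workdir / (proc.get("cwd") or ".")
        stdin_f = open(cwd / stdin, "rb") if stdin else subprocess.DEVNULL
        if stdout:
            (cwd / stdout).parent.mkdir(parents=True, exist_ok=True)
        stdout_f = open(cwd / stdout, "wb") if stdout else subprocess.DEVNULL
        try:
            rc = subprocess.run(
                argv, stdin=stdin_f, stdout=stdout_f,
                stderr=subprocess.DEVNULL, cwd=cwd, env=env, timeout=timeout,
            ).returncode
        except (OSError, subprocess.TimeoutExpired):
            rc = -1
        finally:
            for fh in (stdin_f, stdout_f):
                if fh is not subprocess.DEVNULL:
                    fh.close()
        if rc != 0:
            report.process_status[pk] = EXEC_FAILED
            break
        report.process_status[pk] = VERSION_MISMATCH if exe in mismatched_exes else OK

    produced = workdir / bundle["target"]["path"]
    if produced.is_file():
        report.produced_checksum = checksum_file(produced)
    expected = bundle["target"].get("content_checksum")
    report.target_match = (
        report.produced_checksum is not None and report.produced_checksum == expected
    )
    return report
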