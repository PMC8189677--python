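"""Traced execution of external programs with declared I/O.

Runs each pipeline stage as a real subprocess and records its provenance
through the mount's store: a process record built from the actual invocation
(pid, start time, absolute executable path and checksum, command line,
working directory), read events for declared inputs, and write events plus a
content checksum for declared outputs. This is the event source used where a
kernel mount is unavailable or unnecessary: the recording path, store schema
and lineage semantics are identical to interception.

Execution uses a normalized minimal environment (inherited ``PATH``,
``LC_ALL=C``) so that text utilities behave byte-deterministically; the
replicator applies the same normalization.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import time
from dataclasses import dataclass

from .procinfo import checksum_file
from .store import READ, WRITE, ProcessRecord
from .vfs import Mount


class StageError(RuntimeError):
    pass


@dataclass(frozen=True)
class Stage:
    """A command with declared inputs/outputs, relative to the mount root."""

    argv: tuple[str, ...]
    stdin: str | None = None
    stdout: str | None = None
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    cwd: str = "."


def run_env() -> dict[str, str]:
    return {"PATH": os.environ.get("PATH", "/usr/bin:/bin"), "LC_ALL": "C"}


class TracedRunner:
    """Executes stages under a mount, recording full provenance."""

    def __init__(self, mount: Mount) -> None:
        self.mount = mount
        self.store = mount.store
        self.root = mount.source_root

    def _abs(self, rel: str) -> str:
        return os.path.join(self.root, rel)

    def run_stage(self, stage: Stage, parent_key: str | None = None) -> str:
        """Run one stage to completion; returns its process key."""
        cwd = os.path.normpath(os.path.join(self.root, stage.cwd))
        stdin_f = open(self._abs(stage.stdin), "rb") if stage.stdin else subprocess.DEVNULL
        stdout_f = open(self._abs(stage.stdout), "wb") if stage.stdout else subprocess.DEVNULL
        start_ns = time.time_ns()
        exe = stage.argv[0]
        if not os.path.isabs(exe):
            exe = shutil.which(stage.argv[0], path=run_env()["PATH"]) or stage.argv[0]
        try:
            proc = subprocess.Popen(
                list(stage.argv), stdin=stdin_f, stdout=stdout_f,
                stderr=subprocess.DEVNULL, cwd=cwd, env=run_env(),
            )
            pid = proc.pid
            rc = proc.wait()
        finally:
            for fh in (stdin_f, stdout_f):
                if fh is not subprocess.DEVNULL:
                    fh.close()
        if rc != 0:
            raise StageError(f"{stage.argv} exited with status {rc}")

        try:
            exe_sum = checksum_file(exe)
            algo = "sha256"
        except OSError:
            exe_sum, algo = None, None
        rec = ProcessRecord(
            proc_key=ProcessRecord.key_for(pid, start_ns, self.store.session_id),
            pid=pid,
            start_time=start_ns,
            parent_key=parent_key,
            exe_path=exe,
            exe_checksum=exe_sum,
            checksum_algo=algo,
            cmdline=tuple(stage.argv),
            cwd=stage.cwd,
        )
        proc_key = self.store.record_process(rec)

        # reads recorded before writes: output depends on earlier input
        in_paths = ([stage.stdin] if stage.stdin else []) + list(stage.inputs)
        for rel in in_paths:
            fv = self.store.ensure_version(rel)
            self.store.note_read(fv.file_key)
            size = os.path.getsize(self._abs(rel))
            self.store.record_event(proc_key, fv.file_key, READ, nbytes=size)
        out_paths = ([stage.stdout] if stage.stdout else []) + list(stage.outputs)
        for rel in out_paths:
            fv = self.store.version_for_write(rel, truncate=True)
            size = os.path.getsize(self._abs(rel))
            self.store.record_event(proc_key, fv.file_key, WRITE, nbytes=size)
            self.store.writer_closed(fv.file_key, checksum_file(self._abs(rel)))
        return proc_key

    def run_pipeline(self, pipeline, bin_dir: str | os.PathLike) -> dict:
        """Run a synthetic pipeline under a recorded driver-shell process.

        The driver is recorded as the parent of every stage process (the
        shell-script pattern); it performs no recorded I/O of its own, so
        script reconstruction re-invokes only the stages.
        """
        bin_dir = os.fspath(bin_dir)
        sh = shutil.which("sh") or "/bin/sh"
        try:
            sh_sum = checksum_file(sh)
            algo = "sha256"
        except OSError:
            sh_sum, algo = None, None
        start_ns = time.time_ns()
        driver_key = self.store.record_process(
            ProcessRecord(
                proc_key=ProcessRecord.key_for(os.getpid(), start_ns, self.store.session_id),
                pid=os.getpid(),
                start_time=start_ns,
                exe_path=sh,
                exe_checksum=sh_sum,
                checksum_algo=algo,
                cmdline=("sh", "driver.sh"),
                cwd=".",
            )
        )
        stage_keys = []
        for st in pipeline.stages:
            argv = (os.path.join(bin_dir, st.tool), *st.args)
            stage_keys.append(
                self.run_stage(
                    Stage(argv=argv, stdin=st.stdin, stdout=st.stdout,
                          inputs=tuple(p for p in st.inputs if p != st.stdin)),
                    parent_key=driver_key,
                )
            )
        target_fv = self.store.current_version(pipeline.target)
        return {
            "driver_key": driver_key,
            "stage_keys": stage_keys,
            "target_file_key": target_fv.file_key if target_fv else None,
        }
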