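"""Caller-process inspection via the /proc filesystem.

When an operation reaches the mount, the calling process is identified by
pid and its invocation context is captured: parent pid, command line,
working directory, executable path, and a cryptographic checksum of the
executable. Fields that cannot be read (the process exited, or the
executable is unreadable) are recorded as unavailable rather than failing
the I/O operation.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

CHECKSUM_ALGO = "sha256"
_HASH_CHUNK = 1 << 20


@dataclass(frozen=True)
class CallerInfo:
    """Raw snapshot of a live process; feeds a stored ProcessRecord."""

    pid: int
    ppid: int | None
    start_time: int | None  # kernel start ticks; stable across one lifetime
    exe_path: str | None
    exe_checksum: str | None
    checksum_algo: str | None
    cmdline: tuple[str, ...] | None
    cwd: str | None
    is_self: bool = False

    @property
    def available(self) -> bool:
        return self.start_time is not None


def checksum_file(path: str | os.PathLike, algo: str = CHECKSUM_ALGO) -> str:
    h = hashlib.new(algo)
    with open(path, "rb") as fh:
        while chunk := fh.read(_HASH_CHUNK):
            h.update(chunk)
    return h.hexdigest()


def _read_stat(pid: int) -> tuple[int, int] | None:
    """Return (ppid, starttime ticks) from /proc/<pid>/stat, or None."""
    try:
        with open(f"/proc/{pid}/stat", "rb") as fh:
            data = fh.read()
    except OSError:
        return None
    # comm may contain spaces/parens; fields resume after the last ')'
    rpar = data.rfind(b")")
    fields = data[rpar + 2 :].split()
    # fields[0] is state (field 3); ppid is field 4; starttime is field 22
    return int(fields[1]), int(fields[19])


def capture_caller(pid: int, daemon_pid: int | None = None) -> CallerInfo:
    """Inspect a (presumably live) process.

    Repeated calls for the same live process return identical records. A
    process that exited before inspection yields a record with fields marked
    unavailable (None), never an exception. ``daemon_pid`` marks the mount
    daemon itself; its operations are flagged ``is_self`` and excluded from
    provenance by the caller.
    """
    is_self = daemon_pid is not None and pid == daemon_pid
    stat = _read_stat(pid)
    if stat is None:
        return CallerInfo(
            pid=pid, ppid=None, start_time=None, exe_path=None,
            exe_checksum=None, checksum_algo=None, cmdline=None, cwd=None,
            is_self=is_self,
        )
    ppid, start_time = stat

    try:
        with open(f"/proc/{pid}/cmdline", "rb") as fh:
            raw = fh.read()
        cmdline: tuple[str, ...] | None = tuple(
            a.decode("utf-8", "surrogateescape") for a in raw.split(b"\x00") if a
        )
    except OSError:
        cmdline = None

    try:
        cwd: str | None = os.readlink(f"/proc/{pid}/cwd")
    except OSError:
        cwd = None

    try:
        exe_path: str | None = os.readlink(f"/proc/{pid}/exe")
    except OSError:
        exe_path = None

    exe_checksum = None
    algo = None
    if exe_path is not None:
        try:
            exe_checksum = checksum_file(exe_path)
            algo = CHECKSUM_ALGO
        except OSError:
            exe_checksum = None

    return CallerInfo(
        pid=pid, ppid=ppid, start_time=start_time, exe_path=exe_path,
        exe_checksum=exe_checksum, checksum_algo=algo, cmdline=cmdline,
        cwd=cwd, is_self=is_self,
    )
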