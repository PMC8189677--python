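"""Interception layer: a passthrough view of a directory tree that records
provenance and routes virtual-file access to the VDF engine.

The interception logic is split from any kernel-mount backend behind this
in-process operation interface: :class:`Mount` exposes POSIX-style
open/read/write/close/rename/unlink/truncate/stat/readdir calls, performs
them faithfully against the underlying ``source_root``, records every
data operation in the provenance store, and serves virtual dynamic files
from the VDF engine. A FUSE backend, where a binding is installed, is a
thin adapter over exactly this interface; the full provenance/VDF core is
exercised without any privileged mount.

Operations issued by the mount daemon itself are excluded from recording
(no self-referential provenance). Paths are recorded mount-relative, with
the source root stored once per session, so exported bundles stay
relocatable.
"""

from __future__ import annotations

import os
import posixpath
import time
from dataclasses import dataclass, field

from .config import Config
from .procinfo import capture_caller, checksum_file
from .store import (
    CLOSE,
    CREATE,
    OPEN,
    READ,
    RENAME,
    TRUNCATE,
    UNLINK,
    WRITE,
    ORIGIN_VIRTUAL,
    ProcessRecord,
    ProvenanceStore,
)
from .vdf import VDFEngine

REAL = "real"
VIRTUAL = "virtual"


class AccessError(PermissionError):
    """Path escapes the mounted tree or operation is not permitted."""


@dataclass(frozen=True)
class MountContext:
    source_root: str
    mount_point: str | None
    config: Config
    session_id: str


@dataclass(frozen=True)
class SyscallEvent:
    op_kind: str  # open/read/write/close/create/unlink/rename/truncate/stat/readdir
    path: str  # mount-relative
    caller_pid: int
    timestamp: float = field(default_factory=time.monotonic)
    byte_range: tuple[int, int] | None = None  # (offset, length) for read/write


def normalize_path(path: str) -> str:
    """Mount-relative normalized path; raises AccessError on escape."""
    rel = posixpath.normpath(path.lstrip("/"))
    if rel == ".":
        rel = ""
    if rel == ".." or rel.startswith("../"):
        raise AccessError(f"path escapes the mount: {path!r}")
    return rel


def route_operation(ev: SyscallEvent, ctx: MountContext, engine: VDFEngine | None = None) -> str:
    """Decide whether an operation targets a real file or a virtual one.

    Virtual iff the path matches a registered VDF name for an existing
    source and no real file shadows it; everything else (including VDF-like
    names whose source is absent) falls through to the real file system.
    """
    rel = normalize_path(ev.path)
    if engine is None:
        engine = VDFEngine(ctx.config, ctx.source_root)
    return VIRTUAL if engine.is_virtual(rel) else REAL


class _Handle:
    __slots__ = (
        "path", "file_key", "proc_key", "fobj", "mat", "offset", "wrote", "writable",
    )

    def __init__(self, path, file_key, proc_key, fobj=None, mat=None, writable=False):
        self.path = path
        self.file_key = file_key
        self.proc_key = proc_key
        self.fobj = fobj
        self.mat = mat
        self.offset = 0
        self.wrote = False
        self.writable = writable


class Mount:
    """In-process passthrough mount over ``source_root``.

    All operations behave byte- and metadata-identically to acting on the
    source tree directly; in addition each data operation is recorded in the
    provenance store and VDF paths are served by the block-cache engine.
    """

    def __init__(
        self,
        source_root: str | os.PathLike,
        config: Config | None = None,
        *,
        db_path: str | None = None,
        store: ProvenanceStore | None = None,
        daemon_pid: int | None = None,
        disk_tier: str | os.PathLike | None = None,
        mount_point: str | None = None,
    ) -> None:
        self.source_root = os.path.abspath(os.fspath(source_root))
        if not os.path.isdir(self.source_root):
            raise NotADirectoryError(self.source_root)
        if mount_point is not None and os.path.abspath(mount_point) == self.source_root:
            raise ValueError("mount_point must differ from source_root")
        self.config = config or Config()
        self.store = store or ProvenanceStore(
            db_path,
            source_root=self.source_root,
            config_snapshot=self.config.to_snapshot(),
            flush_threshold=self.config.store.flush_threshold,
        )
        self.daemon_pid = daemon_pid
        self.engine = VDFEngine(
            self.config, self.source_root, store=self.store, disk_tier=disk_tier
        )
        self.ctx = MountContext(
            source_root=self.source_root,
            mount_point=mount_point,
            config=self.config,
            session_id=self.store.session_id,
        )
        self._handles: dict[int, _Handle] = {}
        self._next_handle = 1
        self._caller_cache: dict[int, tuple[int | None, str | None]] = {}
        self._vdf_recorded: set[int] = set()

    # ----------------------------------------------------------- internals
    def _real(self, rel: str) -> str:
        return os.path.join(self.source_root, rel) if rel else self.source_root

    def _caller_key(self, pid: int | None) -> str | None:
        """Provenance process key for a caller pid; None when excluded (self)."""
        if pid is None:
            pid = os.getpid()
        cached = self._caller_cache.get(pid)
        if cached is not None:
            return cached[1]
        info = capture_caller(pid, self.daemon_pid)
        if info.is_self:
            self._caller_cache[pid] = (info.start_time, None)
            return None
        key = self.store.record_caller(info)
        self._caller_cache[pid] = (info.start_time, key)
        return key

    def record_caller_record(self, rec: ProcessRecord) -> str:
        """Register an externally captured process record (traced runners)."""
        return self.store.record_process(rec)

    def _record(self, proc_key: str | None, file_key: str, kind: str, nbytes: int = 0):
        if proc_key is not None:
            self.store.record_event(proc_key, file_key, kind, nbytes=nbytes)

    # ----------------------------------------------------------- directory
    def readdir(self, path: str = "", pid: int | None = None) -> list[str]:
        """Underlying entries plus one virtual entry per matching source file.

        A real file shadows a virtual entry of the same name: each name
        appears exactly once.
        """
        rel = normalize_path(path)
        real = sorted(os.listdir(self._real(rel)))  # errors propagate
        return sorted(real + self.engine.virtual_entries(rel, real))

    def stat(self, path: str, pid: int | None = None) -> os.stat_result | dict:
        rel = normalize_path(path)
        real = self._real(rel)
        if os.path.exists(real):
            return os.stat(real)
        if self.engine.is_virtual(rel):
            return {
                "st_size": self.engine.size_hint(rel),
                "st_mode": 0o100444,  # read-only regular file
                "virtual": True,
            }
        return os.stat(real)  # raises FileNotFoundError with the real errno

    # ----------------------------------------------------------- open/close
    def open(self, path: str, mode: str = "r", pid: int | None = None) -> int:
        """Open a real or virtual file; returns an opaque handle.

        Modes: ``r`` (read), ``w`` (write/truncate), ``a`` (append),
        ``r+`` (read/write without truncation). Virtual files are read-only.
        """
        rel = normalize_path(path)
        proc_key = self._caller_key(pid)
        ev = SyscallEvent(op_kind=OPEN, path=rel, caller_pid=pid or os.getpid())
        decision = route_operation(ev, self.ctx, self.engine)

        # write-intent opens always go to the real file system: creating a
        # real file shadows the virtual entry of the same name
        if decision == VIRTUAL and mode == "r":
            mat = self.engine.materialize(rel)
            file_key = self._ensure_vdf_provenance(rel, mat)
            self._record(proc_key, file_key, OPEN)
            h = self._alloc(_Handle(rel, file_key, proc_key, mat=mat))
            return h

        real = self._real(rel)
        existed = os.path.exists(real)
        if mode.startswith("r") and "+" not in mode:
            fobj = open(real, "rb")
            fv = self.store.ensure_version(rel)
            self._record(proc_key, fv.file_key, OPEN)
            return self._alloc(_Handle(rel, fv.file_key, proc_key, fobj=fobj))

        pymode = {"w": "wb", "a": "ab", "r+": "r+b", "w+": "w+b", "a+": "a+b"}.get(mode)
        if pymode is None:
            raise ValueError(f"unsupported mode {mode!r}")
        fobj = open(real, pymode)
        truncating = mode.startswith("w")
        fv = self.store.version_for_write(rel, truncate=truncating or not existed)
        kind = CREATE if not existed else (TRUNCATE if truncating else OPEN)
        self._record(proc_key, fv.file_key, kind)
        return self._alloc(_Handle(rel, fv.file_key, proc_key, fobj=fobj, writable=True))

    def _alloc(self, h: _Handle) -> int:
        hid = self._next_handle
        self._next_handle += 1
        self._handles[hid] = h
        return hid

    def _get(self, handle: int) -> _Handle:
        try:
            return self._handles[handle]
        except KeyError:
            raise OSError(f"bad file handle {handle}") from None

    def close(self, handle: int) -> None:
        h = self._handles.pop(handle, None)
        if h is None:
            raise OSError(f"bad file handle {handle}")
        if h.fobj is not None:
            h.fobj.close()
        if h.wrote:
            digest = checksum_file(self._real(h.path))
            self.store.writer_closed(h.file_key, digest)
        self._record(h.proc_key, h.file_key, CLOSE)

    # ----------------------------------------------------------- data ops
    def read(self, handle: int, size: int = -1, offset: int | None = None) -> bytes:
        h = self._get(handle)
        if h.mat is not None:
            if offset is None:
                offset = h.offset
            data = (
                h.mat.read(offset, size)
                if size >= 0
                else h.mat.read_all()[offset:]
            )
            h.offset = offset + len(data)
        else:
            if offset is not None:
                h.fobj.seek(offset)
            data = h.fobj.read(size if size >= 0 else None) or b""
        self.store.note_read(h.file_key)
        self._record(h.proc_key, h.file_key, READ, nbytes=len(data))
        return data

    def write(self, handle: int, data: bytes, offset: int | None = None) -> int:
        h = self._get(handle)
        if h.mat is not None:
            raise AccessError("virtual files are read-only")
        if not h.writable:
            raise AccessError(f"handle for {h.path!r} is not writable")
        if offset is not None:
            h.fobj.seek(offset)
        n = h.fobj.write(data)
        h.wrote = True
        self._record(h.proc_key, h.file_key, WRITE, nbytes=n)
        return n

    # ----------------------------------------------------------- tree ops
    def unlink(self, path: str, pid: int | None = None) -> None:
        rel = normalize_path(path)
        proc_key = self._caller_key(pid)
        fv = self.store.current_version(rel)
        os.remove(self._real(rel))  # underlying errors propagate
        if fv is not None:
            self._record(proc_key, fv.file_key, UNLINK)
        self.store.unlink_path(rel)

    def rename(self, old: str, new: str, pid: int | None = None) -> None:
        old_rel, new_rel = normalize_path(old), normalize_path(new)
        proc_key = self._caller_key(pid)
        os.rename(self._real(old_rel), self._real(new_rel))
        fv = self.store.current_version(old_rel)
        self.store.rename_path(old_rel, new_rel)
        if fv is not None:
            self._record(proc_key, fv.file_key, RENAME)

    def truncate(self, path: str, length: int = 0, pid: int | None = None) -> None:
        rel = normalize_path(path)
        proc_key = self._caller_key(pid)
        os.truncate(self._real(rel), length)
        fv = self.store.version_for_write(rel, truncate=True)
        self._record(proc_key, fv.file_key, TRUNCATE)
        self.store.writer_closed(fv.file_key, checksum_file(self._real(rel)))

    def mkdir(self, path: str, pid: int | None = None) -> None:
        os.makedirs(self._real(normalize_path(path)), exist_ok=True)

    # ----------------------------------------------------------- convenience
    def read_file(self, path: str, pid: int | None = None) -> bytes:
        h = self.open(path, "r", pid=pid)
        try:
            return self.read(h)
        finally:
            self.close(h)

    def write_file(self, path: str, data: bytes, pid: int | None = None) -> None:
        h = self.open(path, "w", pid=pid)
        try:
            self.write(h, data)
        finally:
            self.close(h)

    def copy_out(self, path: str, destination: str, pid: int | None = None) -> None:
        """Copy a (possibly virtual) file to a destination outside the mount."""
        rel = normalize_path(path)
        if self.engine.is_virtual(rel):
            mat = self.engine.materialize(rel)
            self._ensure_vdf_provenance(rel, mat)
            proc_key = self._caller_key(pid)
            self.engine.copy_out(rel, destination)
            fv = self.store.current_version(rel)
            if fv is not None:
                self.store.note_read(fv.file_key)
                self._record(proc_key, fv.file_key, READ, nbytes=mat.bytes_produced)
            return
        with open(self._real(rel), "rb") as src, open(destination, "wb") as dst:
            dst.write(src.read())

    # ----------------------------------------------------------- VDF plumbing
    def _ensure_vdf_provenance(self, rel: str, mat) -> str:
        """Record the generating task as provenance: a process that reads the
        source version and writes the virtual file version."""
        if id(mat) in self._vdf_recorded:
            fv = self.store.current_version(rel)
            return fv.file_key if fv else rel
        self._vdf_recorded.add(id(mat))
        src_rel = os.path.relpath(mat.source_abs, self.source_root)
        src_fv = self.store.ensure_version(src_rel)
        vfv = self.store.register_file_version(rel, origin=ORIGIN_VIRTUAL)
        cmd = (
            mat.spec.command_for(mat.source_abs)
            if mat.spec.output_channel == "stdout"
            else mat.spec.command_for(mat.source_abs, "<cache>")
        )
        try:
            sh_sum = checksum_file("/bin/sh")
            algo = "sha256"
        except OSError:
            sh_sum, algo = None, None
        start = self.store.clock.now()
        proc_key = self.store.record_process(
            ProcessRecord(
                proc_key=f"vdf.{mat.spec.name}.{vfv.file_key}",
                pid=-1,
                start_time=start,
                exe_path="/bin/sh",
                exe_checksum=sh_sum,
                checksum_algo=algo,
                cmdline=("/bin/sh", "-c", cmd),
                cwd=".",
            )
        )
        self.store.note_read(src_fv.file_key)
        self.store.record_event(proc_key, src_fv.file_key, READ)
        self.store.record_event(proc_key, vfv.file_key, WRITE)
        return vfv.file_key

    # ----------------------------------------------------------- lifecycle
    def close_session(self) -> None:
        for hid in list(self._handles):
            self.close(hid)
        self.store.close()

    def __enter__(self) -> "Mount":
        return self

    def __exit__(self, *exc) -> None:
        self.close_session()
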