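"""Virtual dynamic files (VDFs) served through a two-tier block cache.

A VDF is a file visible in directory listings that does not reside on disk:
its content is the output of a configured shell command run over a source
file. The first read of a missing block launches the command exactly once
per (rule, source version); output is streamed into fixed-size blocks in a
memory tier, spilling least-recently-used ready blocks to a disk tier when
the memory limit is exceeded. Reads of blocks not yet produced block until
the data arrives (or the task ends), so multiple consumers can process
output concurrently while the producing command is still running — the
benefits of a pipe with the shareability of a disk file.

Cache semantics:

* ``ready`` blocks never change content; ``final_length``, once set, never
  changes;
* a disk-tier hit is promoted back to the memory tier before returning;
* eviction moves least-recently-accessed ready blocks (production order as
  tie-break, via insertion-ordered LRU) to disk until occupancy fits;
* the cache key includes the source file version, so modifying the source
  triggers a fresh task on next access.
"""

from __future__ import annotations

import hashlib
import os
import subprocess
import threading
from collections import OrderedDict
from pathlib import Path

from .config import Config, VDFSpec

_INGEST_CHUNK = 64 * 1024
_MAX_CHAIN_DEPTH = 8

RUNNING = "running"
DONE = "done"
FAILED = "failed"


class VDFError(Exception):
    pass


class VDFTaskError(VDFError):
    """The generating command failed; surfaced to all blocked readers."""


class VDFTimeoutError(VDFError):
    pass


class BlockCache:
    """Block-addressed two-tier store. Not thread-safe by itself; the owning
    materialization serializes access under its condition lock."""

    def __init__(self, block_size: int, memory_limit: int, disk_dir: Path) -> None:
        self.block_size = block_size
        self.memory_limit = memory_limit
        self.disk_dir = Path(disk_dir)
        self._mem: OrderedDict[int, bytes] = OrderedDict()  # LRU: first = oldest
        self._on_disk: set[int] = set()
        self.final_length: int | None = None
        self.spill_count = 0

    def memory_bytes(self) -> int:
        return sum(len(b) for b in self._mem.values())

    def has_block(self, idx: int) -> bool:
        return idx in self._mem or idx in self._on_disk

    def put(self, idx: int, data: bytes) -> None:
        self._mem[idx] = data
        self._mem.move_to_end(idx)
        self.evict()

    def get(self, idx: int) -> bytes | None:
        if idx in self._mem:
            self._mem.move_to_end(idx)
            return self._mem[idx]
        if idx in self._on_disk:
            data = (self.disk_dir / f"{idx}.blk").read_bytes()
            # promoted to the memory tier, then returned
            self._on_disk.discard(idx)
            self.put(idx, data)
            return data
        return None

    def evict(self) -> list[int]:
        """Spill oldest ready blocks to disk until occupancy fits the limit."""
        spilled = []
        while self._mem and self.memory_bytes() > self.memory_limit:
            idx, data = self._mem.popitem(last=False)
            path = self.disk_dir / f"{idx}.blk"
            try:
                self.disk_dir.mkdir(parents=True, exist_ok=True)
                path.write_bytes(data)
            except OSError:
                self._mem[idx] = data  # retain in memory on disk-tier failure
                self._mem.move_to_end(idx, last=False)
                raise
            self._on_disk.add(idx)
            spilled.append(idx)
            self.spill_count += 1
        return spilled


class Materialization:
    """One running/finished VDF task plus its block cache."""

    def __init__(
        self,
        spec: VDFSpec,
        source_abs: str,
        cache: BlockCache,
        *,
        cwd: str,
        read_timeout: float | None = 120.0,
    ) -> None:
        self.spec = spec
        self.source_abs = source_abs
        self.cache = cache
        self.cwd = cwd
        self.read_timeout = read_timeout
        self.status: str | None = None  # None until started
        self.error: str | None = None
        self.bytes_produced = 0
        self.content_sha256: str | None = None
        self._hash = hashlib.sha256()
        self._buf = b""
        self._cond = threading.Condition()
        self._thread: threading.Thread | None = None
        self.launch_count = 0
        self.proc_pid: int | None = None
        self.command: str | None = None

    # ----------------------------------------------------------- lifecycle
    def ensure_started(self) -> None:
        with self._cond:
            if self.status is not None:
                return
            self.status = RUNNING
            self.launch_count += 1
        self._thread = threading.Thread(target=self._run, daemon=True)
        self._thread.start()

    def _run(self) -> None:
        try:
            if self.spec.output_channel == "stdout":
                self._run_stdout()
            else:
                self._run_file()
        except Exception as exc:  # surfaced to readers, never swallowed silently
            with self._cond:
                self.status = FAILED
                self.error = str(exc)
                self._cond.notify_all()

    def _run_stdout(self) -> None:
        cmd = self.spec.command_for(self.source_abs)
        self.command = cmd
        proc = subprocess.Popen(
            ["/bin/sh", "-c", cmd], stdout=subprocess.PIPE,
            stderr=subprocess.DEVNULL, cwd=self.cwd,
        )
        self.proc_pid = proc.pid
        assert proc.stdout is not None
        while chunk := proc.stdout.read(_INGEST_CHUNK):
            self.ingest(chunk)
        rc = proc.wait()
        self._finish(rc)

    def _run_file(self) -> None:
        out_path = self.cache.disk_dir / "task_output.tmp"
        self.cache.disk_dir.mkdir(parents=True, exist_ok=True)
        cmd = self.spec.command_for(self.source_abs, str(out_path))
        self.command = cmd
        proc = subprocess.run(
            ["/bin/sh", "-c", cmd], stdout=subprocess.DEVNULL,
            stderr=subprocess.DEVNULL, cwd=self.cwd,
        )
        if proc.returncode == 0 and out_path.exists():
            with open(out_path, "rb") as fh:
                while chunk := fh.read(_INGEST_CHUNK):
                    self.ingest(chunk)
            out_path.unlink(missing_ok=True)
        self._finish(proc.returncode)

    def ingest(self, chunk: bytes) -> None:
        """Append producer output; completed blocks become ready and any
        readers waiting on them are released."""
        bs = self.cache.block_size
        with self._cond:
            self._buf += chunk
            self._hash.update(chunk)
            self.bytes_produced += len(chunk)
            while len(self._buf) >= bs:
                block, self._buf = self._buf[:bs], self._buf[bs:]
                idx = (self.bytes_produced - len(self._buf)) // bs - 1
                self.cache.put(idx, block)
            self._cond.notify_all()

    def _finish(self, returncode: int) -> None:
        with self._cond:
            if returncode != 0:
                self.status = FAILED
                self.error = f"command exited with status {returncode}"
            else:
                if self._buf:
                    idx = self.bytes_produced // self.cache.block_size
                    self.cache.put(idx, self._buf)
                    self._buf = b""
                self.cache.final_length = self.bytes_produced
                self.content_sha256 = self._hash.hexdigest()
                self.status = DONE
            self._cond.notify_all()

    # ----------------------------------------------------------- reading
    def read_block(self, idx: int) -> bytes:
        """Return block ``idx``, blocking until it is ready, EOF, or failure."""
        if idx < 0:
            raise ValueError("block index must be >= 0")
        self.ensure_started()
        with self._cond:
            while True:
                data = self.cache.get(idx)
                if data is not None:
                    return data
                if self.status == FAILED:
                    raise VDFTaskError(self.error or "VDF task failed")
                if self.status == DONE:
                    fl = self.cache.final_length or 0
                    if idx * self.cache.block_size >= fl:
                        return b""  # end of data
                    raise VDFError(f"block {idx} lost below final length {fl}")
                if not self._cond.wait(timeout=self.read_timeout):
                    raise VDFTimeoutError(
                        f"timed out waiting for block {idx} of {self.spec.name}"
                    )

    def read(self, offset: int, size: int) -> bytes:
        """Byte-range read assembled from blocks (blocking as needed)."""
        if size <= 0 or offset < 0:
            return b""
        bs = self.cache.block_size
        out = bytearray()
        pos = offset
        end = offset + size
        while pos < end:
            block = self.read_block(pos // bs)
            if not block:
                break
            lo = pos - (pos // bs) * bs
            take = block[lo : lo + (end - pos)]
            if not take:
                break
            out.extend(take)
            if lo + len(take) >= len(block) and len(block) < bs:
                break  # short (final) block
            pos += len(take)
        return bytes(out)

    def read_all(self) -> bytes:
        out = bytearray()
        idx = 0
        while True:
            block = self.read_block(idx)
            if not block:
                break
            out.extend(block)
            if len(block) < self.cache.block_size:
                break
            idx += 1
        return bytes(out)


class VDFEngine:
    """Resolves virtual paths against the rule set and serves their content."""

    def __init__(
        self,
        config: Config,
        source_root: str | os.PathLike,
        *,
        store=None,
        disk_tier: str | os.PathLike | None = None,
        read_timeout: float | None = 120.0,
    ) -> None:
        self.config = config
        self.source_root = Path(source_root)
        self.store = store
        base = Path(disk_tier or config.cache.disk_tier or (self.source_root / ".provfs-cache"))
        self.disk_tier = base
        self.read_timeout = read_timeout
        self._mats: dict[tuple, Materialization] = {}
        self._lock = threading.Lock()
        self._mat_serial = 0

    # ------------------------------------------------------------ resolution
    def resolve_virtual(self, relpath: str, _depth: int = 0) -> tuple[VDFSpec, str] | None:
        """Rule and source path that produce ``relpath``, or None.

        A chained rule resolves against a source that is itself virtual.
        """
        if _depth > _MAX_CHAIN_DEPTH:
            return None
        dirname, name = os.path.split(relpath)
        for spec in self.config.vdf_rules:
            if not name.endswith(spec.extension) or len(name) <= len(spec.extension):
                continue
            src_name = name[: -len(spec.extension)]
            if not spec.matches_source(src_name):
                continue
            src_rel = os.path.join(dirname, src_name) if dirname else src_name
            if (self.source_root / src_rel).is_file():
                return spec, src_rel
            if self.resolve_virtual(src_rel, _depth + 1) is not None:
                return spec, src_rel
        return None

    def is_virtual(self, relpath: str) -> bool:
        """Virtual iff a rule reconstructs the name and no real file shadows it."""
        if (self.source_root / relpath).exists():
            return False
        return self.resolve_virtual(relpath) is not None

    def virtual_entries(self, dir_rel: str, real_names: list[str]) -> list[str]:
        """Extra listing entries for a directory's real files (real names shadow)."""
        extra = []
        present = set(real_names)
        for name in real_names:
            if not (self.source_root / dir_rel / name).is_file():
                continue
            for spec in self.config.vdf_rules:
                if spec.matches_source(name):
                    vname = spec.virtual_name(name)
                    if vname not in present:
                        extra.append(vname)
                        present.add(vname)
        return sorted(extra)

    # ------------------------------------------------------------ materialize
    def _source_version_token(self, src_rel: str) -> tuple:
        # stat signature catches modifications made around the store as well
        p = self.source_root / src_rel
        try:
            st = p.stat()
            sig: tuple = (st.st_mtime_ns, st.st_size, st.st_ino)
        except OSError:
            sig = ("missing",)
        if self.store is not None:
            fv = self.store.current_version(src_rel)
            if fv is not None:
                return ("v", fv.file_key, fv.version_no, *sig)
        return ("s", *sig)

    def materialize(self, relpath: str) -> Materialization:
        resolved = self.resolve_virtual(relpath)
        if resolved is None:
            raise VDFError(f"{relpath!r} is not a virtual file under the rule set")
        spec, src_rel = resolved
        src_abs = self.source_root / src_rel
        if src_abs.is_file() and self.store is not None:
            # pin the source's provenance version before keying the cache
            self.store.ensure_version(src_rel)
        if not src_abs.is_file():
            # chained rule: materialize the virtual source to a scratch file
            inner = self.materialize(src_rel)
            staged = self.disk_tier / "chained" / src_rel
            staged.parent.mkdir(parents=True, exist_ok=True)
            staged.write_bytes(inner.read_all())
            src_abs = staged
        token = self._source_version_token(src_rel)
        key = (spec.name, src_rel, token)
        with self._lock:
            mat = self._mats.get(key)
            if mat is None:
                self._mat_serial += 1
                cache = BlockCache(
                    self.config.cache.block_size,
                    self.config.cache.memory_limit,
                    self.disk_tier / f"mat{self._mat_serial}",
                )
                mat = Materialization(
                    spec, str(src_abs), cache,
                    cwd=str(self.source_root), read_timeout=self.read_timeout,
                )
                self._mats[key] = mat
        return mat

    def task_launches(self) -> int:
        """Total generating-command launches across all materializations."""
        with self._lock:
            return sum(m.launch_count for m in self._mats.values())

    # ------------------------------------------------------------ access
    def read(self, relpath: str, offset: int = 0, size: int | None = None) -> bytes:
        mat = self.materialize(relpath)
        if size is None:
            return mat.read_all() if offset == 0 else mat.read_all()[offset:]
        return mat.read(offset, size)

    def size_hint(self, relpath: str) -> int:
        """Reported size of a VDF: bytes produced so far (0 before first read).

        Copy tools that pre-allocate by size must fall back to stream copying;
        end-of-data is signalled by short reads.
        """
        resolved = self.resolve_virtual(relpath)
        if resolved is None:
            raise VDFError(f"{relpath!r} is not a virtual file")
        spec, src_rel = resolved
        token = self._source_version_token(src_rel)
        with self._lock:
            mat = self._mats.get((spec.name, src_rel, token))
        return mat.bytes_produced if mat is not None else 0

    def copy_out(self, relpath: str, destination: str | os.PathLike) -> None:
        """Materialize fully and write the bytes outside the mount."""
        mat = self.materialize(relpath)
        with open(destination, "wb") as fh:
            idx = 0
            while True:
                block = mat.read_block(idx)
                if not block:
                    break
                fh.write(block)
                if len(block) < mat.cache.block_size:
                    break
                idx += 1
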