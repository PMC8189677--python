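"""Embedded SQL provenance store.

Persists processes, file versions and I/O events in SQLite, with in-memory
coalescing of high-throughput reads/writes, and answers the two lineage
queries that drive provenance reconstruction:

* :meth:`ProvenanceStore.query_writes` — all past write operations made to a
  file version (optionally before a time);
* :meth:`ProvenanceStore.query_reads` — all read operations made by a process
  (optionally before a time).

Coalescing
----------
Consecutive primitive reads (resp. writes) by one process on one file
version merge into a single event with an incremented count, accumulated
byte total, and extended time span. A run is broken by:

* any different operation kind by the same process on that file;
* for read runs, any write/create/truncate of the file by *any* process;
* for write runs, any read or write of the file by another process, and any
  read the writing process itself performs (of any file) — a later write
  primitive may depend on that read, so the write run must not span it.

The two file-level break rules guarantee that a coalesced run never spans
an event that could alter the temporal lineage closure, so tracing over
coalesced events is exactly equivalent to tracing over the raw stream.

Timestamps come from a single monotonic clock owned by the store (strictly
increasing integers, nanosecond scale), making the temporal constraint
well-defined across threads. Replayed streams may supply explicit
timestamps.
"""

from __future__ import annotations

import json
import sqlite3
import threading
import time
from dataclasses import dataclass, field

from .procinfo import CallerInfo

SCHEMA_VERSION = 1

READ = "read"
WRITE = "write"
OPEN = "open"
CLOSE = "close"
CREATE = "create"
RENAME = "rename"
UNLINK = "unlink"
TRUNCATE = "truncate"

#: Kinds that make a process a writer of a file version.
WRITE_KINDS = frozenset({WRITE, CREATE, TRUNCATE})

ORIGIN_INTERNAL = "internal"
ORIGIN_EXTERNAL = "external"
ORIGIN_VIRTUAL = "virtual"


class NotFoundError(KeyError):
    """Unknown process or file key."""


@dataclass(frozen=True)
class ProcessRecord:
    """One observed process: identity, lineage, executable fingerprint."""

    proc_key: str
    pid: int
    start_time: int
    parent_key: str | None = None
    exe_path: str | None = None
    exe_checksum: str | None = None
    checksum_algo: str | None = None
    cmdline: tuple[str, ...] = ()
    cwd: str | None = None

    @staticmethod
    def key_for(pid: int, start_time: int, session_id: str) -> str:
        return f"p{pid}.{start_time}.{session_id}"


@dataclass
class FileVersion:
    """One version of one path; the node unit of provenance."""

    file_key: str
    path: str
    version_no: int
    created_time: int
    origin: str = ORIGIN_INTERNAL
    content_checksum: str | None = None


@dataclass
class IOEvent:
    """One (possibly coalesced) operation linking a process to a file version."""

    proc_key: str
    file_key: str
    op_kind: str
    t_first: int
    t_last: int
    count: int = 1
    bytes: int = 0
    event_key: int | None = None  # sqlite rowid once persisted
    _dirty: bool = field(default=False, repr=False)


class _Clock:
    """Strictly increasing integer timestamps (ns scale)."""

    def __init__(self) -> None:
        self._last = 0
        self._lock = threading.Lock()

    def now(self) -> int:
        with self._lock:
            t = time.monotonic_ns()
            if t <= self._last:
                t = self._last + 1
            self._last = t
            return t

    def observe(self, t: int) -> int:
        """Fold an externally supplied timestamp into the clock."""
        with self._lock:
            if t > self._last:
                self._last = t
            return t


@dataclass
class _VersionState:
    had_reader: bool = False
    completed_writer: bool = False
    open_writers: int = 0


_SCHEMA = """
CREATE TABLE IF NOT EXISTS session (
    session_id TEXT PRIMARY KEY,
    source_root TEXT,
    created REAL,
    config_json TEXT,
    schema_version INTEGER
);
CREATE TABLE IF NOT EXISTS process (
    proc_key TEXT PRIMARY KEY,
    pid INTEGER,
    start_time INTEGER,
    parent_key TEXT,
    exe_path TEXT,
    exe_checksum TEXT,
    checksum_algo TEXT,
    cmdline_json TEXT,
    cwd TEXT
);
CREATE TABLE IF NOT EXISTS file_version (
    file_key TEXT PRIMARY KEY,
    path TEXT,
    version_no INTEGER,
    created_time INTEGER,
    origin TEXT,
    content_checksum TEXT
);
CREATE TABLE IF NOT EXISTS io_event (
    event_key INTEGER PRIMARY KEY AUTOINCREMENT,
    proc_key TEXT,
    file_key TEXT,
    op_kind TEXT,
    t_first INTEGER,
    t_last INTEGER,
    count INTEGER,
    bytes INTEGER
);
CREATE INDEX IF NOT EXISTS idx_event_file ON io_event(file_key, op_kind, t_first);
CREATE INDEX IF NOT EXISTS idx_event_proc ON io_event(proc_key, op_kind, t_first);
"""


class ProvenanceStore:
    """One embedded database per mount session.

    ``db_path=None`` keeps everything in memory (plus SQLite ``:memory:``);
    a path makes the session durable and re-openable.
    """

    def __init__(
        self,
        db_path: str | None = None,
        *,
        session_id: str | None = None,
        source_root: str | None = None,
        config_snapshot: dict | None = None,
        flush_threshold: int = 10_000,
    ) -> None:
        self.session_id = session_id or f"s{time.time_ns():x}"
        self.source_root = source_root
        self.flush_threshold = flush_threshold
        self.clock = _Clock()
        self._lock = threading.RLock()
        self._conn = sqlite3.connect(db_path or ":memory:", check_same_thread=False)
        self._conn.executescript(_SCHEMA)

        self._procs: dict[str, ProcessRecord] = {}
        self._files: dict[str, FileVersion] = {}
        self._current: dict[str, str] = {}  # path -> latest file_key
        self._vstate: dict[str, _VersionState] = {}
        self._file_serial = 0
        self._pending: list[IOEvent] = []
        self._dirty: list[IOEvent] = []  # persisted events extended since flush
        # file_key -> proc_key -> live coalescing run
        self._runs: dict[str, dict[str, IOEvent]] = {}
        # proc_key -> files with an active write run by that process
        self._proc_write_runs: dict[str, set[str]] = {}

        self._load_existing()
        self._conn.execute(
            "INSERT OR IGNORE INTO session VALUES (?,?,?,?,?)",
            (
                self.session_id,
                source_root,
                time.time(),
                json.dumps(config_snapshot or {}),
                SCHEMA_VERSION,
            ),
        )
        self._conn.commit()

    # ------------------------------------------------------------------ load
    def _load_existing(self) -> None:
        for row in self._conn.execute(
            "SELECT proc_key,pid,start_time,parent_key,exe_path,exe_checksum,"
            "checksum_algo,cmdline_json,cwd FROM process"
        ):
            rec = ProcessRecord(
                proc_key=row[0], pid=row[1], start_time=row[2], parent_key=row[3],
                exe_path=row[4], exe_checksum=row[5], checksum_algo=row[6],
                cmdline=tuple(json.loads(row[7] or "[]")), cwd=row[8],
            )
            self._procs[rec.proc_key] = rec
        for row in self._conn.execute(
            "SELECT file_key,path,version_no,created_time,origin,content_checksum "
            "FROM file_version"
        ):
            fv = FileVersion(*row)
            self._files[fv.file_key] = fv
            serial = int(fv.file_key[1:]) if fv.file_key[1:].isdigit() else 0
            self._file_serial = max(self._file_serial, serial + 1)
            cur = self._current.get(fv.path)
            if cur is None or self._files[cur].version_no < fv.version_no:
                self._current[fv.path] = fv.file_key

    # ------------------------------------------------------------- processes
    def record_process(self, rec: ProcessRecord) -> str:
        """Idempotent: re-recording the same live process returns the same key."""
        with self._lock:
            existing = self._procs.get(rec.proc_key)
            if existing is not None:
                return existing.proc_key
            self._procs[rec.proc_key] = rec
            self._conn.execute(
                "INSERT OR IGNORE INTO process VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    rec.proc_key, rec.pid, rec.start_time, rec.parent_key,
                    rec.exe_path, rec.exe_checksum, rec.checksum_algo,
                    json.dumps(list(rec.cmdline)), rec.cwd,
                ),
            )
            return rec.proc_key

    def record_caller(self, info: CallerInfo, parent_key: str | None = None) -> str:
        """Build and record a ProcessRecord from a /proc snapshot."""
        start = info.start_time if info.start_time is not None else -1
        key = ProcessRecord.key_for(info.pid, start, self.session_id)
        if parent_key is None and info.ppid is not None:
            # link to the parent only if we have already observed it
            for cand in self._procs.values():
                if cand.pid == info.ppid:
                    parent_key = cand.proc_key
                    break
        return self.record_process(
            ProcessRecord(
                proc_key=key, pid=info.pid, start_time=start,
                parent_key=parent_key, exe_path=info.exe_path,
                exe_checksum=info.exe_checksum, checksum_algo=info.checksum_algo,
                cmdline=info.cmdline or (), cwd=info.cwd,
            )
        )

    def get_process(self, proc_key: str) -> ProcessRecord:
        try:
            return self._procs[proc_key]
        except KeyError:
            raise NotFoundError(proc_key) from None

    def all_processes(self) -> list[ProcessRecord]:
        return sorted(self._procs.values(), key=lambda p: (p.start_time, p.proc_key))

    # ------------------------------------------------------------- files
    def register_file_version(
        self,
        path: str,
        *,
        origin: str = ORIGIN_INTERNAL,
        created_time: int | None = None,
        file_key: str | None = None,
    ) -> FileVersion:
        """Create the next version of ``path`` (version 0 if new)."""
        with self._lock:
            cur = self._current.get(path)
            version_no = 0 if cur is None else self._files[cur].version_no + 1
            if file_key is None:
                file_key = f"f{self._file_serial}"
                self._file_serial += 1
            fv = FileVersion(
                file_key=file_key,
                path=path,
                version_no=version_no,
                created_time=created_time if created_time is not None else self.clock.now(),
                origin=origin,
            )
            self._files[file_key] = fv
            self._current[path] = file_key
            self._vstate[file_key] = _VersionState()
            self._conn.execute(
                "INSERT INTO file_version VALUES (?,?,?,?,?,?)",
                (fv.file_key, fv.path, fv.version_no, fv.created_time, fv.origin, None),
            )
            return fv

    def current_version(self, path: str) -> FileVersion | None:
        key = self._current.get(path)
        return self._files[key] if key is not None else None

    def ensure_version(self, path: str, *, origin: str = ORIGIN_EXTERNAL) -> FileVersion:
        """Current version of ``path``, creating one (default external) if absent.

        A file first seen through a read has no recorded writer: its content
        entered the monitored tree from outside.
        """
        with self._lock:
            fv = self.current_version(path)
            return fv if fv is not None else self.register_file_version(path, origin=origin)

    def version_for_write(self, path: str, *, truncate: bool = False) -> FileVersion:
        """Version that an opening writer should target.

        A new version starts when the path is new, on truncate/create, or when
        the previous version already had a reader or a completed writer; a
        concurrent second writer joins the version in progress.
        """
        with self._lock:
            fv = self.current_version(path)
            if fv is None or truncate:
                fv = self.register_file_version(path)
            else:
                st = self._vstate.setdefault(fv.file_key, _VersionState())
                if st.had_reader or st.completed_writer:
                    fv = self.register_file_version(path)
            self._vstate[fv.file_key].open_writers += 1
            return fv

    def note_read(self, file_key: str) -> None:
        with self._lock:
            self._vstate.setdefault(file_key, _VersionState()).had_reader = True

    def writer_closed(self, file_key: str, content_checksum: str | None = None) -> None:
        with self._lock:
            st = self._vstate.setdefault(file_key, _VersionState())
            st.open_writers = max(0, st.open_writers - 1)
            st.completed_writer = True
            if content_checksum is not None and st.open_writers == 0:
                self.set_content_checksum(file_key, content_checksum)

    def set_content_checksum(self, file_key: str, digest: str) -> None:
        with self._lock:
            fv = self.get_file(file_key)
            fv.content_checksum = digest
            self._conn.execute(
                "UPDATE file_version SET content_checksum=? WHERE file_key=?",
                (digest, file_key),
            )

    def rename_path(self, old_path: str, new_path: str) -> None:
        """Rename transfers identity: paths updated, versions kept."""
        with self._lock:
            for fv in self._files.values():
                if fv.path == old_path:
                    fv.path = new_path
            self._conn.execute(
                "UPDATE file_version SET path=? WHERE path=?", (new_path, old_path)
            )
            if old_path in self._current:
                self._current[new_path] = self._current.pop(old_path)

    def unlink_path(self, path: str) -> None:
        with self._lock:
            self._current.pop(path, None)

    def get_file(self, file_key: str) -> FileVersion:
        try:
            return self._files[file_key]
        except KeyError:
            raise NotFoundError(file_key) from None

    def all_files(self) -> list[FileVersion]:
        return sorted(self._files.values(), key=lambda f: (f.path, f.version_no))

    # ------------------------------------------------------------- events
    def record_event(
        self,
        proc_key: str,
        file_key: str,
        op_kind: str,
        *,
        t: int | None = None,
        nbytes: int = 0,
    ) -> None:
        """Record one primitive operation, coalescing where permitted.

        Unknown processes/files are auto-registered minimally so that a
        recording gap never loses an event.
        """
        with self._lock:
            if proc_key not in self._procs:
                self.record_process(
                    ProcessRecord(proc_key=proc_key, pid=-1, start_time=-1)
                )
            if file_key not in self._files:
                self.register_file_version(
                    file_key, origin=ORIGIN_EXTERNAL, file_key=file_key
                )
            t = self.clock.now() if t is None else self.clock.observe(t)

            if op_kind == READ:
                # this process's later writes may depend on this read: close
                # every write run it has open, on any file
                for fk in self._proc_write_runs.pop(proc_key, ()):
                    fruns = self._runs.get(fk)
                    if fruns is not None:
                        r = fruns.get(proc_key)
                        if r is not None and r.op_kind == WRITE:
                            del fruns[proc_key]

            runs = self._runs.setdefault(file_key, {})
            mine = runs.get(proc_key)

            if op_kind in (READ, WRITE) and mine is not None and mine.op_kind == op_kind:
                mine.count += 1
                mine.bytes += nbytes
                mine.t_last = t
                if mine.event_key is not None and not mine._dirty:
                    mine._dirty = True
                    self._dirty.append(mine)
                self._invalidate_others(runs, proc_key, op_kind)
                return

            # the run (if any) by this process on this file breaks on kind change
            if mine is not None:
                runs.pop(proc_key, None)
            self._invalidate_others(runs, proc_key, op_kind)

            ev = IOEvent(
                proc_key=proc_key, file_key=file_key, op_kind=op_kind,
                t_first=t, t_last=t, count=1, bytes=nbytes,
            )
            self._pending.append(ev)
            if op_kind in (READ, WRITE):
                runs[proc_key] = ev
                if op_kind == WRITE:
                    self._proc_write_runs.setdefault(proc_key, set()).add(file_key)
            if len(self._pending) >= self.flush_threshold:
                self.flush()

    def _invalidate_others(
        self, runs: dict[str, IOEvent], proc_key: str, op_kind: str
    ) -> None:
        """Apply the file-level coalescing break rules (see module docstring)."""
        if op_kind in WRITE_KINDS:
            # a write breaks every other run on this file
            for other in [k for k in runs if k != proc_key]:
                runs.pop(other)
        elif op_kind == READ:
            # a read breaks other processes' write runs; read runs survive
            for other in [k for k, r in runs.items() if k != proc_key and r.op_kind == WRITE]:
                runs.pop(other)

    def flush(self) -> int:
        """Persist buffered events; returns how many new events were written."""
        with self._lock:
            new = [e for e in self._pending if e.event_key is None]
            try:
                for ev in new:
                    cur = self._conn.execute(
                        "INSERT INTO io_event (proc_key,file_key,op_kind,t_first,"
                        "t_last,count,bytes) VALUES (?,?,?,?,?,?,?)",
                        (
                            ev.proc_key, ev.file_key, ev.op_kind,
                            ev.t_first, ev.t_last, ev.count, ev.bytes,
                        ),
                    )
                    ev.event_key = cur.lastrowid
                # runs already persisted but extended since: update in place
                for ev in self._dirty:
                    self._conn.execute(
                        "UPDATE io_event SET t_last=?,count=?,bytes=? "
                        "WHERE event_key=?",
                        (ev.t_last, ev.count, ev.bytes, ev.event_key),
                    )
                    ev._dirty = False
                self._conn.commit()
            except sqlite3.Error:
                raise  # buffered events retained: _pending untouched on failure
            self._pending.clear()
            self._dirty.clear()
            return len(new)

    # ------------------------------------------------------------- queries
    def query_writes(
        self, file_key: str, before: int | None = None
    ) -> list[tuple[ProcessRecord, IOEvent]]:
        """All write/create/truncate events to a file version, ordered by t_first."""
        self.get_file(file_key)
        self.flush()
        q = (
            "SELECT proc_key,file_key,op_kind,t_first,t_last,count,bytes,event_key "
            "FROM io_event WHERE file_key=? AND op_kind IN ('write','create','truncate')"
        )
        args: list = [file_key]
        if before is not None:
            q += " AND t_first < ?"
            args.append(before)
        q += " ORDER BY t_first"
        out = []
        with self._lock:
            rows = self._conn.execute(q, args).fetchall()
        for row in rows:
            ev = IOEvent(*row[:7], event_key=row[7])
            out.append((self.get_process(ev.proc_key), ev))
        return out

    def query_reads(
        self, proc_key: str, before: int | None = None
    ) -> list[tuple[FileVersion, IOEvent]]:
        """All read events by a process (t_first < before), ordered by t_first."""
        self.get_process(proc_key)
        self.flush()
        q = (
            "SELECT proc_key,file_key,op_kind,t_first,t_last,count,bytes,event_key "
            "FROM io_event WHERE proc_key=? AND op_kind='read'"
        )
        args: list = [proc_key]
        if before is not None:
            q += " AND t_first < ?"
            args.append(before)
        q += " ORDER BY t_first"
        out = []
        with self._lock:
            rows = self._conn.execute(q, args).fetchall()
        for row in rows:
            ev = IOEvent(*row[:7], event_key=row[7])
            out.append((self.get_file(ev.file_key), ev))
        return out

    def event_count(self) -> int:
        self.flush()
        return self._conn.execute("SELECT COUNT(*) FROM io_event").fetchone()[0]

    def primitive_op_count(self, kinds: tuple[str, ...] = (READ, WRITE)) -> int:
        """Total primitive operations represented, undoing coalescing."""
        self.flush()
        ph = ",".join("?" for _ in kinds)
        row = self._conn.execute(
            f"SELECT COALESCE(SUM(count),0) FROM io_event WHERE op_kind IN ({ph})",
            kinds,
        ).fetchone()
        return row[0]

    # ------------------------------------------------------------- lifecycle
    def close(self) -> None:
        with self._lock:
            self.flush()
            self._conn.commit()
            self._conn.close()

    def __enter__(self) -> "ProvenanceStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
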