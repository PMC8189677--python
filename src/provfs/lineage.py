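"""Provenance reconstruction: the temporal lineage closure.

Starting from a target file version, the tracer alternates two store queries
until closure: (1) which processes wrote this file, and (2) which files each
such process read *before* the time it wrote. Each file discovered in step 2
seeds a new iteration, constrained so that only writes occurring before the
discovering read time are followed. Recursion bottoms out at external-origin
files — versions with no recorded writer, whose content entered the monitored
tree from outside (another file system, the network, the keyboard).

The dependency assumption is deliberately coarse: data written by a process
is assumed to depend on *all* data it read earlier, in lieu of analyzing the
program itself. The temporal constraint keeps the closure sound: only data
read before an output was produced can have influenced that output.

Closure semantics (implemented identically by :func:`trace` against the
store and by :func:`brute_force_trace` against a raw event list):

* ``bound[target] = +∞``; for any other file, ``bound[f]`` is the maximum
  read time through which ``f`` entered the closure.
* every write ``w`` to an in-closure file ``f`` with ``w.t_first <
  bound[f]`` contributes its process and a write edge ``(proc, f)``;
* for each such write, every read ``r`` by that process with ``r.t_first <
  w.t_first`` contributes a read edge ``(r.file, proc)`` and raises
  ``bound[r.file]`` to at least ``r.t_first``;
* ancestry (spawn) edges are added for every traced process's recorded
  parent chain.

Edge times are the earliest qualifying operation time. Bounds only grow and
every step moves strictly backward in time, so the closure terminates on any
finite log.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .store import FileVersion, ProvenanceStore

READ = "read"
WRITE = "write"


@dataclass(frozen=True)
class RawEvent:
    """One primitive operation in a raw (uncoalesced) event stream."""

    t: int
    proc: str
    file: str
    kind: str  # "read" | "write"
    nbytes: int = 0


@dataclass
class ProvenanceGraph:
    """Bipartite file/process DAG with read, write and spawn edges.

    Edges are keyed by endpoints with the earliest qualifying time as value;
    the graph is acyclic when edges are oriented by time (file versions are
    immutable once read).
    """

    target: str
    file_nodes: set[str] = field(default_factory=set)
    proc_nodes: set[str] = field(default_factory=set)
    read_edges: dict[tuple[str, str], int] = field(default_factory=dict)  # (file, proc) -> t
    write_edges: dict[tuple[str, str], int] = field(default_factory=dict)  # (proc, file) -> t
    spawn_edges: set[tuple[str, str]] = field(default_factory=set)  # (parent, child)

    def summary(self) -> tuple:
        """Canonical comparable form (node and edge sets with times)."""
        return (
            self.target,
            frozenset(self.file_nodes),
            frozenset(self.proc_nodes),
            frozenset(self.read_edges.items()),
            frozenset(self.write_edges.items()),
            frozenset(self.spawn_edges),
        )

    def readers_of(self, file_key: str) -> set[str]:
        return {p for (f, p) in self.read_edges if f == file_key}

    def writers_of(self, file_key: str) -> set[str]:
        return {p for (p, f) in self.write_edges if f == file_key}


def _add_ancestry(graph: ProvenanceGraph, parent_of: Mapping[str, str | None]) -> None:
    """Extend proc nodes with recorded ancestors; add spawn edges along chains."""
    stack = list(graph.proc_nodes)
    seen = set(stack)
    while stack:
        child = stack.pop()
        parent = parent_of.get(child)
        if parent is None:
            continue
        graph.spawn_edges.add((parent, child))
        if parent not in seen:
            seen.add(parent)
            graph.proc_nodes.add(parent)
            stack.append(parent)


def trace(target: str | FileVersion, store: ProvenanceStore) -> ProvenanceGraph:
    """Reconstruct the provenance graph of ``target`` from the store.

    Raises :class:`~provfs.store.NotFoundError` for an unknown target.
    """
    target_key = target.file_key if isinstance(target, FileVersion) else target
    store.get_file(target_key)  # not-found check up front

    g = ProvenanceGraph(target=target_key, file_nodes={target_key})
    bound: dict[str, float] = {target_key: math.inf}
    pending: deque[str] = deque([target_key])
    done_writes: set[tuple[str, int | None]] = set()

    while pending:
        fk = pending.popleft()
        b = bound[fk]
        before = None if math.isinf(b) else int(b)
        for proc, wev in store.query_writes(fk, before=before):
            g.proc_nodes.add(proc.proc_key)
            key = (proc.proc_key, fk)
            g.write_edges[key] = min(g.write_edges.get(key, wev.t_first), wev.t_first)
            wid = (proc.proc_key, wev.event_key)
            if wid in done_writes:
                continue
            done_writes.add(wid)
            for fv, rev in store.query_reads(proc.proc_key, before=wev.t_first):
                rkey = (fv.file_key, proc.proc_key)
                g.read_edges[rkey] = min(g.read_edges.get(rkey, rev.t_first), rev.t_first)
                g.file_nodes.add(fv.file_key)
                if bound.get(fv.file_key, -math.inf) < rev.t_first:
                    bound[fv.file_key] = rev.t_first
                    pending.append(fv.file_key)

    # ancestry lookups may reach parents outside the traced set; resolve lazily
    full_parents: dict[str, str | None] = {}

    def parent(k: str) -> str | None:
        if k not in full_parents:
            try:
                full_parents[k] = store.get_process(k).parent_key
            except KeyError:
                full_parents[k] = None
        return full_parents[k]

    _add_ancestry(g, _LazyParents(parent))
    return g


class _LazyParents:
    def __init__(self, fn):
        self._fn = fn

    def get(self, key, default=None):
        val = self._fn(key)
        return default if val is None else val


def brute_force_trace(
    events: Sequence[RawEvent],
    target: str,
    parent_of: Mapping[str, str | None] | None = None,
) -> ProvenanceGraph:
    """Reference closure by naive repeated scanning of the full event list.

    Independent of the store and of :func:`trace`: a fixpoint loop over the
    raw stream applying the same temporal rule. Used as the test oracle.
    """
    g = ProvenanceGraph(target=target, file_nodes={target})
    bound: dict[str, float] = {target: math.inf}
    included: set[int] = set()

    changed = True
    while changed:
        changed = False
        for i, w in enumerate(events):
            if w.kind != WRITE:
                continue
            b = bound.get(w.file)
            if b is None or w.t >= b:
                continue
            g.proc_nodes.add(w.proc)
            wkey = (w.proc, w.file)
            prev = g.write_edges.get(wkey)
            if prev is None or w.t < prev:
                g.write_edges[wkey] = w.t
                changed = True
            if i in included:
                continue
            included.add(i)
            changed = True
            for r in events:
                if r.kind != READ or r.proc != w.proc or r.t >= w.t:
                    continue
                rkey = (r.file, r.proc)
                prev = g.read_edges.get(rkey)
                if prev is None or r.t < prev:
                    g.read_edges[rkey] = r.t
                g.file_nodes.add(r.file)
                if bound.get(r.file, -math.inf) < r.t:
                    bound[r.file] = r.t

    if parent_of:
        _add_ancestry(g, parent_of)
    return g


def replay_into_store(
    events: Iterable[RawEvent],
    store: ProvenanceStore,
    *,
    processes: Iterable[tuple[str, int, int, str | None]] = (),
) -> None:
    """Replay a raw stream into a store (for testing and simulation).

    ``processes`` supplies (proc_id, pid, start_time, parent_id) tuples so
    pid reuse and spawn ancestry are representable; file ids become file
    keys directly, each its own version.
    """
    from .store import ProcessRecord

    for proc_id, pid, start_time, parent in processes:
        store.record_process(
            ProcessRecord(
                proc_key=proc_id, pid=pid, start_time=start_time, parent_key=parent
            )
        )
    for ev in events:
        store.record_event(ev.proc, ev.file, ev.kind, t=ev.t, nbytes=ev.nbytes)
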