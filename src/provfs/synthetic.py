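"""Deterministic synthetic fixtures: pipelines, event logs, VDF trees.

Everything here is a pure function of its arguments (seed-determinism), so a
failing test is always replayable. Three generators cover the rest of the
package:

* :func:`gen_pipeline` — multi-stage shell pipelines built exclusively from
  ubiquitous deterministic text utilities (sort, tr, head, cat, cut) wrapped
  in tiny generated tool scripts, with every intermediate file's expected
  content computed analytically in Python (an oracle independent of the
  subprocesses that later produce the real bytes);
* :func:`gen_event_log` — randomized raw I/O event streams with adversarial
  features (writes after reads, multi-writer files, external-origin roots,
  pid reuse, spawn chains) and a generation-time exhaustive lineage closure
  that shares no code with the lineage module;
* :func:`gen_vdf_fixtures` — small FASTQ-like and delimited-table trees plus
  rules exercising both stdout-channel and file-channel VDF commands.
"""

from __future__ import annotations

import hashlib
import math
import os
import random
import stat as stat_mod
from dataclasses import dataclass, field
from pathlib import Path

from .config import CacheConfig, Config, VDFSpec
from .lineage import RawEvent

# --------------------------------------------------------------------------
# Pipelines
# --------------------------------------------------------------------------

TOOL_SCRIPTS = {
    "t_sort": '#!/bin/sh\nexec sort "$@"\n',
    "t_upper": "#!/bin/sh\nexec tr 'a-z' 'A-Z'\n",
    "t_head": '#!/bin/sh\nexec head "$@"\n',
    "t_cat": '#!/bin/sh\nexec cat "$@"\n',
    "t_cut": '#!/bin/sh\nexec cut "$@"\n',
}

_WORDS = (
    "alpha bravo charlie delta echo foxtrot golf hotel india juliet kilo lima "
    "mike november oscar papa quebec romeo sierra tango uniform victor whiskey "
    "xray yankee zulu"
).split()


@dataclass(frozen=True)
class PlanStage:
    """One pipeline stage: a wrapped utility with declared I/O.

    ``args`` are command-line arguments (may include input paths, as for
    cat); ``stdin``/``stdout`` are mount-relative paths redirected at run
    time. Inputs = stdin + any path args; output = stdout.
    """

    tool: str
    args: tuple[str, ...]
    stdin: str | None
    stdout: str
    inputs: tuple[str, ...]  # all inputs including stdin


@dataclass
class SyntheticPipeline:
    seed: int
    inputs: dict[str, bytes]  # mount-relative path -> content
    stages: tuple[PlanStage, ...]
    target: str
    expected: dict[str, bytes]  # every file path -> expected final content
    closure_files: frozenset[str]  # files in the target's lineage (incl. target)
    closure_stages: frozenset[int]  # stage indices in the target's lineage

    @property
    def expected_target(self) -> bytes:
        return self.expected[self.target]

    @property
    def expected_target_sha256(self) -> str:
        return hashlib.sha256(self.expected_target).hexdigest()

    def driver_script(self, bindir: str) -> str:
        """POSIX driver script equivalent to running all stages in order."""
        lines = ["#!/bin/sh", "set -e"]
        for st in self.stages:
            cmd = " ".join([os.path.join(bindir, st.tool), *st.args])
            if st.stdin:
                cmd += f" < {st.stdin}"
            cmd += f" > {st.stdout}"
            lines.append(cmd)
        return "\n".join(lines) + "\n"


def _apply_tool(tool: str, args: tuple[str, ...], stdin_data: bytes,
                files: dict[str, bytes]) -> bytes:
    """Python model of each wrapped utility (the analytic oracle)."""
    if tool == "t_sort":
        lines = stdin_data.splitlines(keepends=True)
        return b"".join(sorted(lines))
    if tool == "t_upper":
        return stdin_data.upper()
    if tool == "t_head":
        n = int(args[args.index("-n") + 1])
        return b"".join(stdin_data.splitlines(keepends=True)[:n])
    if tool == "t_cat":
        return b"".join(files[a] for a in args)
    if tool == "t_cut":
        out = []
        for line in stdin_data.splitlines():
            out.append(line.split(b",")[0] + b"\n")
        return b"".join(out)
    raise ValueError(tool)


def gen_pipeline(n_stages: int, branching: int = 2, seed: int = 0) -> SyntheticPipeline:
    """Generate a deterministic synthetic pipeline.

    Commands contain no timestamps or randomness, so replication must be
    byte-exact. Expected content for every file, and the target's lineage
    topology, are computed analytically from the stage list.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    rng = random.Random(seed)

    n_inputs = max(1, min(branching, 3))
    inputs: dict[str, bytes] = {}
    for i in range(n_inputs):
        n_lines = rng.randint(20, 60)
        lines = []
        for _ in range(n_lines):
            a, b = rng.choice(_WORDS), rng.choice(_WORDS)
            lines.append(f"{a},{b}{rng.randint(0, 99)}".encode())
        inputs[f"inputs/in{i}.txt"] = b"\n".join(lines) + b"\n"

    files: dict[str, bytes] = dict(inputs)
    pool = list(inputs)
    stages: list[PlanStage] = []
    produced_by: dict[str, int] = {}

    for i in range(n_stages):
        out = f"work/s{i}.txt" if i < n_stages - 1 else "work/target.txt"
        tool = rng.choice(list(TOOL_SCRIPTS))
        if tool == "t_cat":
            k = rng.randint(1, min(branching, len(pool)))
            srcs = tuple(rng.sample(pool, k))
            st = PlanStage(tool, srcs, None, out, srcs)
            data = _apply_tool(tool, srcs, b"", files)
        else:
            src = rng.choice(pool)
            args: tuple[str, ...] = ()
            if tool == "t_head":
                n_avail = max(1, len(files[src].splitlines()))
                args = ("-n", str(rng.randint(1, n_avail)))
            elif tool == "t_cut":
                args = ("-d,", "-f1")
            st = PlanStage(tool, args, src, out, (src,))
            data = _apply_tool(tool, args, files[src], files)
        stages.append(st)
        files[out] = data
        produced_by[out] = i
        pool.append(out)

    # analytic lineage closure over the stage DAG
    closure_files = {stages[-1].stdout}
    closure_stages: set[int] = set()
    frontier = [stages[-1].stdout]
    while frontier:
        f = frontier.pop()
        idx = produced_by.get(f)
        if idx is None:
            continue  # root input (external origin)
        if idx in closure_stages:
            continue
        closure_stages.add(idx)
        for src in stages[idx].inputs:
            if src not in closure_files:
                closure_files.add(src)
                frontier.append(src)

    return SyntheticPipeline(
        seed=seed,
        inputs=inputs,
        stages=tuple(stages),
        target=stages[-1].stdout,
        expected=files,
        closure_files=frozenset(closure_files),
        closure_stages=frozenset(closure_stages),
    )


def materialize_pipeline(
    pipeline: SyntheticPipeline, data_dir: str | os.PathLike, bin_dir: str | os.PathLike
) -> None:
    """Write input files under ``data_dir`` and tool scripts under ``bin_dir``.

    Tool scripts stand in for installed software: they live outside the
    monitored tree and are referenced by absolute path, so environment
    verification and tampering scenarios behave like real installations.
    """
    data_dir, bin_dir = Path(data_dir), Path(bin_dir)
    for rel, content in pipeline.inputs.items():
        p = data_dir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_bytes(content)
    (data_dir / "work").mkdir(parents=True, exist_ok=True)
    bin_dir.mkdir(parents=True, exist_ok=True)
    for name, text in TOOL_SCRIPTS.items():
        p = bin_dir / name
        p.write_text(text)
        p.chmod(p.stat().st_mode | stat_mod.S_IXUSR | stat_mod.S_IXGRP | stat_mod.S_IXOTH)


# --------------------------------------------------------------------------
# Event logs
# --------------------------------------------------------------------------


@dataclass
class EventLog:
    """Raw event stream with ground-truth lineage closures.

    ``processes`` holds (proc_id, pid, start_time, parent_id) tuples;
    ``events`` are strictly increasing in time. ``ground_truth`` maps a
    sample of file ids to closure dictionaries computed at generation time
    by :func:`exhaustive_closure` (independent of the lineage module).
    """

    seed: int
    processes: tuple[tuple[str, int, int, str | None], ...]
    events: tuple[RawEvent, ...]
    ground_truth: dict[str, dict] = field(default_factory=dict)

    @property
    def parent_of(self) -> dict[str, str | None]:
        return {p: parent for p, _, _, parent in self.processes}

    def files(self) -> list[str]:
        return sorted({e.file for e in self.events})


def exhaustive_closure(
    events: tuple[RawEvent, ...],
    target: str,
    parent_of: dict[str, str | None],
) -> dict:
    """Generation-time lineage oracle: exhaustive fixpoint over the raw log.

    Same temporal rule as the tracer, implemented independently: a write to
    an in-closure file qualifies if it precedes the file's entry bound (∞
    for the target); each qualifying write pulls in all strictly earlier
    reads by that process, each read raising its file's bound.
    """
    bound: dict[str, float] = {target: math.inf}
    files = {target}
    procs: set[str] = set()
    read_edges: dict[tuple[str, str], int] = {}
    write_edges: dict[tuple[str, str], int] = {}

    stable = False
    while not stable:
        stable = True
        for w in events:
            if w.kind != "write" or w.file not in bound or w.t >= bound[w.file]:
                continue
            if w.proc not in procs:
                procs.add(w.proc)
                stable = False
            ek = (w.proc, w.file)
            if ek not in write_edges or w.t < write_edges[ek]:
                write_edges[ek] = w.t
                stable = False
            for r in events:
                if r.kind != "read" or r.proc != w.proc or r.t >= w.t:
                    continue
                rk = (r.file, r.proc)
                if rk not in read_edges or r.t < read_edges[rk]:
                    read_edges[rk] = r.t
                    stable = False
                if r.file not in files:
                    files.add(r.file)
                    stable = False
                if bound.get(r.file, -math.inf) < r.t:
                    bound[r.file] = r.t
                    stable = False

    spawn: set[tuple[str, str]] = set()
    work = list(procs)
    seen = set(work)
    while work:
        c = work.pop()
        p = parent_of.get(c)
        if p is None:
            continue
        spawn.add((p, c))
        if p not in seen:
            seen.add(p)
            procs.add(p)
            work.append(p)

    return {
        "target": target,
        "files": frozenset(files),
        "procs": frozenset(procs),
        "read_edges": frozenset(read_edges.items()),
        "write_edges": frozenset(write_edges.items()),
        "spawn_edges": frozenset(spawn),
    }


def gen_event_log(
    n_procs: int,
    n_files: int,
    seed: int = 0,
    *,
    n_ops: int | None = None,
    n_ground_truth: int = 5,
) -> EventLog:
    """Randomized raw event log with known ground-truth lineage.

    The stream includes external-origin roots (files only ever read),
    multi-writer files, post-read writers (temporal exclusion), reused pids
    and spawn chains. Timestamps are strictly increasing integers.
    """
    if n_procs < 1 or n_files < 1:
        raise ValueError("n_procs and n_files must be >= 1")
    rng = random.Random(seed)
    n_ops = n_ops or max(4, 4 * n_files)

    processes: list[tuple[str, int, int, str | None]] = []
    t = 0
    for i in range(n_procs):
        t += 1
        parent = None
        if i > 0 and rng.random() < 0.4:
            parent = processes[rng.randrange(len(processes))][0]
        # deliberate pid reuse: pids drawn from a small range
        pid = rng.randint(100, 100 + max(1, n_procs // 2))
        processes.append((f"P{i}", pid, t, parent))

    proc_ids = [p[0] for p in processes]
    start_of = {p[0]: p[2] for p in processes}
    file_ids = [f"F{i}" for i in range(n_files)]
    # a slice of files is reserved as external roots: read-only forever
    n_external = max(1, n_files // 5)
    external = set(file_ids[:n_external])

    events: list[RawEvent] = []
    for _ in range(n_ops):
        t += 1
        proc = rng.choice(proc_ids)
        if start_of[proc] >= t:
            continue
        f = rng.choice(file_ids)
        if f in external:
            kind = "read"
        else:
            kind = "write" if rng.random() < 0.45 else "read"
        events.append(RawEvent(t=t, proc=proc, file=f, kind=kind,
                               nbytes=rng.randint(1, 4096)))

    log = EventLog(seed=seed, processes=tuple(processes), events=tuple(events))
    written = sorted({e.file for e in events if e.kind == "write"})
    sample = written[:n_ground_truth] if written else log.files()[:n_ground_truth]
    for f in sample:
        log.ground_truth[f] = exhaustive_closure(log.events, f, log.parent_of)
    return log


# --------------------------------------------------------------------------
# VDF fixtures
# --------------------------------------------------------------------------


def gen_vdf_fixtures(seed: int = 0) -> tuple[dict[str, bytes], Config]:
    """Small file tree plus VDF rules covering format conversion and analysis.

    Two rule classes are exercised with ubiquitous utilities only: a
    FASTQ-to-FASTA conversion and a column extraction over a delimited
    table (stdout channel), and a sort rule writing through a file channel.
    """
    rng = random.Random(seed)

    def seq(n):
        return "".join(rng.choice("ACGT") for _ in range(n))

    tree: dict[str, bytes] = {}
    for i in range(3):
        records = []
        for j in range(rng.randint(3, 8)):
            s = seq(rng.randint(12, 40))
            records.append(f"@read{i}_{j}\n{s}\n+\n{'I' * len(s)}\n")
        tree[f"reads{i}.fastq"] = "".join(records).encode()
    tree["empty.fastq"] = b""

    rows = ["taxon,count,site"]
    for i in range(rng.randint(5, 12)):
        rows.append(f"{rng.choice(_WORDS)},{rng.randint(1, 500)},s{i}")
    tree["abundance.csv"] = ("\n".join(rows) + "\n").encode()

    lines = [f"{rng.choice(_WORDS)} {rng.randint(0, 9)}" for _ in range(20)]
    tree["notes.txt"] = ("\n".join(lines) + "\n").encode()

    config = Config(
        vdf_rules=[
            VDFSpec(
                name="fastq_to_fasta",
                source_pattern="*.fastq",
                extension=".fasta",
                command_template=(
                    "awk 'NR%4==1{sub(/^@/,\">\");print} NR%4==2{print}' {source}"
                ),
                output_channel="stdout",
            ),
            VDFSpec(
                name="first_column",
                source_pattern="*.csv",
                extension=".col1",
                command_template="cut -d, -f1 {source}",
                output_channel="stdout",
            ),
            VDFSpec(
                name="sorted_text",
                source_pattern="*.txt",
                extension=".sorted",
                command_template="LC_ALL=C sort {source} -o {output}",
                output_channel="file",
            ),
        ],
        cache=CacheConfig(),
    )
    return tree, config


def materialize_tree(tree: dict[str, bytes], root: str | os.PathLike) -> None:
    root = Path(root)
    for rel, content in tree.items():
        p = root / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_bytes(content)
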