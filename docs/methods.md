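# Methods

This note documents the recording model, the lineage algorithm and its
temporal semantics, the virtual-file cache, the replication procedure, the
synthetic generators used for testing, and the design decisions taken where
the problem left room for interpretation.

## Recording model

The interception layer is deliberately split from any kernel-mount backend.
`provfs.vfs.Mount` is an in-process operation interface with POSIX-style
semantics (open/read/write/close/create/unlink/rename/truncate/stat/readdir)
over a real `source_root`: every operation is performed faithfully on the
underlying tree and simultaneously recorded. A FUSE adapter, where a binding
is available, is a thin translation onto exactly this interface; nothing in
the provenance, lineage, VDF or replication machinery depends on a kernel
mount, which keeps the entire core testable without privileges.
`provfs.runner.TracedRunner` is the second event source: it executes real
subprocesses with declared inputs/outputs and records the same schema
(actual pid, start time, absolute executable path, executable checksum,
command line, working directory; then read events, then write events with
content checksums at close).

Caller identity comes from `/proc/<pid>/{stat,cmdline,cwd,exe}` plus a
SHA-256 of the executable. A process that exits before inspection yields a
record with fields marked unavailable — never a failed I/O. Operations by
the mount daemon itself are flagged and excluded from recording to prevent
self-referential provenance. Paths are stored mount-relative with the
source root kept once per session, so exported bundles are relocatable.

Reads of file *data* create dependency edges; `stat` and `readdir` do not.
This is an interpretation: metadata-only access rarely carries analytical
content, and treating it as input would wire spurious edges through every
directory scan.

### File versions

A `FileVersion` is the node unit of lineage. A new version starts when a
path is created or truncated, or when it is opened for writing after the
previous version already had a reader or a completed writer; concurrent
writers that open before any reader share the version in progress. This
rule keeps read edges pointing at the content that was actually read.
Renames transfer identity (the path is updated, versions are kept) — an
interpretation, flagged as such: renaming does not alter content, so
severing lineage at a rename would lose true history. Content checksums are
computed once, at last-writer close, not per write.

### Event coalescing

Consecutive primitive reads (or writes) by one process on one file version
coalesce into a single event carrying `count`, `bytes`, and a `[t_first,
t_last]` span; the store buffers events in memory (default flush threshold
10 000 events, configurable) and flushes to SQLite on demand, at the
threshold, and at session close. Flushing never changes query results: a
run that continues after a flush updates its persisted row in place.

Coalescing must not change lineage. A run therefore breaks not only on a
different operation kind by the same process on that file (the obvious
rule) but also on two file-level conditions:

* a **read run** breaks when *any* process writes the file version;
* a **write run** breaks when any *other* process touches the version, and
  when the writing process itself performs a read (of any file).

With these rules no coalesced run ever spans an event that the temporal
closure could be sensitive to, and tracing over coalesced events is exactly
equivalent to tracing over the raw stream — the property the test suite
verifies against an independent brute-force oracle on randomized logs. The
last rule is the subtle one: without it, a process that alternates writing
an output with reading further input would present a single write event
whose `t_first` predates those reads, hiding genuine dependencies.

Timestamps come from one strictly monotonic integer clock owned by the
store, so "before" is well-defined across threads.

## Lineage closure

`trace(target, store)` computes a fixpoint over two queries: all writes to
an in-closure file before that file's entry bound (∞ for the target), and
for each such write all reads by the writing process strictly before the
write's `t_first`. Each read raises its file's bound to at least the read
time; bounds only grow and every step moves strictly backward in time, so
the closure terminates on any finite log. Using `t_first` (first byte
written) as the write endpoint is the conservative choice — the problem
statement does not fix an endpoint. Edge times record the earliest
qualifying operation. Spawn edges are added along the recorded parent chain
of every traced process; dependency granularity remains per-process (a
child's reads are not imputed to its parent — causality flows through
recorded I/O, with ancestry shown explicitly).

`brute_force_trace` implements the same semantics by naive repeated
scanning of a raw event list and exists solely as a reference oracle; a
third, independently written closure lives in the synthetic generator so
the oracle itself is cross-checked. Environment variables are not part of
the recorded process context.

## Graph rendering

Files with identical (reader set, writer set) signatures collapse into one
counted group node; the target is never absorbed, so the lineage anchor
stays visible. The default view collapses all spawned children onto their
root ancestor, re-attaching their file I/O; processes can be expanded and
re-collapsed, and renderings are deterministic (stable sort keys), so equal
graphs produce byte-identical DOT/JSON. Node styling follows the usual
convention: processes red boxes, files blue ellipses, the target green.

## Virtual dynamic files

A VDF rule maps sources matching a filename pattern to a virtual sibling
named *source name + extension* (the full name is kept — `reads.fastq` →
`reads.fastq.fasta` — avoiding collisions between sources differing only in
extension). Listings show one virtual entry per matching real file; a real
file of the same name shadows it. Rules chain: a rule may consume another
rule's virtual output.

The first read of a missing block launches the configured command exactly
once per (rule, source version). Stdout-channel commands are streamed;
file-channel commands run to completion and their output file is then
ingested. Output fills fixed-size blocks (default 128 KiB) in a memory tier
(default limit 256 MiB; both configurable). Readers of not-yet-produced
blocks wait on a condition variable and are released by block readiness,
end-of-data, or task failure (a nonzero exit is surfaced to all blocked
readers; a configurable timeout guards against wedged producers). When the
memory tier exceeds its limit, least-recently-accessed ready blocks spill
to a disk tier in production order as tie-break; a disk hit is promoted
back to memory before returning. Ready blocks never change; the final
length, once set, never changes.

The cache key includes the source's provenance version *and* a stat
signature (mtime, size, inode), so modifying the source through or around
the mount triggers regeneration. The reported size of an unmaterialized VDF
is the bytes produced so far (0 before first access) with end-of-data
signalled by short reads — copy tools that pre-allocate by size must fall
back to stream copying. VDF access is itself provenance: the generating
command is recorded as a process that reads the source version and writes
the virtual version (registered at first open, with the content checksum
attached at completion), so lineage flows through virtual files. The disk
tier is per-session; regeneration, not persistence, is the contract, and
VDFs are read-only (a write-intent open falls through to the real file
system, creating a real shadow).

## Replication

A bundle is a single canonical JSON document (schema-versioned, sorted
keys) embedding the lineage graph, full process records, external inputs
with content checksums, and the target checksum — self-contained by
construction. Script reconstruction orders leaf processes (those with no
captured children; shell wrappers are skipped to prevent double execution)
by writer-before-reader dependency with recorded start time as tie-break.
Command lines do not contain shell redirections, so the reconstructor
infers at most one unnamed input and one unnamed output per process — a
file it read/wrote whose path does not appear among its arguments — and
emits `<`/`>`; more than one of either is reported as ambiguous rather than
guessed. Execution (both original recording via the traced runner and
replication) uses a normalized environment (`LC_ALL=C`, inherited `PATH`)
so byte-determinism of text utilities is well-defined; environment
variables are otherwise outside the recorded context.

Verification checksums every recorded executable, looking at the recorded
absolute path first and then the search path; missing tools and checksum
mismatches are report entries, not exceptions. Mismatches are warnings —
execution proceeds, because a different build may still produce identical
bytes, and the target verdict (`target_match`) is checksum equality of the
produced target. A nonzero process exit halts replication at that process
with status `exec_failed`. Replication consults only the bundle and the
local environment, never the original database.

## Synthetic generators

All fixtures are pure functions of a seed.

* **Pipelines** (`gen_pipeline`) are DAGs of 1–8 stages over wrapped
  ubiquitous utilities (`sort`, `tr`, `head`, `cat`, `cut`) with CSV-like
  random text inputs (20–60 lines per input, 1–3 roots). Every
  intermediate's expected bytes are computed by an in-Python model of each
  utility — an oracle independent of the subprocesses that later produce
  the real bytes — and the target's lineage topology is derived
  analytically from the stage list. Tool wrappers are written outside the
  monitored tree and invoked by absolute path, standing in for installed
  software so tampering and version-verification scenarios behave like
  real installations.
* **Event logs** (`gen_event_log`) draw random reads/writes (45% writes)
  over up to 100 processes and 500 files with strictly increasing integer
  timestamps, reserving ~20% of files as external-origin roots and
  including pid reuse, spawn chains, multi-writer files and post-read
  writers (the temporal-exclusion case). Ground truth comes from a
  generation-time exhaustive closure that shares no code with the lineage
  module.
* **VDF fixtures** (`gen_vdf_fixtures`) emit FASTQ-like records, a
  delimited table, plain text and an empty file, with three rules covering
  both output channels (awk-based FASTQ→FASTA and `cut` column extraction
  on stdout; `sort -o` through the file channel).

What the generators deliberately do not emulate: real bioinformatics
executables and their version drift, multi-gigabyte data volumes, kernel
page-cache and mmap effects, or cross-file-system activity. Passing tests
therefore demonstrate the correctness of recording, closure, caching and
replication logic — not performance at terabyte scale or coverage of every
syscall a kernel mount would surface.

## Problem sizes and numerical choices

The acceptance checks run 100 randomized event logs (up to 100 processes /
500 files, ~3 traced targets each), eight pipeline configurations spanning
1–8 stages and branching 1–3, six tampering trials, 48 VDF identity reads
across two block sizes (4 KiB and 128 KiB) with a two-block memory limit to
force spill, 25 planted grouping graphs, and an 11 000-operation mixed
workload — sizes chosen to exercise every code path and adversarial case
while completing in seconds. Checksums are SHA-256 throughout, recorded
alongside the algorithm name. Ties in rendering and topological order are
broken by stable sort keys (ids, start times) for determinism. Degenerate
inputs covered explicitly: empty VDF sources (final length 0), external
targets (bundles with zero processes refuse script reconstruction with a
clear message), unknown keys (not-found errors), and escape paths
(`..`) rejected at normalization.

## Known limitations

* No kernel-mount backend ships in this build; real system-call
  interception of arbitrary unmodified binaries requires a FUSE binding on
  the host. The traced runner records subprocesses it launches with
  *declared* I/O rather than observed syscalls.
* Memory-mapped I/O and extended attributes are out of scope; provenance
  does not cross file-system boundaries.
* Dependency inference is the read-before-write assumption — coarse by
  design; it can over-approximate (a process that read a config file it
  ignored) but never under-approximates within recorded activity.
* Redirection inference at replication is a heuristic (one unnamed
  input/output per process); workflows that shuffle many anonymous streams
  per process need their driver script, which the bundle also supports
  via the wrapper process record.
* The disk cache is per-session; VDF content is regenerated across
  sessions by design.
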