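# provfs

A passthrough provenance layer for reproducible computational workflows.

Informatics analyses — a genome assembly, a phylogenetic inference, any
multi-tool pipeline — are rarely reproducible from a methods section alone:
results depend on exact software versions, command-line parameters,
reference files and intermediate data that nobody wrote down. `provfs`
addresses this at the file-system level. It observes every file operation on
a monitored directory tree **without any change to the original methods**,
and from that record it can:

* reconstruct the complete **lineage** of any file (which processes wrote
  it, what those processes read, recursively back to external inputs);
* **export** that lineage as a portable, self-contained bundle;
* **reconstruct an executable script** for the workflow — even if the
  original driver script no longer exists — and **replicate** it elsewhere,
  verifying software identity by executable checksum and the result by
  content checksum;
* render lineage as **provenance graphs** (Graphviz DOT or JSON), grouping
  files with identical read/write activity and expanding shell scripts into
  their child processes;
* serve **virtual dynamic files (VDFs)**: on-demand derived files (e.g. a
  FASTA view of every FASTQ) that appear in directory listings, are
  materialized by a configured shell command on first read, and stream
  through a two-tier block cache so several consumers can read concurrently
  while the command is still running.

## The model

Provenance is a bipartite graph of **file versions** and **processes**.
Every primitive operation is recorded as an event `(process, file version,
kind, t)`; high-throughput reads/writes are coalesced in memory (count and
byte totals preserved) and flushed to an embedded SQLite store. Lineage of a
target file is the closure of two alternating queries:

1. *writes(f, before)* — all processes that wrote file `f` before time
   `before` (unbounded for the target itself);
2. *reads(p, before)* — all files process `p` read before the time it wrote.

A write is assumed to depend on **all data the process read earlier** — a
deliberate, conservative stand-in for true dataflow analysis. The temporal
constraint keeps the closure sound: a write at time `t_w` only pulls in
reads with `t_r < t_w`, and a read at `t_r` only pulls in writes with
`t_w < t_r`. Recursion terminates at *external-origin* files: versions with
no recorded writer, whose content entered the tree from outside.

Replication re-executes the recorded command lines in dependency order
(shell wrappers whose children were captured are not re-invoked), compares
every executable's checksum against the record, and declares success iff
the produced target's checksum equals the recorded one.

## Worked example

Record a small synthetic pipeline, export its provenance, reconstruct the
script and replicate it in a clean directory:

```python
from pathlib import Path
import provfs as P
from provfs.synthetic import gen_pipeline, materialize_pipeline

td = Path("example"); (td / "data").mkdir(parents=True)
pl = gen_pipeline(n_stages=4, branching=2, seed=1)
materialize_pipeline(pl, td / "data", td / "bin")

mount = P.Mount(td / "data", db_path=str(td / "session.db"))
run = P.TracedRunner(mount).run_pipeline(pl, td / "bin")

bundle = P.export_bundle(run["target_file_key"], mount.store)
print("processes recorded:", len(bundle["processes"]))
print("file versions in lineage:", len(bundle["files"]))
print("external inputs:", [e["path"] for e in bundle["external_inputs"]])
print(P.reconstruct_script(bundle))
report = P.replicate(bundle, td / "replica",
                     inputs={e["path"]: str(td / "data" / e["path"])
                             for e in bundle["external_inputs"]})
print("environment mismatches:", report.mismatches)
print("target byte-identical:", report.target_match)
```

Output:

```
processes recorded: 4
file versions in lineage: 5
external inputs: ['inputs/in0.txt', 'inputs/in1.txt']
#!/bin/sh
# reconstructed from recorded provenance
set -e
export LC_ALL=C
mkdir -p inputs
mkdir -p work
$BIN/t_cut -d, -f1 < inputs/in0.txt > work/s0.txt
$BIN/t_cat inputs/in1.txt > work/s1.txt
$BIN/t_cat work/s0.txt work/s1.txt > work/target.txt
environment mismatches: []
target byte-identical: True
```

The four recorded processes are the driver shell plus the three stages that
causally contributed to the target (a fourth pipeline stage whose output the
target never consumed is correctly absent). The two root inputs have no
recorded writer, so they are classified external and shipped as checksummed
bundle references. `report.target_match` is the byte-exactness verdict; had
a tool been swapped for a different build, `report.mismatches` would name
exactly that executable.

The same flows are available from the shell:

```sh
provfs export work/target.txt --db session.db -o bundle.json
provfs graph bundle.json --format dot        # grouped lineage graph
provfs script bundle.json                    # reconstructed shell script
provfs verify bundle.json                    # checksum every recorded tool
provfs replicate bundle.json --workdir replica --input inputs/in0.txt=...
```

VDFs are configured in YAML; with the rule below, every `*.fastq` file gains
a readable `*.fastq.fasta` sibling materialized on first access:

```yaml
vdf_rules:
  - name: fastq_to_fasta
    source_pattern: "*.fastq"
    extension: ".fasta"
    command: "awk 'NR%4==1{sub(/^@/,\">\");print} NR%4==2{print}' {source}"
    output_channel: stdout
```

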