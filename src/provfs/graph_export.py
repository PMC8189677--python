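"""Human-oriented rendering of provenance graphs.

Two transformations keep large lineages legible, mirroring how provenance
figures are usually drawn:

* **file grouping** — files with identical reader and writer process sets
  collapse into a single counted group node (the target file is never
  absorbed into a group, so the lineage anchor stays visible);
* **process collapsing** — by default only root processes are shown; a
  script's spawned children are hidden and their file I/O is re-attached to
  the nearest visible ancestor. Individual processes can be expanded to
  reveal their children (and collapsed again, restoring the prior view).

Rendering is deterministic: nodes are ordered by stable sort keys, so the
same graph always yields byte-identical DOT/JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .lineage import ProvenanceGraph

FILE = "file"
PROCESS = "process"
FILE_GROUP = "file_group"


@dataclass(frozen=True)
class RenderedNode:
    id: str
    kind: str  # file | process | file_group
    label: str
    member_count: int = 1
    members: tuple[str, ...] = ()
    is_target: bool = False


@dataclass(frozen=True)
class RenderedEdge:
    src: str
    dst: str
    kind: str  # read | write | spawn


@dataclass
class RenderedGraph:
    nodes: list[RenderedNode]
    edges: list[RenderedEdge]
    collapsed: dict[str, tuple[str, ...]]  # visible proc -> hidden descendants
    expanded: frozenset[str] = frozenset()
    source: ProvenanceGraph | None = field(default=None, repr=False, compare=False)

    def node(self, node_id: str) -> RenderedNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)


def _children_map(g: ProvenanceGraph) -> dict[str, list[str]]:
    kids: dict[str, list[str]] = {}
    for parent, child in sorted(g.spawn_edges):
        kids.setdefault(parent, []).append(child)
    return kids


def _visible_procs(g: ProvenanceGraph, expanded: frozenset[str]) -> dict[str, str]:
    """Map every process to the visible process representing it.

    A process is visible iff every ancestor on its chain is expanded. Hidden
    processes map to their nearest visible ancestor.
    """
    parents: dict[str, str] = {c: p for p, c in g.spawn_edges}
    rep: dict[str, str] = {}
    for proc in g.proc_nodes:
        chain = [proc]
        cur = proc
        while cur in parents:
            cur = parents[cur]
            chain.append(cur)
        # walk down from the root; stop at the first non-expanded node
        visible = chain[-1]
        for node in reversed(chain[:-1]):
            if visible in expanded:
                visible = node
            else:
                break
        rep[proc] = visible
    return rep


def render(
    g: ProvenanceGraph,
    expanded: frozenset[str] | set[str] = frozenset(),
    *,
    labels: dict[str, str] | None = None,
) -> RenderedGraph:
    """Produce the grouped, collapsed rendering of a provenance graph.

    ``labels`` optionally maps node ids to display labels (e.g. command
    lines for processes, paths for files).
    """
    expanded = frozenset(expanded) & g.proc_nodes
    labels = labels or {}
    rep = _visible_procs(g, expanded)
    visible = sorted(set(rep.values()))

    # re-attach file edges from hidden children to their visible representative
    read_pairs = {(f, rep[p]) for (f, p) in g.read_edges}
    write_pairs = {(rep[p], f) for (p, f) in g.write_edges}

    # signature partition over files (reader set, writer set)
    sig: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for f in g.file_nodes:
        readers = tuple(sorted(p for (ff, p) in read_pairs if ff == f))
        writers = tuple(sorted(p for (p, ff) in write_pairs if ff == f))
        sig[f] = (readers, writers)

    groups: dict[tuple, list[str]] = {}
    for f in sorted(g.file_nodes):
        if f == g.target:
            continue  # target always rendered individually
        groups.setdefault(sig[f], []).append(f)

    node_of_file: dict[str, str] = {g.target: g.target}
    nodes: list[RenderedNode] = []
    group_serial = 0
    for s in sorted(groups):
        members = groups[s]
        if len(members) > 1:
            gid = f"group{group_serial}"
            group_serial += 1
            for m in members:
                node_of_file[m] = gid
            nodes.append(
                RenderedNode(
                    id=gid, kind=FILE_GROUP,
                    label=f"{len(members)} files",
                    member_count=len(members), members=tuple(members),
                )
            )
        else:
            (m,) = members
            node_of_file[m] = m
            nodes.append(
                RenderedNode(id=m, kind=FILE, label=labels.get(m, m), members=(m,))
            )
    nodes.append(
        RenderedNode(
            id=g.target, kind=FILE, label=labels.get(g.target, g.target),
            members=(g.target,), is_target=True,
        )
    )

    kids = _children_map(g)
    hidden_of: dict[str, list[str]] = {}
    for proc, r in rep.items():
        if proc != r:
            hidden_of.setdefault(r, []).append(proc)
    for p in visible:
        nodes.append(RenderedNode(id=p, kind=PROCESS, label=labels.get(p, p)))

    edges = set()
    for f, p in read_pairs:
        edges.add(RenderedEdge(node_of_file[f], p, "read"))
    for p, f in write_pairs:
        edges.add(RenderedEdge(p, node_of_file[f], "write"))
    for parent, child in g.spawn_edges:
        if parent in set(visible) and child in set(visible):
            edges.add(RenderedEdge(parent, child, "spawn"))

    nodes.sort(key=lambda n: (n.kind, n.id))
    collapsed = {
        p: tuple(sorted(hidden_of.get(p, ()))) for p in visible if hidden_of.get(p)
    }
    return RenderedGraph(
        nodes=nodes,
        edges=sorted(edges, key=lambda e: (e.kind, e.src, e.dst)),
        collapsed=collapsed,
        expanded=expanded,
        source=g,
    )


def group_files(g: ProvenanceGraph, **kw) -> RenderedGraph:
    """Default top-level rendering: all children collapsed, files grouped."""
    return render(g, frozenset(), **kw)


def expand_process(rg: RenderedGraph, proc_id: str) -> RenderedGraph:
    """Reveal a process's spawned children; no-op for unknown/leaf processes."""
    if rg.source is None:
        raise ValueError("rendered graph lost its source provenance graph")
    has_children = any(p == proc_id for p, _ in rg.source.spawn_edges)
    if not has_children:
        return rg
    return render(rg.source, rg.expanded | {proc_id})


def collapse_process(rg: RenderedGraph, proc_id: str) -> RenderedGraph:
    if rg.source is None:
        raise ValueError("rendered graph lost its source provenance graph")
    return render(rg.source, rg.expanded - {proc_id})


# ------------------------------------------------------------------ export
_DOT_STYLE = {
    FILE: 'shape=ellipse, color=blue, fontcolor=blue',
    FILE_GROUP: 'shape=box3d, color=blue, fontcolor=blue',
    PROCESS: 'shape=box, color=red, fontcolor=red',
}
_TARGET_STYLE = 'shape=ellipse, color=green, fontcolor=green, penwidth=2'
_EDGE_STYLE = {
    "read": 'color=black',
    "write": 'color=black, style=solid',
    "spawn": 'color=red',
}


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(rg: RenderedGraph) -> str:
    """Emit the rendering as a deterministic Graphviz digraph."""
    lines = ["digraph provenance {", "  rankdir=TB;"]
    for n in rg.nodes:
        style = _TARGET_STYLE if n.is_target else _DOT_STYLE[n.kind]
        label = n.label if n.member_count == 1 else f"{n.label}"
        lines.append(f"  {_dot_quote(n.id)} [label={_dot_quote(label)}, {style}];")
    for e in rg.edges:
        lines.append(
            f"  {_dot_quote(e.src)} -> {_dot_quote(e.dst)} [{_EDGE_STYLE[e.kind]}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_json(rg: RenderedGraph) -> str:
    """JSON mirror of the DOT structure for programmatic consumption."""
    doc = {
        "nodes": [
            {
                "id": n.id,
                "kind": n.kind,
                "label": n.label,
                "member_count": n.member_count,
                "members": list(n.members),
                "is_target": n.is_target,
            }
            for n in rg.nodes
        ],
        "edges": [{"src": e.src, "dst": e.dst, "kind": e.kind} for e in rg.edges],
        "collapsed": {k: list(v) for k, v in sorted(rg.collapsed.items())},
        "expanded": sorted(rg.expanded),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"
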