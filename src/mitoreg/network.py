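"""TF-TF regulatory network construction and vertex-sort hierarchy.

An edge u -> v means "TF u binds the promoter of the gene encoding TF v".
The hierarchy decomposition condenses strongly connected components
(SCCs), classifies each condensation supernode as top / core / bottom /
isolated, and assigns each node a level span on the condensation DAG:

* top — a source supernode (in-degree 0, out-degree > 0) that is a
  singleton without a self-loop. SCCs of size >= 2, and self-looped
  nodes, are never top: their members regulate each other (or
  themselves), so they have upstream regulators by definition.
* bottom — a sink supernode (out-degree 0, in-degree > 0).
* isolated — no edges at all.
* core — everything else (the "middle" layers of the hierarchy).

level_min is the longest path (in edges) from any source supernode;
level_max is (H - 1) minus the longest path to any sink supernode, where
H is the number of levels (longest source-to-sink path + 1). Nodes inherit
their supernode's span, so level_min <= level_max always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .genome_io import DEGTable
from .binding import BindingMatrix
from .integration import DEGClassParams, classify_table

__all__ = [
    "NodeAssignment",
    "HierarchyAssignment",
    "build_tf_network",
    "strongly_connected_components",
    "vertex_sort",
    "upstream_tfs",
    "downstream_tfs",
    "indirect_targets",
    "IndirectTargets",
]

LAYERS = ("top", "core", "bottom", "isolated")


@dataclass(frozen=True)
class NodeAssignment:
    node: str
    layer: str
    level_min: int
    level_max: int
    scc_id: int
    scc_size: int


class HierarchyAssignment:
    """Per-TF layer and level span from vertex sort."""

    def __init__(self, assignments: Iterable[NodeAssignment], n_levels: int):
        self.nodes: dict[str, NodeAssignment] = {a.node: a for a in assignments}
        self.n_levels = n_levels

    def __getitem__(self, node: str) -> NodeAssignment:
        return self.nodes[node]

    def __iter__(self):
        return iter(self.nodes.values())

    def layer_of(self, node: str) -> str:
        return self.nodes[node].layer

    def layers(self) -> dict[str, str]:
        return {n: a.layer for n, a in self.nodes.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a.node, a.layer, a.level_min, a.level_max, a.scc_id, a.scc_size)
            for a in sorted(self.nodes.values(), key=lambda a: a.node)
        ]
        return pd.DataFrame(rows, columns=["tf", "layer", "level_min", "level_max", "scc_id", "scc_size"])


def build_tf_network(matrix: BindingMatrix, tf_gene_map: Mapping[str, str]) -> nx.DiGraph:
    """Edge u -> v iff the matrix says u binds the gene encoding v.

    TFs missing from ``tf_gene_map`` (or mapped to genes outside the
    matrix universe) stay in the graph as nodes without incoming edges.
    Self-loops are recorded.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(matrix.tf_names))
    import warnings

    for v in matrix.tf_names:
        gene = tf_gene_map.get(v)
        if gene is None or gene not in matrix._gene_index:
            warnings.warn(f"TF {v}: encoding gene unknown or outside universe; node kept isolated", stacklevel=2)
            continue
        for u in matrix.tf_names:
            if matrix.is_bound(u, gene):
                graph.add_edge(u, v)
    return graph


def strongly_connected_components(graph: nx.DiGraph) -> dict[str, int]:
    """node -> scc_id; ids are assigned by sorted smallest member, so the
    labelling is deterministic for a given node set."""
    sccs = [sorted(c) for c in nx.strongly_connected_components(graph)]
    sccs.sort(key=lambda c: c[0])
    return {node: i for i, comp in enumerate(sccs) for node in comp}


def vertex_sort(graph: nx.DiGraph) -> HierarchyAssignment:
    """Decompose a TF network into top/core/bottom/isolated layers with levels."""
    scc_id = strongly_connected_components(graph)
    members: dict[int, list[str]] = {}
    for node, cid in scc_id.items():
        members.setdefault(cid, []).append(node)

    # Condensation DAG over our deterministic SCC ids (self-loops absorbed).
    dag = nx.DiGraph()
    dag.add_nodes_from(members)
    for u, v in graph.edges():
        cu, cv = scc_id[u], scc_id[v]
        if cu != cv:
            dag.add_edge(cu, cv)

    has_self_loop = {cid: any(graph.has_edge(n, n) for n in ms) for cid, ms in members.items()}

    layer: dict[int, str] = {}
    for cid in dag.nodes:
        indeg, outdeg = dag.in_degree(cid), dag.out_degree(cid)
        nontrivial = len(members[cid]) >= 2 or has_self_loop[cid]
        if indeg == 0 and outdeg == 0:
            layer[cid] = "core" if nontrivial else "isolated"
        elif indeg == 0 and not nontrivial:
            layer[cid] = "top"
        elif outdeg == 0:
            layer[cid] = "bottom"
        else:
            layer[cid] = "core"

    # Longest paths (in edges) from sources / to sinks on the DAG.
    order = list(nx.topological_sort(dag))
    from_source = {cid: 0 for cid in dag.nodes}
    for cid in order:
        for succ in dag.successors(cid):
            from_source[succ] = max(from_source[succ], from_source[cid] + 1)
    to_sink = {cid: 0 for cid in dag.nodes}
    for cid in reversed(order):
        for succ in dag.successors(cid):
            to_sink[cid] = max(to_sink[cid], to_sink[succ] + 1)
    height = max((from_source[c] + to_sink[c] for c in dag.nodes), default=0) + 1

    assignments = []
    for cid, ms in members.items():
        lmin = from_source[cid]
        lmax = (height - 1) - to_sink[cid]
        for node in ms:
            assignments.append(
                NodeAssignment(
                    node=node,
                    layer=layer[cid],
                    level_min=lmin,
                    level_max=lmax,
                    scc_id=cid,
                    scc_size=len(ms),
                )
            )
    return HierarchyAssignment(assignments, n_levels=height)


def upstream_tfs(tf: str, graph: nx.DiGraph) -> set[str]:
    """In-neighbors of a TF, excluding itself."""
    if tf not in graph:
        raise KeyError(f"unknown TF {tf!r}")
    return {u for u in graph.predecessors(tf) if u != tf}


def downstream_tfs(
    tf: str,
    graph: nx.DiGraph,
    deg: DEGTable | None = None,
    tf_gene_map: Mapping[str, str] | None = None,
    params: DEGClassParams = DEGClassParams(),
) -> set[str]:
    """Out-neighbors of a TF, excluding itself.

    With a DEG table (and the TF -> gene map) the set is restricted to TFs
    whose encoding gene is differentially expressed (class != ns) — the
    filter used when inferring which bound TFs actually respond to the
    knockout.
    """
    if tf not in graph:
        raise KeyError(f"unknown TF {tf!r}")
    down = {v for v in graph.successors(tf) if v != tf}
    if deg is None:
        return down
    if tf_gene_map is None:
        raise ValueError("tf_gene_map is required to DEG-filter downstream TFs")
    classes = classify_table(deg, params)
    return {v for v in down if classes.get(tf_gene_map.get(v, v), "ns") != "ns"}


@dataclass
class IndirectTargets:
    """Genes reachable through a TF's downstream TFs but not bound directly."""

    all_indirect: set[str]
    indirect_down: set[str]
    indirect_down_in_set: set[str]
    provenance: dict[str, list[str]]  # gene -> downstream TFs binding it
    downstream_used: set[str]


def indirect_targets(
    tf: str,
    graph: nx.DiGraph,
    matrix: BindingMatrix,
    deg: DEGTable | None = None,
    target_set=None,
    tf_gene_map: Mapping[str, str] | None = None,
    params: DEGClassParams = DEGClassParams(),
) -> IndirectTargets:
    """Genes bound by a TF's (DEG-filtered) downstream TFs but not by the TF.

    The focal TF's own encoding gene is excluded — the knocked-out locus
    is not a regulatory target of the perturbation. ``indirect_down``
    intersects with down-regulated DEGs, ``indirect_down_in_set`` further
    with a gene set (e.g. the mitochondrial inventory).
    """
    if tf not in matrix.tf_names:
        raise KeyError(f"TF {tf!r} not in binding matrix")
    down = downstream_tfs(tf, graph, deg=deg, tf_gene_map=tf_gene_map, params=params)
    own_gene = (tf_gene_map or {}).get(tf)
    direct = matrix.targets_of(tf)
    provenance: dict[str, list[str]] = {}
    for d in sorted(down):
        if d not in matrix.tf_names:
            continue
        for gene in matrix.targets_of(d):
            if gene in direct or gene == own_gene:
                continue
            provenance.setdefault(gene, []).append(d)
    all_indirect = set(provenance)
    if deg is not None:
        classes = classify_table(deg, params)
        indirect_down = {g for g in all_indirect if classes.get(g, "ns") == "down"}
    else:
        indirect_down = set()
    indirect_down_in_set = indirect_down & set(target_set.genes) if target_set is not None else set()
    return IndirectTargets(
        all_indirect=all_indirect,
        indirect_down=indirect_down,
        indirect_down_in_set=indirect_down_in_set,
        provenance=provenance,
        downstream_used=down,
    )


def write_edge_list(graph: nx.DiGraph, path) -> None:
    rows = sorted(graph.edges())
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


def write_dot(graph: nx.DiGraph, hierarchy: HierarchyAssignment, path) -> None:
    """Minimal DOT export with the layer as a node attribute."""
    with open(path, "w") as fh:
        fh.write("digraph tf_network {\n")
        for node in sorted(graph.nodes):
            fh.write(f'  "{node}" [layer="{hierarchy.layer_of(node)}"];\n')
        for u, v in sorted(graph.edges):
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")
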