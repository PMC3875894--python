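"""Directed weighted pathway-to-pathway network induced by detected loops.

An edge P1 -> P2 means a loop generated from P1 has its antagonist gene
(PAG) inside P2; the weight counts the distinct loops linking the pair.  A
PAG found in k input pathways contributes to k edges; a PAG found in none
increments the source pathway's ``orphan_pag_count`` (each distinct orphan
gene counted once).  Nodes that neither generate loops nor host PAGs are
omitted.  Node kinds follow the drawing convention of the source analysis:
``ppl_source`` (hexagonal) for pathways generating at least one loop,
``pag_only`` (rhomboidal) for pathways that merely contain PAGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .pathways import Pathway
from .ppl_finder import PPLRecord


@dataclass(frozen=True)
class NetworkStats:
    n_ppl_source: int
    n_pag_only: int
    n_edges: int
    total_weight: int
    n_self_edges: int
    mean_out_neighbors: float
    mean_neighbors: float  # in- or out-neighbors, self excluded once
    is_empty: bool


def build_network(ppls: list[PPLRecord], pathways: list[Pathway]) -> nx.DiGraph:
    """Build the loop-induced pathway graph.

    Raises if a loop references a pathway id absent from ``pathways``.
    """
    known = {p.pathway_id for p in pathways}
    membership: dict[str, set[str]] = {}
    for p in pathways:
        for g in p.gene_ids:
            membership.setdefault(g, set()).add(p.pathway_id)

    graph = nx.DiGraph()
    orphans: dict[str, set[str]] = {}
    for loop in ppls:
        if loop.pathway_id not in known:
            raise ValueError(f"loop references unknown pathway {loop.pathway_id!r}")
        src = loop.pathway_id
        if src not in graph:
            graph.add_node(src, kind="ppl_source", orphan_pag_count=0)
        else:
            graph.nodes[src]["kind"] = "ppl_source"
        containers = membership.get(loop.pag_gene_id, set())
        if not containers:
            orphans.setdefault(src, set()).add(loop.pag_gene_id)
            continue
        for tgt in containers:
            if tgt not in graph:
                graph.add_node(tgt, kind="pag_only", orphan_pag_count=0)
            if graph.has_edge(src, tgt):
                graph[src][tgt]["weight"] += 1
            else:
                graph.add_edge(src, tgt, weight=1)
    for src, genes in orphans.items():
        graph.nodes[src]["orphan_pag_count"] = len(genes)
    return graph


def network_stats(graph: nx.DiGraph) -> NetworkStats:
    """Summary counts; the mean connectivity of loop-generating pathways is
    reported both as out-neighbors only and as total distinct neighbors."""
    sources = [n for n, d in graph.nodes(data=True) if d.get("kind") == "ppl_source"]
    pag_only = [n for n, d in graph.nodes(data=True) if d.get("kind") == "pag_only"]
    n_edges = graph.number_of_edges()
    total_weight = sum(w for _, _, w in graph.edges(data="weight"))
    n_self = sum(1 for u, v in graph.edges() if u == v)
    if sources:
        out_mean = sum(
            len({v for v in graph.successors(n)}) for n in sources
        ) / len(sources)
        all_mean = sum(
            len((set(graph.successors(n)) | set(graph.predecessors(n))) - {n})
            for n in sources
        ) / len(sources)
    else:
        out_mean = 0.0
        all_mean = 0.0
    return NetworkStats(
        n_ppl_source=len(sources),
        n_pag_only=len(pag_only),
        n_edges=n_edges,
        total_weight=total_weight,
        n_self_edges=n_self,
        mean_out_neighbors=out_mean,
        mean_neighbors=all_mean,
        is_empty=graph.number_of_nodes() == 0,
    )


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    lines = ["digraph pathway_network {"]
    for n, d in sorted(graph.nodes(data=True)):
        shape = "hexagon" if d.get("kind") == "ppl_source" else "diamond"
        lines.append(
            f'  "{n}" [kind="{d.get("kind", "")}" shape={shape} '
            f'orphan_pag_count={d.get("orphan_pag_count", 0)}];'
        )
    for u, v, w in sorted(graph.edges(data="weight")):
        lines.append(f'  "{u}" -> "{v}" [weight={w}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_tsv(graph: nx.DiGraph, path: Path) -> None:
    """Edge list plus a node-list companion file (``<stem>.nodes.tsv``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w}\n")
    nodes_path = path.with_suffix(".nodes.tsv")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tkind\torphan_pag_count\n")
        for n, d in sorted(graph.nodes(data=True)):
            fh.write(f"{n}\t{d.get('kind', '')}\t{d.get('orphan_pag_count', 0)}\n")


def read_tsv(path: str | Path) -> nx.DiGraph:
    """Rebuild a graph from the TSV edge/node pair written by export_graph."""
    path = Path(path)
    graph = nx.DiGraph()
    nodes_path = path.with_suffix(".nodes.tsv")
    with open(nodes_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            n, kind, orphan = line.rstrip("\n").split("\t")
            graph.add_node(n, kind=kind, orphan_pag_count=int(orphan))
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            graph.add_edge(u, v, weight=int(w))
    return graph


def export_graph(graph: nx.DiGraph, path: str | Path, fmt: str) -> None:
    """Write the graph as ``dot``, ``graphml`` or ``tsv``.

    TSV round-trips losslessly via :func:`read_tsv`; DOT and GraphML carry
    the kind, weight and orphan_pag_count attributes.
    """
    path = Path(path)
    if fmt == "dot":
        _write_dot(graph, path)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        _write_tsv(graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
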