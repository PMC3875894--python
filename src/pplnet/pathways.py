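"""Pathway gene sets with group labels and non-gene (metabolite) nodes.

File dialect (one pathway per line, tab-separated, GMT-like)::

    pathway_id <TAB> name <TAB> group <TAB> kind:identifier [<TAB> ...]

Node tokens are ``gene:<gene_id>`` or ``met:<label>``.  Groups are
``metabolic``, ``non_metabolic`` or ``random``; metabolic pathways are rich
in metabolite nodes, which cannot host miRNAs and are skipped by every
coordinate query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

VALID_GROUPS = ("metabolic", "non_metabolic", "random")


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayNode:
    node_kind: str  # "gene" | "non_gene"
    label: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.node_kind == "gene" and not self.gene_id:
            raise PathwayError("gene node requires a gene_id")
        if self.node_kind == "non_gene" and self.gene_id is not None:
            raise PathwayError("non_gene node must not carry a gene_id")
        if self.node_kind not in ("gene", "non_gene"):
            raise PathwayError(f"unknown node kind {self.node_kind!r}")


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    group: str
    nodes: tuple[PathwayNode, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise PathwayError(
                f"{self.pathway_id}: group must be one of {VALID_GROUPS}, "
                f"got {self.group!r}"
            )
        gene_ids = [n.gene_id for n in self.nodes if n.node_kind == "gene"]
        if len(gene_ids) != len(set(gene_ids)):
            raise PathwayError(f"{self.pathway_id}: duplicate gene ids")

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(
            n.gene_id for n in self.nodes if n.node_kind == "gene" and n.gene_id
        )

    @property
    def n_non_gene(self) -> int:
        return sum(1 for n in self.nodes if n.node_kind == "non_gene")


def _parse_token(token: str, pathway_id: str) -> PathwayNode:
    kind, _, ident = token.partition(":")
    if not ident:
        raise PathwayError(f"{pathway_id}: malformed node token {token!r}")
    if kind == "gene":
        return PathwayNode(node_kind="gene", label=ident, gene_id=ident)
    if kind == "met":
        return PathwayNode(node_kind="non_gene", label=ident)
    raise PathwayError(f"{pathway_id}: unknown node token kind {kind!r}")


def load_pathways(path: str | Path) -> list[Pathway]:
    """Parse a pathway file; duplicate pathway ids are an error."""
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PathwayError(f"{path}, line {lineno}: expected >= 3 fields")
            pid, name, group, *tokens = parts
            if pid in seen:
                raise PathwayError(
                    f"{path}, line {lineno}: duplicate pathway_id {pid!r}"
                )
            seen.add(pid)
            nodes = tuple(_parse_token(t, pid) for t in tokens if t)
            pathways.append(Pathway(pathway_id=pid, name=name, group=group, nodes=nodes))
    return pathways


def write_pathways(pathways: Iterable[Pathway], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            tokens = [
                f"gene:{n.gene_id}" if n.node_kind == "gene" else f"met:{n.label}"
                for n in pw.nodes
            ]
            fh.write("\t".join([pw.pathway_id, pw.name, pw.group, *tokens]) + "\n")
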