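"""Five-step pathway protection loop (PPL) search.

For a pathway P the finder enumerates every distinct 5-tuple
``(host gene g, intragenic miRNA m, PATF t, PAG h, antagonist miRNA a)``
satisfying:

1. g is a gene node of P and hosts the intragenic miRNA m;
2. m has a filtered target prediction onto t (the PATF);
3. t is a transcription factor of h (the PAG);
4. h hosts the antagonist miRNA a;
5. a has a filtered target prediction onto at least one gene of P
   (those genes are the loop's *protected* genes).

Direct targeting of pathway genes by the pathway's own intragenic miRNAs is
intra-pathway regulation and is not itself a loop; it is counted only when
the full five-step chain closes.  The protected-gene set is an attribute of
the loop, not part of its identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .knowledge_base import (
    KnowledgeBase,
    find_host_genes,
    find_intragenic_mirnas,
    get_targets,
    get_tfs,
)
from .pathways import Pathway


@dataclass(frozen=True)
class PPLRecord:
    """One detected loop; identity is the 5-tuple of actors."""

    pathway_id: str
    host_gene_id: str
    intragenic_mirna: str
    patf_gene_id: str
    pag_gene_id: str
    antagonist_mirna: str
    protected_gene_ids: frozenset[str] = field(default_factory=frozenset)
    is_intra_pathway: bool = False  # PAG is itself a gene of the pathway
    is_degenerate: bool = False  # antagonist miRNA == intragenic miRNA

    @property
    def actor_tuple(self) -> tuple[str, str, str, str, str, str]:
        return (
            self.pathway_id,
            self.host_gene_id,
            self.intragenic_mirna,
            self.patf_gene_id,
            self.pag_gene_id,
            self.antagonist_mirna,
        )


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    group: str
    n_loops: int

    @property
    def has_loop(self) -> bool:
        return self.n_loops >= 1


def pathway_gene_set(pathway: Pathway) -> frozenset[str]:
    """Gene ids of the pathway's gene nodes (metabolite nodes dropped)."""
    return pathway.gene_ids


def find_antagonist_mirnas(
    pathway: Pathway, threshold: float, kb: KnowledgeBase
) -> dict[str, frozenset[str]]:
    """Map each miRNA with a filtered prediction onto a pathway gene to the
    set of pathway genes it protects (i.e. would down-regulate)."""
    genes = pathway_gene_set(pathway)
    # route through get_targets so one code path owns the mirSVR rule
    out: dict[str, frozenset[str]] = {}
    for mirna_name in kb._targets_by_mirna:
        protected = {
            p.target_gene_id
            for p in get_targets(mirna_name, threshold, kb)
            if p.target_gene_id in genes
        }
        if protected:
            out[mirna_name] = frozenset(protected)
    return out


def find_ppls(
    pathway: Pathway,
    threshold: float,
    kb: KnowledgeBase,
    exclude_intra_pathway: bool = False,
) -> list[PPLRecord]:
    """Enumerate all loops of ``pathway``, sorted by actor tuple.

    ``exclude_intra_pathway`` drops loops whose PAG is itself a pathway
    gene; by default they are kept and flagged.
    """
    genes = pathway_gene_set(pathway)
    antagonists = find_antagonist_mirnas(pathway, threshold, kb)
    if not antagonists:
        return []

    # candidate (PATF, PAG, antagonist) triples: antagonist's host is the
    # PAG, and the PATF must regulate that PAG
    patf_to_pag_ant: dict[str, list[tuple[str, str]]] = {}
    for ant, _protected in antagonists.items():
        mirna = kb.mirnas.get(ant)
        if mirna is None:
            continue
        for host in find_host_genes(mirna, kb):
            for tf in get_tfs(host.gene_id, kb):
                patf_to_pag_ant.setdefault(tf, []).append((host.gene_id, ant))
    if not patf_to_pag_ant:
        return []

    records: list[PPLRecord] = []
    for gene_id in sorted(genes):
        gene = kb.genes.get(gene_id)
        if gene is None:
            continue
        for mirna in find_intragenic_mirnas(gene, kb):
            for pred in get_targets(mirna.mirna_name, threshold, kb):
                patf = pred.target_gene_id
                for pag, ant in patf_to_pag_ant.get(patf, ()):
                    intra = pag in genes
                    if exclude_intra_pathway and intra:
                        continue
                    records.append(
                        PPLRecord(
                            pathway_id=pathway.pathway_id,
                            host_gene_id=gene_id,
                            intragenic_mirna=mirna.mirna_name,
                            patf_gene_id=patf,
                            pag_gene_id=pag,
                            antagonist_mirna=ant,
                            protected_gene_ids=antagonists[ant],
                            is_intra_pathway=intra,
                            is_degenerate=ant == mirna.mirna_name,
                        )
                    )
    # duplicates can arise when the same prediction row exists in both
    # conservation classes; collapse on actor identity
    unique = {r.actor_tuple: r for r in records}
    return [unique[key] for key in sorted(unique)]


def analyze_all(
    pathways: list[Pathway],
    threshold: float,
    kb: KnowledgeBase,
    exclude_intra_pathway: bool = False,
) -> tuple[list[PathwayResult], list[PPLRecord]]:
    """Run the loop search over every pathway.

    Returns one :class:`PathwayResult` per pathway (input order) and the
    concatenated loop list.  Deterministic given identical inputs.
    """
    ids = [p.pathway_id for p in pathways]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate pathway_id in input")
    results: list[PathwayResult] = []
    loops: list[PPLRecord] = []
    for pw in pathways:
        found = find_ppls(pw, threshold, kb, exclude_intra_pathway)
        results.append(
            PathwayResult(pathway_id=pw.pathway_id, group=pw.group, n_loops=len(found))
        )
        loops.extend(found)
    return results, loops


def write_loops_tsv(loops: list[PPLRecord], path) -> None:
    """One row per loop: the five actors, protected genes, flags."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "pathway_id\thost_gene_id\tintragenic_mirna\tpatf_gene_id\t"
            "pag_gene_id\tantagonist_mirna\tprotected_gene_ids\t"
            "is_intra_pathway\tis_degenerate\n"
        )
        for r in loops:
            fh.write(
                "\t".join(
                    [
                        r.pathway_id,
                        r.host_gene_id,
                        r.intragenic_mirna,
                        r.patf_gene_id,
                        r.pag_gene_id,
                        r.antagonist_mirna,
                        ";".join(sorted(r.protected_gene_ids)),
                        str(int(r.is_intra_pathway)),
                        str(int(r.is_degenerate)),
                    ]
                )
                + "\n"
            )


def loops_to_dot(loops: list[PPLRecord], pathway_id: str) -> str:
    """Render one pathway's loops as a DOT digraph (actors as nodes,
    regulatory steps as edges)."""
    lines = [f'digraph "{pathway_id}" {{']
    seen: set[str] = set()

    def edge(a: str, b: str, label: str) -> None:
        key = f'"{a}" -> "{b}" [label="{label}"];'
        if key not in seen:
            seen.add(key)
            lines.append(f"  {key}")

    for r in loops:
        if r.pathway_id != pathway_id:
            continue
        edge(r.host_gene_id, r.intragenic_mirna, "hosts")
        edge(r.intragenic_mirna, r.patf_gene_id, "silences")
        edge(r.patf_gene_id, r.pag_gene_id, "activates")
        edge(r.pag_gene_id, r.antagonist_mirna, "hosts")
        for g in sorted(r.protected_gene_ids):
            edge(r.antagonist_mirna, g, "targets")
    lines.append("}")
    return "\n".join(lines) + "\n"
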