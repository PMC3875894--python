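"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's indexed query paths: they
scan the raw record collections so that equivalence tests compare two
independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest

from pplnet.knowledge_base import (
    GeneRecord,
    GenomicInterval,
    KnowledgeBase,
    MirnaRecord,
    TargetPrediction,
    TFRelation,
    build_knowledge_base,
)
from pplnet.pathways import Pathway, PathwayNode
from pplnet.synthetic_data import SynthConfig, generate

GOOD = {"good_conserved", "good_nonconserved"}


def interval(chrom="chr1", start=1, end=100, strand="+"):
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)


def gene(gene_id, chrom="chr1", start=1, end=100, strand="+", symbol=None):
    return GeneRecord(
        gene_id=gene_id,
        symbol=symbol or gene_id.upper(),
        location=interval(chrom, start, end, strand),
    )


def mirna(name, chrom="chr1", start=1, end=80, strand="+"):
    return MirnaRecord(mirna_name=name, location=interval(chrom, start, end, strand))


def prediction(mirna_name, gene_id, score=-0.7, conservation="good_conserved"):
    return TargetPrediction(
        mirna_name=mirna_name,
        target_gene_id=gene_id,
        mirsvr_score=score,
        conservation_class=conservation,
    )


def tf_relation(tf, target, source="targetmine"):
    return TFRelation(tf_gene_id=tf, target_gene_id=target, source=source)


def gene_pathway(pathway_id, gene_ids, group="non_metabolic", mets=()):
    nodes = [PathwayNode(node_kind="gene", label=g, gene_id=g) for g in gene_ids]
    nodes += [PathwayNode(node_kind="non_gene", label=m) for m in mets]
    return Pathway(
        pathway_id=pathway_id,
        name=pathway_id,
        group=group,
        nodes=tuple(nodes),
    )


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """Strand-blind both-ends containment, written independently."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def filtered_targets_scan(kb: KnowledgeBase, mirna_name: str, threshold: float):
    """Linear-scan version of the mirSVR filter."""
    return {
        p.target_gene_id
        for p in kb.targets
        if p.mirna_name == mirna_name
        and p.conservation_class in GOOD
        and p.mirsvr_score < threshold
    }


def brute_force_ppls(pathway: Pathway, threshold: float, kb: KnowledgeBase):
    """Exhaustive enumeration of all (g, m, t, h, a) tuples satisfying the
    five loop predicates; the independent oracle for find_ppls."""
    genes = pathway.gene_ids
    antagonists = {}
    for a in kb.mirnas.values():
        protected = filtered_targets_scan(kb, a.mirna_name, threshold) & genes
        if protected:
            antagonists[a.mirna_name] = frozenset(protected)
    tf_pairs = {(r.tf_gene_id, r.target_gene_id) for r in kb.tf_relations}
    tuples = set()
    for g in genes:
        grec = kb.genes.get(g)
        if grec is None:
            continue
        for m in kb.mirnas.values():
            if not contains(grec.location, m.location):
                continue
            for t in filtered_targets_scan(kb, m.mirna_name, threshold):
                for h in kb.genes.values():
                    if (t, h.gene_id) not in tf_pairs:
                        continue
                    for a_name in antagonists:
                        if contains(h.location, kb.mirnas[a_name].location):
                            tuples.add(
                                (
                                    pathway.pathway_id,
                                    g,
                                    m.mirna_name,
                                    t,
                                    h.gene_id,
                                    a_name,
                                )
                            )
    return tuples


def random_kb(rng: np.random.Generator, n_genes=10, n_mirnas=8, n_preds=20, n_tfs=10):
    """Small random knowledge base; genes may overlap (unlike the synthetic
    generator's layout) to stress the containment queries."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(1, 2000))
        length = int(rng.integers(50, 1500))
        genes.append(
            gene(
                f"g{i}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    mirnas = []
    for i in range(n_mirnas):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(1, 3200))
        length = int(rng.integers(20, 120))
        mirnas.append(
            mirna(
                f"m{i}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    preds = set()
    while len(preds) < n_preds:
        preds.add(
            (
                f"m{rng.integers(n_mirnas)}",
                f"g{rng.integers(n_genes)}",
                round(float(-rng.exponential(0.4)), 4),
                ["good_conserved", "good_nonconserved", "other"][rng.integers(3)],
            )
        )
    tfs = set()
    while len(tfs) < n_tfs:
        tfs.add(
            (
                f"g{rng.integers(n_genes)}",
                f"g{rng.integers(n_genes)}",
                ["targetmine", "tfe"][rng.integers(2)],
            )
        )
    return build_knowledge_base(
        genes,
        mirnas,
        [prediction(m, g, s, c) for m, g, s, c in preds],
        [tf_relation(a, b, s) for a, b, s in tfs],
    )


SMALL_SYNTH = SynthConfig(
    seed=11,
    n_genes=400,
    n_mirnas=60,
    n_target_predictions=800,
    n_tf_relations=150,
    n_metabolic=6,
    n_non_metabolic=6,
    pathway_size_mean=8.0,
    pathway_size_sd=2.0,
    n_planted_loops=5,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SMALL_SYNTH)
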