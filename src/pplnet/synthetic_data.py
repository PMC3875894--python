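"""Synthetic knowledge bases and pathway sets with planted loops.

The generator emulates the statistical shape of the real inputs: a genome
of non-overlapping genes laid out per chromosome, roughly half of all
miRNAs intragenic, target predictions with negatively skewed mirSVR scores
and mostly "good" conservation labels, sparse TF fan-out, and pathway gene
counts drawn from a Normal.  Metabolic-group pathways receive a majority of
non-gene (metabolite) nodes, mirroring why that group rarely hosts loops.

Planted loops use dedicated genes and miRNAs so each one satisfies the five
finder predicates by construction.  With ``background_closure_guard`` on,
the gene-identifier space is partitioned into roles (pathway-eligible
genes, background TFs, background TF targets) and pathway gene sets are
kept disjoint, so background prediction and TF rows can never complete all
five predicates: the finder must then recover exactly the planted loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .knowledge_base import (
    GeneRecord,
    GenomicInterval,
    KnowledgeBase,
    MirnaRecord,
    TargetPrediction,
    TFRelation,
    build_knowledge_base,
)
from .pathways import Pathway, PathwayNode, write_pathways
from .ppl_finder import PPLRecord


@dataclass
class SynthConfig:
    """Generation parameters; defaults mirror the study conditions of the
    source analysis at desk scale (group sizes 107 metabolic / 51
    non-metabolic, half of miRNAs intragenic) — see docs/methods.md."""

    seed: int = 0
    n_chromosomes: int = 5
    n_genes: int = 8000
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    intergenic_gap_range: tuple[int, int] = (1_000, 20_000)
    n_mirnas: int = 600
    frac_intragenic: float = 0.5
    n_target_predictions: int = 20_000
    mirsvr_scale: float = 0.3  # exponential scale of -score, truncated at -1.5
    frac_good_conservation: float = 0.7
    n_tf_relations: int = 3_000
    n_metabolic: int = 107
    n_non_metabolic: int = 51
    pathway_size_mean: float = 35.0
    pathway_size_sd: float = 15.0
    metabolic_non_gene_frac: float = 0.6
    non_metabolic_non_gene_frac: float = 0.1
    n_planted_loops: int = 40
    loop_group_weights: dict[str, float] = field(
        default_factory=lambda: {"metabolic": 0.2, "non_metabolic": 0.8}
    )
    background_closure_guard: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_intragenic <= 1.0:
            raise ValueError("frac_intragenic must be in [0, 1]")
        for name in (
            "n_chromosomes",
            "n_genes",
            "n_mirnas",
            "n_target_predictions",
            "n_tf_relations",
            "n_metabolic",
            "n_non_metabolic",
            "n_planted_loops",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted loops and the loop count each pathway must show."""

    loops: list[PPLRecord] = field(default_factory=list)
    expected_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    kb: KnowledgeBase
    pathways: list[Pathway]
    ground_truth: GroundTruth
    config: SynthConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the five TSV tables consumed by the loaders."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "mirnas": outdir / "mirnas.tsv",
            "targets": outdir / "targets.tsv",
            "tf_relations": outdir / "tf_relations.tsv",
            "pathways": outdir / "pathways.tsv",
        }
        with open(paths["genes"], "w", encoding="utf-8") as fh:
            fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\n")
            for g in self.kb.genes.values():
                loc = g.location
                fh.write(
                    f"{g.gene_id}\t{g.symbol}\t{loc.chrom}\t{loc.start}\t"
                    f"{loc.end}\t{loc.strand}\n"
                )
        with open(paths["mirnas"], "w", encoding="utf-8") as fh:
            fh.write("mirna_name\tchrom\tstart\tend\tstrand\n")
            for m in self.kb.mirnas.values():
                loc = m.location
                fh.write(
                    f"{m.mirna_name}\t{loc.chrom}\t{loc.start}\t{loc.end}\t"
                    f"{loc.strand}\n"
                )
        with open(paths["targets"], "w", encoding="utf-8") as fh:
            fh.write("mirna_name\tgene_id\tmirsvr_score\tconservation_class\n")
            for t in self.kb.targets:
                fh.write(
                    f"{t.mirna_name}\t{t.target_gene_id}\t{t.mirsvr_score:.6f}\t"
                    f"{t.conservation_class}\n"
                )
        with open(paths["tf_relations"], "w", encoding="utf-8") as fh:
            fh.write("tf_gene_id\ttarget_gene_id\tsource\n")
            for r in self.kb.tf_relations:
                fh.write(f"{r.tf_gene_id}\t{r.target_gene_id}\t{r.source}\n")
        write_pathways(self.pathways, paths["pathways"])
        return paths


class SyntheticBuilder:
    """Mutable accumulator for records; tracks per-chromosome append
    cursors so planted genes never overlap the background layout."""

    def __init__(self, config: SynthConfig):
        self.config = config
        self.genes: dict[str, GeneRecord] = {}
        self.mirnas: dict[str, MirnaRecord] = {}
        self.targets: list[TargetPrediction] = []
        self.target_keys: set[tuple[str, str, str]] = set()
        self.tf_relations: list[TFRelation] = []
        self.tf_keys: set[tuple[str, str, str]] = set()
        self.chrom_cursor: dict[str, int] = {}
        self.gaps: list[tuple[str, int, int]] = []  # intergenic slots
        self.n_planted = 0

    def add_target(
        self, mirna: str, gene: str, score: float, conservation: str
    ) -> bool:
        key = (mirna, gene, conservation)
        if key in self.target_keys:
            return False
        self.target_keys.add(key)
        self.targets.append(
            TargetPrediction(
                mirna_name=mirna,
                target_gene_id=gene,
                mirsvr_score=score,
                conservation_class=conservation,
            )
        )
        return True

    def add_tf_relation(self, tf: str, target: str, source: str) -> bool:
        key = (tf, target, source)
        if key in self.tf_keys:
            return False
        self.tf_keys.add(key)
        self.tf_relations.append(
            TFRelation(tf_gene_id=tf, target_gene_id=target, source=source)
        )
        return True

    def append_gene(self, rng: np.random.Generator, prefix: str) -> GeneRecord:
        """Place a fresh gene at a chromosome tail, beyond everything laid
        out so far."""
        chrom = f"chr{rng.integers(1, self.config.n_chromosomes + 1)}"
        lo, hi = self.config.gene_length_range
        length = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(*self.config.intergenic_gap_range))
        start = self.chrom_cursor[chrom] + gap
        end = start + length - 1
        self.chrom_cursor[chrom] = end + 1
        gene_id = f"{prefix}{len(self.genes) + 1:05d}"
        rec = GeneRecord(
            gene_id=gene_id,
            symbol=gene_id.upper(),
            location=GenomicInterval(
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
            ),
        )
        self.genes[gene_id] = rec
        return rec

    def place_mirna_inside(
        self, rng: np.random.Generator, host: GeneRecord, name: str
    ) -> MirnaRecord:
        loc = host.location
        length = int(rng.integers(60, 121))
        start = int(rng.integers(loc.start, loc.end - length + 1))
        rec = MirnaRecord(
            mirna_name=name,
            location=GenomicInterval(
                chrom=loc.chrom,
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            ),
        )
        self.mirnas[name] = rec
        return rec


def _draw_score(rng: np.random.Generator, scale: float) -> float:
    """Negatively skewed mirSVR score: minus an exponential, truncated to
    [-1.5, 0]."""
    return -float(min(rng.exponential(scale), 1.5))


def _layout_genome(builder: SyntheticBuilder, rng: np.random.Generator) -> None:
    cfg = builder.config
    chroms = [f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)]
    builder.chrom_cursor = {c: 1 for c in chroms}
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        lo, hi = cfg.gene_length_range
        length = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        gap_start = builder.chrom_cursor[chrom]
        start = gap_start + gap
        end = start + length - 1
        if gap > 200:  # usable intergenic slot, clear of both gene ends
            builder.gaps.append((chrom, gap_start + 10, start - 10))
        builder.chrom_cursor[chrom] = end + 1
        gene_id = f"g{i + 1:05d}"
        builder.genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            symbol=f"SYN{i + 1}",
            location=GenomicInterval(
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
            ),
        )


def _partition_roles(
    config: SynthConfig, gene_ids: list[str]
) -> tuple[list[str], list[str], list[str]]:
    """Split background genes into (pathway-eligible, background-TF,
    background-TF-target) roles; the guard relies on the split being
    disjoint."""
    n = len(gene_ids)
    n_tf = max(1, n // 10)
    n_tf_target = max(1, n // 10)
    eligible = gene_ids[: n - n_tf - n_tf_target]
    tf_pool = gene_ids[n - n_tf - n_tf_target : n - n_tf_target]
    tf_target_pool = gene_ids[n - n_tf_target :]
    return eligible, tf_pool, tf_target_pool


def plant_ppl(
    builder: SyntheticBuilder, pathway: Pathway, rng: np.random.Generator
) -> PPLRecord:
    """Insert one loop into ``pathway`` using dedicated actors.

    A fresh intragenic miRNA goes into an existing pathway gene; a fresh
    PATF gene, a TF relation onto a fresh PAG gene, a fresh antagonist
    miRNA inside the PAG, and predictions (scores below -0.6, good
    conservation) close the chain.  The loop therefore survives both the
    -0.3 and the -0.6 mirSVR thresholds.
    """
    genes = sorted(pathway.gene_ids)
    if len(genes) < 2:
        raise ValueError(
            f"{pathway.pathway_id}: planting requires >= 2 gene nodes"
        )
    builder.n_planted += 1
    idx = builder.n_planted
    host_id = str(rng.choice(genes))
    host = builder.genes[host_id]
    intragenic = builder.place_mirna_inside(rng, host, f"mirp-{idx:04d}i")
    patf = builder.append_gene(rng, "tfp")
    pag = builder.append_gene(rng, "pag")
    antagonist = builder.place_mirna_inside(rng, pag, f"mirp-{idx:04d}a")

    def planted_score() -> float:
        return float(rng.uniform(-1.0, -0.65))

    builder.add_target(
        intragenic.mirna_name, patf.gene_id, planted_score(), "good_conserved"
    )
    builder.add_tf_relation(patf.gene_id, pag.gene_id, "synthetic")
    n_protected = int(rng.integers(1, min(3, len(genes)) + 1))
    protected = [
        str(g) for g in rng.choice(genes, size=n_protected, replace=False)
    ]
    for g in protected:
        builder.add_target(
            antagonist.mirna_name, g, planted_score(), "good_conserved"
        )
    return PPLRecord(
        pathway_id=pathway.pathway_id,
        host_gene_id=host_id,
        intragenic_mirna=intragenic.mirna_name,
        patf_gene_id=patf.gene_id,
        pag_gene_id=pag.gene_id,
        antagonist_mirna=antagonist.mirna_name,
        protected_gene_ids=frozenset(protected),
        is_intra_pathway=False,
        is_degenerate=False,
    )


def _draw_pathway_sizes(
    rng: np.random.Generator, n: int, mean: float, sd: float, cap: int
) -> list[int]:
    sizes = []
    for _ in range(n):
        while True:
            s = int(round(rng.normal(mean, sd)))
            if 2 <= s <= cap:
                sizes.append(s)
                break
    return sizes


def generate(config: SynthConfig) -> SyntheticDataset:
    """Build a full synthetic dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    builder = SyntheticBuilder(config)
    _layout_genome(builder, rng)
    background_gene_ids = sorted(builder.genes)
    eligible, tf_pool, tf_target_pool = _partition_roles(
        config, background_gene_ids
    )
    guard = config.background_closure_guard

    # --- background miRNAs -------------------------------------------------
    n_intra = int(round(config.n_mirnas * config.frac_intragenic))
    host_pool = eligible if guard else background_gene_ids
    for i in range(config.n_mirnas):
        name = f"mir-{i + 1:04d}"
        if i < n_intra:
            host = builder.genes[str(rng.choice(host_pool))]
            builder.place_mirna_inside(rng, host, name)
        else:
            chrom, lo, hi = builder.gaps[int(rng.integers(len(builder.gaps)))]
            length = int(rng.integers(60, 121))
            if hi - lo < length:
                length = max(1, hi - lo)
            start = int(rng.integers(lo, max(lo, hi - length) + 1))
            builder.mirnas[name] = MirnaRecord(
                mirna_name=name,
                location=GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=start + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                ),
            )

    # --- background target predictions ------------------------------------
    mirna_names = sorted(builder.mirnas)
    pred_target_pool = eligible if guard else background_gene_ids
    attempts = 0
    added = 0
    max_attempts = config.n_target_predictions * 20 + 100
    while added < config.n_target_predictions and attempts < max_attempts:
        attempts += 1
        mirna = str(rng.choice(mirna_names))
        gene = str(rng.choice(pred_target_pool))
        u = rng.random()
        if u < config.frac_good_conservation:
            conservation = (
                "good_conserved" if rng.random() < 0.5 else "good_nonconserved"
            )
        else:
            conservation = "other"
        if builder.add_target(
            mirna, gene, _draw_score(rng, config.mirsvr_scale), conservation
        ):
            added += 1

    # --- background TF relations (sparse fan-out) --------------------------
    tf_src_pool = tf_pool if guard else background_gene_ids
    tf_tgt_pool = tf_target_pool if guard else background_gene_ids
    attempts = 0
    added = 0
    max_attempts = config.n_tf_relations * 20 + 100
    while added < config.n_tf_relations and attempts < max_attempts:
        attempts += 1
        tf = str(rng.choice(tf_src_pool))
        target = str(rng.choice(tf_tgt_pool))
        source = "targetmine" if rng.random() < 0.5 else "tfe"
        if builder.add_tf_relation(tf, target, source):
            added += 1

    # --- pathways ----------------------------------------------------------
    specs = [("metabolic", config.n_metabolic), ("non_metabolic", config.n_non_metabolic)]
    total = sum(n for _, n in specs)
    sizes = _draw_pathway_sizes(
        rng,
        total,
        config.pathway_size_mean,
        config.pathway_size_sd,
        cap=len(eligible),
    )
    if guard and sum(sizes) > len(eligible):
        raise ValueError(
            "gene universe too small for disjoint pathway gene sets; "
            "increase n_genes or reduce pathway count/size"
        )
    pool = list(eligible)
    if guard:
        pool = [str(g) for g in rng.permutation(eligible)]
    pathways: list[Pathway] = []
    cursor = 0
    k = 0
    for group, count in specs:
        frac = (
            config.metabolic_non_gene_frac
            if group == "metabolic"
            else config.non_metabolic_non_gene_frac
        )
        for _ in range(count):
            size = sizes[k]
            k += 1
            if guard:
                genes = pool[cursor : cursor + size]
                cursor += size
            else:
                genes = [
                    str(g) for g in rng.choice(eligible, size=size, replace=False)
                ]
            n_met = int(round(size * frac / (1.0 - frac))) if frac > 0 else 0
            nodes = [
                PathwayNode(node_kind="gene", label=g, gene_id=g) for g in genes
            ] + [
                PathwayNode(node_kind="non_gene", label=f"C{k:04d}_{j:03d}")
                for j in range(n_met)
            ]
            pid = f"syn{k:05d}"
            pathways.append(
                Pathway(
                    pathway_id=pid,
                    name=f"synthetic {group} pathway {k}",
                    group=group,
                    nodes=tuple(nodes),
                )
            )

    # --- planted loops ------------------------------------------------------
    truth = GroundTruth()
    if config.n_planted_loops:
        weights = np.array(
            [config.loop_group_weights.get(p.group, 0.0) for p in pathways]
        )
        if weights.sum() == 0:
            weights = np.ones(len(pathways))
        weights = weights / weights.sum()
        for _ in range(config.n_planted_loops):
            pw = pathways[int(rng.choice(len(pathways), p=weights))]
            loop = plant_ppl(builder, pw, rng)
            truth.loops.append(loop)
    truth.expected_counts = {p.pathway_id: 0 for p in pathways}
    for loop in truth.loops:
        truth.expected_counts[loop.pathway_id] += 1

    kb = build_knowledge_base(
        builder.genes.values(),
        builder.mirnas.values(),
        builder.targets,
        builder.tf_relations,
    )
    return SyntheticDataset(
        kb=kb, pathways=pathways, ground_truth=truth, config=config
    )
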