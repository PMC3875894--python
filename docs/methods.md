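# Methods

## Motif definition and counting unit

A pathway protection loop is the 5-tuple (host gene *g*, intragenic miRNA
*m*, PATF *t*, PAG *h*, antagonist miRNA *a*) satisfying, for a pathway P:
*g* ∈ gene nodes of P; *m*'s coordinates embedded in *g*'s; a filtered
target prediction *m* → *t*; a TF relation *t* → *h*; *h*'s coordinates
embracing *a*'s; and a filtered prediction from *a* onto ≥1 gene of P.
The protected-gene set attached to a loop is the full set of P's genes
that *a* targets through the filter — an attribute, not part of loop
identity, because the same five actors protect however many genes the
antagonist reaches. Two readings the data leave open are kept explicit
rather than resolved silently: loops whose PAG lies inside P itself are
detected, flagged `is_intra_pathway`, and included in counts (a CLI switch
excludes them); loops where the antagonist coincides with the intragenic
miRNA are allowed if all predicates hold and flagged `is_degenerate`. The
PATF is not required to lie outside the pathway. Direct targeting of
pathway genes by the pathway's own intragenic miRNAs is ordinary
intra-pathway regulation and never counted by itself.

## Coordinates and containment

All coordinates are 1-based, inclusive on both ends. Containment requires
both ends inside (a miRNA exactly coextensive with a gene counts as
intragenic; a boundary-straddling one does not) and ignores strand, since
both sense and anti-sense intragenic miRNAs are biologically relevant
here. Intronic and exonic positions are not distinguished. Queries are
served by per-chromosome interval trees (half-open internally, stored
with end+1); property tests assert equality with a linear scan on random
instances, including overlapping genes.

## Target filtering

Predictions pass the filter iff the conservation class is
`good_conserved` or `good_nonconserved` and the mirSVR score is *strictly*
below the cutoff. The default cutoff is −0.3; −0.6 re-runs the whole
analysis on a strict subset of predictions, so the loop set at −0.6 is
provably a subset of the loop set at −0.3 (tested per pathway). TF
relations from both upstream sources are merged by union with provenance
retained; dangling cross-references in the target/TF tables are tolerated
with a warning and counted, so partial fixtures remain loadable.

## Null model

Random pathways contain only gene nodes. Their sizes are drawn from
N(μ_size, σ_size) with μ, σ the mean and sample (n−1) standard deviation
of the real pathways' gene-node counts; draws are rounded to the nearest
integer and redrawn while < 1 (or beyond the universe), which preserves
the distribution's shape above zero; genes are sampled uniformly without
replacement within a network, with replacement across networks. The
population size defaults to 100. Everything is reproducible from one
integer seed.

## Statistical battery

The omnibus test on the groups × {L, NL} matrix is Pearson's χ² without
continuity correction; the pairwise 2×2 tests use the Yates correction;
both delegate to `scipy.stats.chi2_contingency`. This correction
convention is the one that reproduces all published values of this
battery exactly, and the pairwise p-values are reported both raw and
Holm-adjusted (the adjusted ones are what the occurrence tables print).
Holm adjustment is statsmodels' step-down implementation, cross-checked
in the tests against a hand-rolled oracle. Kruskal–Wallis uses the
tie-corrected H with a χ² reference (identical-everything input returns
H = 0 by convention); Mann–Whitney U is two-sided, exact for small
tie-free samples and normal-approximated with tie correction otherwise,
with the method recorded in the result. The Lilliefors statistic D is the
sup-distance between the empirical CDF and the Normal fitted by moments;
its p-value comes from a seeded Monte-Carlo null (default 10⁵ replicates;
the pipeline report uses 2×10⁴) with the statsmodels table approximation
available as an option. Requires n ≥ 4 and a non-constant vector. Which
vector to test is an open choice; the pipeline pools per-pathway loop
counts across all groups, documented as an assumption.

## Pathway network

Each loop whose PAG occurs in k input pathways contributes one count to
each of the k corresponding edges; a PAG found in no pathway increments
the source node's orphan count once per distinct gene. Self-edges
(intra-pathway PAGs) are retained and reported separately. Node kinds:
`ppl_source` iff the pathway generated ≥1 loop, else `pag_only`.
Pathways with neither role are omitted. The mean connectivity of
loop-generating nodes is reported both as out-neighbors only and as total
distinct neighbors, since either reading is defensible. TSV export
round-trips losslessly; DOT and GraphML carry all attributes (the DOT
writer is a ~20-line emitter of the attribute subset we need).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale: a genome of non-overlapping genes (default 8000 genes,
5–50 kb, on 5 chromosomes) — real genomes have overlapping loci, which
the query layer supports and the random-instance tests exercise, but the
generator avoids so planted hosts are unambiguous; ~50 % of miRNAs placed
inside genes (the accepted estimate for mammalian intragenic miRNAs),
the rest in intergenic gaps; mirSVR scores drawn as minus an exponential
(scale 0.3) truncated to [−1.5, 0], giving the negative skew of real
score dumps — only the filtering rule matters to the finder, not the
exact shape; ~70 % of predictions in the good-conservation classes;
sparse uniform TF fan-out; 107 metabolic and 51 non-metabolic pathways
(the real group sizes) with gene counts from N(35, 15) — a deliberately
modest stand-in for real pathway sizes — and metabolite-node fractions of
0.6 and 0.1 respectively, reproducing why the metabolic group rarely
hosts loops.

Planted loops use dedicated actors: a fresh miRNA inside an existing
pathway gene, a fresh PATF gene, a fresh PAG gene with a fresh antagonist
miRNA, and predictions scored in [−1.0, −0.65] so every planted loop
survives both cutoffs. The **closure guard** (default on) partitions the
gene-id space — pathway-eligible genes, background TFs, background TF
targets — and keeps pathway gene sets disjoint, so no combination of
background rows can satisfy all five predicates: with the guard, detected
loops must equal planted loops exactly, which is what the recall = 
precision = 1 tests assert. With the guard off, gene sets may overlap and
accidental closures become possible (recall stays 1; precision may drop),
which is the realistic regime. Consequences of the guard worth noting:
random networks rarely show loops in guarded synthetic data (planted
actors are pathway-exclusive), so the synthetic random group's L-rate is
lower than a real genome would give; passing tests therefore demonstrate
correctness of the search and statistics, not the real-data frequency of
the motif.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery experiment on
100 seeded knowledge bases of 300 genes / 40 miRNAs / 8 pathways each,
oracle-equivalence on ≤30-gene instances against exhaustive 5-tuple
enumeration, the null-model calibration at n = 10,000 draws (mean within
3σ/√n of target), and one end-to-end experiment at the full default
scale (258 pathways including the random population). Published
χ² statistics are asserted to 4 decimal places and Holm-adjusted
p-values to 6 significant figures. Rank-test values published for the
original full-scale per-pathway loop counts depend on data shipped as
supplementary files to the original analysis and are not recomputable
from the package's inputs; the same battery is instead validated on
closed-form oracles and synthetic experiments.

## Known limitations

No sequence content is generated (coordinates and relations only); no
expression data is integrated; the null model is size-and-composition
based only (no degree-preserving randomization); loops are not ranked
beyond the mirSVR filter; the generator does not mimic real human genome
scale, real miRNA clustering, or correlated TF regulons.
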