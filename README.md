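# pplnet

Detection of **pathway protection loops (PPLs)** — a five-step,
miRNA-mediated, inter-pathway regulatory motif — over an integrated
gene/miRNA/target/TF/pathway knowledge base, with the statistical battery
needed to compare motif frequency across pathway groups and the directed
pathway-to-pathway network the motif induces.

## The motif

A pathway protection loop ties five actors together:

1. a gene *g* of an activated pathway hosts an **intragenic miRNA** *m*
   (coordinates embedded in *g*, either strand), co-expressed with *g*;
2. *m* has a reliable target prediction onto a transcription factor *t*,
   the **pathway antagonist transcription factor (PATF)**;
3. *t* regulates a gene *h*, the **pathway antagonist gene (PAG)**;
4. *h* hosts an **antagonist miRNA** *a*;
5. *a*'s predicted targets include genes of the original pathway — the
   genes the loop *protects*: by silencing *t*, the pathway prevents *h*
   from expressing *a*.

Target predictions carry **mirSVR** down-regulation scores (more negative
is stronger); only predictions in the two "good score" conservation
classes with score strictly below a cutoff (−0.3 by default, −0.6 as a
robustness check) are trusted. A loop is a distinct 5-tuple
(*g*, *m*, *t*, *h*, *a*); its protected-gene set is an attribute.

To decide whether loops occur more often than chance, pathway groups
(metabolic, non-metabolic, and a population of 100 size-matched random
gene sets, sizes drawn from N(μ_size, σ_size) fitted to the real
pathways) are compared with:

- an omnibus Pearson χ² on the groups × {L, NL} occurrence matrix
  (L = pathways with ≥1 loop), pairwise 2×2 χ² tests with Yates
  continuity correction, Holm step-down adjustment across the pairs;
- a Lilliefors normality check of per-pathway loop counts, then
  Kruskal–Wallis and pairwise two-sided Mann–Whitney U tests
  (Holm-adjusted).

Loops whose PAG lies in another pathway induce a directed weighted edge
between the two pathways; the resulting graph (hexagonal = loop-generating
nodes, rhomboidal = PAG-only nodes, orphan-PAG counts as node labels) is
exported as TSV, DOT or GraphML.

## Worked example

The whole experiment runs on synthetic data (no downloads): the generator
lays out a genome of non-overlapping genes, places ~50 % of miRNAs inside
genes, draws negatively skewed mirSVR scores, builds 107 metabolic + 51
non-metabolic pathways, and plants loops that satisfy all five predicates
by construction.

```bash
pplnet run-all --seed 5 --out out/
```

prints (abridged):

```
== Loop occurrence contingency matrix (count (row %), [col %]) ==
group	L	NL	total
metabolic	12 (11.2), [32.4]	95 (88.8), [43.0]	107
non_metabolic	21 (41.2), [56.8]	30 (58.8), [13.6]	51
random	4 (4.0), [10.8]	96 (96.0), [43.4]	100

== Omnibus Pearson chi-square ==
chi2 = 39.4537, df = 2, p = 2.70862e-09
...
== Kruskal-Wallis ==
H = 40.1129, df = 2, p = 1.94799e-09

network: 37 loop sources, 23 edges
```

Here 41.2 % of non-metabolic pathways carry at least one loop against
11.2 % of metabolic ones (metabolite nodes cannot host miRNAs), and the
χ² and rank tests reject homogeneity across groups. `out/` also receives the
loop table, per-pathway DOT graphs, the statistical report, and the
pathway-to-pathway network in TSV and GraphML.

The stages are also available separately (`pplnet synth / find / null /
stats / network`); `pplnet stats --counts-file counts.tsv` runs the
occurrence battery directly on a printed contingency matrix.

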