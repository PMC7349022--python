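# Methods

## Model

`kgprior` ranks candidate disease genes by similarity to an enrichment
profile learned from a set of known disease genes over a heterogeneous
knowledge graph. The graph has gene, disease, and annotation (GO term)
nodes and three undirected edge relations: `interacts_with` (gene–gene,
protein interactions mapped to the encoding genes), `annotated_with`
(gene–GO term), and `associated_with` (gene–disease). Namespaced node ids
(`gene:`, `disease:`, `go:`) keep the three populations disjoint; between
any two nodes at most one edge type is possible, so the container is a
simple typed graph (backed by `networkx.Graph`).

### Feature selection

Candidate features are every node adjacent to at least one positive gene,
tagged by the edge type through which it is reached: GO terms, other
diseases (co-morbidity signal is evidence, only the *target* disease node is
excluded), and interaction-partner genes. With *n* positives in an *N*-gene
universe, a feature carried by *k* positives and *K* universe genes is
scored by the exact one-sided hypergeometric tail P(X ≥ k); it enters the
profile iff the tail passes α/m (Bonferroni over the m candidates; α = 0.05
default, `correction="none"` available). The universe deliberately includes
the positives: the model compares known genes with *all other* genes, and
this keeps K, N consistent across features.

The assumptions are those of guilt by association: disease genes share
neighbourhood structure, and one-step neighbourhoods carry enough of it.
There is no diffusion or random-walk component, no GO-hierarchy
propagation, and no edge weighting by annotation evidence codes.

### Scoring, weights, threshold

For each edge type *t* with at least one profile feature, a gene's overlap
fraction f_t ∈ [0, 1] is the share of type-*t* profile features it carries;
the score is the convex combination Σ_t w_t f_t. Weights come from a grid —
default per-type values {0, 0.25, 0.5, 0.75, 1}, normalised to sum to one,
deduplicated — and the decision threshold θ from the observed scores.

Weight/threshold selection maximises mean F1 over an inner split of the
positives (default 3 folds, seeded, clipped to |P|). Two conventions matter
because unlinked genes are *unlabeled*, not confirmed negatives
(positive-unlabeled learning):

* **Precision** is estimated as the share of known positives among all
  genes at or above θ. It is biased low by whatever true-but-unlabeled
  positives sit above θ, but the bias is flat across candidate thresholds.
* **Recall** is measured on the held-out inner fold only, so θ must
  generalise to positives it was not tuned on.
* **Candidate thresholds** are restricted to the positives' observed
  scores: a cut placed between two positives excludes only unlabeled genes,
  which raises measured precision without evidence and overfits.

Exact F1 ties resolve toward the higher threshold (fewer predictions —
conservative), then the first weight vector in a fixed enumeration order.
Fitting is fully deterministic given graph, positives, and `random_state`.
Under this objective the threshold occasionally collapses to the tightest
separating set when the positives concentrate at score 1.0 on one edge
type; per-run hidden-gene recall then drops, which is why the recovery
benchmark below is stated as an average over seeds.

Predictions are all universe genes with score ≥ θ that are not input
positives — a model cannot "predict" a gene it was trained on, which is why
the predictions from a union list are not the union of per-list predictions.
Positives absent from the graph are dropped from training with a logged
count. Training-time scoring uses the full profile (no per-gene
leave-one-out correction of the positive's own contribution).

## Link-deletion cross-validation

The gene list is split into k = 5 seeded folds (sizes differing by ≤ 1).
For each fold the held-out genes' `associated_with` edges to the target
disease are deleted — the genes keep every other edge and are therefore
trained on as apparent negatives — and the model is fitted on the remaining
positives. Per fold we report:

* training precision/recall of the thresholded score against the training
  positives (over all genes, training positives included in the denominator);
* validation precision/recall of the *new* predictions (training positives
  excluded) against the held-out genes;
* expected random precision |held-out| / |candidates| with candidates =
  universe minus training positives, and fold-change = precision / that;
* fold significance: hypergeometric tail P(≥ observed correct) for a random
  draw of the same number of predictions from the candidates; a fold is
  significant at p < 0.05.

Summaries are means with sample (n−1) standard deviations; a single fold
reports std 0 by convention; a fold with no predictions reports precision 0
with a flag; an untrainable fold is recorded as failed, excluded from the
summary statistics, never silently skipped. Per-fold seeds derive from the
master seed through a fixed `numpy.random.SeedSequence` stream and are
recorded in the report. A null-calibration mode permutes the fitted score
vector across genes before thresholding, preserving the prediction count
while destroying the association — under it fold significance holds its
nominal level exactly.

## Over-representation and GWAS validation

Predicted sets are tested against gene-set collections with the one-sided
Fisher exact test, which on a 2×2 overlap table equals the hypergeometric
tail used everywhere else. The background is explicit — for predicted
disease genes, every graph gene the relevant definition did not link to the
disease (the genes that could have been predicted). Bonferroni correction is
the default, with m counting only terms that have at least one background
gene; Benjamini–Hochberg is available behind a flag. Ranked reports re-sort
significant terms by descending enrichment fold.

GWAS validation consumes MAGMA `.genes.out` per-gene p-values. A candidate
list's effective size N is the number of candidates present in the table
after symbol matching (upper-cased; unmapped candidates logged and
excluded), and a candidate validates iff p < 0.05/N, strictly. Adjacent
genes in strong LD can be merged into one locus via an explicit member →
locus map; the merged locus is counted once and takes the p-value of the
stats record bearing the merged name. The by-chance test is a
reconstruction (the natural exact null, not uniquely determined by the
analyses it mirrors): the probability that a random draw of N genes from
all genes tested genome-wide contains at least the observed number passing
the same list-specific 0.05/N threshold — again the hypergeometric tail.

## Synthetic data

The generator plants a disease module in an otherwise unstructured graph.
Defaults define the package's standard benchmark: 300 genes, 50 noise GO
terms, 5 other diseases, a 30-gene planted module of which one third is
hidden (no edge to the target disease), and 8 planted features cycling
through the three edge relations (enriched GO term, interaction-hub gene,
co-associated disease). Planted genes carry each planted feature with
probability p_in = 0.9, background genes with p_out = 0.05, and noise
edges of all three types appear with density 0.02. Every gene is guaranteed
at least one edge so the universe survives file round trips. Fixture output
covers all supported formats (MITAB 2.5 + interactor sidecar map, GAF 2.2,
DisGeNet-style TSV, gene list, MAGMA `.genes.out` with the GWAS signal
coupled to the hidden genes only), reads back to exactly the generated
graph, and is byte-identical across runs with one seed.

What it emulates: the statistical structure the method assumes — a module
sharing enriched features above background, with recoverable missing links.
What it does not: scale-free interaction-degree distributions, the GO
hierarchy, annotation evidence codes, LD structure, or realistic GWAS
effect sizes. Passing benchmarks therefore show the machinery is correct
and well calibrated under its own assumptions, not that real databases
satisfy those assumptions.

Two benchmark conventions follow from the hidden-gene mechanism:

* **Hidden-gene recovery** trains on the visible module genes and measures
  recall and fold-change enrichment on the hidden ones — the end-to-end
  prediction task.
* **Cross-validation** runs on the *full* planted list. In a real analysis
  the known list and the graph's disease links coincide, and the
  link-deletion protocol itself creates the hidden genes fold by fold;
  cross-validating only the visible list on a graph that already hides ten
  further true positives would count those genes as false positives in
  every fold.

At the default conditions, averaged over five seeds: hidden-gene recall
≈ 0.8–0.9 with fold-change enrichment ≈ 28, all five CV folds significant
per seed, and ≥ 90% of twenty shuffled-score runs with at most one
significant fold. `scripts/acceptance.py` recomputes all of these; the
problem sizes above (300-gene universes, 5 recovery seeds, 20 calibration
seeds) are the package's standard benchmark configuration.

## Numerical and format conventions

* All tails are exact (`scipy.stats.hypergeom.sf`); no normal
  approximations anywhere.
* Gene symbols are upper-cased once at load time and matched exactly
  thereafter; node ids are otherwise case-preserved.
* MITAB self-interactions are dropped (no between-gene signal) and
  (A,B)/(B,A) duplicates collapse to one undirected edge; interactor-to-gene
  mapping is an explicit sidecar table, with unmapped interactors skipped
  and counted.
* GAF rows with a `NOT` qualifier are excluded; the annotation aspect is
  kept as provenance but does not subdivide the edge type; GO terms are
  used as annotated, without ontology propagation.
* The DisGeNet score filter defaults to 0 (keep all); disease subtypes are
  merged through an explicit many-to-one map *before* deduplication, so
  near-duplicate diseases cannot make learning artificially easy.
* Ordering is deterministic everywhere ties exist: predictions by
  descending score then gene id; enrichment results by adjusted p, then
  descending fold, then term id; validated GWAS genes by ascending p.

## Known limitations

* The exact weighting and threshold objective of the originating profile
  method are reconstructions (documented above), as is the by-chance null.
* No GO-hierarchy propagation: annotation features are as specific as the
  input file, and parent terms never aggregate evidence.
* The per-edge-type overlap fraction treats all profile features of a type
  as exchangeable; a gene carrying many weakly enriched features can match
  a gene carrying few strongly enriched ones.
* Indirect information leakage (e.g. features derivable only from the very
  links being predicted) must be controlled by the user's choice of inputs;
  only the target disease node is excluded automatically.
* Real-data headline numbers depend on specific IntAct/GO/DisGeNet releases
  and GWAS summary statistics and are out of scope here; the packaged
  reference tables preserve published values for fixture-level checks only.
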