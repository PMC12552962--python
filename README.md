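# gosum

Summarise large sets of enriched Gene Ontology (GO) terms into a small
number of interpretable, ranked clusters.

Functional enrichment analysis — GSEA or over-representation analysis
(ORA) — routinely returns hundreds of significant GO Biological Process
terms, most of them near-duplicates of one another along the ontology's
`is_a`/`part_of` hierarchy. `gosum` condenses such a result into a
clustered similarity heatmap in which every cluster is

* **ranked** by the magnitude of its mean enrichment score (the
  normalized enrichment score NES from GSEA, or the gene-overlap
  proportion from ORA),
* **labelled** by *representative terms* — the deepest common ancestor
  terms that cover the cluster's members, chosen greedily so the labels
  are specific rather than generic, and
* put in context by a **broad-term panel**: shallow (level-2) ontology
  terms annotated with the percentage of input terms descending from
  each.

It also ships a gene-set overlap analysis for comparing a GO-derived
collection against a second collection (e.g. MSigDB Hallmark) by
row-relative overlap proportions.

## Method

1. **Similarity.** For significant terms *t₁, t₂* the package computes
   information-content (IC) based semantic similarity. With
   ic(t) = −ln p(t) and MICA the most informative common ancestor, the
   default measure is the Schlicker relevance
   `rel = 2·ic(MICA)/(ic(t₁)+ic(t₂)) · (1 − e^(−ic(MICA)))`;
   `lin`, normalised Resnik and ancestor-Jaccard are also available.
   IC defaults to a structural estimate,
   ic(t) = −ln((|descendants(t)|+1)/N), and switches to annotation
   frequencies when a term→gene GMT is supplied.
2. **Clustering.** Three methods over the similarity matrix **S**
   (distance 1 − S):
   * *binary cut* — recursive 2-way partitioning; a submatrix whose
     mean off-diagonal similarity reaches the cutoff (default 0.85) is
     accepted as one cluster, otherwise it is split (2-medoid PAM on
     row profiles, or 2-means) and both halves recurse;
   * *hierarchical* — average-linkage agglomerative clustering with
     the flat cut chosen by mean silhouette width over k = 2..25;
   * *combined* (default) — binary cut followed by hierarchical
     refinement of every cluster that is loose (within-cluster mean
     similarity < 0.5) or oversized (> 50 terms).
3. **Summarisation.** Clusters are ordered by |mean score| and each is
   covered greedily by its deepest common ancestors (level ≥ 3,
   covering ≥ 2 members per pick, ≤ 5 picks; leftovers self-represent).
4. **Separation statistic.** Methods are compared by the *difference
   score* — mean within-cluster pair similarity minus mean
   between-cluster pair similarity — with paired Wilcoxon signed-rank
   tests across fixtures.

Signed NES input must be single-signed: up- and down-regulated terms
are separate analyses, and mixed-sign tables are rejected.

## Worked example

Everything runs offline: the `simulate` subcommand writes a synthetic
ontology (OBO), an enrichment table (TSV) and annotations (GMT), and
`cluster` runs the full pipeline on them.

```sh
gosum simulate --n-terms 300 --n-enrich 80 --seed 7 --out-dir demo
gosum cluster --enrichment demo/enrichment.tsv --obo demo/ontology.obo \
      --method combined --out-prefix demo/run --seed 7
```

which prints the six outputs it wrote:

```
clusters        demo/run.clusters.tsv
representatives demo/run.representatives.tsv
panel           demo/run.panel.tsv
heatmap         demo/run.heatmap.png
config          demo/run.config.yaml
log             demo/run.log
```

`run.clusters.tsv` assigns every term a dense 1-based cluster index,
the cluster's rank (1 = strongest |mean score|) and its display row in
the heatmap:

```
term_id  cluster  cluster_rank  cluster_mean_score  row_order  method
T0002    1        62            1.38493             67         combined
T0004    2        8             2.85581             7          combined
```

`run.panel.tsv` is the broad-term panel — here 92.5% of the 80 input
terms descend from the level-2 term `T0002`:

```
broad_term_id  name                 percentage
T0002          synthetic term 0002  92.5000
T0003          synthetic term 0003  85.0000
```

`run.representatives.tsv` lists each cluster's representative terms
with their ontology level and the members they cover. The heatmap
shows the clustered matrix with the broad-term bar above and the
representative terms on the right.

To compare the three clustering methods on planted-block matrices:

```sh
gosum benchmark --n-fixtures 10 --seed 3 --out-prefix demo/bm
```

```
        binary    hclust  combined
mean  0.781962  0.787557  0.781962
50%   0.785037  0.788254  0.785037
```

Cross-collection overlap (GMT vs GMT, row-relative proportions and
containment calls at a threshold):

```sh
gosum overlap --gmt-a gobp.gmt --gmt-b hallmark.gmt --threshold 0.8 \
      --out-prefix demo/ov
```

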