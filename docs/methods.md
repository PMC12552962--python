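# Methods

This note records the model choices behind `gosum`, the defaults and
why they were picked, what the synthetic-data generators do and do not
emulate, and the numerical conventions that make runs reproducible.

## Ontology model

The engine accepts any single-rooted DAG; GO Biological Process is the
intended use, selected from a multi-namespace OBO file with
`namespace_filter`. Only `is_a` and `relationship: part_of` edges form
the transitive backbone — they are the relations along which annotation
and meaning propagate in go-basic; `regulates`-style relations are
ignored. Obsolete terms are retained in the term table (so lookups can
explain them) but carry no edges, no level, and never participate in
queries.

**Levels.** The term level is defined as 1 + the length of the
*shortest* path to the root (root = 1), computed by breadth-first
search over both backbone relations. Shortest-path levels are the
common GO convention and give the property the display relies on:
"broad" terms have small levels. The alternative longest-path
convention would push multi-parent terms deeper; if a use case needs
it, it would change only the `levels` computation, but it is not
offered because two level conventions in one tool invites confusion.

## Information content and similarity

No single IC source fits every user, so two are provided:

* **structural** (default): ic(t) = −ln((|descendants(t)|+1)/N). It
  needs nothing but the ontology, gives ic(root) = 0 and is monotone
  non-decreasing toward the leaves. Its weakness is that it reflects
  ontology topology, not usage: a rarely annotated but highly-branched
  term looks informative.
* **annotation-based**: p(t) = propagated gene count / corpus size from
  a term→gene GMT. Terms with zero propagated count get a pseudo-count
  of 1 (logged) so IC stays finite.

The default similarity is the Schlicker relevance (`rel`), which
down-weights pairs whose MICA is near the root; `lin`, `resnik_norm`
(normalised by the ontology-wide maximum IC so it lands in [0, 1]) and
`jaccard_anc` (ancestor-closure Jaccard, IC-free) are selectable. The
similarity matrix's diagonal is forced to exactly 1 for every measure —
`rel` is strictly below 1 on the diagonal by construction, and the
clustering contract requires a unit diagonal.

Duplicated term ids in the input are rejected rather than deduplicated:
in practice they signal an upstream join bug that silent deduplication
would hide. Terms absent from the ontology are dropped with a logged
count.

## Clustering

**Binary cut.** The node score of a submatrix is the mean of its
off-diagonal entries (1 for a 1×1 block). A node is accepted as a
cluster when its score ≥ `cutoff` (default 0.85) or it is smaller than
`min_split` (default 2); otherwise it is split in two and both halves
recurse. The default partitioner (`pam2`) is an exhaustive 2-medoid
search on **row-profile** (Euclidean) distances between the submatrix's
similarity rows. Partitioning row profiles rather than raw 1 − S
distances matters when a node contains three or more latent blocks: the
members of the block that holds neither medoid are nearly equidistant
from both medoids in 1 − S and would be split by noise, while their
row profiles keep them together. `kmeans2` (seeded k-means on the
rows) is the alternative. A split that leaves one side empty accepts
the node as a cluster, guaranteeing termination.

**Hierarchical.** Average-linkage (or complete-linkage) agglomerative
clustering on 1 − S. When k is not fixed, the flat cut maximises the
mean silhouette width over k = 2..min(n−1, 25), ties to the smallest k;
the cap at 25 bounds the search at the display scale this tool targets.
For n = 2 no silhouette is defined and the items become singletons —
relevant only when refinement is asked to split a 2-term cluster, where
splitting is the intended outcome.

**Combined (default).** Binary cut, then hierarchical refinement of
every stage-1 cluster that is loose (within-cluster mean off-diagonal
similarity < `refine_threshold`, default 0.5) or oversized
(> `max_cluster_size`, default 50). Tight small clusters pass through
byte-identically, which yields the metamorphic identity the tests
exploit: when no trigger fires, combined ≡ binary cut. The triggers and
defaults are this package's own definition of the combined strategy;
they were chosen so refinement acts exactly where binary cut is known
to fail (heterogeneous merges and giant clusters) and nowhere else.

**Determinism.** `pam2` is exhaustive with first-index tie-breaks;
`kmeans2` and every other stochastic step take the run seed; cluster
indices are assigned in emission order so the first input term is
always in cluster 1. Identical config + seed ⇒ byte-identical TSVs.

**Difference score.** d = mean within-cluster pair similarity − mean
between-cluster pair similarity, over unordered pairs. Singletons
contribute no within-pairs; if all clusters are singletons the within
mean is defined as 0; fewer than two clusters is an error (no
between-pairs). This is the package's fixed definition of the
separation statistic used by the benchmark harness; note that under
this definition *larger* means better-separated clusters, so the
benchmark reports distributions and paired Wilcoxon statistics without
asserting a direction of "better" between methods. All-zero difference
vectors (e.g. combined vs binary on uniformly tight fixtures) are
reported as p = 1 with a degenerate flag.

## Representative terms and the broad panel

"Most specific covering ancestor" is operationalised greedily: each
round enumerates every ancestor-or-self of the still-uncovered members,
keeps candidates at level ≥ `min_level` (default 3 — excludes the root
and its immediate children, which are never useful labels) covering at
least `min_cover` (default 2) uncovered members, and picks the maximum
by (level, coverage, lexicographically smallest id) in that priority:
depth first, because escaping generic labels is the point; coverage
second; the id tie-break makes runs reproducible. Selection stops at
`max_reps` (default 5, a display budget) and leftover members represent
themselves rather than being dropped — self-representatives are exempt
from `min_level` since a member is always an honest label for itself.
A representative may be a pure ancestor outside the input set; it is
flagged `is_member=false` in the output. The covered sets partition the
cluster (first cover wins).

Raising `min_level` can only shrink the first pick's coverage (the
candidate pool only loses members), a monotonicity the tests check.

The broad panel takes all terms at `broad_level` (default 2: the root's
direct children, e.g. "immune system process"-scale terms in GO BP) and
labels each with the percentage of input terms that are its
descendant-or-self. Percentages need not sum to 100: a DAG term can
descend from several broad terms and counts toward each. The top
`top_k` (default 8) non-zero entries are shown, ties broken by term id.

## Cluster ranking

Clusters are ordered by descending |mean score|, ties preferring the
larger cluster, then the smaller index. The magnitude is used, not the
signed mean, so all-negative NES analyses rank by enrichment strength;
mixing signs in one table is rejected at validation (up- and
down-regulated terms are separate analyses by contract), so |mean| and
signed mean never disagree within a valid run. Heatmap row order is
rank order, with members of each cluster arranged by average-linkage
dendrogram leaf order of the cluster's own submatrix for visually
coherent blocks.

## Gene-set overlap

Overlap proportions are **row-relative**: |A_i ∩ B_j| / |A_i|, the
fraction of the row set contained in the column set; the orientation is
recorded in the output header because the matrix is not symmetric. A
row is "included" in the other collection when its best column reaches
the threshold (default 0.8, ≥ comparison — the boundary case counts).
Gene identity is exact string match; `--fold-case` uppercases symbols
first. The threshold is a reporting knob, not a correctness parameter:
inclusion-call counts are non-increasing in it, which the tests sweep.

## Synthetic data: what it emulates, what it does not

* `synth_dag` grows a single-rooted DAG in level order (each non-root
  term takes one parent from the level above and up to
  `max_parents − 1` extra parents among earlier terms, ~20% of edges
  `part_of`), and serialises to OBO; parsing the serialisation
  reproduces the graph exactly. It mimics GO's *shape* (rooted,
  multi-parent, bounded depth), not its term vocabulary, branching
  statistics or annotation distributions.
* `synth_similarity` plants block structure: within-block entries drawn
  U(0.80, 0.98), between-block U(0.0, 0.20), blocks of 8–20 terms,
  2–4 blocks per matrix in the benchmark and recovery studies. The
  within range is set so a block's mean similarity (~0.89) clears the
  binary-cut cutoff 0.85 with margin even at the smallest block size —
  with the low end at the cutoff or below, "recovery" would be
  ill-posed for the method being tested, not merely hard. The
  separation constraint (within low > between high) is enforced unless
  explicitly disabled for fuzzing, where no recovery guarantee holds.
* `synth_enrichment` samples terms uniformly and draws NES ~ U(1, 3)
  (times a single sign) or overlap proportions in (0, 1], with padj
  ~ U(0, 0.05) mimicking a pre-filtered significant set.

Because planted blocks are unstructured noise plus separation, passing
the recovery tests shows the clustering machinery is correct, not that
real GO similarity matrices — which have nested, overlapping structure
and no clean block boundaries — will produce equally clean clusters.
Likewise the end-to-end run on 277 random terms of an 800-term
synthetic ontology (the scale of a realistic GSEA result) demonstrates
determinism and throughput, not biological cluster quality.

## Problem sizes and numerical conventions

The test and acceptance studies use: 100 random DAGs of 20–50 terms for
ontology oracles; 100 DAGs of 10–17 terms, all pairs, for similarity
oracles (tolerance 1e-12); 100 planted matrices (n ≤ 80) for recovery
(ARI ≥ 0.9 required in ≥ 95% of draws, per method); 50 fixtures for the
benchmark; 50 random instances for the difference-score oracle; 100
DAG/cluster fixtures for representative selection. These sizes exercise
every code path at matrix scales where brute-force oracles stay exact.

Floating-point conventions: matrices are validated to 1e-12 (symmetry,
bounds, diagonal); similarity values are symmetrised and clipped into
[0, 1] after vectorised computation; silhouette ties use strict
improvement so the smallest k wins; all RNG is `numpy.random.default_rng`
seeded explicitly — there is no global random state anywhere.

## Known limitations

* The engine requires an explicit single-rooted hierarchy; flat
  collections (Hallmark, KEGG) can be *compared against* via the
  overlap analysis but not summarised.
* Structural IC reflects topology, not annotation usage; supply a GMT
  for corpus-based IC when one is available.
* The exhaustive 2-medoid search is O(n³) per node; fine at enrichment
  scale (hundreds of terms), not intended for n in the tens of
  thousands.
* `replaced_by` chains for obsolete terms are not followed; obsolete
  ids in the input are simply dropped with a warning.
* Wang-style graph similarity and gene-level best-match-average
  similarity are out of scope.
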