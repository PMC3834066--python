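# conceptprofiles

Literature-based discovery works by turning co-occurrence statistics from a
concept-indexed abstract corpus into a weighted semantic network, and then
ranking candidate associations (protein–protein interactions, gene–disease
links) by how similar the two entities' literature neighborhoods are.  This
package implements that pipeline end to end for researchers studying how
*generic* concepts (near-ubiquitous terms like "Homo sapiens" or "binding")
and *specific* concepts (individual protein names, rare context terms)
contribute to retrieval, and what happens when either class is filtered out
of the network.

## The model

Each abstract is reduced to a binary set of recognized concept ids.  For two
concepts X and Y with document frequencies over N abstracts, the association
weight is the **symmetric uncertainty coefficient** of their 2×2 co-occurrence
contingency table:

    U(X, Y) = 2 · [H(X) + H(Y) − H(X, Y)] / [H(X) + H(Y)]

where H is entropy — mutual information normalized to [0, 1].  A concept owns
a **concept profile** w_i = (w_i1, …, w_iM), the sparse vector of its U-weights
over the thesaurus, provided it appears in at least 5 abstracts.  A candidate
pair (A, B) is scored by the **inner product** Σ_j w_Aj · w_Bj, and each shared
concept's product term is its *contribution* to the match.  Scores can be
percentile-ranked against a distribution of randomly sampled pairs.  Retrieval
of a benchmark (known true pairs vs random pairs of the same semantic types)
is summarized by the ROC AUC, computed with the mid-rank Mann–Whitney
convention.

Concept specificity is quantified by abstract count, network degree, and edge
weight; networks are filtered forward (remove generic: high-count/high-degree
nodes, low-weight edges) or inverse (remove specific), and AUC is tracked
along threshold grids.  Single-concept networks isolate the retrieval power of
each individual concept.

Because the original corpus-scale inputs (a full MEDLINE index, curated
interaction and disease databases) are not reproducible at desk scale, the
package ships a first-class synthetic corpus generator with planted PPI and
gene–disease truth, power-law generic concept frequencies, association-type
affine generics (a "binding"-like concept enriched in interaction abstracts, a
"mutation"-like concept in disease abstracts), and Zipf study-intensity skew.
See `docs/methods.md` for the generator's assumptions and limits.

## Worked example

```
conceptprofiles generate --seed 1 --out-dir demo
conceptprofiles index    --seed 1 --out-dir demo
conceptprofiles profiles --seed 1 --out-dir demo
conceptprofiles evaluate --seed 1 --out-dir demo
conceptprofiles sweep    --seed 1 --out-dir demo --axis abstract_count
conceptprofiles report   --seed 1 --out-dir demo
```

`evaluate` prints the unfiltered network's retrieval performance on the two
planted benchmarks (300 planted PPIs and 100 planted gene–disease pairs, each
against 3,000 random pairs):

```
ppi: AUC 0.9658 (300 positives vs 3000 random pairs)
gene_disease: AUC 0.9956 (100 positives vs 3000 random pairs)
```

The abstract-count sweep (`demo/sweep_abstract_count_ppi.csv`) shows the
two-phase response.  Forward filtering (`remove_generic`, reading the
threshold from loose log10 = 7 down to 0) barely moves the AUC until almost
every edge is gone, then collapses to chance; inverse filtering
(`remove_specific`) leaves a network of a handful of generic concepts that
still retrieves at AUC ≈ 0.9:

```
 threshold            mode           axis      auc  n_concepts  n_edges
       0.0  remove_generic abstract_count 0.500000           1        1
       1.0  remove_generic abstract_count 0.516921         400      776
       1.5  remove_generic abstract_count 0.973408        1461     4546
       5.0  remove_generic abstract_count 0.965810        3102    59937
       1.5 remove_specific abstract_count 0.926870        1641    55391
       3.0 remove_specific abstract_count 0.897520          15     3420
       5.0 remove_specific abstract_count 0.500000           0        0
```

`report` writes tabular analogues of the standard diagnostics under
`demo/report/`: the concept rank–frequency table, the sweep curves, the
shared-core-concept histogram for planted vs random pairs, the per-concept
dual AUC table, and the contribution table of the top-scoring planted pair.
The per-concept table shows the association-type affinity of the planted
generics — the "protein binding"-like concept alone retrieves PPIs at
AUC 0.87 but gene–disease pairs at only 0.76:

```
concept_id,name,auc_ppi,auc_gd
G05,protein binding,0.8651561111111111,0.7586183333333333
G07,regulation,0.84904,0.72992
G09,binding,0.8389377777777778,0.729405
```

The same operations are available as a library (`conceptprofiles.build_network`,
`match_score`, `filter_sweep`, `per_concept_auc`, …); the CLI is a thin layer
over those functions.

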