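# Methods

## Association weighting

Co-occurrence is counted at document level and binary: a corpus record is one
abstract's set of recognized concept ids, and repeated mentions collapse.  For
concepts X and Y the four contingencies (both, only X, only Y, neither) over
the N documents define empirical Bernoulli variables, and the edge weight is
the symmetric uncertainty coefficient

U(X, Y) = 2·[H(X) + H(Y) − H(X, Y)] / [H(X) + H(Y)],

i.e. mutual information normalized by the mean marginal entropy.  Properties
relied on downstream: U ∈ [0, 1]; symmetric in X and Y; independent of the
entropy log base; U = 1 exactly when either variable determines the other.
Numerical conventions: 0·log 0 ≡ 0; when H(X) + H(Y) = 0 (a concept in all
documents or in none) U is defined as 0, since a degenerate variable carries
no information; floating-point results are clipped to [0, 1] at the 1e-16
fringe.

A subtlety worth recording: mutual information is *not* zero for a pair that
never co-occurs when both concepts have nondegenerate frequencies — perfect
avoidance is also statistical dependence.  `uncertainty_coefficient` returns
that mathematically correct positive value.  Profile *support*, however, is
deliberately restricted to concepts with at least one joint document: a
profile summarizes the literature a concept actually appears in, and
anti-co-occurrence "associations" at corpus scale are artifacts of frequency,
not of subject matter.  Batch network construction therefore enumerates only
positive-n11 pairs (sparse matrix product of the document–concept incidence
matrix), which also keeps the network sparse.

For the same reason the generic-concept penalty is a *regime* statement, not
a global monotonicity: fixing n11 and df(X), U falls as df(Y) grows toward
the independence point n11·N/(df(X)) and reaches 0 there; past that point the
pair becomes anti-correlated and U rises again.  A truly ubiquitous Y
(df(Y) = N) is degenerate and scores exactly 0.  Tests assert the penalty on
the co-occurrence-dominated side, which is the regime generic concepts occupy
in practice.

## Profiles and matching

An entity earns a profile only if it occurs in ≥ 5 abstracts (`min_docs`,
configurable).  Refusal for an under-represented entity is a distinct error
from an unknown id, and network construction reports excluded entities rather
than dropping them silently.  The owner's self-association is never stored:
it is uninformative for matching.  No epsilon floor is applied to weights —
edge filtering is the only truncation mechanism, so filtered and unfiltered
networks differ exactly by the filtered edges.

Match score is the plain inner product over shared support.  Contributions
are ranked by descending product with lexicographic tie-break, expressed as
percent of the score; they sum to 100 within 1e-6 whenever the score is
positive.  Percentile normalization uses the mid-rank convention
100·(#below + ½·#equal)/n against a sorted reference of match scores from
uniformly sampled distinct profile pairs (default 10,000 pairs).  Percentile
ranking is monotone in the score, so it never changes an AUC except through
quantization ties when two scores fall in the same gap of the reference.

## Specificity and filtering

Specificity attributes per feature concept: abstract count (document
frequency) and degree (number of entity profiles whose support contains it);
edge weight is the third, per-association attribute.  Filtering conventions,
chosen so that forward and inverse keeps partition the network exactly:

* node filtering, `remove_generic`: keep metric ≤ threshold (thresholds on
  the log10 scale for abstract counts, raw integers for degree);
  `remove_specific`: keep metric > threshold (strict).
* edge filtering, `remove_generic`: keep log10(weight) ≥ threshold (weak
  links are the signature of a generic endpoint); `remove_specific`: the
  strict complement.
* log10(0) is treated as −∞: a zero-count metric is always kept by
  `remove_generic` and always dropped by `remove_specific`.
* Owners are never removed as entities; a fully filtered owner keeps an
  empty profile, and an empty network scores every pair 0, which the tie
  rule maps to AUC 0.5 — giving sweep curves well-defined endpoints.

Sweeps filter the *original* network at every grid point (never
cumulatively), with a fixed seeded benchmark, so curves differ only by the
filter.  Default grids mirror the filtering conventions of corpus-scale
studies, scaled to this network: log10 abstracts 0–7 in 0.5 steps, log10
weight −11.5–0 in 0.5 steps, and degree 0–n_profiles in steps of
n_profiles/20 (≈ 500 at an 11,541-profile scale).

## ROC evaluation

AUC is the normalized mid-rank Mann–Whitney statistic, computed rank-based
(no quadratic pair loop in production); brute-force pair counting and
scikit-learn's `roc_auc_score` serve as independent oracles in the tests.
Benchmark pairs whose entities lack profiles are excluded and counted.
Per-concept AUC uses single-concept networks, whose match score provably
collapses to the product of the two stored weights.

## The synthetic corpus

The generator emulates the statistical features of a concept-indexed MEDLINE
slice that the pipeline's behavior depends on, with defaults (the study
conditions) of 20,000 documents over 3,300 concepts: 200 proteins, 50
diseases, 2,000 context terms, 50 generics, 1,000 noise terms; 300 planted
PPI pairs and 100 gene–disease pairs (genes drawn from the protein pool);
topic mix 0.5 background / 0.3 PPI / 0.2 gene–disease; entity inclusion 0.8
and per-pair context inclusion 0.5 over 5 context concepts per pair; Poisson
noise mean 3.  These sizes keep a full pipeline run in minutes on one CPU
while leaving the planted signal strong (end-to-end PPI AUC ≈ 0.97).

Design choices where the emulation target was open:

* **Generic frequencies.**  Rank r of the 50 generics gets per-document
  inclusion probability 0.8·r^−1 (power law, exponent 1.0, max 0.8).  The
  shallow exponent and 0.8 ceiling mirror the observed top of real concept
  frequency rankings, where the most generic term appears in ~80% of
  abstracts and the top 30 each appear in ≥ 10%.  Combined with the specific
  and noise concepts this makes the overall document-frequency distribution
  heavy-tailed (top 1% of concepts carry > 30% of occurrences).
* **Association-type affinity.**  Four generics are enriched ×3 in PPI-topic
  documents and four in gene–disease documents, interleaved at frequency
  ranks 5–12 — type-indicative terms are common but not ubiquitous, and
  placing them off rank 1 keeps the multiplied probabilities below 1 without
  clamping.
* **Study-intensity skew.**  PPI pair endpoints, disease genes, and diseases
  are sampled with Zipf(1) weights over independently permuted orderings.
  Real interactome literature coverage is scale-free: a few hub proteins
  dominate, and benchmark positives are systematically better-studied than
  random pairs.  This skew is what gives generic-only networks genuine
  retrieval power — the profiles of heavily co-studied entities carry
  correlated, type-affine generic weights that random pairs lack.
* **Background subjects.**  Background-topic documents are "about"
  1 + Poisson(1) uniformly drawn specific concepts.  This gives every concept
  a baseline literature presence, so the minimum-abstract rule is satisfiable
  and the null corpus (topic mix 1/0/0) is a well-defined chance-level
  control rather than an empty network.
* **Minimum-abstract top-up.**  If a planted-pair entity ends below 5
  documents, pair-topic documents force-including it are appended
  (deterministically) until it qualifies; corpus size may exceed `n_docs` by
  those few documents.

What the generator does *not* model: real token text, sentence structure,
recognition/disambiguation errors, citation growth over time, or corpus
scale (10^7 abstracts, 6.4·10^5 concepts).  Passing tests therefore show
that the pipeline's statistical machinery behaves as designed and that the
filtering phenomena (two-phase response, generic-only retrieval, per-concept
affinity, shared-core enrichment) follow from the planted mechanisms — they
do not certify absolute AUC levels on real literature.

## Determinism

All randomness flows from integer seeds through `numpy.random.default_rng`;
thesaurus, truth, corpus, benchmark sampling, and reference distributions use
distinct child streams of the config seed.  Identical config and seed yield
byte-identical exports, which the CLI manifests (config hash, input hashes,
row counts) make checkable after the fact.

## Known limitations

* The degree metric is computed against the network being filtered, so a
  degree sweep point reflects degrees in the *original* network, matching
  the one-filter-per-point sweep semantics; iterated (cumulative) filtering
  would recompute degrees and shrink faster.
* Percentile normalization against a sampled reference quantizes scores into
  at most 2·n_ref + 1 levels; AUC computed on percentiles can differ from the
  raw-score AUC by a small tie-induced amount.
* `uncertainty_from_counts` works on dense row blocks of the co-occurrence
  matrix; corpora far beyond ~10^5 concepts would need a chunked path.
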