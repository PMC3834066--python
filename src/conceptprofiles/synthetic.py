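"""Synthetic literature corpora with planted association structure.

The generator emulates the statistical shape of a concept-indexed abstract
corpus so that every downstream stage (weighting, profile matching, filtering,
ROC evaluation) can be exercised and validated without external data:

* a small set of very-high-frequency *generic* concepts whose per-document
  inclusion probabilities follow a power law (few near-ubiquitous terms, many
  rarer ones), mirroring the rank/frequency profile of real thesaurus terms;
* planted true protein-protein interaction (PPI) and gene-disease (GD) pairs;
  a document about a pair mentions the two entities and a few pair-specific
  *context* concepts, which is what makes the pair retrievable;
* *association-type affinity*: some generic concepts are enriched in PPI
  documents and others in gene-disease documents (a "binding"-like concept vs
  a "mutation"-like concept), so that even generic-only networks carry signal;
* study-intensity skew: pair endpoints are drawn with Zipf weights, so a few
  heavily-studied hub entities dominate the planted literature the way real
  interactome coverage does;
* background documents about uniformly chosen specific concepts, giving every
  concept a baseline literature presence (and making the no-planted-topics
  null corpus a well-defined control);
* uniform *noise* concepts sprinkled Poisson-fashion over all documents.

Each document is a set (not a multiset) of concept ids: repeated mentions in
one abstract collapse, matching binary per-abstract occurrence counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cooccurrence import DocumentIndex, build_document_index
from .errors import BenchmarkError, ConfigurationError
from .evaluation import BenchmarkSet

__all__ = [
    "CATEGORIES",
    "Concept",
    "Thesaurus",
    "GeneratorConfig",
    "PlantedTruth",
    "SyntheticCorpus",
    "power_law_frequencies",
    "generate_thesaurus",
    "generate_truth",
    "generate_corpus",
    "export_benchmark",
]

CATEGORIES = ("protein", "disease", "context", "generic", "noise")

#: evocative names for the association-type-affine generic concepts; the first
#: block is enriched in PPI documents, the second in gene-disease documents.
_PPI_AFFINE_NAMES = ("protein binding", "regulation", "binding", "mediation")
_GD_AFFINE_NAMES = (
    "mutation abnormality",
    "hereditary syndrome",
    "genetic inheritance",
    "clinical phenotype",
)


@dataclass(frozen=True)
class Concept:
    id: str
    name: str
    category: str


@dataclass
class Thesaurus:
    """Concept inventory: ids, names, categories, generic base frequencies.

    ``base_freq`` maps each generic concept id to its per-document inclusion
    probability in background documents; ``affinity`` maps generic ids to
    per-topic-type multipliers (``{"ppi": m}`` / ``{"gd": m}``).
    """

    concepts: list[Concept]
    base_freq: dict[str, float] = field(default_factory=dict)
    affinity: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.concepts]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("thesaurus concept ids are not unique")

    @property
    def m(self) -> int:
        """Total concept count (the profile-vector dimension)."""
        return len(self.concepts)

    def ids(self, category: str | None = None) -> list[str]:
        if category is None:
            return [c.id for c in self.concepts]
        return [c.id for c in self.concepts if c.category == category]

    def name_of(self, concept_id: str) -> str:
        for c in self.concepts:
            if c.id == concept_id:
                return c.name
        raise KeyError(concept_id)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus; defaults are the study conditions.

    Sizes are chosen so a full pipeline runs in minutes on one CPU while the
    planted signal is strong enough for end-to-end retrieval AUC well above
    chance.  ``topic_probabilities`` are the (background, ppi, gene-disease)
    document-topic weights.
    """

    n_docs: int = 20_000
    n_proteins: int = 200
    n_diseases: int = 50
    n_context: int = 2_000
    n_generic: int = 50
    n_noise: int = 1_000
    n_true_ppi: int = 300
    n_true_gd: int = 100
    context_per_pair: int = 5
    topic_probabilities: tuple[float, float, float] = (0.5, 0.3, 0.2)
    entity_inclusion_prob: float = 0.8
    context_inclusion_prob: float = 0.5
    #: rank-r generic gets base frequency max_freq * r**-exponent
    generic_exponent: float = 1.0
    generic_max_freq: float = 0.8
    #: number of generics enriched in PPI / gene-disease topic documents
    n_affine_ppi: int = 4
    n_affine_gd: int = 4
    #: frequency rank of the first affine generic (PPI/GD blocks interleave
    #: from here); off rank 1 so multipliers do not clamp at probability 1
    affine_start_rank: int = 5
    affinity_multiplier: float = 3.0
    noise_mean: float = 3.0
    #: background documents are "about" 1 + Poisson(mean) specific concepts
    background_subject_mean: float = 1.0
    #: Zipf exponent for study-intensity skew of pair endpoints
    pair_skew: float = 1.0
    min_docs: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_docs", "n_proteins", "n_diseases", "n_context", "n_generic",
            "n_noise", "n_true_ppi", "n_true_gd", "context_per_pair",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        probs = self.topic_probabilities
        if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("topic_probabilities must be three values in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("topic_probabilities must sum to 1")
        for name in ("entity_inclusion_prob", "context_inclusion_prob",
                     "generic_max_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        if self.affinity_multiplier < 1.0:
            raise ConfigurationError("affinity_multiplier must be >= 1")
        if self.affine_start_rank < 1:
            raise ConfigurationError("affine_start_rank must be >= 1")
        last = self.affine_start_rank + 2 * max(self.n_affine_ppi, self.n_affine_gd) - 1
        if last > self.n_generic:
            raise ConfigurationError("not enough generic concepts for the affine blocks")
        if self.context_per_pair > self.n_context:
            raise ConfigurationError("context_per_pair exceeds the context pool")
        if self.n_true_ppi > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ConfigurationError("more planted PPIs than distinct protein pairs")
        if self.n_true_gd > self.n_proteins * self.n_diseases:
            raise ConfigurationError("more planted GD pairs than gene-disease pairs")


@dataclass
class PlantedTruth:
    """Ground-truth associations planted into the corpus.

    ``ppi_pairs`` are unordered protein-id pairs stored in canonical
    (lexicographic) order; ``gd_pairs`` are (gene-id, disease-id) pairs where
    genes are drawn from the protein inventory.  ``context_assignment`` gives
    each planted pair its private set of context concepts.
    """

    ppi_pairs: list[tuple[str, str]]
    gd_pairs: list[tuple[str, str]]
    context_assignment: dict[tuple[str, str], tuple[str, ...]]

    def __post_init__(self) -> None:
        for pair in list(self.ppi_pairs) + list(self.gd_pairs):
            if pair not in self.context_assignment or not self.context_assignment[pair]:
                raise ConfigurationError(f"planted pair {pair} has no context concepts")


@dataclass
class SyntheticCorpus:
    """A generated corpus: document index, the truth behind it, topic labels.

    ``topics`` records the drawn topic of every document ("background",
    "ppi", or "gd"), aligned with ``index.doc_ids``; generation contracts
    (affinity enrichment, independence in the null corpus) are asserted
    against these labels.
    """

    index: DocumentIndex
    truth: PlantedTruth
    topics: list[str]


def power_law_frequencies(n: int, exponent: float, max_freq: float) -> np.ndarray:
    """Rank-frequency power law: rank r (1-based) gets ``max_freq * r**-exponent``.

    On a log-log rank/frequency plot this is an exact line of slope
    ``-exponent``, the shape real concept document frequencies approximate.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    ranks = np.arange(1, n + 1, dtype=np.float64)
    return max_freq * ranks ** -exponent


def generate_thesaurus(config: GeneratorConfig) -> Thesaurus:
    """Deterministically build the concept inventory for ``config``.

    Generic concepts receive power-law base document frequencies.  The
    association-type-affine generics are placed at frequency ranks 5..12
    (interleaved PPI/GD) rather than at the very top: type-indicative terms
    are common but not ubiquitous, and keeping them off rank 1 avoids
    multiplier clamping at probability 1.
    """
    config.validate()
    concepts: list[Concept] = []
    for i in range(config.n_proteins):
        concepts.append(Concept(f"P{i + 1:04d}", f"protein {i + 1}", "protein"))
    for i in range(config.n_diseases):
        concepts.append(Concept(f"D{i + 1:03d}", f"disease {i + 1}", "disease"))
    for i in range(config.n_context):
        concepts.append(Concept(f"C{i + 1:05d}", f"context term {i + 1}", "context"))

    freqs = power_law_frequencies(
        config.n_generic, config.generic_exponent, config.generic_max_freq
    )
    # affine generics interleave from affine_start_rank (ppi even offsets,
    # gd odd offsets)
    start = config.affine_start_rank
    ppi_ranks = [start + 2 * k for k in range(config.n_affine_ppi)]
    gd_ranks = [start + 1 + 2 * k for k in range(config.n_affine_gd)]
    base_freq: dict[str, float] = {}
    affinity: dict[str, dict[str, float]] = {}
    for r in range(1, config.n_generic + 1):
        gid = f"G{r:02d}"
        if r in ppi_ranks:
            k = ppi_ranks.index(r)
            name = _PPI_AFFINE_NAMES[k % len(_PPI_AFFINE_NAMES)]
            affinity[gid] = {"ppi": config.affinity_multiplier}
        elif r in gd_ranks:
            k = gd_ranks.index(r)
            name = _GD_AFFINE_NAMES[k % len(_GD_AFFINE_NAMES)]
            affinity[gid] = {"gd": config.affinity_multiplier}
        else:
            name = f"generic term {r}"
        concepts.append(Concept(gid, name, "generic"))
        base_freq[gid] = float(freqs[r - 1])
    for i in range(config.n_noise):
        concepts.append(Concept(f"N{i + 1:04d}", f"incidental term {i + 1}", "noise"))
    return Thesaurus(concepts, base_freq, affinity)


def _zipf_weights(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zipf sampling weights over a randomly permuted identity ordering."""
    w = np.arange(1, n + 1, dtype=np.float64) ** -exponent
    rng.shuffle(w)
    return w / w.sum()


def generate_truth(thesaurus: Thesaurus, config: GeneratorConfig) -> PlantedTruth:
    """Sample the planted PPI and gene-disease pairs and their contexts.

    Endpoints are drawn with Zipf study-intensity weights over independently
    permuted orderings, so PPI hubness and disease-gene hubness of a protein
    are unrelated.  Every pair receives ``context_per_pair`` context concepts
    sampled without replacement from the context pool.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    proteins = np.array(thesaurus.ids("protein"))
    diseases = np.array(thesaurus.ids("disease"))
    contexts = np.array(thesaurus.ids("context"))

    ppi_w = _zipf_weights(len(proteins), config.pair_skew, rng)
    gene_w = _zipf_weights(len(proteins), config.pair_skew, rng)
    dis_w = _zipf_weights(len(diseases), config.pair_skew, rng)

    ppi_pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(ppi_pairs) < config.n_true_ppi:
        a, b = rng.choice(proteins, size=2, replace=False, p=ppi_w)
        pair = (a, b) if a < b else (b, a)
        if pair not in seen:
            seen.add(pair)
            ppi_pairs.append(pair)

    gd_pairs: list[tuple[str, str]] = []
    seen_gd: set[tuple[str, str]] = set()
    while len(gd_pairs) < config.n_true_gd:
        g = str(rng.choice(proteins, p=gene_w))
        d = str(rng.choice(diseases, p=dis_w))
        if (g, d) not in seen_gd:
            seen_gd.add((g, d))
            gd_pairs.append((g, d))

    context_assignment = {
        pair: tuple(rng.choice(contexts, size=config.context_per_pair, replace=False))
        for pair in ppi_pairs + gd_pairs
    }
    return PlantedTruth(ppi_pairs, gd_pairs, context_assignment)


def generate_corpus(
    thesaurus: Thesaurus, truth: PlantedTruth, config: GeneratorConfig
) -> SyntheticCorpus:
    """Generate the document corpus around ``truth``.

    Each document draws a topic from ``topic_probabilities``.  A pair-topic
    document includes each pair member with ``entity_inclusion_prob`` and each
    of the pair's context concepts with ``context_inclusion_prob``; a
    background document is about ``1 + Poisson`` uniformly chosen specific
    concepts.  Every document then includes each generic concept with its base
    frequency times the topic-type affinity multiplier (clamped to 1) and a
    Poisson number of uniform noise concepts.  Empty documents are redrawn,
    never emitted.  Finally, any planted-pair entity below the minimum-
    abstract rule gets appended pair-topic documents (force-including it)
    until it qualifies for a profile.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    proteins = thesaurus.ids("protein")
    diseases = thesaurus.ids("disease")
    contexts = thesaurus.ids("context")
    noise_ids = np.array(thesaurus.ids("noise"))
    specific_pool = np.array(proteins + diseases + contexts)

    generic_ids = np.array(thesaurus.ids("generic"))
    base = np.array([thesaurus.base_freq[g] for g in generic_ids])
    p_topic = {"background": base.copy(), "ppi": base.copy(), "gd": base.copy()}
    for j, g in enumerate(generic_ids):
        for topic, mult in thesaurus.affinity.get(g, {}).items():
            p_topic[topic][j] = min(1.0, base[j] * mult)

    all_pairs = {"ppi": truth.ppi_pairs, "gd": truth.gd_pairs}
    topic_names = ("background", "ppi", "gd")

    def one_document(topic: str, force_entity: str | None = None,
                     pair: tuple[str, str] | None = None) -> set[str]:
        concepts: set[str] = set()
        if topic == "background":
            k = 1 + rng.poisson(config.background_subject_mean)
            k = min(k, len(specific_pool))
            concepts.update(rng.choice(specific_pool, size=k, replace=False))
        else:
            if pair is None:
                pairs = all_pairs[topic]
                pair = pairs[rng.integers(len(pairs))]
            for member in pair:
                if member == force_entity or rng.random() < config.entity_inclusion_prob:
                    concepts.add(member)
            for ctx in truth.context_assignment[pair]:
                if rng.random() < config.context_inclusion_prob:
                    concepts.add(ctx)
        mask = rng.random(len(generic_ids)) < p_topic[topic]
        concepts.update(generic_ids[mask])
        k_noise = rng.poisson(config.noise_mean)
        if k_noise:
            concepts.update(rng.choice(noise_ids, size=min(k_noise, len(noise_ids)),
                                       replace=False))
        return concepts

    topics = [topic_names[t] for t in rng.choice(
        3, size=config.n_docs, p=config.topic_probabilities)]
    records: list[tuple[str, set[str]]] = []
    for i, topic in enumerate(topics):
        doc = one_document(topic)
        while not doc:  # rare; redraw rather than emit an empty abstract
            doc = one_document(topic)
        records.append((f"doc-{i + 1:06d}", doc))

    # minimum-abstract top-up for planted-pair entities
    counts: dict[str, int] = {}
    for _, doc in records:
        for c in doc:
            counts[c] = counts.get(c, 0) + 1
    membership: dict[str, list[tuple[str, tuple[str, str]]]] = {}
    for topic, pairs in all_pairs.items():
        for pair in pairs:
            for member in pair:
                membership.setdefault(member, []).append((topic, pair))
    extra = 0
    for entity in sorted(membership):
        while counts.get(entity, 0) < config.min_docs:
            topic, pair = membership[entity][extra % len(membership[entity])]
            doc = one_document(topic, force_entity=entity, pair=pair)
            extra += 1
            records.append((f"doc-extra-{extra:04d}", doc))
            topics.append(topic)
            for c in doc:
                counts[c] = counts.get(c, 0) + 1

    index = build_document_index(records)
    return SyntheticCorpus(index=index, truth=truth, topics=topics)


def export_benchmark(
    truth: PlantedTruth,
    thesaurus: Thesaurus,
    n_random: int,
    seed: int,
    association_type: str = "ppi",
    eligible: frozenset | set | None = None,
) -> BenchmarkSet:
    """Positive (planted) and random negative pairs for retrieval evaluation.

    Positives are the planted pairs of the requested type, restricted to
    profile-bearing concepts when ``eligible`` is given.  Negatives are
    ``n_random`` uniformly sampled non-planted pairs of the same semantic
    types, disjoint from the positives.

    Raises
    ------
    BenchmarkError
        ``n_random <= 0``, unknown association type, or fewer candidate
        negative pairs than requested.
    """
    if n_random <= 0:
        raise BenchmarkError("n_random must be positive")
    if association_type not in ("ppi", "gene_disease"):
        raise BenchmarkError(f"unknown association type {association_type!r}")
    rng = np.random.default_rng([seed, 3])

    def ok(cid: str) -> bool:
        return eligible is None or cid in eligible

    if association_type == "ppi":
        planted = {tuple(sorted(p)) for p in truth.ppi_pairs}
        pool = sorted(c for c in thesaurus.ids("protein") if ok(c))
        candidates = [
            (a, b)
            for i, a in enumerate(pool)
            for b in pool[i + 1:]
            if (a, b) not in planted
        ]
    else:
        planted = set(truth.gd_pairs)
        genes = sorted(c for c in thesaurus.ids("protein") if ok(c))
        dis = sorted(c for c in thesaurus.ids("disease") if ok(c))
        candidates = [(g, d) for g in genes for d in dis if (g, d) not in planted]
    if len(candidates) < n_random:
        raise BenchmarkError(
            f"only {len(candidates)} candidate negatives available, "
            f"{n_random} requested"
        )
    positives = [p for p in sorted(planted) if ok(p[0]) and ok(p[1])]
    chosen = rng.choice(len(candidates), size=n_random, replace=False)
    negatives = [candidates[i] for i in sorted(chosen)]
    return BenchmarkSet(
        positives=positives,
        negatives=negatives,
        association_type=association_type,
    )
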