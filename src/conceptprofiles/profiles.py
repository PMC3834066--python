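"""Concept profiles, inner-product matching, and percentile normalization.

A concept profile is a sparse vector of symmetric-uncertainty weights over the
thesaurus, summarizing one entity's literature associations.  An entity earns
a profile only if it occurs in at least ``min_docs`` abstracts (default 5).
The profile's support is the set of concepts the entity co-occurs with at
least once; the weight of each is the uncertainty coefficient of their joint
occurrence table.  Two entities are matched by the inner product of their
profiles over the shared support, and each shared concept's product term is
its "contribution" to the match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import cooccurrence as co
from .errors import BenchmarkError, ProfileEligibilityError, UnknownConceptError

logger = logging.getLogger(__name__)

__all__ = [
    "ConceptProfile",
    "SemanticNetwork",
    "MatchResult",
    "build_profile",
    "build_network",
    "match_score",
    "percentile_normalize",
    "sample_reference_distribution",
]


@dataclass(frozen=True)
class ConceptProfile:
    """Sparse weight vector over thesaurus concepts for one entity.

    ``weights`` maps concept id -> uncertainty coefficient, zeros excluded.
    The owner's (uninformative) self-association is never stored.
    """

    owner: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.owner in self.weights:
            raise ValueError("profile stores a self-weight for its owner")
        if any(w <= 0.0 for w in self.weights.values()):
            raise ValueError("profile stores a non-positive weight")

    @property
    def support(self) -> frozenset:
        return frozenset(self.weights)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class MatchResult:
    """Inner-product match between two profiles.

    ``contributions`` holds ``(concept_id, product, percent_of_score)`` ranked
    by descending product, ties broken lexicographically by concept id.
    ``percentile`` is filled by :func:`percentile_normalize` when requested.
    """

    score: float
    contributions: list[tuple[str, float, float]]
    percentile: float | None = None


class SemanticNetwork:
    """A collection of entity concept profiles: the weighted semantic network.

    Nodes are the profile owners (entities) plus every concept appearing in a
    profile support (the feature universe); edges are the stored weights.
    ``doc_freq`` carries per-concept abstract counts from the source corpus so
    filtering can act on abstract-count specificity without the raw corpus.
    """

    def __init__(
        self,
        profiles: Mapping[str, ConceptProfile],
        doc_freq: Mapping[str, int],
        entity_type: str = "mixed",
        excluded: Sequence[str] = (),
    ):
        self.profiles: dict[str, ConceptProfile] = dict(profiles)
        self.doc_freq: dict[str, int] = dict(doc_freq)
        self.entity_type = entity_type
        self.excluded: list[str] = list(excluded)

    def __contains__(self, entity: str) -> bool:
        return entity in self.profiles

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def feature_universe(self) -> frozenset:
        """Union of all profile supports."""
        out: set[str] = set()
        for p in self.profiles.values():
            out.update(p.weights)
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        """Total number of stored (entity, feature) weights."""
        return sum(len(p) for p in self.profiles.values())

    def replace_profiles(self, profiles: Mapping[str, ConceptProfile]) -> "SemanticNetwork":
        """New network with the same corpus statistics but different profiles."""
        return SemanticNetwork(profiles, self.doc_freq, self.entity_type, self.excluded)


def _profile_from_counts(
    owner: str,
    joint_row: np.ndarray,
    vocab: Sequence[str],
    doc_freq: Mapping[str, int],
    n_docs: int,
) -> ConceptProfile:
    cols = np.nonzero(joint_row)[0]
    df_owner = doc_freq[owner]
    df_other = np.array([doc_freq[vocab[j]] for j in cols], dtype=np.int64)
    u = co.uncertainty_from_counts(joint_row[cols], df_owner, df_other, n_docs)
    weights = {
        vocab[j]: float(w)
        for j, w in zip(cols, u)
        if vocab[j] != owner and w > 0.0
    }
    return ConceptProfile(owner, weights)


def build_profile(
    index: co.DocumentIndex, owner: str, min_docs: int = 5
) -> ConceptProfile:
    """Build the concept profile of ``owner`` from a document index.

    The support is every concept co-occurring with ``owner`` in at least one
    document and carrying a positive uncertainty weight.

    Raises
    ------
    UnknownConceptError
        ``owner`` does not occur in the corpus at all.
    ProfileEligibilityError
        ``owner`` occurs in fewer than ``min_docs`` documents (the
        minimum-abstract rule refuses a profile; this is not an unknown id).
    """
    if owner not in index.postings:
        raise UnknownConceptError(f"concept {owner!r} not in index")
    if index.doc_freq[owner] < min_docs:
        raise ProfileEligibilityError(
            f"{owner!r} occurs in {index.doc_freq[owner]} documents; "
            f"minimum is {min_docs}"
        )
    # per-owner route: enumerate co-occurring concepts via the inverted index
    others: dict[str, int] = {}
    for pos in index.postings[owner]:
        for c in index.concept_sets[pos]:
            if c != owner:
                others[c] = others.get(c, 0) + 1
    weights: dict[str, float] = {}
    for c, n11 in others.items():
        u = co.uncertainty_from_counts(
            n11, index.doc_freq[owner], index.doc_freq[c], index.n_docs
        )
        if u > 0.0:
            weights[c] = float(u)
    return ConceptProfile(owner, weights)


def build_network(
    index: co.DocumentIndex,
    entities: Sequence[str],
    min_docs: int = 5,
    entity_type: str = "mixed",
) -> SemanticNetwork:
    """Build one profile per eligible entity; batch path over sparse counts.

    Entities below the minimum-abstract rule (or absent from the corpus) are
    excluded, logged, and reported on the returned network's ``excluded``
    list — never silently dropped.

    Raises
    ------
    ValueError
        Empty entity list, or no entity is eligible.
    """
    if not entities:
        raise ValueError("entity list is empty")
    eligible = [e for e in entities if index.doc_freq.get(e, 0) >= min_docs]
    excluded = [e for e in entities if e not in set(eligible)]
    if excluded:
        logger.info(
            "excluding %d of %d entities below the %d-document rule",
            len(excluded), len(entities), min_docs,
        )
    if not eligible:
        raise ValueError("no entity meets the minimum-document rule")
    joint, vocab = co.cooccurrence_counts(index, eligible)
    profiles = {
        e: _profile_from_counts(e, joint[i], vocab, index.doc_freq, index.n_docs)
        for i, e in enumerate(eligible)
    }
    return SemanticNetwork(profiles, index.doc_freq, entity_type, excluded)


def match_score(a: ConceptProfile, b: ConceptProfile) -> MatchResult:
    """Inner product of two profiles over their shared support.

    The score is ``sum_j w_aj * w_bj``; it is symmetric and zero for disjoint
    supports.  Contributions are ranked descending by product (ties broken by
    concept id) and expressed as percent of the total score.
    """
    if len(a.weights) > len(b.weights):
        a, b = b, a
    terms = [
        (c, w * b.weights[c]) for c, w in a.weights.items() if c in b.weights
    ]
    score = float(sum(t for _, t in terms))
    terms.sort(key=lambda item: (-item[1], item[0]))
    if score > 0.0:
        contributions = [(c, t, 100.0 * t / score) for c, t in terms]
    else:
        contributions = []
    return MatchResult(score=score, contributions=contributions)


def percentile_normalize(score: float, reference: Sequence[float]) -> float:
    """Percentile rank of ``score`` against a sorted reference distribution.

    Mid-rank convention: ``100 * (#below + 0.5 * #equal) / len(reference)``.

    Raises
    ------
    ValueError
        Empty reference.
    """
    ref = np.asarray(reference, dtype=np.float64)
    if ref.size == 0:
        raise ValueError("reference distribution is empty")
    lo = int(np.searchsorted(ref, score, side="left"))
    hi = int(np.searchsorted(ref, score, side="right"))
    return 100.0 * (lo + 0.5 * (hi - lo)) / ref.size


def sample_reference_distribution(
    network: SemanticNetwork, n_pairs: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Match scores of uniformly sampled distinct unordered profile pairs.

    Returns a sorted array suitable for :func:`percentile_normalize`.  The
    reference emulates the match-score distribution of randomly chosen entity
    pairs against which real candidates are percentile-ranked.

    Raises
    ------
    BenchmarkError
        Fewer than two profiles, or ``n_pairs`` exceeding the number of
        distinct unordered pairs.
    """
    owners = sorted(network.profiles)
    m = len(owners)
    if m < 2:
        raise BenchmarkError("need at least two profiles to sample pairs")
    total = m * (m - 1) // 2
    if n_pairs > total:
        raise BenchmarkError(f"requested {n_pairs} pairs but only {total} exist")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_pairs, replace=False)
    scores = np.empty(n_pairs, dtype=np.float64)
    for k, idx in enumerate(flat):
        # decode linear index into (i, j), i < j, over the upper triangle
        i = int((2 * m - 1 - np.sqrt((2 * m - 1) ** 2 - 8 * idx)) // 2)
        j = int(idx - i * (2 * m - i - 1) // 2 + i + 1)
        scores[k] = match_score(
            network.profiles[owners[i]], network.profiles[owners[j]]
        ).score
    scores.sort()
    return scores
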