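"""Retrieval benchmarking: ROC AUC, filtering sweeps, per-concept power.

A benchmark is a list of known true pairs (planted associations standing in
for curated interaction/disease databases) and a list of random pairs of the
same semantic types.  The network retrieves well when true pairs outscore
random pairs; the AUC of the ROC summarizes the ranking (1 = perfect
separation, 0.5 = chance).  Sweeps re-filter the ORIGINAL network at each
grid threshold and re-evaluate, producing the forward/inverse response
curves; per-concept evaluation isolates each concept's individual retrieval
power through single-concept networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import BenchmarkError
from .filtering import FilterSpec, apply_filter, shared_concept_count, single_concept_network
from .profiles import ConceptProfile, SemanticNetwork, match_score

__all__ = [
    "BenchmarkSet",
    "RocResult",
    "roc_auc",
    "score_pairs",
    "evaluate_network",
    "filter_sweep",
    "per_concept_auc",
    "shared_concept_histogram",
]


@dataclass
class BenchmarkSet:
    """Positive (known-true) and negative (random) entity pairs."""

    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    association_type: str = "ppi"

    def __post_init__(self) -> None:
        overlap = set(map(tuple, self.positives)) & set(map(tuple, self.negatives))
        if overlap:
            raise BenchmarkError(f"{len(overlap)} pairs are both positive and negative")


@dataclass(frozen=True)
class RocResult:
    """Mid-rank Mann-Whitney AUC plus the counts behind it."""

    auc: float
    n_pos: int
    n_neg: int
    tie_count: int = 0
    n_excluded_pos: int = 0
    n_excluded_neg: int = 0


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """AUC of the ROC from positive and negative score lists.

    Computed rank-based (mid-rank ties), equivalent to the normalized
    Mann-Whitney U statistic:
    ``[#(pos > neg) + 0.5 * #(pos == neg)] / (n_pos * n_neg)``.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise BenchmarkError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u / (pos.size * neg.size)
    # number of tied positive-negative score pairs
    vals, pos_counts = np.unique(pos, return_counts=True)
    nvals, neg_counts = np.unique(neg, return_counts=True)
    common, ip, iq = np.intersect1d(vals, nvals, return_indices=True)
    ties = int(np.sum(pos_counts[ip] * neg_counts[iq]))
    return RocResult(auc=float(auc), n_pos=int(pos.size), n_neg=int(neg.size),
                     tie_count=ties)


def score_pairs(
    network: SemanticNetwork, pairs: Iterable[tuple[str, str]]
) -> tuple[np.ndarray, int]:
    """Match scores of the mappable pairs; returns (scores, n_excluded)."""
    scores: list[float] = []
    excluded = 0
    for a, b in pairs:
        pa = network.profiles.get(a)
        pb = network.profiles.get(b)
        if pa is None or pb is None:
            excluded += 1
            continue
        scores.append(match_score(pa, pb).score)
    return np.asarray(scores, dtype=np.float64), excluded


def evaluate_network(network: SemanticNetwork, benchmark: BenchmarkSet) -> RocResult:
    """Retrieval AUC of a network on a benchmark.

    Pairs whose entities lack profiles are excluded and counted, never
    silently dropped.  Scores are raw inner products; percentile
    normalization is a strictly monotone transform of the score and leaves
    the AUC unchanged, so it is not applied here.
    """
    pos, ex_pos = score_pairs(network, benchmark.positives)
    neg, ex_neg = score_pairs(network, benchmark.negatives)
    if pos.size == 0 or neg.size == 0:
        raise BenchmarkError("no mappable positive or negative pairs")
    base = roc_auc(pos, neg)
    return RocResult(
        auc=base.auc, n_pos=base.n_pos, n_neg=base.n_neg, tie_count=base.tie_count,
        n_excluded_pos=ex_pos, n_excluded_neg=ex_neg,
    )


def filter_sweep(
    network: SemanticNetwork,
    benchmark: BenchmarkSet,
    axis: str,
    thresholds: Sequence[float],
    modes: Sequence[str] = ("remove_generic", "remove_specific"),
) -> pd.DataFrame:
    """Forward/inverse filtering response curves.

    Every grid point filters the ORIGINAL network (sweeps are not
    cumulative) and re-evaluates the benchmark.  Returns a DataFrame with
    columns threshold, mode, axis, auc, n_concepts, n_edges.  An empty
    filtered network scores every pair 0, giving AUC 0.5 by the tie rule, so
    both curves have well-defined endpoints.
    """
    thr = list(thresholds)
    if any(b <= a for a, b in zip(thr, thr[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for mode in modes:
        for t in thr:
            try:
                filtered = apply_filter(network, FilterSpec(axis=axis, mode=mode, threshold=t))
                result = evaluate_network(filtered, benchmark)
            except Exception as exc:
                raise type(exc)(f"{exc} (axis={axis} mode={mode} threshold={t})") from exc
            rows.append(
                (t, mode, axis, result.auc, len(filtered.feature_universe),
                 filtered.n_edges)
            )
    return pd.DataFrame(
        rows, columns=["threshold", "mode", "axis", "auc", "n_concepts", "n_edges"]
    )


def per_concept_auc(
    network: SemanticNetwork,
    benchmark: BenchmarkSet,
    concepts: Iterable[str],
) -> pd.DataFrame:
    """Retrieval AUC of each concept alone.

    For each concept the match score of a pair is the product of the two
    profiles' weights on that concept (0 when either lacks it); a concept
    absent from every pair scores all ties and lands at AUC 0.5.  Returns a
    DataFrame with columns concept_id, auc, sorted by descending auc.
    """
    concepts = sorted(set(concepts))
    if not concepts:
        raise ValueError("empty concept set")
    universe = network.feature_universe
    missing = [c for c in concepts if c not in universe]
    if missing:
        raise BenchmarkError(f"concepts not in the feature universe: {missing[:5]}")

    def pair_scores(pairs, concept):
        out = []
        for a, b in pairs:
            pa, pb = network.profiles.get(a), network.profiles.get(b)
            if pa is None or pb is None:
                continue
            out.append(pa.weights.get(concept, 0.0) * pb.weights.get(concept, 0.0))
        return np.asarray(out)

    rows = []
    for c in concepts:
        pos = pair_scores(benchmark.positives, c)
        neg = pair_scores(benchmark.negatives, c)
        if pos.size == 0 or neg.size == 0:
            raise BenchmarkError("no mappable pairs for per-concept evaluation")
        rows.append((c, roc_auc(pos, neg).auc))
    return (
        pd.DataFrame(rows, columns=["concept_id", "auc"])
        .sort_values(["auc", "concept_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def shared_concept_histogram(
    network: SemanticNetwork,
    pairs: Sequence[tuple[str, str]],
    restriction: frozenset | set,
) -> np.ndarray:
    """Histogram of per-pair shared-concept counts within ``restriction``.

    Entry ``k`` is the number of pairs sharing exactly ``k`` restricted
    concepts; the array has length ``len(restriction) + 1`` and sums to the
    number of mappable pairs.
    """
    if not restriction:
        raise ValueError("restriction set is empty")
    restriction = frozenset(restriction)
    counts = []
    for a, b in pairs:
        pa, pb = network.profiles.get(a), network.profiles.get(b)
        if pa is None or pb is None:
            continue
        counts.append(shared_concept_count(pa, pb, restriction))
    return np.bincount(counts, minlength=len(restriction) + 1)
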