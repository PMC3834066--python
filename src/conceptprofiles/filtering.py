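"""Concept specificity metrics and network filtering.

Specificity of a concept is quantified by three attributes: the number of
abstracts it appears in, its degree in the semantic network (how many entity
profiles contain it), and the weights of its associations.  Generic concepts
score high on the first two and low on the third.  Filtering removes either
feature concepts (node filtering, by abstract count or degree) or individual
associations (edge filtering, by weight), in a *forward* direction (remove
generic) or the *inverse* direction (remove specific).  Forward and inverse
keeps at the same threshold always partition the original feature/edge set,
so the two sweep curves are exact complements of one another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

from .errors import UnknownConceptError
from .profiles import ConceptProfile, SemanticNetwork

__all__ = [
    "AXES",
    "MODES",
    "FilterSpec",
    "compute_specificity",
    "filter_nodes",
    "filter_edges",
    "apply_filter",
    "single_concept_network",
    "shared_concept_count",
    "write_provenance",
]

AXES = ("abstract_count", "degree", "edge_weight")
MODES = ("remove_generic", "remove_specific")


@dataclass(frozen=True)
class FilterSpec:
    """One filtering operation.

    ``threshold`` is on the log10 scale for ``abstract_count`` (log10
    abstracts) and ``edge_weight`` (log10 weight), and a plain integer count
    for ``degree``.  ``remove_generic`` keeps the specific side of the
    threshold, ``remove_specific`` the generic side; the two keeps partition
    the network.
    """

    axis: str
    mode: str
    threshold: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.axis == "degree":
            if self.threshold < 0 or self.threshold != int(self.threshold):
                raise ValueError("degree threshold must be a non-negative integer")

    @property
    def raw_threshold(self) -> float:
        """Threshold in raw metric units (de-logged where applicable)."""
        if self.axis == "degree":
            return float(self.threshold)
        return 10.0 ** self.threshold


def compute_specificity(network: SemanticNetwork, index=None) -> pd.DataFrame:
    """Per-feature-concept specificity attributes.

    Returns a DataFrame indexed by concept id with columns ``doc_count`` (the
    number of abstracts containing the concept) and ``degree`` (the number of
    entity profiles whose support contains it).  Only concepts in the feature
    universe appear.  When ``index`` is given its document frequencies are
    used and must know every feature concept.
    """
    doc_freq = index.doc_freq if index is not None else network.doc_freq
    degree: dict[str, int] = {}
    for profile in network.profiles.values():
        for c in profile.weights:
            degree[c] = degree.get(c, 0) + 1
    rows = []
    for c in sorted(degree):
        if c not in doc_freq:
            raise UnknownConceptError(f"feature concept {c!r} unknown to the corpus index")
        rows.append((c, doc_freq[c], degree[c]))
    return pd.DataFrame(rows, columns=["concept_id", "doc_count", "degree"]).set_index(
        "concept_id"
    )


def _keep(metric: float, spec: FilterSpec) -> bool:
    # remove_generic keeps metric <= threshold; remove_specific keeps the
    # strict complement, so the two keeps partition the network exactly.
    if spec.mode == "remove_generic":
        return metric <= spec.raw_threshold
    return metric > spec.raw_threshold


def filter_nodes(network: SemanticNetwork, spec: FilterSpec) -> SemanticNetwork:
    """Remove feature concepts by abstract count or degree.

    The entity set is unchanged: profile owners always keep their profiles
    (possibly emptied).  All edges to removed feature concepts drop.  A
    concept with zero abstracts or zero degree has metric log10 = -inf, i.e.
    it is always kept by ``remove_generic`` and dropped by ``remove_specific``.
    """
    if spec.axis not in ("abstract_count", "degree"):
        raise ValueError("filter_nodes requires axis abstract_count or degree")
    if spec.axis == "degree" and spec.threshold > len(network.profiles):
        raise ValueError("degree threshold exceeds the number of profiles")
    if spec.axis == "abstract_count":
        metric = {c: float(network.doc_freq.get(c, 0)) for c in network.feature_universe}
    else:
        metric = compute_specificity(network)["degree"].astype(float).to_dict()
    kept = {c for c, m in metric.items() if _keep(m, spec)}
    profiles = {
        owner: ConceptProfile(
            owner, {c: w for c, w in p.weights.items() if c in kept}
        )
        for owner, p in network.profiles.items()
    }
    return network.replace_profiles(profiles)


def filter_edges(network: SemanticNetwork, spec: FilterSpec) -> SemanticNetwork:
    """Remove associations by weight.

    ``remove_generic`` keeps edges with log10(weight) >= threshold (weak
    links, the mark of a generic endpoint, are dropped); ``remove_specific``
    keeps log10(weight) < threshold.  Owners left with empty support remain
    in the network as entities with empty profiles.
    """
    if spec.axis != "edge_weight":
        raise ValueError("filter_edges requires axis edge_weight")
    cut = spec.raw_threshold
    if spec.mode == "remove_generic":
        profiles = {
            owner: ConceptProfile(owner, {c: w for c, w in p.weights.items() if w >= cut})
            for owner, p in network.profiles.items()
        }
    else:
        profiles = {
            owner: ConceptProfile(owner, {c: w for c, w in p.weights.items() if w < cut})
            for owner, p in network.profiles.items()
        }
    return network.replace_profiles(profiles)


def apply_filter(network: SemanticNetwork, spec: FilterSpec) -> SemanticNetwork:
    """Dispatch to node or edge filtering based on the filter's axis."""
    if spec.axis == "edge_weight":
        return filter_edges(network, spec)
    return filter_nodes(network, spec)


def single_concept_network(network: SemanticNetwork, concept: str) -> SemanticNetwork:
    """Restrict every profile's support to a single concept.

    The match score between two entities then collapses to the product of
    their two stored weights for ``concept`` (or 0 if either lacks it),
    isolating that concept's individual retrieval power.
    """
    if concept not in network.feature_universe:
        raise UnknownConceptError(f"concept {concept!r} not in the feature universe")
    profiles = {
        owner: ConceptProfile(
            owner,
            {concept: p.weights[concept]} if concept in p.weights else {},
        )
        for owner, p in network.profiles.items()
    }
    return network.replace_profiles(profiles)


def shared_concept_count(
    a: ConceptProfile, b: ConceptProfile, restriction: frozenset | set
) -> int:
    """Number of concepts shared by two profiles within ``restriction``."""
    return len(a.support & b.support & frozenset(restriction))


def write_provenance(
    path, spec: FilterSpec, before: SemanticNetwork, after: SemanticNetwork
) -> None:
    """Sidecar JSON describing one filtering operation and its effect."""
    payload = {
        "axis": spec.axis,
        "mode": spec.mode,
        "threshold": spec.threshold,
        "nodes_before": len(before.feature_universe),
        "nodes_after": len(after.feature_universe),
        "edges_before": before.n_edges,
        "edges_after": after.n_edges,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
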