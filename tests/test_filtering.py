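"""Specificity metrics, node/edge filtering, single-concept networks."""

import numpy as np
import pytest

from conceptprofiles import (
    ConceptProfile,
    FilterSpec,
    SemanticNetwork,
    compute_specificity,
    filter_edges,
    filter_nodes,
    match_score,
    shared_concept_count,
    single_concept_network,
)
from conceptprofiles.errors import UnknownConceptError
from conceptprofiles.filtering import apply_filter


@pytest.fixture()
def small_network():
    """Three entities; 'g' is a generic feature (many docs, full degree)."""
    profiles = {
        "E1": ConceptProfile("E1", {"g": 0.001, "s1": 0.4, "s2": 0.3}),
        "E2": ConceptProfile("E2", {"g": 0.002, "s1": 0.5}),
        "E3": ConceptProfile("E3", {"g": 0.001, "s3": 0.2}),
    }
    doc_freq = {"E1": 10, "E2": 12, "E3": 9, "g": 200_000, "s1": 50, "s2": 30,
                "s3": 20}
    return SemanticNetwork(profiles, doc_freq)


class TestSpecificity:
    def test_degree_and_doc_count(self, small_network):
        table = compute_specificity(small_network)
        assert table.loc["g", "degree"] == 3  # maximum: present in every profile
        assert table.loc["s1", "degree"] == 2
        assert table.loc["g", "doc_count"] == 200_000
        # only feature concepts appear
        assert "E1" not in table.index

    def test_doc_count_matches_corpus_recount(self, default_run):
        net, idx = default_run["network"], default_run["index"]
        table = compute_specificity(net, idx)
        rng = np.random.default_rng(2)
        for c in rng.choice(table.index.to_numpy(), size=40, replace=False):
            assert table.loc[c, "doc_count"] == sum(c in s for s in idx.concept_sets)

    def test_degree_bounded_by_profile_count(self, default_run):
        table = compute_specificity(default_run["network"])
        assert table["degree"].max() <= len(default_run["network"])

    def test_unknown_feature_concept_rejected(self, small_network):
        small_network.doc_freq.pop("s3")
        with pytest.raises(UnknownConceptError):
            compute_specificity(small_network)


class TestNodeFiltering:
    def test_generic_concept_removed_above_abstract_cutoff(self, small_network):
        # threshold log10 = 5 keeps concepts in <= 100,000 abstracts; the
        # 200,000-abstract generic vanishes from every profile
        out = filter_nodes(
            small_network, FilterSpec("abstract_count", "remove_generic", 5.0)
        )
        assert "g" not in out.feature_universe
        assert all("g" not in p.weights for p in out.profiles.values())
        assert set(out.profiles) == set(small_network.profiles)  # owners stay

    def test_threshold_above_max_is_identity(self, small_network):
        out = filter_nodes(
            small_network, FilterSpec("abstract_count", "remove_generic", 7.0)
        )
        assert out.n_edges == small_network.n_edges
        assert out.feature_universe == small_network.feature_universe

    @pytest.mark.parametrize("axis,thresholds", [
        ("abstract_count", [0.0, 1.5, 4.0, 5.0, 6.0]),
        ("degree", [0, 1, 2, 3]),
    ])
    def test_forward_and_inverse_keeps_partition_features(
        self, small_network, axis, thresholds
    ):
        for t in thresholds:
            fwd = filter_nodes(small_network, FilterSpec(axis, "remove_generic", t))
            inv = filter_nodes(small_network, FilterSpec(axis, "remove_specific", t))
            assert fwd.feature_universe | inv.feature_universe == \
                small_network.feature_universe
            assert not fwd.feature_universe & inv.feature_universe
            assert fwd.n_edges + inv.n_edges == small_network.n_edges

    def test_missing_doc_count_treated_as_log_zero(self, small_network):
        # log10(0) = -inf: always kept forward, always dropped inverse
        small_network.doc_freq.pop("s3")  # s3 now counts as zero abstracts
        fwd = filter_nodes(
            small_network, FilterSpec("abstract_count", "remove_generic", 0.0)
        )
        inv = filter_nodes(
            small_network, FilterSpec("abstract_count", "remove_specific", 0.0)
        )
        assert "s3" in fwd.feature_universe
        assert "s3" not in inv.feature_universe

    def test_degree_threshold_validation(self, small_network):
        with pytest.raises(ValueError):
            FilterSpec("degree", "remove_generic", 1.5)
        with pytest.raises(ValueError):
            filter_nodes(small_network, FilterSpec("degree", "remove_generic", 99))


class TestEdgeFiltering:
    def test_threshold_below_min_weight_is_identity(self, small_network):
        out = filter_edges(
            small_network, FilterSpec("edge_weight", "remove_generic", -11.5)
        )
        assert out.n_edges == small_network.n_edges

    def test_forward_and_inverse_keeps_partition_edges(self, small_network):
        for t in [-11.5, -3.0, -2.5, -0.3, 0.0]:
            fwd = filter_edges(small_network, FilterSpec("edge_weight", "remove_generic", t))
            inv = filter_edges(small_network, FilterSpec("edge_weight", "remove_specific", t))
            assert fwd.n_edges + inv.n_edges == small_network.n_edges
            for owner in small_network.profiles:
                joint = dict(fwd.profiles[owner].weights)
                joint.update(inv.profiles[owner].weights)
                assert joint == dict(small_network.profiles[owner].weights)

    def test_emptied_owners_remain_as_entities(self, small_network):
        out = filter_edges(
            small_network, FilterSpec("edge_weight", "remove_generic", 0.0)
        )
        assert set(out.profiles) == set(small_network.profiles)
        assert out.n_edges == 0

    def test_edge_counts_monotone_along_forward_grid(self, default_run):
        net = default_run["network"]
        grid = [x / 2 for x in range(-23, 1)]  # -11.5 .. 0 in 0.5 steps
        counts = [
            filter_edges(net, FilterSpec("edge_weight", "remove_generic", t)).n_edges
            for t in grid
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestIdempotence:
    @pytest.mark.parametrize("axis,mode,threshold", [
        ("abstract_count", "remove_generic", 2.0),
        ("abstract_count", "remove_specific", 2.0),
        ("degree", "remove_generic", 2),
        ("edge_weight", "remove_generic", -2.5),
        ("edge_weight", "remove_specific", -2.5),
    ])
    def test_applying_twice_equals_once(self, small_network, axis, mode, threshold):
        spec = FilterSpec(axis, mode, threshold)
        once = apply_filter(small_network, spec)
        twice = apply_filter(once, spec)
        assert {o: dict(p.weights) for o, p in once.profiles.items()} == \
            {o: dict(p.weights) for o, p in twice.profiles.items()}


class TestSingleConcept:
    def test_score_is_product_of_stored_weights(self):
        profiles = {
            "E1": ConceptProfile("E1", {"c": 0.2, "d": 0.9}),
            "E2": ConceptProfile("E2", {"c": 0.2}),
            "E3": ConceptProfile("E3", {"d": 0.5}),
        }
        net = SemanticNetwork(profiles, {"c": 10, "d": 10})
        restricted = single_concept_network(net, "c")
        r = match_score(restricted.profiles["E1"], restricted.profiles["E2"])
        assert r.score == pytest.approx(0.2 * 0.2)
        # an entity lacking the concept scores zero against everyone
        assert match_score(
            restricted.profiles["E3"], restricted.profiles["E1"]
        ).score == 0.0

    def test_unknown_concept_rejected(self, small_network):
        with pytest.raises(UnknownConceptError):
            single_concept_network(small_network, "nope")

    def test_matches_full_network_on_default_corpus(self, default_run):
        net = default_run["network"]
        concept = sorted(default_run["thesaurus"].ids("generic"))[0]
        restricted = single_concept_network(net, concept)
        for owner in list(net.profiles)[:10]:
            w = net.profiles[owner].weights.get(concept)
            rw = restricted.profiles[owner].weights
            assert (rw == {concept: w}) if w is not None else (rw == {})


class TestSharedConcepts:
    def test_disjoint_profiles_share_nothing(self):
        a = ConceptProfile("a", {"x": 0.1})
        b = ConceptProfile("b", {"y": 0.1})
        assert shared_concept_count(a, b, {"x", "y"}) == 0

    def test_count_bounded_by_restriction(self, default_run):
        net = default_run["network"]
        owners = sorted(net.profiles)[:6]
        restriction = frozenset(sorted(net.feature_universe)[:735])
        for i, a in enumerate(owners):
            for b in owners[i + 1:]:
                c = shared_concept_count(net.profiles[a], net.profiles[b], restriction)
                assert 0 <= c <= len(restriction)

    def test_equals_bruteforce_set_intersection(self):
        rng = np.random.default_rng(8)
        pool = [f"c{i}" for i in range(30)]
        for _ in range(25):
            wa = {c: 0.1 for c in rng.choice(pool, size=rng.integers(1, 15),
                                             replace=False)}
            wb = {c: 0.1 for c in rng.choice(pool, size=rng.integers(1, 15),
                                             replace=False)}
            restriction = set(rng.choice(pool, size=10, replace=False))
            a, b = ConceptProfile("a", wa), ConceptProfile("b", wb)
            assert shared_concept_count(a, b, restriction) == len(
                set(wa) & set(wb) & restriction
            )
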