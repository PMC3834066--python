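"""Shared fixtures: hand-built toy corpora and one default synthetic run.

The default synthetic run (20k documents, planted PPI and gene-disease truth)
is built once per session and shared by the filtering, evaluation, and
acceptance tests; the null corpora (no pair topics) likewise.
"""

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from conceptprofiles import (
    GeneratorConfig,
    build_document_index,
    build_network,
    export_benchmark,
    generate_corpus,
    generate_thesaurus,
)
from conceptprofiles.synthetic import generate_truth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURE_DIR = Path(__file__).parent / "data"

MIN_DOCS = 5
N_RANDOM = 3000


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return FIXTURE_DIR


@pytest.fixture()
def toy_index():
    """The three-document corpus {A,B}, {A}, {B,C}."""
    return build_document_index(
        [("d1", ["A", "B"]), ("d2", ["A"]), ("d3", ["B", "C"])]
    )


def build_run(config: GeneratorConfig) -> dict:
    """Full pipeline on one generated corpus: network plus both benchmarks."""
    thesaurus = generate_thesaurus(config)
    truth = generate_truth(thesaurus, config)
    corpus = generate_corpus(thesaurus, truth, config)
    entities = thesaurus.ids("protein") + thesaurus.ids("disease")
    network = build_network(corpus.index, entities, min_docs=MIN_DOCS)
    eligible = frozenset(
        c for c, n in corpus.index.doc_freq.items() if n >= MIN_DOCS
    )
    bench_ppi = export_benchmark(
        truth, thesaurus, N_RANDOM, config.seed, "ppi", eligible
    )
    bench_gd = export_benchmark(
        truth, thesaurus, N_RANDOM, config.seed, "gene_disease", eligible
    )
    return {
        "config": config,
        "thesaurus": thesaurus,
        "truth": truth,
        "corpus": corpus,
        "index": corpus.index,
        "network": network,
        "bench_ppi": bench_ppi,
        "bench_gd": bench_gd,
    }


@pytest.fixture(scope="session")
def default_run() -> dict:
    """The default study conditions, seed 1."""
    return build_run(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_run() -> dict:
    """Default sizes but background-only topics: no planted signal."""
    return build_run(GeneratorConfig(seed=0, topic_probabilities=(1.0, 0.0, 0.0)))
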