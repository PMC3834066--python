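"""Readers and writers for the pipeline's plain-text dialects.

Formats (all UTF-8, ids contain no whitespace):

* corpus JSONL — one object per document: ``{"doc_id": ..., "concepts": [...]}``
* corpus TSV — two columns ``doc_id`` / ``concept_id``, one row per occurrence
* thesaurus TSV — ``concept_id`` / ``name`` / ``category`` / ``planted_base_freq``
* benchmark TSV — ``id_a`` / ``id_b`` / ``label`` (1 = positive, 0 = random)
* profile store TSV — ``owner_id`` / ``concept_id`` / ``weight`` with weights
  printed at 10 significant digits (round-trips exactly at that precision)
* weight dump TSV — ``concept_a`` / ``concept_b`` / ``n11`` / ``weight``,
  one undirected pair per line, ``concept_a < concept_b``
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cooccurrence import DocumentIndex, build_document_index
from .errors import CorpusFormatError
from .evaluation import BenchmarkSet
from .profiles import ConceptProfile, SemanticNetwork

__all__ = [
    "atomic_write_text",
    "write_corpus_jsonl", "read_corpus_jsonl",
    "write_corpus_tsv", "read_corpus_tsv",
    "write_thesaurus_tsv", "read_thesaurus_tsv",
    "write_benchmark_tsv", "read_benchmark_tsv",
    "write_profiles_tsv", "read_profiles_tsv",
    "write_weights_tsv",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_corpus_jsonl(index: DocumentIndex, path: str | Path) -> None:
    lines = [
        json.dumps({"doc_id": doc_id, "concepts": sorted(cs)})
        for doc_id, cs in zip(index.doc_ids, index.concept_sets)
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_corpus_jsonl(path: str | Path) -> DocumentIndex:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from None
    return build_document_index(records)


def write_corpus_tsv(index: DocumentIndex, path: str | Path) -> None:
    rows = ["doc_id\tconcept_id"]
    for doc_id, cs in zip(index.doc_ids, index.concept_sets):
        rows.extend(f"{doc_id}\t{c}" for c in sorted(cs))
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_corpus_tsv(path: str | Path) -> DocumentIndex:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["doc_id", "concept_id"]:
        raise CorpusFormatError("corpus TSV must have columns doc_id, concept_id")
    grouped = df.groupby("doc_id", sort=False)["concept_id"].apply(list)
    return build_document_index(grouped.items())


def write_thesaurus_tsv(thesaurus, path: str | Path) -> None:
    rows = ["concept_id\tname\tcategory\tplanted_base_freq"]
    for c in thesaurus.concepts:
        freq = thesaurus.base_freq.get(c.id, "")
        rows.append(f"{c.id}\t{c.name}\t{c.category}\t{freq}")
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_thesaurus_tsv(path: str | Path):
    from .synthetic import Concept, Thesaurus  # deferred: io must not force synthetic

    df = pd.read_csv(path, sep="\t", dtype={"concept_id": str, "name": str,
                                            "category": str})
    concepts = [
        Concept(r.concept_id, r.name, r.category) for r in df.itertuples(index=False)
    ]
    base_freq = {}
    if "planted_base_freq" in df.columns:
        for r in df.itertuples(index=False):
            if pd.notna(r.planted_base_freq) and r.planted_base_freq != "":
                base_freq[r.concept_id] = float(r.planted_base_freq)
    return Thesaurus(concepts, base_freq)


def write_benchmark_tsv(benchmark: BenchmarkSet, path: str | Path) -> None:
    rows = ["id_a\tid_b\tlabel"]
    rows.extend(f"{a}\t{b}\t1" for a, b in benchmark.positives)
    rows.extend(f"{a}\t{b}\t0" for a, b in benchmark.negatives)
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_benchmark_tsv(path: str | Path, association_type: str = "ppi") -> BenchmarkSet:
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str, "label": int})
    pos = [(r.id_a, r.id_b) for r in df.itertuples(index=False) if r.label == 1]
    neg = [(r.id_a, r.id_b) for r in df.itertuples(index=False) if r.label == 0]
    return BenchmarkSet(positives=pos, negatives=neg, association_type=association_type)


def write_profiles_tsv(network: SemanticNetwork, path: str | Path) -> None:
    rows = ["owner_id\tconcept_id\tweight"]
    for owner in sorted(network.profiles):
        p = network.profiles[owner]
        for c in sorted(p.weights):
            rows.append(f"{owner}\t{c}\t{p.weights[c]:.10g}")
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_profiles_tsv(
    path: str | Path, doc_freq: dict | None = None, entity_type: str = "mixed"
) -> SemanticNetwork:
    df = pd.read_csv(path, sep="\t",
                     dtype={"owner_id": str, "concept_id": str, "weight": float})
    profiles: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        profiles.setdefault(r.owner_id, {})[r.concept_id] = r.weight
    built = {o: ConceptProfile(o, w) for o, w in profiles.items()}
    return SemanticNetwork(built, doc_freq or {}, entity_type)


def write_weights_tsv(pairs: Iterable[tuple[str, str, int, float]], path: str | Path) -> None:
    rows = ["concept_a\tconcept_b\tn11\tweight"]
    rows.extend(f"{a}\t{b}\t{n11}\t{w:.10g}" for a, b, n11, w in sorted(pairs))
    atomic_write_text(path, "\n".join(rows) + "\n")
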