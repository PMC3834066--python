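"""Document-level co-occurrence counting and symmetric-uncertainty weighting.

A corpus is reduced to binary per-document concept occurrence.  For a pair of
concepts X and Y the four contingencies (both occur, only X, only Y, neither)
over the N documents define empirical Bernoulli variables, and the association
weight is the symmetric uncertainty coefficient

    U(X, Y) = 2 * [H(X) + H(Y) - H(X, Y)] / [H(X) + H(Y)]

with H the (empirical) entropy.  U is the mutual information normalized by the
mean marginal entropy: 0 for independent occurrence, 1 when either variable
determines the other.  A generic concept -- one present in a large fraction of
all documents -- has high marginal entropy but shares little information with
any specific concept, so its weights are systematically small; this is the
property the downstream filtering modules exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import xlogy

from .errors import CorpusFormatError, UnknownConceptError

__all__ = [
    "ContingencyTable",
    "DocumentIndex",
    "build_document_index",
    "contingency",
    "uncertainty_coefficient",
    "uncertainty_from_counts",
    "cooccurrence_counts",
    "iter_pair_weights",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Document counts for the joint occurrence of two concepts.

    n11: both present; n10: only the first; n01: only the second; n00: neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            if getattr(self, name) < 0:
                raise ValueError(f"contingency count {name} is negative")

    @property
    def n(self) -> int:
        """Total number of documents behind the table."""
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def swapped(self) -> "ContingencyTable":
        return ContingencyTable(self.n11, self.n01, self.n10, self.n00)


class DocumentIndex:
    """Binary per-document concept occurrence, the corpus's computational form.

    Holds the ordered documents (as frozensets of concept ids), per-concept
    document frequencies, and an inverted index used for fast pairwise counts.
    Construct via :func:`build_document_index`.
    """

    def __init__(self, doc_ids: Sequence[str], concept_sets: Sequence[frozenset]):
        if len(doc_ids) != len(concept_sets):
            raise ValueError("doc_ids and concept_sets length mismatch")
        self.doc_ids: list[str] = list(doc_ids)
        self.concept_sets: list[frozenset] = list(concept_sets)
        self.postings: dict[str, set[int]] = {}
        for pos, cs in enumerate(self.concept_sets):
            for c in cs:
                self.postings.setdefault(c, set()).add(pos)
        self.doc_freq: dict[str, int] = {c: len(p) for c, p in self.postings.items()}
        self._vocab: list[str] | None = None
        self._matrix: sp.csc_matrix | None = None

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def __len__(self) -> int:
        return len(self.doc_ids)

    def __contains__(self, concept: str) -> bool:
        return concept in self.postings

    @property
    def vocabulary(self) -> list[str]:
        """All concept ids occurring in the corpus, sorted."""
        if self._vocab is None:
            self._vocab = sorted(self.postings)
        return self._vocab

    def to_sparse(self) -> tuple[sp.csc_matrix, list[str]]:
        """Binary documents x concepts matrix plus its column vocabulary."""
        if self._matrix is None:
            vocab = self.vocabulary
            col = {c: j for j, c in enumerate(vocab)}
            indptr = [0]
            indices: list[int] = []
            for cs in self.concept_sets:
                indices.extend(sorted(col[c] for c in cs))
                indptr.append(len(indices))
            mat = sp.csr_matrix(
                (np.ones(len(indices), dtype=np.int32), indices, indptr),
                shape=(self.n_docs, len(vocab)),
            )
            self._matrix = mat.tocsc()
        return self._matrix, self.vocabulary


def build_document_index(records: Iterable) -> DocumentIndex:
    """Build a :class:`DocumentIndex` from corpus records.

    Parameters
    ----------
    records
        Iterable of ``(doc_id, concepts)`` pairs or of mappings with keys
        ``doc_id`` and ``concepts``.  Repeated concept mentions within one
        record collapse to a single occurrence (set semantics).

    Raises
    ------
    CorpusFormatError
        On an empty corpus, a duplicate ``doc_id``, or a malformed record
        (the error names the offending record number).
    """
    doc_ids: list[str] = []
    concept_sets: list[frozenset] = []
    seen: set[str] = set()
    for lineno, rec in enumerate(records, start=1):
        if isinstance(rec, Mapping):
            try:
                doc_id, concepts = rec["doc_id"], rec["concepts"]
            except KeyError as exc:
                raise CorpusFormatError(f"record {lineno}: missing key {exc}") from None
        else:
            try:
                doc_id, concepts = rec
            except (TypeError, ValueError):
                raise CorpusFormatError(
                    f"record {lineno}: expected (doc_id, concepts)"
                ) from None
        doc_id = str(doc_id)
        if doc_id in seen:
            raise CorpusFormatError(f"record {lineno}: duplicate doc_id {doc_id!r}")
        cs = frozenset(str(c) for c in concepts)
        if not cs or any(not c for c in cs):
            raise CorpusFormatError(f"record {lineno}: empty concept id or empty document")
        seen.add(doc_id)
        doc_ids.append(doc_id)
        concept_sets.append(cs)
    if not doc_ids:
        raise CorpusFormatError("no documents")
    return DocumentIndex(doc_ids, concept_sets)


def contingency(index: DocumentIndex, x: str, y: str) -> ContingencyTable:
    """The 2x2 co-occurrence table of concepts ``x`` and ``y`` in ``index``."""
    if x == y:
        raise ValueError("contingency requires two distinct concepts")
    for c in (x, y):
        if c not in index.postings:
            raise UnknownConceptError(f"concept {c!r} not in index")
    px, py = index.postings[x], index.postings[y]
    n11 = len(px & py)
    n10 = len(px) - n11
    n01 = len(py) - n11
    n00 = index.n_docs - n11 - n10 - n01
    return ContingencyTable(n11, n10, n01, n00)


def _entropy_from_probs(p: np.ndarray, axis=None) -> np.ndarray:
    # natural log; xlogy(0, 0) == 0 handles empty cells
    return -np.sum(xlogy(p, p), axis=axis)


def uncertainty_coefficient(table: ContingencyTable) -> float:
    """Symmetric uncertainty coefficient of a contingency table.

    Returns ``2*(H(X)+H(Y)-H(X,Y)) / (H(X)+H(Y))`` with entropies computed
    from the table's empirical probabilities.  The value is in [0, 1],
    symmetric in X and Y, and independent of the entropy log base.  When both
    marginals are degenerate (a concept in all documents or in none carries no
    information) the coefficient is defined as 0.
    """
    n = table.n
    if n <= 0:
        raise ValueError("contingency table is empty (N=0)")
    value = uncertainty_from_counts(
        np.array(table.n11), np.array(table.n11 + table.n10),
        np.array(table.n11 + table.n01), n,
    )
    return float(value)


def uncertainty_from_counts(n11, df_x, df_y, n_docs) -> np.ndarray:
    """Vectorized symmetric uncertainty from co-occurrence and marginal counts.

    Parameters are broadcastable arrays: joint document count(s) ``n11``,
    marginal document frequencies ``df_x`` and ``df_y``, and the corpus size
    ``n_docs``.  Used for batch profile construction; the scalar
    :func:`uncertainty_coefficient` routes through the same arithmetic.
    """
    n11 = np.asarray(n11, dtype=np.float64)
    df_x = np.asarray(df_x, dtype=np.float64)
    df_y = np.asarray(df_y, dtype=np.float64)
    n = float(n_docs)
    if np.any(n11 > df_x) or np.any(n11 > df_y) or np.any(df_x > n) or np.any(df_y > n):
        raise ValueError("marginals inconsistent with n11 or corpus size")
    px = df_x / n
    py = df_y / n
    p11 = n11 / n
    p10 = px - p11
    p01 = py - p11
    p00 = 1.0 - px - py + p11
    hx = _entropy_from_probs(np.stack([px, 1.0 - px]), axis=0)
    hy = _entropy_from_probs(np.stack([py, 1.0 - py]), axis=0)
    hxy = _entropy_from_probs(np.stack([p11, p10, p01, np.clip(p00, 0.0, 1.0)]), axis=0)
    denom = hx + hy
    with np.errstate(invalid="ignore", divide="ignore"):
        u = 2.0 * (denom - hxy) / denom
    u = np.where(denom > 0.0, u, 0.0)
    # guard the floating-point fringe: MI is mathematically in [0, min(hx, hy)]
    return np.clip(u, 0.0, 1.0)


def cooccurrence_counts(
    index: DocumentIndex, rows: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Joint document counts between ``rows`` concepts and the full vocabulary.

    Returns a dense ``(len(rows), M)`` integer array of n11 counts and the
    column vocabulary.  Sparse matrix multiplication makes this the batch
    workhorse behind network construction.
    """
    mat, vocab = index.to_sparse()
    col = {c: j for j, c in enumerate(vocab)}
    try:
        row_idx = [col[r] for r in rows]
    except KeyError as exc:
        raise UnknownConceptError(f"concept {exc} not in index") from None
    sub = mat[:, row_idx]  # docs x rows
    joint = (sub.T @ mat).toarray().astype(np.int64)
    return joint, vocab


def iter_pair_weights(
    index: DocumentIndex, entities: Sequence[str]
) -> Iterator[tuple[str, str, int, float]]:
    """Yield ``(concept_a, concept_b, n11, weight)`` for entity-feature pairs.

    One undirected pair per item, ``concept_a < concept_b`` lexicographically,
    restricted to pairs that co-occur at least once.  Feeds the weight-dump
    TSV dialect.
    """
    joint, vocab = cooccurrence_counts(index, entities)
    n = index.n_docs
    emitted: set[tuple[str, str]] = set()
    for i, e in enumerate(entities):
        dfx = index.doc_freq[e]
        cols = np.nonzero(joint[i])[0]
        for j in cols:
            other = vocab[j]
            if other == e:
                continue
            a, b = (e, other) if e < other else (other, e)
            if (a, b) in emitted:
                continue
            emitted.add((a, b))
            n11 = int(joint[i, j])
            w = float(uncertainty_from_counts(n11, dfx, index.doc_freq[other], n))
            yield a, b, n11, w
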