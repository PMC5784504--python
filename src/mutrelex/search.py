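"""Local co-occurrence search engine over an annotated background corpus.

A lightweight inverted index stands in for a PubMed-scale biomedical entity
search engine: given a query of entity terms it retrieves the documents
containing them (AND, with an optional OR group) and ranks the entities of a
target kind found in those documents.  The ranking score is a transparent
tf-idf-style surrogate,

    score(e) = sum_{d in docs} count(d, e) * log(1 + N / df(e)),

whose relative magnitudes carry the co-occurrence signal the downstream
classifiers consume; absolute values are not meaningful across corpora.

Four query strategies turn the index into per-candidate features for a
(mutation, partner) pair, using the non-target-kind entities around the
mutation as query context:

* BSSM  — mutation-only query;
* BSSA  — conjunctive query: mutation AND every context entity;
* BSSO  — mutation required, context entities as an OR group;
* BSSAO — mean over per-context-entity conjunctive (mutation AND c) queries.

Entities of the same kind as the target are excluded from the context before
querying: a second drug in the sentence distorts rather than informs a
mutation-drug query.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Corpus, EntityMention

INDEX_FORMAT_NAME = "mutrelex-index"
INDEX_FORMAT_VERSION = 1

_WORD_RE = re.compile(r"[A-Za-z0-9_][A-Za-z0-9_.\-]*")


@dataclass(frozen=True)
class SearchScoreVector:
    """The four search-engine-score features for one candidate pair."""

    bssm: float = 0.0
    bssa: float = 0.0
    bsso: float = 0.0
    bssao: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.bssm, self.bssa, self.bsso, self.bssao)


@dataclass
class IndexedCorpus:
    """Inverted index plus per-document entity counts.

    ``postings`` maps lower-cased terms (words and normalized entity forms)
    to the set of documents containing them; ``entity_counts`` maps
    ``(doc_id, kind)`` to per-entity occurrence counts keyed by normalized
    form; ``df`` is the entity document frequency used for idf weighting.
    """

    n_documents: int = 0
    postings: dict[str, set[str]] = field(default_factory=dict)
    entity_counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)

    def idf(self, entity: str) -> float:
        d = self.df.get(entity, 0)
        if d == 0:
            return 0.0
        return math.log(1.0 + self.n_documents / d)


def tokenize_text(text: str) -> list[str]:
    return [t.lower() for t in _WORD_RE.findall(text)]


def build_index(corpus: Corpus) -> IndexedCorpus:
    """Index a corpus: plain words and normalized entity forms become terms.

    Deterministic for a fixed corpus; rebuilding yields an equal index.
    """
    index = IndexedCorpus(n_documents=len(corpus))
    df_docs: dict[str, set[str]] = {}
    for doc in corpus:
        terms = set(tokenize_text(doc.text))
        for m in doc.mentions:
            terms.add(m.normalized.lower())
            counts = index.entity_counts.setdefault((doc.doc_id, m.kind), {})
            counts[m.normalized] = counts.get(m.normalized, 0) + 1
            df_docs.setdefault(m.normalized, set()).add(doc.doc_id)
        for term in terms:
            index.postings.setdefault(term, set()).add(doc.doc_id)
    index.df = {e: len(docs) for e, docs in df_docs.items()}
    return index


def retrieve(
    index: IndexedCorpus,
    required_terms: Iterable[str],
    optional_group: Iterable[str] = (),
) -> set[str]:
    """AND/OR retrieval: documents containing every required term and, when
    the optional group is non-empty, at least one optional term."""
    required = [t.lower() for t in required_terms]
    if not required:
        raise ValueError("at least one required term")
    result: set[str] | None = None
    for term in required:
        docs = index.postings.get(term, set())
        result = set(docs) if result is None else result & docs
        if not result:
            return set()
    assert result is not None
    optional = [t.lower() for t in optional_group]
    if optional:
        union: set[str] = set()
        for term in optional:
            union |= index.postings.get(term, set())
        result &= union
    return result


def score_entities(
    index: IndexedCorpus, docs: Iterable[str], target_kind: str
) -> dict[str, float]:
    """Rank target-kind entities of the retrieved documents.

    score(e) = sum over docs of count * log(1 + N/df(e)); entities with zero
    total count are omitted.
    """
    scores: dict[str, float] = {}
    for doc_id in docs:
        for entity, count in index.entity_counts.get((doc_id, target_kind), {}).items():
            scores[entity] = scores.get(entity, 0.0) + count * index.idf(entity)
    return scores


def search_score_features(
    index: IndexedCorpus,
    mutation: str,
    context: Sequence[EntityMention],
    target_kind: str,
    candidate: str,
) -> SearchScoreVector:
    """Compute the four query-strategy scores for one candidate pair.

    ``context`` holds the entity mentions surrounding the mutation (its
    sentence for sentence-level features, the whole document for
    document-level); target-kind mentions and the mutation itself are
    excluded, the rest deduplicated to normalized forms.
    """
    ctx = sorted(
        {
            m.normalized
            for m in context
            if m.kind != target_kind and m.normalized.lower() != mutation.lower()
        }
    )

    def score_for(required: list[str], optional: list[str]) -> float:
        docs = retrieve(index, required, optional)
        return score_entities(index, docs, target_kind).get(candidate, 0.0)

    bssm = score_for([mutation], [])
    if ctx:
        bssa = score_for([mutation, *ctx], [])
        bsso = score_for([mutation], ctx)
        bssao = sum(score_for([mutation, c], []) for c in ctx) / len(ctx)
    else:
        bssa = bsso = bssm
        bssao = 0.0
    return SearchScoreVector(bssm, bssa, bsso, bssao)


# ---------------------------------------------------------------------------
# Persistence (JSON text artifact with a version header)


def save_index(index: IndexedCorpus, path) -> None:
    payload = {
        "format": INDEX_FORMAT_NAME,
        "version": INDEX_FORMAT_VERSION,
        "n_documents": index.n_documents,
        "postings": {t: sorted(d) for t, d in index.postings.items()},
        "entity_counts": [
            {"doc_id": doc_id, "kind": kind, "counts": counts}
            for (doc_id, kind), counts in index.entity_counts.items()
        ],
        "df": index.df,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_index(path) -> IndexedCorpus:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != INDEX_FORMAT_NAME:
        raise ValueError(f"not a {INDEX_FORMAT_NAME} file")
    if payload.get("version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index version {payload.get('version')!r}")
    return IndexedCorpus(
        n_documents=payload["n_documents"],
        postings={t: set(d) for t, d in payload["postings"].items()},
        entity_counts={
            (rec["doc_id"], rec["kind"]): dict(rec["counts"])
            for rec in payload["entity_counts"]
        },
        df=dict(payload["df"]),
    )
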