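"""Document-level candidates, distance/frequency features, and the
distant-supervision sentence-dataset constructors.

Document-level candidate generation is exhaustive: with m unique mutations
and n unique partner entities in a document, all m x n pairs are candidates,
labelled true when the pair is asserted anywhere in the document by a gold
relation set.

The four distance/frequency features per candidate (partner generalizes the
original target-disease formulation to the gene or drug being scored):

* NTDS — number of sentences in which the mutation and the partner co-occur;
* TDFS — total mention count of the partner in the document;
* ODFS — mention count of the most frequent same-kind rival entity;
* DMCS — binary: some mutation mention has the partner as its nearest
  partner-kind mention (span-midpoint distance, ties broken leftward) and
  that mention sits in the same sentence.

Sentence datasets are built by distant supervision: a curated relation table
labels co-occurring pairs positive, everything else pseudo-negative, with
the wild-type residue check (SEQ_Filter) applied for gene partners.  A
sentence enters each labelled set at most once even when several qualifying
pairs occur in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import AnnotatedDocument, Corpus, EntityMention, RelationRecord
from .normalize import ProteinRecord, parse_mutation, seq_filter
from .search import IndexedCorpus, SearchScoreVector, search_score_features

logger = logging.getLogger(__name__)

#: Fixed feature order shared by the classifier harness and ablation tooling.
FEATURE_NAMES = ("ntds", "tdfs", "odfs", "dmcs", "bssm", "bssa", "bsso", "bssao")


@dataclass(frozen=True)
class DocCandidate:
    doc_id: str
    mutation: str
    partner: str
    partner_kind: str
    label: bool | None = None


@dataclass(frozen=True)
class DocFeatureVector:
    ntds: int
    tdfs: int
    odfs: int
    dmcs: int
    scores: SearchScoreVector

    def as_tuple(self) -> tuple[float, ...]:
        return (self.ntds, self.tdfs, self.odfs, self.dmcs) + self.scores.as_tuple()


@dataclass(frozen=True)
class SentenceExample:
    """One labelled sentence with its chosen target pair, CNN-ready.

    ``text`` is the sentence slice; ``sentence_start`` its document offset so
    mention offsets (document-anchored) can be mapped into it; ``mentions``
    holds every entity mention of the sentence, targets included.
    """

    doc_id: str
    sentence_index: int
    text: str
    sentence_start: int
    mentions: tuple[EntityMention, ...]
    mutation_mention: EntityMention
    partner_mention: EntityMention
    label: bool

    @property
    def mutation(self) -> str:
        return self.mutation_mention.normalized

    @property
    def partner(self) -> str:
        return self.partner_mention.normalized


def _unique_normalized(doc: AnnotatedDocument, kind: str) -> list[str]:
    return sorted({m.normalized for m in doc.mentions if m.kind == kind})


def generate_doc_candidates(
    document: AnnotatedDocument,
    partner_kind: str,
    gold: Iterable[RelationRecord] = (),
) -> list[DocCandidate]:
    """All m x n (mutation, partner) pairs of a document, gold-labelled.

    A pair is true iff the gold set asserts it for this document (the
    any-sentence rule: one true mention anywhere makes the document-level
    relation true).  Candidates come back in (mutation, partner) lexicographic
    order so downstream sampling is reproducible.
    """
    gold_pairs = {
        (r.mutation, r.partner)
        for r in gold
        if r.doc_id == document.doc_id and r.partner_kind == partner_kind and r.label
    }
    mutations = _unique_normalized(document, "mutation")
    partners = _unique_normalized(document, partner_kind)
    return [
        DocCandidate(document.doc_id, m, p, partner_kind, (m, p) in gold_pairs)
        for m in mutations
        for p in partners
    ]


def compute_doc_features(
    document: AnnotatedDocument,
    candidate: DocCandidate,
    index: IndexedCorpus | None = None,
) -> DocFeatureVector:
    """Evaluate NTDS/TDFS/ODFS/DMCS and the search scores for one candidate."""
    if candidate.doc_id != document.doc_id:
        raise ValueError(
            f"candidate {candidate.doc_id!r} does not belong to document {document.doc_id!r}"
        )
    mut_mentions = [
        m for m in document.mentions
        if m.kind == "mutation" and m.normalized == candidate.mutation
    ]
    partner_mentions = [
        m for m in document.mentions
        if m.kind == candidate.partner_kind and m.normalized == candidate.partner
    ]
    if not mut_mentions or not partner_mentions:
        raise ValueError(
            f"candidate ({candidate.mutation}, {candidate.partner}) has no mention "
            f"in document {document.doc_id}"
        )

    mut_sentences = {m.sentence_index for m in mut_mentions}
    partner_sentences = {m.sentence_index for m in partner_mentions}
    ntds = len(mut_sentences & partner_sentences)

    tdfs = len(partner_mentions)
    rival_counts: dict[str, int] = {}
    for m in document.mentions:
        if m.kind == candidate.partner_kind and m.normalized != candidate.partner:
            rival_counts[m.normalized] = rival_counts.get(m.normalized, 0) + 1
    odfs = max(rival_counts.values(), default=0)

    same_kind = [m for m in document.mentions if m.kind == candidate.partner_kind]
    dmcs = 0
    for mm in mut_mentions:
        # nearest partner-kind mention by span-midpoint distance, ties leftward
        nearest = min(same_kind, key=lambda p: (abs(p.midpoint - mm.midpoint), p.start))
        if (
            nearest.normalized == candidate.partner
            and nearest.sentence_index == mm.sentence_index
        ):
            dmcs = 1
            break

    if index is not None:
        context = [m for m in document.mentions if m.kind != "mutation"]
        scores = search_score_features(
            index, candidate.mutation, context, candidate.partner_kind, candidate.partner
        )
    else:
        scores = SearchScoreVector()
    return DocFeatureVector(ntds, tdfs, odfs, dmcs, scores)


# ---------------------------------------------------------------------------
# Distant-supervision sentence datasets


def _sentence_pairs(
    doc: AnnotatedDocument, sentence_index: int, partner_kind: str
) -> list[tuple[EntityMention, EntityMention]]:
    """All (mutation mention, partner mention) pairs of one sentence, in
    reading order of the mutation then the partner."""
    mentions = doc.mentions_in_sentence(sentence_index)
    muts = sorted((m for m in mentions if m.kind == "mutation"), key=lambda m: m.start)
    partners = sorted((m for m in mentions if m.kind == partner_kind), key=lambda m: m.start)
    return [(mm, pm) for mm in muts for pm in partners]


def build_pair_sentence_dataset(
    corpus: Corpus,
    relation_table: Iterable[RelationRecord],
    proteins: Mapping[str, ProteinRecord],
    partner_kind: str,
    known_relations: Iterable[RelationRecord] = (),
) -> tuple[list[SentenceExample], list[SentenceExample]]:
    """Distant-supervision construction of (positives, negatives).

    A sentence is positive when it contains a co-occurring (mutation, partner)
    pair asserted by ``relation_table`` for its document and — for gene
    partners — passing SEQ_Filter.  It is negative when it contains a
    co-occurring pair absent from ``relation_table`` and ``known_relations``
    and — for gene partners — failing SEQ_Filter.  Each sentence contributes
    at most one example per label set (the first qualifying pair in reading
    order is kept), and a sentence that qualifies as positive is never also
    emitted as negative.  DNA-level mutations cannot be residue-checked and
    are excluded from gene-pair datasets; gene partners without a protein
    record are skipped with a warning.
    """
    table_pairs = {
        (r.mutation, r.partner, r.doc_id)
        for r in relation_table
        if r.partner_kind == partner_kind
    }
    known_pairs = {
        (r.mutation, r.partner)
        for r in known_relations
        if r.partner_kind == partner_kind
    } | {(m, p) for (m, p, _) in table_pairs}

    positives: list[SentenceExample] = []
    negatives: list[SentenceExample] = []
    for doc in corpus:
        for sent_idx, _, _ in doc.sentences:
            pos_pick: tuple[EntityMention, EntityMention] | None = None
            neg_pick: tuple[EntityMention, EntityMention] | None = None
            for mm, pm in _sentence_pairs(doc, sent_idx, partner_kind):
                if partner_kind == "gene":
                    parsed = parse_mutation(mm.normalized)
                    if parsed is None:
                        continue  # DNA-level: residue check impossible
                    protein = proteins.get(pm.normalized)
                    if protein is None:
                        logger.warning(
                            "%s: no protein record for gene %s; pair skipped",
                            doc.doc_id, pm.normalized,
                        )
                        continue
                    passes = seq_filter(protein, parsed)
                else:
                    passes = True
                in_table = (mm.normalized, pm.normalized, doc.doc_id) in table_pairs
                if in_table and passes:
                    if pos_pick is None:
                        pos_pick = (mm, pm)
                elif (mm.normalized, pm.normalized) not in known_pairs:
                    if partner_kind == "gene" and passes:
                        continue  # plausible but unconfirmed: too risky as a negative
                    if neg_pick is None:
                        neg_pick = (mm, pm)
            if pos_pick is not None or neg_pick is not None:
                label = pos_pick is not None
                mm, pm = pos_pick if label else neg_pick
                _, s_start, _ = doc.sentences[sent_idx]
                sentence_mentions = tuple(
                    sorted(doc.mentions_in_sentence(sent_idx), key=lambda m: m.start)
                )
                example = SentenceExample(
                    doc.doc_id, sent_idx, doc.sentence_text(sent_idx), s_start,
                    sentence_mentions, mm, pm, label,
                )
                (positives if label else negatives).append(example)
    return positives, negatives


# ---------------------------------------------------------------------------
# Relation-table I/O (tab separated: mutation, partner, partner_kind, doc_id)


def write_relation_table(records: Iterable[RelationRecord], stream) -> None:
    stream.write("mutation\tpartner\tpartner_kind\tdoc_id\n")
    for r in records:
        stream.write(f"{r.mutation}\t{r.partner}\t{r.partner_kind}\t{r.doc_id}\n")


def read_relation_table(lines: Iterable[str], level: str = "document") -> list[RelationRecord]:
    records = []
    for i, line in enumerate(lines):
        line = line.rstrip("\n")
        if not line or (i == 0 and line.startswith("mutation\t")):
            continue
        mutation, partner, partner_kind, doc_id = line.split("\t")[:4]
        records.append(
            RelationRecord(mutation, partner, partner_kind, doc_id, True, level,
                           0 if level == "sentence" else None)
        )
    return records
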