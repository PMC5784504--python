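"""Annotated-document data model and readers/writers.

Every stage of the pipeline consumes a :class:`Corpus`: sentence-segmented
documents carrying typed, offset-anchored entity mentions (mutation, gene,
drug, disease, cell line).  Two on-disk formats are supported:

* PubTator (``ID|t|title`` / ``ID|a|abstract`` + tab-separated annotation
  lines) — the de-facto exchange format for PubMed entity annotations;
* an internal line-delimited JSON format (one document per line) chosen for
  streaming and diffability.

Offsets are 0-based half-open throughout.  PubTator abstract offsets count
from the start of the title, so title and abstract are joined by a single
space when the document text is assembled.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

ENTITY_KINDS = frozenset({"mutation", "gene", "drug", "disease", "cell_line"})

#: PubTator annotation-type spellings mapped onto the closed kind set.
_PUBTATOR_KIND_MAP = {
    "mutation": "mutation",
    "dnamutation": "mutation",
    "proteinmutation": "mutation",
    "snp": "mutation",
    "gene": "gene",
    "chemical": "drug",
    "drug": "drug",
    "disease": "disease",
    "cellline": "cell_line",
    "cell_line": "cell_line",
}

CORPUS_FORMAT_NAME = "mutrelex-corpus"
CORPUS_FORMAT_VERSION = 1


class MalformedRecordError(ValueError):
    """A record in an input stream violates the format contract."""


class CorpusFormatError(ValueError):
    """The internal corpus file is truncated or carries a wrong version."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity occurrence anchored to character offsets.

    ``start``/``end`` are 0-based half-open offsets into the *document* text;
    ``normalized`` is the canonical form used everywhere downstream (e.g. the
    one-letter mutation ``V600E``).
    """

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    kind: str
    normalized: str

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad mention span [{self.start}, {self.end}) in {self.doc_id}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class AnnotatedDocument:
    """A document with sentence spans and entity mentions.

    ``sentences`` is an ordered list of ``(sentence_index, start, end)``
    character spans; spans are disjoint and every mention lies inside exactly
    one of them.
    """

    doc_id: str
    text: str
    sentences: list[tuple[int, int, int]]
    mentions: list[EntityMention] = field(default_factory=list)

    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on breach."""
        prev_end = -1
        for i, (idx, start, end) in enumerate(self.sentences):
            if idx != i:
                raise ValueError(f"{self.doc_id}: sentence indices not consecutive")
            if not (0 <= start < end <= len(self.text)):
                raise ValueError(f"{self.doc_id}: sentence span [{start},{end}) out of range")
            if start < prev_end:
                raise ValueError(f"{self.doc_id}: overlapping sentence spans")
            prev_end = end
        for m in self.mentions:
            if m.doc_id != self.doc_id:
                raise ValueError(f"mention doc_id {m.doc_id!r} != {self.doc_id!r}")
            if self.text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: mention surface {m.surface!r} does not match "
                    f"text slice {self.text[m.start:m.end]!r} at [{m.start},{m.end})"
                )
            owner = self.sentence_of_span(m.start, m.end)
            if owner is None:
                raise ValueError(f"{self.doc_id}: mention {m.surface!r} crosses sentence spans")
            if owner != m.sentence_index:
                raise ValueError(
                    f"{self.doc_id}: mention {m.surface!r} sentence_index "
                    f"{m.sentence_index} != containing span {owner}"
                )

    def sentence_of_span(self, start: int, end: int) -> int | None:
        """Index of the sentence span containing [start, end), or None."""
        for idx, s, e in self.sentences:
            if s <= start and end <= e:
                return idx
        return None

    def sentence_text(self, index: int) -> str:
        _, s, e = self.sentences[index]
        return self.text[s:e]

    def mentions_in_sentence(self, index: int) -> list[EntityMention]:
        return [m for m in self.mentions if m.sentence_index == index]


@dataclass
class Corpus:
    documents: list[AnnotatedDocument] = field(default_factory=list)

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def validate(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            doc.validate()


@dataclass(frozen=True)
class RelationRecord:
    """A (mutation, partner) relation assertion tied to a document.

    ``level`` is ``document`` or ``sentence``; ``sentence_index`` is present
    exactly when the record is sentence-level.
    """

    mutation: str
    partner: str
    partner_kind: str
    doc_id: str
    label: bool
    level: str
    sentence_index: int | None = None

    def __post_init__(self) -> None:
        if self.partner_kind not in ("gene", "drug"):
            raise ValueError(f"partner_kind must be gene or drug, got {self.partner_kind!r}")
        if self.level not in ("document", "sentence"):
            raise ValueError(f"level must be document or sentence, got {self.level!r}")
        if (self.sentence_index is None) == (self.level == "sentence"):
            raise ValueError("sentence_index present iff level == sentence")

    def pair(self) -> tuple[str, str]:
        return (self.mutation, self.partner)


# ---------------------------------------------------------------------------
# Sentence segmentation

#: Abbreviations whose trailing period never ends a sentence.
_ABBREVIATIONS = (
    "e.g", "i.e", "cf", "vs", "et al", "Fig", "fig", "Figs", "Dr", "Prof",
    "No", "no", "approx", "ca",
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")


def split_sentences(
    text: str, mentions: Sequence[EntityMention] | tuple = ()
) -> list[tuple[int, int, int]]:
    """Rule-based sentence segmentation returning (index, start, end) spans.

    Splits after sentence-final punctuation followed by whitespace and an
    uppercase letter or digit.  A protection list suppresses boundaries after
    common abbreviations, and any candidate boundary falling strictly inside a
    supplied mention span (e.g. the period of ``p.V600E``) is ignored.  Spans
    are trimmed of surrounding whitespace; when no boundary is found a single
    span covering the text is returned.
    """
    if not text:
        return []
    protected = [(m.start, m.end) for m in mentions]
    cuts: list[int] = []
    for match in _BOUNDARY_RE.finditer(text):
        cut = match.end()  # position just after the punctuation run
        if any(s < cut <= e for s, e in protected):
            continue
        before = text[: match.start()]
        if any(before.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        cuts.append(cut)
    spans: list[tuple[int, int, int]] = []
    start = 0
    for cut in cuts + [len(text)]:
        seg = text[start:cut]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        s, e = start + lead, cut - trail
        if e > s:
            spans.append((len(spans), s, e))
        start = cut
    if not spans:
        spans = [(0, 0, len(text))]
    return spans


def assign_sentences(doc_id: str, text: str, raw_mentions: Iterable[dict]) -> AnnotatedDocument:
    """Build an AnnotatedDocument from raw mention dicts, segmenting sentences.

    Mentions crossing a sentence boundary would violate the data model; the
    splitter is given the mention spans so in-mention periods are protected.
    """
    probe = [
        EntityMention(doc_id, 0, m["start"], m["end"], m["surface"], m["kind"], m["normalized"])
        for m in raw_mentions
    ]
    spans = split_sentences(text, probe)
    doc = AnnotatedDocument(doc_id=doc_id, text=text, sentences=spans)
    for m in probe:
        owner = doc.sentence_of_span(m.start, m.end)
        if owner is None:
            raise MalformedRecordError(
                f"{doc_id}: mention {m.surface!r} at [{m.start},{m.end}) crosses sentences"
            )
        doc.mentions.append(replace(m, sentence_index=owner))
    return doc


# ---------------------------------------------------------------------------
# PubTator reader


def read_pubtator(stream: Iterable[str], strict: bool = True) -> Corpus:
    """Parse a PubTator-format stream into a Corpus.

    Each record is ``ID|t|title``, ``ID|a|abstract``, then tab-separated
    annotation lines ``(ID, start, end, surface, type, normalized)``; records
    are separated by blank lines.  Document text is title + one space +
    abstract, which is the convention PubTator offsets assume.  Unknown
    annotation types are dropped with a warning; offset/surface mismatches
    raise :class:`MalformedRecordError` under ``strict`` and are dropped with
    a warning otherwise.
    """
    documents: list[AnnotatedDocument] = []
    block: list[str] = []

    def flush(block: list[str]) -> None:
        if not block:
            return
        title_line = block[0]
        parts = title_line.split("|", 2)
        if len(parts) != 3 or parts[1] != "t":
            raise MalformedRecordError(f"missing title line, got {title_line!r}")
        doc_id, _, title = parts
        abstract = ""
        ann_start = 1
        if len(block) > 1:
            parts = block[1].split("|", 2)
            if len(parts) == 3 and parts[1] == "a" and parts[0] == doc_id:
                abstract = parts[2]
                ann_start = 2
        text = title + " " + abstract if abstract else title
        raw_mentions: list[dict] = []
        for line in block[ann_start:]:
            cols = line.split("\t")
            if len(cols) < 6:
                raise MalformedRecordError(f"{doc_id}: bad annotation line {line!r}")
            _, start_s, end_s, surface, ann_type, normalized = cols[:6]
            start, end = int(start_s), int(end_s)
            kind = _PUBTATOR_KIND_MAP.get(ann_type.lower().replace(" ", ""))
            if kind is None:
                logger.warning("%s: dropping annotation of unknown type %r", doc_id, ann_type)
                continue
            if text[start:end] != surface:
                msg = (
                    f"{doc_id}: annotation surface {surface!r} does not match text "
                    f"slice {text[start:end]!r} in line {line!r}"
                )
                if strict:
                    raise MalformedRecordError(msg)
                logger.warning("%s -- dropped", msg)
                continue
            raw_mentions.append(
                {"start": start, "end": end, "surface": surface,
                 "kind": kind, "normalized": normalized or surface}
            )
        documents.append(assign_sentences(doc_id, text, raw_mentions))

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            flush(block)
            block = []
        else:
            block.append(line)
    flush(block)
    return Corpus(documents)


def write_pubtator(corpus: Corpus, stream: IO[str]) -> None:
    """Write a corpus in PubTator format (title = first sentence heuristic).

    The internal model has no title/abstract distinction, so the first
    sentence is emitted as the title and the remainder as the abstract.
    """
    kind_out = {"mutation": "Mutation", "gene": "Gene", "drug": "Chemical",
                "disease": "Disease", "cell_line": "CellLine"}
    for doc in corpus:
        if doc.sentences:
            _, _, t_end = doc.sentences[0]
        else:
            t_end = len(doc.text)
        title = doc.text[:t_end]
        abstract = doc.text[t_end + 1 :] if t_end + 1 <= len(doc.text) else ""
        stream.write(f"{doc.doc_id}|t|{title}\n")
        stream.write(f"{doc.doc_id}|a|{abstract}\n")
        for m in sorted(doc.mentions, key=lambda m: m.start):
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t"
                f"{kind_out[m.kind]}\t{m.normalized}\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------------
# Internal line-delimited format


def _doc_to_json(doc: AnnotatedDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "sentences": [list(s) for s in doc.sentences],
        "mentions": [
            {"sentence_index": m.sentence_index, "start": m.start, "end": m.end,
             "surface": m.surface, "kind": m.kind, "normalized": m.normalized}
            for m in doc.mentions
        ],
    }


def _doc_from_json(obj: dict) -> AnnotatedDocument:
    try:
        doc = AnnotatedDocument(
            doc_id=obj["doc_id"],
            text=obj["text"],
            sentences=[tuple(s) for s in obj["sentences"]],
            mentions=[
                EntityMention(obj["doc_id"], m["sentence_index"], m["start"], m["end"],
                              m["surface"], m["kind"], m["normalized"])
                for m in obj["mentions"]
            ],
        )
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"record missing field: {exc}") from exc
    return doc


def write_corpus(corpus: Corpus, path_or_stream) -> None:
    """Write a corpus to the internal line-delimited format (one doc/line)."""
    if hasattr(path_or_stream, "write"):
        _write_corpus_stream(corpus, path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            _write_corpus_stream(corpus, fh)


def _write_corpus_stream(corpus: Corpus, fh: IO[str]) -> None:
    header = {"format": CORPUS_FORMAT_NAME, "version": CORPUS_FORMAT_VERSION,
              "n_documents": len(corpus)}
    fh.write(json.dumps(header) + "\n")
    for doc in corpus:
        fh.write(json.dumps(_doc_to_json(doc), sort_keys=True) + "\n")


def read_corpus(path_or_stream) -> Corpus:
    """Read the internal format; truncated or mis-versioned files error."""
    if hasattr(path_or_stream, "read"):
        return _read_corpus_stream(path_or_stream)
    with open(path_or_stream, "r", encoding="utf-8") as fh:
        return _read_corpus_stream(fh)


def _read_corpus_stream(fh: IO[str]) -> Corpus:
    lines = fh.read().splitlines()
    if not lines:
        raise CorpusFormatError("empty corpus file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"bad header line: {exc}") from exc
    if header.get("format") != CORPUS_FORMAT_NAME:
        raise CorpusFormatError(f"not a {CORPUS_FORMAT_NAME} file")
    if header.get("version") != CORPUS_FORMAT_VERSION:
        raise CorpusFormatError(f"unsupported version {header.get('version')!r}")
    documents = []
    for i, line in enumerate(lines[1:], start=2):
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"truncated or corrupt record at line {i}") from exc
        documents.append(_doc_from_json(obj))
    expected = header.get("n_documents")
    if expected is not None and expected != len(documents):
        raise CorpusFormatError(
            f"header promises {expected} documents, file holds {len(documents)}"
        )
    return Corpus(documents)
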