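"""Seeded generator of annotated corpora with planted relation structure.

The generator emulates the statistical shape of the data the pipeline is
built for: documents whose sentences mention mutations, genes, drugs and
diseases; curated relation tables; protein sequences consistent with the
planted mutation-gene truths; and a background corpus in which truly related
pairs co-occur at an elevated rate (the signal the search index features
pick up).

Planted structure:

* mutation-gene truth is 1:1 — each mutation belongs to exactly one gene and
  its wild-type residue matches that gene's protein sequence, so every true
  pair passes the SEQ_Filter residue check;
* mutation-drug truth is mixed 1:0 / 1:1 / 1:n, reproducing the asymmetry
  that makes drug extraction harder than gene extraction;
* each mutation also gets a decoy gene it co-occurs with but is not related
  to; a configurable fraction of decoy pairs fail the residue check (the
  rest are engineered to pass, as erroneous-but-plausible pairings do);
* positive sentences use relational trigger templates, negatives co-mention
  entities with neutral phrasing, and a configurable fraction of positives
  is expressed with non-trigger phrasing (label noise of distant
  supervision); positive sentences carry distractor entities so the
  classifier cannot succeed on bag-of-entities evidence alone;
* document-level labels follow from sentence plants by the any-sentence rule.

Everything is driven by one ``numpy`` generator seeded from the config, so a
fixed config reproduces byte-identical corpora.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .corpus import AnnotatedDocument, Corpus, EntityMention, RelationRecord
from .normalize import AMINO_ACIDS, ProteinRecord, parse_mutation, seq_filter


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_genes: int = 15
    n_drugs: int = 15
    n_mutations: int = 30
    n_documents: int = 120
    sentences_per_document: int = 5
    positive_rate: float = 0.45
    seqfilter_violation_rate: float = 0.9
    cooccurrence_boost: float = 4.0
    template_noise: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_drugs, self.n_mutations,
               self.n_documents, self.sentences_per_document) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.positive_rate < 1.0):
            raise ValueError("positive_rate must lie in (0, 1)")
        if not (0.0 <= self.seqfilter_violation_rate <= 1.0):
            raise ValueError("seqfilter_violation_rate must lie in [0, 1]")
        if self.cooccurrence_boost < 1.0:
            raise ValueError("cooccurrence_boost must be >= 1")
        if not (0.0 <= self.template_noise < 1.0):
            raise ValueError("template_noise must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted relations at both levels, plus the protein records."""

    mutation_gene: set[RelationRecord] = field(default_factory=set)
    mutation_drug: set[RelationRecord] = field(default_factory=set)
    sentence_mutation_gene: set[RelationRecord] = field(default_factory=set)
    sentence_mutation_drug: set[RelationRecord] = field(default_factory=set)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)
    drugs_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: the unrelated gene each mutation co-occurs with (negative plants)
    decoy_gene_of: dict[str, str] = field(default_factory=dict)

    def doc_level(self, partner_kind: str) -> set[RelationRecord]:
        return self.mutation_gene if partner_kind == "gene" else self.mutation_drug

    def sentence_level(self, partner_kind: str) -> set[RelationRecord]:
        if partner_kind == "gene":
            return self.sentence_mutation_gene
        return self.sentence_mutation_drug

    def relation_pairs(self, partner_kind: str) -> set[tuple[str, str]]:
        return {(r.mutation, r.partner) for r in self.doc_level(partner_kind)}


# ---------------------------------------------------------------------------
# Sentence templates.  Positives carry relational trigger phrasing; negatives
# co-mention the pair neutrally.  Slots: {mut} {gene} {drug} {disease}
# {drug2} (a distractor drug, never the target).

POSITIVE_DRUG_TEMPLATES = (
    "Patients with {disease} harboring {mut} showed marked sensitivity to {drug}.",
    "The {mut} mutation conferred resistance to {drug} in {disease} models.",
    "Tumors carrying {mut} responded durably to {drug} treatment.",
    "{mut} predicts clinical response to {drug} in {disease}.",
    "In {disease} lines expressing {gene}, {mut} was associated with sensitivity to {drug}.",
    "Unlike {drug2}, {drug} produced objective responses in {disease} patients with {mut}.",
)

POSITIVE_GENE_TEMPLATES = (
    "{mut} is an activating mutation of {gene} found in {disease}.",
    "Sequencing revealed that {mut} alters the kinase domain of {gene}.",
    "The {gene} {mut} mutation drives proliferation in {disease}.",
    "Functional assays confirmed that {mut} impairs {gene} activity in {disease}.",
)

NEGATIVE_DRUG_TEMPLATES = (
    "This cohort study of {disease} recorded {mut} status and {drug} exposure separately.",
    "Baseline characteristics included {mut} frequency, while {drug} dosing followed protocol.",
    "We screened samples for {mut} and collected {drug} pharmacokinetics in {disease}.",
    "{drug} toxicity was monitored, and {mut} was genotyped in all participants.",
)

NEGATIVE_GENE_TEMPLATES = (
    "Expression of {gene} was profiled and {mut} was genotyped in {disease} samples.",
    "The panel covered {gene} transcripts as well as the {mut} variant.",
    "We examined {gene} methylation alongside {mut} carrier status in {disease}.",
    "{mut} screening and {gene} expression analysis were performed independently.",
)

TITLE_TEMPLATES = (
    "Genomic and pharmacologic profiling in {disease}.",
    "A molecular study of biomarkers in {disease}.",
    "Targeted therapy and variant analysis in {disease}.",
)

DISEASES = tuple(f"disease{i:03d}" for i in range(8)) + (
    "non-small cell lung cancer",
    "soft tissue sarcoma",
)

_SLOT_RE = re.compile(r"\{(\w+)\}")
_SLOT_KIND = {"mut": "mutation", "gene": "gene", "drug": "drug",
              "drug2": "drug", "disease": "disease"}


def _render(template: str, slots: dict[str, str], offset: int) -> tuple[str, list[dict]]:
    """Fill a template, returning text and raw mention dicts with offsets
    relative to the document (``offset`` = sentence start)."""
    out: list[str] = []
    mentions: list[dict] = []
    cursor = 0
    pos = 0
    for m in _SLOT_RE.finditer(template):
        out.append(template[cursor : m.start()])
        pos += m.start() - cursor
        name = m.group(1)
        surface = slots[name]
        mentions.append({
            "start": offset + pos,
            "end": offset + pos + len(surface),
            "surface": surface,
            "kind": _SLOT_KIND[name],
            "normalized": surface,
        })
        out.append(surface)
        pos += len(surface)
        cursor = m.end()
    out.append(template[cursor:])
    return "".join(out), mentions


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(0, len(seq)))]


def generate(config: GeneratorConfig) -> tuple[Corpus, GroundTruth, Corpus]:
    """Generate (annotated corpus, ground truth, background corpus)."""
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:03d}" for i in range(config.n_genes)]
    drugs = [f"drugab{i:03d}" for i in range(config.n_drugs)]

    # protein sequences; positions claimed by a mutation (true or engineered
    # decoy) are reserved so later sequence edits cannot contradict them
    sequences = {
        g: "".join(_pick(rng, AMINO_ACIDS) for _ in range(int(rng.integers(200, 400))))
        for g in genes
    }
    reserved: dict[str, set[int]] = {g: set() for g in genes}

    if config.n_mutations > sum(len(s) for s in sequences.values()):
        raise ValueError("more mutations requested than available protein positions")

    truth = GroundTruth()
    mutations: list[str] = []
    seen_canonical: set[str] = set()
    mut_meta: dict[str, dict] = {}
    for i in range(config.n_mutations):
        gene = genes[i % config.n_genes]
        for _ in range(1000):
            position = int(rng.integers(1, len(sequences[gene]) + 1))
            wt = sequences[gene][position - 1]
            variant = _pick(rng, [a for a in AMINO_ACIDS if a != wt])
            canonical = f"{wt}{position}{variant}"
            if canonical not in seen_canonical and position not in reserved[gene]:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ValueError("could not draw a unique mutation")
        seen_canonical.add(canonical)
        reserved[gene].add(position)
        mutations.append(canonical)
        truth.gene_of[canonical] = gene

        # mutation-drug cardinality: 0 / 1 / 2 / 3 partners
        n_partner = int(rng.choice([0, 1, 2, 3], p=[0.2, 0.5, 0.2, 0.1]))
        chosen = rng.choice(len(drugs), size=min(n_partner, len(drugs)), replace=False)
        truth.drugs_of[canonical] = tuple(drugs[int(j)] for j in sorted(chosen))
        mut_meta[canonical] = {
            "gene": gene, "position": position, "wild_type": wt,
            "disease": _pick(rng, DISEASES),
        }

    # decoy genes: co-occurring but unrelated; a violation-rate fraction
    # fails the residue check, the rest is engineered to pass
    for canonical in mutations:
        meta = mut_meta[canonical]
        position, wt = meta["position"], meta["wild_type"]
        others = [g for g in genes if g != meta["gene"] and position <= len(sequences[g])]
        if not others:
            others = [g for g in genes if g != meta["gene"]]
        must_fail = bool(rng.random() < config.seqfilter_violation_rate)
        decoy = None
        for _ in range(200):
            g = _pick(rng, others)
            if position > len(sequences[g]):
                if must_fail:
                    decoy = g
                    break
                continue
            matches = sequences[g][position - 1] == wt
            if must_fail and not matches and position not in reserved[g]:
                decoy = g
                break
            if not must_fail:
                if matches:
                    decoy = g
                elif position not in reserved[g]:
                    seq = sequences[g]
                    sequences[g] = seq[: position - 1] + wt + seq[position:]
                    decoy = g
                else:
                    continue
                break
        if decoy is None:
            decoy = _pick(rng, others)
        if position <= len(sequences[decoy]):
            reserved[decoy].add(position)
        meta["decoy_gene"] = decoy
        truth.decoy_gene_of[canonical] = decoy
        # an unrelated drug for negative drug sentences
        unrelated = [d for d in drugs if d not in truth.drugs_of[canonical]]
        meta["decoy_drug"] = _pick(rng, unrelated) if unrelated else None

    truth.proteins = {g: ProteinRecord(g, s) for g, s in sequences.items()}

    # main corpus ----------------------------------------------------------
    documents: list[AnnotatedDocument] = []
    for d in range(config.n_documents):
        doc_id = f"DOC{d:04d}"
        n_muts = int(rng.integers(2, 4))
        doc_muts = [mutations[int(j)]
                    for j in rng.choice(len(mutations), size=n_muts, replace=False)]
        pieces: list[str] = []
        raw_mentions: list[dict] = []
        sent_records: list[tuple[str, str, str, bool]] = []  # (mut, partner, kind, positive)
        offset = 0

        def emit(template: str, slots: dict[str, str]) -> None:
            nonlocal offset
            text, ms = _render(template, slots, offset)
            pieces.append(text)
            raw_mentions.extend(ms)
            offset += len(text) + 1  # sentences joined by one space

        emit(_pick(rng, TITLE_TEMPLATES),
             {"disease": mut_meta[doc_muts[0]]["disease"]})
        sent_records.append(("", "", "", False))

        for _ in range(config.sentences_per_document):
            mut = _pick(rng, doc_muts)
            meta = mut_meta[mut]
            disease = meta["disease"] if rng.random() < 0.8 else _pick(rng, DISEASES)
            want_positive = bool(rng.random() < config.positive_rate)
            task = "drug" if rng.random() < 0.5 else "gene"
            if task == "drug" and not truth.drugs_of[mut]:
                task = "gene"
            if want_positive:
                if task == "drug":
                    partner = _pick(rng, truth.drugs_of[mut])
                    templates = POSITIVE_DRUG_TEMPLATES
                    neutral = NEGATIVE_DRUG_TEMPLATES
                else:
                    partner = meta["gene"]
                    templates = POSITIVE_GENE_TEMPLATES
                    neutral = NEGATIVE_GENE_TEMPLATES
                noisy = bool(rng.random() < config.template_noise)
                template = _pick(rng, neutral if noisy else templates)
            else:
                if task == "drug":
                    partner = meta["decoy_drug"] or _pick(rng, drugs)
                    template = _pick(rng, NEGATIVE_DRUG_TEMPLATES)
                else:
                    partner = meta["decoy_gene"]
                    template = _pick(rng, NEGATIVE_GENE_TEMPLATES)
            slots = {"mut": mut, "disease": disease}
            if task == "drug":
                slots["drug"] = partner
                # distractors are genuinely unrelated so they never create
                # accidental true-pair co-occurrences
                slots["gene"] = meta["decoy_gene"]
                distractors = [x for x in drugs
                               if x != partner and x not in truth.drugs_of[mut]]
                slots["drug2"] = _pick(rng, distractors) if distractors else partner
            else:
                slots["gene"] = partner
            emit(template, slots)
            sent_records.append((mut, partner, task, want_positive))

        text = " ".join(pieces)
        doc = AnnotatedDocument(doc_id=doc_id, text=text, sentences=[], mentions=[])
        # sentence spans follow directly from the emission offsets
        spans = []
        start = 0
        for i, piece in enumerate(pieces):
            spans.append((i, start, start + len(piece)))
            start += len(piece) + 1
        doc.sentences = spans
        for m in raw_mentions:
            idx = doc.sentence_of_span(m["start"], m["end"])
            doc.mentions.append(EntityMention(doc_id, idx, m["start"], m["end"],
                                              m["surface"], m["kind"], m["normalized"]))
        documents.append(doc)

        for idx, (mut, partner, task, positive) in enumerate(sent_records):
            if not positive:
                continue
            rec = RelationRecord(mut, partner, task, doc_id, True, "sentence", idx)
            truth.sentence_level(task).add(rec)
            truth.doc_level(task).add(
                RelationRecord(mut, partner, task, doc_id, True, "document")
            )
    corpus = Corpus(documents)

    # background corpus: true pairs co-occur at boosted rates --------------
    bg_documents: list[AnnotatedDocument] = []
    bg_counter = 0

    def bg_doc(mut: str, partner: str, kind: str, disease: str) -> None:
        nonlocal bg_counter
        doc_id = f"BG{bg_counter:05d}"
        bg_counter += 1
        template = "Co-occurrence of {mut} and {partner} reported in {disease}."
        text, _ = _render(
            template.replace("{partner}", "{" + kind + "}"),
            {"mut": mut, kind: partner, "disease": disease}, 0,
        )
        _, ms = _render(
            template.replace("{partner}", "{" + kind + "}"),
            {"mut": mut, kind: partner, "disease": disease}, 0,
        )
        doc = AnnotatedDocument(doc_id, text, [(0, 0, len(text))])
        for m in ms:
            doc.mentions.append(EntityMention(doc_id, 0, m["start"], m["end"],
                                              m["surface"], m["kind"], m["normalized"]))
        bg_documents.append(doc)

    for mut in mutations:
        meta = mut_meta[mut]
        true_pairs = [(meta["gene"], "gene")] + [(d, "drug") for d in truth.drugs_of[mut]]
        decoy_pairs = [(meta["decoy_gene"], "gene")]
        if meta["decoy_drug"]:
            decoy_pairs.append((meta["decoy_drug"], "drug"))
        for partner, kind in true_pairs:
            for _ in range(1 + int(rng.poisson(config.cooccurrence_boost))):
                bg_doc(mut, partner, kind, meta["disease"])
        for partner, kind in decoy_pairs:
            for _ in range(int(rng.poisson(1.0))):
                bg_doc(mut, partner, kind, _pick(rng, DISEASES))
    background = Corpus(bg_documents)

    corpus.validate()
    background.validate()
    _check_truth(truth)
    return corpus, truth, background


def _check_truth(truth: GroundTruth) -> None:
    for mut, gene in truth.gene_of.items():
        parsed = parse_mutation(mut)
        assert parsed is not None
        if not seq_filter(truth.proteins[gene], parsed):
            raise AssertionError(f"planted pair ({mut}, {gene}) fails the residue check")


def corpus_statistics(corpus: Corpus, truth: GroundTruth | None = None) -> dict:
    """Counts used by tests and logs to verify generator contracts."""
    stats = {
        "documents": len(corpus),
        "sentences": sum(len(d.sentences) for d in corpus),
        "mentions": {k: 0 for k in ("mutation", "gene", "drug", "disease", "cell_line")},
    }
    for doc in corpus:
        for m in doc.mentions:
            stats["mentions"][m.kind] += 1
    if truth is not None:
        stats["doc_positives"] = {
            "gene": len(truth.mutation_gene), "drug": len(truth.mutation_drug),
        }
        stats["sentence_positives"] = {
            "gene": len(truth.sentence_mutation_gene),
            "drug": len(truth.sentence_mutation_drug),
        }
    return stats
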