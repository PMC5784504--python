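import math

import numpy as np
import pytest

from mutrelex.corpus import AnnotatedDocument, Corpus, EntityMention
from mutrelex.search import (
    IndexedCorpus, build_index, load_index, retrieve, save_index,
    score_entities, search_score_features, tokenize_text,
)
from mutrelex.synthetic import GeneratorConfig, generate


def make_doc(doc_id, items):
    """Build a one-sentence document from words and (surface, kind) pairs."""
    words, mentions = [], []
    pos = 0
    for item in items:
        if isinstance(item, tuple):
            surface, kind = item
            mentions.append((pos, pos + len(surface), surface, kind))
            words.append(surface)
            pos += len(surface) + 1
        else:
            words.append(item)
            pos += len(item) + 1
    text = " ".join(words)
    doc = AnnotatedDocument(doc_id, text, [(0, 0, len(text))])
    for s, e, surface, kind in mentions:
        doc.mentions.append(EntityMention(doc_id, 0, s, e, surface, kind, surface))
    return doc


@pytest.fixture()
def fixture_corpus():
    """Five documents: mutation M1 with drug D1 in 3 of them, gene G1 in 2."""
    return Corpus([
        make_doc("d1", [("V600E", "mutation"), "with", ("dtest1", "drug"),
                        "and", ("GENEX", "gene")]),
        make_doc("d2", [("V600E", "mutation"), "with", ("dtest1", "drug"),
                        "and", ("GENEX", "gene")]),
        make_doc("d3", [("V600E", "mutation"), "with", ("dtest1", "drug")]),
        make_doc("d4", [("V600E", "mutation"), "alone", "here"]),
        make_doc("d5", [("dtest1", "drug"), "without", "mutation"]),
    ])


def doc_terms(doc):
    return set(tokenize_text(doc.text)) | {m.normalized.lower() for m in doc.mentions}


def brute_retrieve(corpus, required, optional=()):
    required = [t.lower() for t in required]
    optional = [t.lower() for t in optional]
    out = set()
    for doc in corpus:
        terms = doc_terms(doc)
        if all(t in terms for t in required):
            if not optional or any(t in terms for t in optional):
                out.add(doc.doc_id)
    return out


def brute_scores(corpus, docs, kind):
    n = len(corpus)
    counts, df = {}, {}
    for doc in corpus:
        seen = set()
        for m in doc.mentions:
            if m.normalized not in seen:
                df[m.normalized] = df.get(m.normalized, 0) + 1
                seen.add(m.normalized)
            if m.kind == kind and doc.doc_id in docs:
                counts.setdefault(m.normalized, 0)
                counts[m.normalized] += 1
    return {
        e: c * math.log(1 + n / df[e]) for e, c in counts.items() if c > 0
    }


class TestBuildIndex:
    def test_counts_on_hand_fixture(self):
        corpus = Corpus([
            make_doc("d1", [("V600E", "mutation"), "and", ("BRAF", "gene"),
                            "then", ("BRAF", "gene"), "again"]),
        ])
        index = build_index(corpus)
        assert index.df["V600E"] == 1
        assert index.entity_counts[("d1", "gene")]["BRAF"] == 2

    def test_empty_corpus(self):
        index = build_index(Corpus([]))
        assert index.n_documents == 0
        assert index.postings == {} and index.df == {}

    def test_rebuild_is_identical(self, fixture_corpus):
        a, b = build_index(fixture_corpus), build_index(fixture_corpus)
        assert a.n_documents == b.n_documents
        assert a.postings == b.postings
        assert a.entity_counts == b.entity_counts
        assert a.df == b.df

    def test_df_bounded_by_document_count(self, default_index):
        assert all(0 < d <= default_index.n_documents for d in default_index.df.values())


class TestRetrieve:
    def test_single_term(self, fixture_corpus):
        index = build_index(fixture_corpus)
        assert retrieve(index, {"V600E"}) == {"d1", "d2", "d3", "d4"}

    def test_conjunction_is_subset(self, fixture_corpus):
        index = build_index(fixture_corpus)
        both = retrieve(index, {"V600E", "dtest1"})
        assert both == {"d1", "d2", "d3"}
        assert both <= retrieve(index, {"V600E"})

    def test_absent_term_empty(self, fixture_corpus):
        index = build_index(fixture_corpus)
        assert retrieve(index, {"absent-term"}) == set()

    def test_optional_group_restricts(self, fixture_corpus):
        index = build_index(fixture_corpus)
        with_opt = retrieve(index, {"V600E"}, {"GENEX"})
        assert with_opt == {"d1", "d2"}
        assert with_opt <= retrieve(index, {"V600E"})

    def test_requires_at_least_one_term(self, fixture_corpus):
        with pytest.raises(ValueError):
            retrieve(build_index(fixture_corpus), set())

    def test_matches_enumeration_oracle_on_random_corpora(self):
        _, _, background = generate(GeneratorConfig(seed=3, n_documents=10))
        index = build_index(background)
        rng = np.random.default_rng(0)
        entities = sorted(index.df)
        for _ in range(50):
            req = list(rng.choice(entities, size=rng.integers(1, 3), replace=False))
            opt = list(rng.choice(entities, size=rng.integers(0, 3), replace=False))
            assert retrieve(index, req, opt) == brute_retrieve(background, req, opt)


class TestScoreEntities:
    def test_empty_docs_empty_map(self, fixture_corpus):
        assert score_entities(build_index(fixture_corpus), set(), "drug") == {}

    def test_formula_on_hand_fixture(self):
        # 4 documents; entity counted twice in one doc, df = 1 -> 2 * log(5)
        corpus = Corpus([
            make_doc("d1", [("dtest1", "drug"), "and", ("dtest1", "drug")]),
            make_doc("d2", ["plain", "words"]),
            make_doc("d3", ["plain", "again"]),
            make_doc("d4", ["still", "plain"]),
        ])
        scores = score_entities(build_index(corpus), {"d1"}, "drug")
        assert scores["dtest1"] == pytest.approx(2 * math.log(5))

    def test_matches_brute_force_on_fixture(self, fixture_corpus):
        index = build_index(fixture_corpus)
        docs = retrieve(index, {"V600E"})
        assert score_entities(index, docs, "drug") == pytest.approx(
            brute_scores(fixture_corpus, docs, "drug")
        )


class TestSearchScoreFeatures:
    def test_absent_candidate_all_zero(self, fixture_corpus):
        index = build_index(fixture_corpus)
        vec = search_score_features(index, "V600E", [], "drug", "neverseen")
        assert vec.as_tuple() == (0.0, 0.0, 0.0, 0.0)

    def test_empty_context_collapses_strategies(self, fixture_corpus):
        index = build_index(fixture_corpus)
        vec = search_score_features(index, "V600E", [], "drug", "dtest1")
        assert vec.bssa == vec.bsso == vec.bssm
        assert vec.bssao == 0.0

    def test_hand_enumerated_fixture(self, fixture_corpus):
        index = build_index(fixture_corpus)
        gene_ctx = [EntityMention("q", 0, 0, 5, "GENEX", "gene", "GENEX")]
        vec = search_score_features(index, "V600E", gene_ctx, "drug", "dtest1")
        # bssm over {d1,d2,d3}; conjunctive and optional strategies over {d1,d2}
        expected_m = brute_scores(fixture_corpus, {"d1", "d2", "d3"}, "drug")["dtest1"]
        expected_ag = brute_scores(fixture_corpus, {"d1", "d2"}, "drug")["dtest1"]
        assert vec.bssm == pytest.approx(expected_m)
        assert vec.bssa == pytest.approx(expected_ag)
        assert vec.bsso == pytest.approx(expected_ag)
        assert vec.bssao == pytest.approx(expected_ag)

    def test_same_kind_context_is_excluded(self, fixture_corpus):
        index = build_index(fixture_corpus)
        gene_ctx = [EntityMention("q", 0, 0, 5, "GENEX", "gene", "GENEX")]
        with_drug = gene_ctx + [
            EntityMention("q", 0, 6, 12, "dtest9", "drug", "dtest9")
        ]
        a = search_score_features(index, "V600E", gene_ctx, "drug", "dtest1")
        b = search_score_features(index, "V600E", with_drug, "drug", "dtest1")
        assert a == b

    def test_monotone_under_supporting_document(self, fixture_corpus):
        index = build_index(fixture_corpus)
        gene_ctx = [EntityMention("q", 0, 0, 5, "GENEX", "gene", "GENEX")]
        before = search_score_features(index, "V600E", gene_ctx, "drug", "dtest1")
        extra = make_doc("d6", [("V600E", "mutation"), ("GENEX", "gene"),
                                ("dtest1", "drug")])
        bigger = Corpus(list(fixture_corpus.documents) + [extra])
        after = search_score_features(build_index(bigger), "V600E", gene_ctx,
                                      "drug", "dtest1")
        for x, y in zip(before.as_tuple(), after.as_tuple()):
            assert y >= x - 1e-12


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, fixture_corpus):
        index = build_index(fixture_corpus)
        path = tmp_path / "index.json"
        save_index(index, path)
        back = load_index(path)
        assert back.n_documents == index.n_documents
        assert back.postings == index.postings
        assert back.entity_counts == index.entity_counts
        assert back.df == index.df
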