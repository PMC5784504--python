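import dataclasses

import numpy as np
import pytest

from mutrelex.corpus import EntityMention
from mutrelex.cnn import (
    CnnConfig, Vocab, build_and_train, encode_examples, encode_sentence,
    example_vocab, load_word_vectors, make_cnn_trainer, predict,
    save_word_vectors, sentence_tokens, train_word_vectors, TYPE_ALPHABET,
    WordVectors, PAD_ID,
)
from mutrelex.docfeatures import build_pair_sentence_dataset
from mutrelex.synthetic import GeneratorConfig, generate

SMALL = CnnConfig(word_dim=24, type_dim=4, pos_dim=4, maps_per_width=8,
                  filter_widths=(2, 3), epochs=3, batch_size=16,
                  max_sentence_len=15, seed=0)


def toy_sentence():
    """'M1 found near drugA today .' with mutation at token 0, drug at token 3."""
    text = "M1 found near drugA today"
    mut = EntityMention("d", 0, 0, 2, "M1", "mutation", "M1")
    drug = EntityMention("d", 0, 14, 19, "drugA", "drug", "drugA")
    return text, [mut, drug], mut, drug


class TestEncodeSentence:
    def test_relative_positions(self):
        text, mentions, mut, drug = toy_sentence()
        vocab = Vocab(["m1", "found", "near", "druga", "today"])
        enc = encode_sentence(text, 0, mentions, mut, drug, vocab, SMALL)
        L = SMALL.max_sentence_len
        # 5 tokens; offsets from mutation (token 0): 0..4; from drug (token 3)
        assert list(enc.rel_pos_mut[:5]) == [o + L + 1 for o in [0, 1, 2, 3, 4]]
        assert list(enc.rel_pos_partner[:5]) == [o + L + 1 for o in [-3, -2, -1, 0, 1]]
        assert list(enc.rel_pos_mut[5:]) == [0] * (L - 5)  # pad sentinel

    def test_exactly_one_target_of_each_type(self):
        text, mentions, mut, drug = toy_sentence()
        other = EntityMention("d", 0, 20, 25, "today", "drug", "drugB")
        enc = encode_sentence(text + " tail", 0, mentions + [other], mut, drug,
                              Vocab([]), SMALL)
        types = [TYPE_ALPHABET[t] for t in enc.type_ids]
        assert types.count("target_mutation") == 1
        assert types.count("target_drug") == 1
        assert types.count("other_drug") == 1

    def test_non_target_gene_typed_other_gene(self):
        text = "M1 in GENEX with drugA"
        mut = EntityMention("d", 0, 0, 2, "M1", "mutation", "M1")
        gene = EntityMention("d", 0, 6, 11, "GENEX", "gene", "GENEX")
        drug = EntityMention("d", 0, 17, 22, "drugA", "drug", "drugA")
        enc = encode_sentence(text, 0, [mut, gene, drug], mut, drug, Vocab([]), SMALL)
        types = [TYPE_ALPHABET[t] for t in enc.type_ids]
        assert "other_gene" in types and "target_gene" not in types

    def test_truncation_window_covers_both_targets(self):
        words = [f"w{i}" for i in range(40)]
        words[18], words[22] = "M1", "drugA"
        text = " ".join(words)
        start18 = sum(len(w) + 1 for w in words[:18])
        start22 = sum(len(w) + 1 for w in words[:22])
        mut = EntityMention("d", 0, start18, start18 + 2, "M1", "mutation", "M1")
        drug = EntityMention("d", 0, start22, start22 + 5, "drugA", "drug", "drugA")
        enc = encode_sentence(text, 0, [mut, drug], mut, drug, Vocab([]), SMALL)
        types = [TYPE_ALPHABET[t] for t in enc.type_ids]
        assert types.count("target_mutation") == 1
        assert types.count("target_drug") == 1
        assert (enc.token_ids != PAD_ID).sum() == SMALL.max_sentence_len

    def test_target_outside_sentence_is_contract_violation(self):
        text, mentions, mut, drug = toy_sentence()
        stranger = EntityMention("d", 0, 0, 2, "M9", "mutation", "M9")
        with pytest.raises(ValueError):
            encode_sentence(text, 0, mentions, stranger, drug, Vocab([]), SMALL)

    def test_entity_mentions_collapse_to_single_tokens(self):
        text = "M1 causes non-small cell lung cancer badly"
        mut = EntityMention("d", 0, 0, 2, "M1", "mutation", "M1")
        dis = EntityMention("d", 0, 10, 36, "non-small cell lung cancer",
                            "disease", "non-small cell lung cancer")
        tokens, owners = sentence_tokens(text, 0, [mut, dis])
        assert tokens == ["M1", "causes", "non-small_cell_lung_cancer", "badly"]
        assert owners[2] == dis


@pytest.fixture(scope="module")
def small_dataset():
    # template_noise 0: every positive carries trigger phrasing, so the
    # sentences alone are fully separable
    corpus, truth, bg = generate(
        GeneratorConfig(seed=5, n_documents=80, template_noise=0.0))
    table = sorted(truth.sentence_mutation_drug | truth.sentence_mutation_gene, key=str)
    pos, neg = build_pair_sentence_dataset(corpus, table, truth.proteins, "drug")
    return pos, neg


class TestTraining:
    def test_template_separable_training_f1(self, small_dataset):
        pos, neg = small_dataset
        examples = pos[:60] + neg[:60]
        vocab = example_vocab(examples)
        cfg = dataclasses.replace(SMALL, epochs=6)
        enc = encode_examples(examples, vocab, cfg)
        model = build_and_train(cfg, enc, [], vocab=vocab)
        probs = predict(model, enc)
        truth = np.array([e.label for e in examples])
        from mutrelex.evaluation import prf_from_predictions
        assert prf_from_predictions(truth, probs > 0.5).f1 >= 0.95

    def test_training_is_reproducible(self, small_dataset):
        pos, neg = small_dataset
        examples = pos[:20] + neg[:20]
        vocab = example_vocab(examples)
        enc = encode_examples(examples, vocab, SMALL)
        m1 = build_and_train(SMALL, enc, enc[:10], vocab=vocab)
        m2 = build_and_train(SMALL, enc, enc[:10], vocab=vocab)
        assert [h["dev_f1"] for h in m1.history] == [h["dev_f1"] for h in m2.history]
        assert np.array_equal(predict(m1, enc), predict(m2, enc))

    def test_probabilities_sum_to_one_and_empty_input(self, small_dataset):
        pos, neg = small_dataset
        examples = pos[:8] + neg[:8]
        vocab = example_vocab(examples)
        enc = encode_examples(examples, vocab, SMALL)
        model = build_and_train(SMALL, enc, [], vocab=vocab)
        p_true = predict(model, enc)
        assert ((0 <= p_true) & (p_true <= 1)).all()
        assert predict(model, []).shape == (0,)

    def test_scalar_translation_invariance(self, small_dataset):
        # standardization absorbs a uniform shift of all scalar inputs
        pos, neg = small_dataset
        examples = pos[:16] + neg[:16]
        vocab = example_vocab(examples)
        enc = encode_examples(examples, vocab, SMALL)
        base = [dataclasses.replace(x, scalar_features=np.full(4, i % 3, dtype=float))
                for i, x in enumerate(enc)]
        shifted = [dataclasses.replace(x, scalar_features=x.scalar_features + 5.0)
                   for x in base]
        m_base = build_and_train(SMALL, base, [], vocab=vocab)
        m_shift = build_and_train(SMALL, shifted, [], vocab=vocab)
        np.testing.assert_allclose(predict(m_base, base), predict(m_shift, shifted),
                                   atol=1e-8)

    def test_mismatched_vector_dim_is_configuration_error(self, small_dataset):
        pos, neg = small_dataset
        examples = pos[:8] + neg[:8]
        vocab = example_vocab(examples)
        enc = encode_examples(examples, vocab, SMALL)
        wrong = WordVectors(["tumors"], np.zeros((1, 7)))
        with pytest.raises(ValueError, match="word_dim"):
            build_and_train(SMALL, enc, [], initial_vectors=wrong, vocab=vocab)


class TestWordVectors:
    def test_min_count_excludes_rare_words(self):
        corpus, _, _ = generate(GeneratorConfig(seed=6, n_documents=30))
        counts = {}
        for doc in corpus:
            for idx, _, _ in doc.sentences:
                for tok in doc.sentence_text(idx).split():
                    counts[tok] = counts.get(tok, 0) + 1
        wv = train_word_vectors(corpus, [], dim=16, min_count=5, seed=0, epochs=1)
        rare = [w for w, c in counts.items() if c < 5]
        assert rare, "fixture must contain rare words"
        assert not any(w in wv for w in rare)
        assert all(len(wv[w]) == 16 for w in wv.words[:5])

    def test_merged_entity_is_single_vocabulary_entry(self):
        corpus, _, _ = generate(GeneratorConfig(seed=7, n_documents=60))
        lexicon = ["non-small cell lung cancer"]
        wv = train_word_vectors(corpus, lexicon, dim=16, min_count=5, seed=0, epochs=1)
        assert "non-small_cell_lung_cancer" in wv

    def test_shared_context_drugs_closer_than_random_word(self):
        wins = 0
        for seed in range(5):
            corpus, truth, _ = generate(GeneratorConfig(seed=30 + seed, n_documents=60))
            wv = train_word_vectors(corpus, [], dim=32, min_count=5,
                                    seed=seed, epochs=3)
            drugs = [w for w in wv.words if w.startswith("drugab")]
            plain = [w for w in wv.words
                     if not w.startswith(("drugab", "GENE", "disease"))]
            def cos(a, b):
                return float(wv[a] @ wv[b] /
                             (np.linalg.norm(wv[a]) * np.linalg.norm(wv[b])))
            rng = np.random.default_rng(seed)
            d1, d2 = rng.choice(drugs, size=2, replace=False)
            w = plain[int(rng.integers(0, len(plain)))]
            wins += int(cos(d1, d2) > cos(d1, w))
        assert wins >= 3  # majority vote over 5 seeds

    @pytest.mark.parametrize("binary", [False, True])
    def test_word2vec_round_trip(self, tmp_path, binary):
        rng = np.random.default_rng(0)
        wv = WordVectors(["alpha", "beta_gamma", "V600E"], rng.normal(size=(3, 8)))
        path = tmp_path / ("v.bin" if binary else "v.txt")
        save_word_vectors(wv, path, binary=binary)
        back = load_word_vectors(path, binary=binary)
        assert back.words == wv.words
        np.testing.assert_allclose(back.matrix, wv.matrix, atol=1e-5)

    def test_truncated_binary_file_is_format_error(self, tmp_path):
        rng = np.random.default_rng(0)
        wv = WordVectors(["alpha", "beta"], rng.normal(size=(2, 8)))
        path = tmp_path / "v.bin"
        save_word_vectors(wv, path, binary=True)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 10])
        with pytest.raises(ValueError, match="truncated"):
            load_word_vectors(path, binary=True)
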