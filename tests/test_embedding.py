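"""k-mer tokenization, skip-gram training, and sequence vectorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from its2vec import (
    EmbeddingModel,
    EmbeddingParams,
    Its2vecError,
    ModelFormatError,
    SyntheticConfig,
    build_corpus,
    generate_dataset,
    tokenize,
    train_embedding,
    vectorize_dataset,
    vectorize_sequence,
)
from its2vec import partition_subsets

from conftest import make_record


class TestTokenize:
    def test_worked_3mer_example(self):
        assert tokenize("TAGAG", 3) == ["TAG", "AGA", "GAG"]

    def test_shorter_than_k_is_empty(self):
        assert tokenize("ACG", 9) == []

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120),
           st.integers(3, 12))
    @settings(max_examples=200, deadline=None)
    def test_count_identity(self, seq, k):
        tokens = tokenize(seq, k)
        assert len(tokens) == max(len(seq) - k + 1, 0)
        assert all(len(t) == k for t in tokens)

    def test_tokens_overlap_in_order(self):
        seq = "ACGTACG"
        tokens = tokenize(seq, 4)
        for i, token in enumerate(tokens):
            assert seq[i:i + 4] == token


class TestBuildCorpus:
    def test_sentence_lengths(self):
        records = [make_record(accession="A", sequence="A" * 100),
                   make_record(accession="B", sequence="C" * 50)]
        corpus = build_corpus(records, 9)
        assert [len(s) for s in corpus.sentences] == [92, 42]

    def test_empty_records(self):
        corpus = build_corpus([], 9)
        assert corpus.sentences == []

    def test_short_records_skipped_and_logged(self):
        records = [make_record(accession="long", sequence="ACGTACGTACGT"),
                   make_record(accession="short", sequence="ACG")]
        corpus = build_corpus(records, 9)
        assert len(corpus.sentences) == 1
        assert corpus.skipped == ["short"]

    def test_token_multiset_matches_per_record_tokenization(self, tiny_records):
        corpus = build_corpus(tiny_records, 6)
        from collections import Counter
        direct = Counter(t for r in tiny_records for t in tokenize(r.sequence, 6))
        in_corpus = Counter(t for s in corpus.sentences for t in s)
        assert direct == in_corpus


class TestTraining:
    def test_vocab_covers_corpus_with_min_count_1(self, tiny_records, tiny_model):
        corpus = build_corpus(tiny_records, 6)
        tokens = {t for s in corpus.sentences for t in s}
        assert set(tiny_model.vocab) == tokens

    def test_vector_dimension(self, tiny_model):
        assert tiny_model.vectors.shape == (len(tiny_model.vocab), 32)

    def test_seeded_training_is_bitwise_reproducible(self, tiny_records):
        corpus = build_corpus(tiny_records, 6)
        params = EmbeddingParams(k=6, dim=16, epochs=2, seed=42)
        a = train_embedding(corpus, params)
        b = train_embedding(corpus, params)
        assert a.vocab == b.vocab
        assert np.array_equal(a.vectors, b.vectors)

    def test_different_seeds_differ(self, tiny_records):
        corpus = build_corpus(tiny_records, 6)
        a = train_embedding(corpus, EmbeddingParams(k=6, dim=16, epochs=1, seed=1))
        b = train_embedding(corpus, EmbeddingParams(k=6, dim=16, epochs=1, seed=2))
        assert not np.array_equal(a.vectors, b.vectors)

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(Its2vecError):
            train_embedding(build_corpus([], 9), EmbeddingParams())

    def test_min_count_filters_vocabulary(self, tiny_records):
        corpus = build_corpus(tiny_records, 6)
        model = train_embedding(
            corpus, EmbeddingParams(k=6, dim=8, epochs=1, min_count=3, seed=0))
        from collections import Counter
        counts = Counter(t for s in corpus.sentences for t in s)
        assert set(model.vocab) == {t for t, c in counts.items() if c >= 3}

    def test_ambiguity_letters_are_vocabulary(self):
        records = [make_record(sequence="ACGTNNACGTNN" * 4)]
        model = train_embedding(build_corpus(records, 4),
                                EmbeddingParams(k=4, dim=8, epochs=1, seed=0))
        assert any("N" in token for token in model.vocab)


class TestVectorize:
    def test_length_k_sequence_is_its_kmer_vector(self, tiny_model):
        token = next(iter(tiny_model.vocab))
        vec = vectorize_sequence(token, tiny_model)
        assert np.allclose(vec, tiny_model[token])

    def test_two_token_sequence_is_elementwise_mean(self, tiny_model):
        # a 7-base sequence has exactly two 6-mers
        seq = None
        for token in tiny_model.vocab:
            for base in "ACGT":
                if (token[1:] + base) in tiny_model.vocab:
                    seq = token + base
                    break
            if seq:
                break
        assert seq is not None
        u = tiny_model[seq[:6]]
        v = tiny_model[seq[1:]]
        assert np.allclose(vectorize_sequence(seq, tiny_model), (u + v) / 2)

    def test_all_novel_tokens_give_zero_vector_and_flag(self, tiny_model):
        vec, n_tokens, n_oov = vectorize_sequence(
            "N" * 40, tiny_model, return_stats=True)
        assert not vec.any()
        assert n_tokens == 35 and n_oov == 35

    def test_short_sequence_gives_zero_vector(self, tiny_model):
        vec, n_tokens, n_oov = vectorize_sequence("ACG", tiny_model,
                                                  return_stats=True)
        assert not vec.any() and n_tokens == 0

    def test_averaging_linearity(self, tiny_model, tiny_records):
        """Concatenating token multisets averages with token-count weights."""
        s1 = tiny_records[0].sequence
        s2 = tiny_records[4].sequence
        v1, n1, o1 = vectorize_sequence(s1, tiny_model, return_stats=True)
        v2, n2, o2 = vectorize_sequence(s2, tiny_model, return_stats=True)
        w1, w2 = n1 - o1, n2 - o2
        ids = [tiny_model.vocab[t]
               for s in (s1, s2) for t in tokenize(s, 6)
               if t in tiny_model.vocab]
        pooled = tiny_model.vectors[ids].mean(axis=0, dtype=np.float64)
        assert np.allclose(pooled, (w1 * v1 + w2 * v2) / (w1 + w2))


class TestVectorizeDataset:
    def test_shape_and_labels(self, tiny_records, tiny_model):
        subsets = partition_subsets(tiny_records)
        (subset,) = subsets.values()
        data = vectorize_dataset(subset, tiny_model)
        assert data.X.shape == (len(subset.records), 32)
        assert data.y.shape == (len(subset.records),)
        assert sorted(data.label_map) == list(range(subset.n_classes))
        assert not data.flagged

    def test_rows_follow_record_order(self, tiny_records, tiny_model):
        subsets = partition_subsets(tiny_records)
        (subset,) = subsets.values()
        data = vectorize_dataset(subset, tiny_model)
        for i in (0, 7, 12):
            expected = vectorize_sequence(subset.records[i].sequence, tiny_model)
            assert np.allclose(data.X[i], expected)


class TestPersistence:
    def test_save_load_roundtrip_exact(self, tiny_model, tmp_path):
        path = tmp_path / "model.kv"
        tiny_model.save(path)
        loaded = EmbeddingModel.load(path)
        assert loaded.vocab == tiny_model.vocab
        assert np.array_equal(loaded.vectors, tiny_model.vectors)
        assert loaded.params.k == 6

    def test_load_rejects_garbage(self, tmp_path):
        path = tmp_path / "junk.kv"
        path.write_text("not a model\n1 2 3\n")
        with pytest.raises(ModelFormatError):
            EmbeddingModel.load(path)


def test_cooccurring_kmers_are_more_similar_than_cross_species():
    """Distributional-semantics smoke test: k-mers that co-occur within a
    species' sequences end up closer (centered cosine) than k-mers drawn from
    different species."""
    records = generate_dataset(SyntheticConfig(
        n_species=10, seqs_per_species=8, length_low=400, length_high=400,
        substitution_rate_within=0.02, seed=21))
    k = 7
    corpus = build_corpus(records, k)
    model = train_embedding(
        corpus, EmbeddingParams(k=k, window=4, dim=50, epochs=10, seed=33))
    rng = np.random.default_rng(0)
    V = model.vectors - model.vectors.mean(axis=0)
    V = V / np.linalg.norm(V, axis=1, keepdims=True)

    def cos(t1, t2):
        return float(V[model.vocab[t1]] @ V[model.vocab[t2]])

    sents = corpus.sentences
    same, cross = [], []
    while len(same) < 1000 or len(cross) < 1000:
        s = rng.integers(len(sents))
        i = rng.integers(len(sents[s]) - 4)
        t1, t2 = sents[s][i], sents[s][i + rng.integers(1, 5)]
        if t1 != t2:
            same.append(cos(t1, t2))
        s1, s2 = rng.choice(len(sents), 2, replace=False)
        u1 = sents[s1][rng.integers(len(sents[s1]))]
        u2 = sents[s2][rng.integers(len(sents[s2]))]
        if u1 != u2:
            cross.append(cos(u1, u2))
    assert np.mean(same) > np.mean(cross) + 0.05
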