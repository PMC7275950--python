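"""Distributed representation of barcode sequences.

A sequence of length N is tokenized into its N - k + 1 overlapping k-mers by
sliding a window of size k along it. The k-mer "words" across all sequences
form a corpus on which a skip-gram word embedding is trained; each k-mer then
maps to a dense real vector (default dimension 100), and a whole sequence is
represented by the elementwise mean of its k-mers' vectors — a fixed-length
dense feature vector regardless of sequence length. This replaces the sparse
4^k-dimensional k-mer frequency representation (65,536 features at k=8) used
by frequency-based barcode classifiers.

The embedding is trained unsupervised on the full corpus before any
cross-validation split, with ``min_count=1`` so the vocabulary covers every
corpus token; tokens containing IUPAC ambiguity letters are legitimate
vocabulary entries. At inference, out-of-vocabulary k-mers are skipped in the
averaging; a sequence with no in-vocabulary k-mer (or shorter than k) maps to
the zero vector and is flagged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _sgns
from .errors import Its2vecError, ModelFormatError
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingParams:
    """Skip-gram training parameters.

    ``window`` is the (maximal) symmetric context half-width; the effective
    window per center token is reduced uniformly, as in the reference
    skip-gram implementation. ``deterministic`` pins training to a single
    worker (this implementation is always single-threaded, so seeded runs are
    bitwise reproducible either way).
    """

    k: int = 9
    window: int = 4
    dim: int = 100
    epochs: int = 5
    min_count: int = 1
    negative_samples: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    subsample: float = 1e-3
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def tokenize(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers of a sequence, in order; empty if len(sequence) < k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    return [sequence[i:i + k] for i in range(n - k + 1)]


def kmer_feature_space_size(k: int) -> int:
    """Dimensionality of the k-mer *frequency* feature space over {A,C,G,T}."""
    return 4 ** k


@dataclass
class KmerCorpus:
    """One token sentence per sequence, plus the accessions too short to tokenize."""

    sentences: list[list[str]]
    k: int
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)


def build_corpus(records: Sequence[SequenceRecord], k: int) -> KmerCorpus:
    """Tokenize records (in order) into a k-mer corpus.

    Records shorter than k contribute no sentence and are logged in
    ``skipped``.
    """
    sentences: list[list[str]] = []
    skipped: list[str] = []
    for record in records:
        tokens = tokenize(record.sequence, k)
        if tokens:
            sentences.append(tokens)
        else:
            skipped.append(record.accession)
    if skipped:
        logger.warning("%d sequence(s) shorter than k=%d skipped", len(skipped), k)
    return KmerCorpus(sentences=sentences, k=k, skipped=skipped)


_MODEL_MAGIC = "its2vec-kv-v1"


@dataclass
class EmbeddingModel:
    """A trained k-mer embedding: vocabulary plus one dense vector per token."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim) float32
    params: EmbeddingParams

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def save(self, path: str | Path) -> None:
        """Persist in the classic word-vector text format (token + floats per
        line), preceded by a tagged count/dimension header."""
        with open(path, "w") as handle:
            handle.write(f"{_MODEL_MAGIC} {len(self.vocab)} {self.dim} "
                         f"k={self.params.k}\n")
            order = sorted(self.vocab, key=self.vocab.get)
            for token in order:
                vec = " ".join(repr(float(x)) for x in self.vectors[self.vocab[token]])
                handle.write(f"{token} {vec}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path) as handle:
            header = handle.readline().split()
            if len(header) != 4 or header[0] != _MODEL_MAGIC:
                raise ModelFormatError(f"{path}: not an its2vec key-vector file")
            n_vocab, dim = int(header[1]), int(header[2])
            k = int(header[3].removeprefix("k="))
            vocab: dict[str, int] = {}
            vectors = np.empty((n_vocab, dim), dtype=np.float32)
            for i, line in enumerate(handle):
                parts = line.split()
                if len(parts) != dim + 1:
                    raise ModelFormatError(f"{path}: malformed vector line {i + 2}")
                vocab[parts[0]] = i
                vectors[i] = np.array(parts[1:], dtype=np.float32)
        if len(vocab) != n_vocab:
            raise ModelFormatError(
                f"{path}: header claims {n_vocab} tokens, found {len(vocab)}"
            )
        return cls(vocab=vocab, vectors=vectors,
                   params=EmbeddingParams(k=k, dim=dim))


def train_embedding(corpus: KmerCorpus, params: EmbeddingParams | None = None
                    ) -> EmbeddingModel:
    """Train the skip-gram embedding on a k-mer corpus.

    With ``min_count=1`` (default) the vocabulary covers every corpus token.
    Token ids are assigned by descending corpus frequency (ties broken
    lexicographically) so training is independent of dict iteration order.
    """
    params = params or EmbeddingParams()
    if not corpus.sentences:
        raise Its2vecError("cannot train an embedding on an empty corpus")

    counts = Counter()
    for sentence in corpus.sentences:
        counts.update(sentence)
    kept = [t for t, c in counts.items() if c >= params.min_count]
    kept.sort(key=lambda t: (-counts[t], t))
    vocab = {t: i for i, t in enumerate(kept)}
    count_arr = np.array([counts[t] for t in kept], dtype=np.int64)

    id_sentences = [
        [vocab[t] for t in sentence if t in vocab] for sentence in corpus.sentences
    ]
    id_sentences = [s for s in id_sentences if s]
    if not id_sentences:
        raise Its2vecError("min_count filtered out the entire corpus")

    tokens = np.fromiter(
        (tid for s in id_sentences for tid in s), dtype=np.int64,
        count=sum(len(s) for s in id_sentences),
    )
    offsets = np.zeros(len(id_sentences) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in id_sentences], out=offsets[1:])

    vectors = _sgns.train_kernel(
        tokens,
        offsets,
        _sgns.keep_probabilities(count_arr, params.subsample),
        _sgns.build_noise_table(count_arr),
        params.dim,
        params.window,
        params.epochs,
        params.negative_samples,
        params.alpha,
        params.min_alpha,
        int(params.seed) % (2**31),
        int(max(len(s) for s in id_sentences)),
    )
    return EmbeddingModel(vocab=vocab, vectors=vectors, params=params)


def vectorize_sequence(
    sequence: str, model: EmbeddingModel, return_stats: bool = False
):
    """Mean of the sequence's in-vocabulary k-mer vectors (length ``dim``).

    Out-of-vocabulary k-mers are skipped; if no k-mer is in vocabulary (or the
    sequence is shorter than k) the zero vector is returned. With
    ``return_stats`` the (vector, n_tokens, n_oov) triple is returned so
    callers can flag degenerate records.
    """
    ids = [model.vocab[t] for t in tokenize(sequence, model.params.k)
           if t in model.vocab]
    n_total = max(len(sequence) - model.params.k + 1, 0)
    if ids:
        vec = model.vectors[ids].mean(axis=0, dtype=np.float64)
    else:
        vec = np.zeros(model.dim, dtype=np.float64)
    if return_stats:
        return vec, n_total, n_total - len(ids)
    return vec


@dataclass
class LabeledDataset:
    """Embedded sequences with integer class labels.

    ``X`` has one row per sequence (columns = embedding dimensions); ``y``
    holds dense 0-based class labels; ``label_map`` maps each label back to
    its SH code, and ``lineage_map`` (optional) to a formatted lineage.
    ``flagged`` lists row indices whose sequence had no in-vocabulary k-mer
    (all-zero rows).
    """

    X: np.ndarray
    y: np.ndarray
    label_map: dict[int, str]
    lineage_map: dict[int, str] | None = None
    flagged: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")


def vectorize_dataset(subset, model: EmbeddingModel) -> LabeledDataset:
    """Embed every record of an ITSSubset; row i is record i's mean vector."""
    n = len(subset.records)
    X = np.zeros((n, model.dim), dtype=np.float64)
    y = np.empty(n, dtype=np.int64)
    flagged: list[int] = []
    lineage_map: dict[int, str] = {}
    for i, record in enumerate(subset.records):
        vec, n_tokens, n_oov = vectorize_sequence(record.sequence, model,
                                                  return_stats=True)
        X[i] = vec
        label = subset.sh_index[record.sh_code]
        y[i] = label
        lineage_map.setdefault(label, record.lineage.format())
        if n_tokens == 0 or n_oov == n_tokens:
            flagged.append(i)
    label_map = {label: sh for sh, label in subset.sh_index.items()}
    return LabeledDataset(X=X, y=y, label_map=label_map,
                          lineage_map=lineage_map, flagged=flagged)
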