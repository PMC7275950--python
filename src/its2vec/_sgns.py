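"""Skip-gram-with-negative-sampling training kernel.

A single-threaded, numba-compiled implementation of the classic word2vec
skip-gram objective: for each (context, center) pair within a reduced
symmetric window, one positive update against the center token and
``negative`` updates against tokens drawn from the unigram^0.75 noise
distribution. Learning rate decays linearly from ``alpha0`` to ``min_alpha``
over the corpus; frequent tokens are down-sampled with the standard
sqrt-threshold rule. Being single-threaded, training is bitwise reproducible
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NOISE_TABLE_SIZE = 1_000_000
_MAX_EXP = 6.0


def build_noise_table(counts: np.ndarray, power: float = 0.75) -> np.ndarray:
    """Unigram^power sampling table (token id per table slot)."""
    weights = counts.astype(np.float64) ** power
    cum = np.cumsum(weights / weights.sum())
    grid = (np.arange(NOISE_TABLE_SIZE) + 0.5) / NOISE_TABLE_SIZE
    return np.searchsorted(cum, grid).astype(np.int64)


def keep_probabilities(counts: np.ndarray, sample: float) -> np.ndarray:
    """Per-token retention probability for frequent-token down-sampling.

    Tokens with corpus frequency f below the ``sample`` threshold get a value
    >= 1 (always kept); above it, the word2vec rule
    (sqrt(f/sample) + 1) * sample / f.
    """
    total = counts.sum()
    if sample <= 0 or total == 0:
        return np.ones(counts.shape[0], dtype=np.float64)
    freq = counts.astype(np.float64) / total
    with np.errstate(divide="ignore"):
        keep = (np.sqrt(freq / sample) + 1.0) * sample / freq
    return keep


@njit(cache=True)
def train_kernel(
    tokens: np.ndarray,      # int64, all sentences concatenated
    offsets: np.ndarray,     # int64, sentence start offsets, len S+1
    keep_prob: np.ndarray,   # float64, per token id
    noise_table: np.ndarray, # int64
    dim: int,
    window: int,
    epochs: int,
    negative: int,
    alpha0: float,
    min_alpha: float,
    seed: int,
    max_sentence: int,
) -> np.ndarray:
    np.random.seed(seed)
    n_vocab = keep_prob.shape[0]
    syn0 = ((np.random.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((n_vocab, dim), dtype=np.float32)
    table_size = noise_table.shape[0]
    sen = np.empty(max_sentence, dtype=np.int64)
    neu1e = np.empty(dim, dtype=np.float32)
    total = tokens.shape[0] * epochs
    processed = 0
    alpha = alpha0
    for _epoch in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            m = 0
            for t in range(start, end):
                w = tokens[t]
                if keep_prob[w] >= 1.0 or np.random.random() < keep_prob[w]:
                    sen[m] = w
                    m += 1
            processed += end - start
            alpha = alpha0 * (1.0 - processed / (total + 1.0))
            if alpha < min_alpha:
                alpha = min_alpha
            for i in range(m):
                center = sen[i]
                reduction = np.random.randint(0, window)
                span = window - reduction
                for j in range(i - span, i + span + 1):
                    if j == i or j < 0 or j >= m:
                        continue
                    context = sen[j]
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = center
                            label = 1.0
                        else:
                            target = noise_table[np.random.randint(0, table_size)]
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += syn0[context, d] * syn1[target, d]
                        if f > _MAX_EXP:
                            g = (label - 1.0) * alpha
                        elif f < -_MAX_EXP:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        gf = np.float32(g)
                        for d in range(dim):
                            neu1e[d] += gf * syn1[target, d]
                            syn1[target, d] += gf * syn0[context, d]
                    for d in range(dim):
                        syn0[context, d] += neu1e[d]
    return syn0
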