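"""Pretrained word-embedding backend behind one uniform train/load contract.

Four method families are supported under a single call signature:
``word2vec_skipgram`` and ``word2vec_cbow`` (negative sampling),
``glove`` (weighted least squares on the log co-occurrence matrix), and
``fasttext`` (skip-gram with character n-gram subword vectors).  Training is
single-threaded and fully deterministic given the seed.  The trained matrix
``E`` is *fixed* downstream: supervised adaptation happens in the projection
model, never here.

Interchange uses the standard word2vec text format: a ``"v e"`` header line
followed by one ``token x_1 ... x_e`` line per word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .corpus_io import Corpus, Vocabulary, build_vocabulary

METHODS = ("word2vec_cbow", "word2vec_skipgram", "glove", "fasttext")

_NGRAM_MIN, _NGRAM_MAX = 3, 5


@dataclass
class EmbeddingMatrix:
    """The fixed pretrained matrix E (vocabulary size v x embedding dim e)."""

    matrix: np.ndarray
    vocab: Vocabulary
    method: str
    dim: int
    _unit: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.vocab.size, self.dim):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"(vocab={self.vocab.size}, dim={self.dim})"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains NaN/Inf")

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.matrix[self.vocab.index_of[token]]
        except KeyError:
            raise ValueError(f"out-of-vocabulary: {token!r}") from None

    @property
    def unit_matrix(self) -> np.ndarray:
        """Row-normalized copy, computed once and cached; makes cosine a
        plain dot product for retrieval."""
        if self._unit is None:
            norms = np.linalg.norm(self.matrix, axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            self._unit = self.matrix / norms
        return self._unit

    def checksum(self) -> int:
        return hash(self.matrix.tobytes())


def _encode(corpus: Corpus, vocab: Vocabulary) -> tuple[np.ndarray, np.ndarray]:
    ids: list[int] = []
    offsets = [0]
    idx = vocab.index_of
    for msg in corpus.messages:
        ids.extend(idx[t] for t in msg)
        offsets.append(len(ids))
    return np.asarray(ids, dtype=np.int32), np.asarray(offsets, dtype=np.int64)


def _negative_cdf(vocab: Vocabulary, power: float = 0.75) -> np.ndarray:
    freqs = np.array([vocab.freq[t] for t in vocab.tokens], dtype=np.float64)
    weights = freqs**power
    if weights.sum() == 0:
        weights[:] = 1.0
    cdf = np.cumsum(weights / weights.sum())
    cdf[-1] = 1.0
    return cdf


def _subword_csr(
    vocab: Vocabulary, n_buckets: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hashed character n-gram ids (FNV-1a) per word, CSR layout."""

    def fnv1a(s: str) -> int:
        h = 0x811C9DC5
        for byte in s.encode("utf-8"):
            h = ((h ^ byte) * 0x01000193) & 0xFFFFFFFF
        return h

    indices: list[int] = []
    offsets = [0]
    for tok in vocab.tokens:
        padded = f"<{tok}>"
        grams = {
            padded[i : i + n]
            for n in range(_NGRAM_MIN, _NGRAM_MAX + 1)
            for i in range(len(padded) - n + 1)
        }
        indices.extend(sorted(fnv1a(g) % n_buckets for g in grams))
        offsets.append(len(indices))
    return (
        np.asarray(indices, dtype=np.int64),
        np.asarray(offsets, dtype=np.int64),
    )


def _cooccurrence(
    data: np.ndarray, offsets: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric window co-occurrence with 1/distance weighting."""
    counts: dict[tuple[int, int], float] = {}
    for si in range(len(offsets) - 1):
        start, end = offsets[si], offsets[si + 1]
        for i in range(start, end):
            wi = int(data[i])
            for j in range(i + 1, min(i + window + 1, end)):
                wj = int(data[j])
                w = 1.0 / (j - i)
                counts[(wi, wj)] = counts.get((wi, wj), 0.0) + w
                counts[(wj, wi)] = counts.get((wj, wi), 0.0) + w
    items = sorted(counts.items())
    i_idx = np.array([k[0] for k, _ in items], dtype=np.int64)
    j_idx = np.array([k[1] for k, _ in items], dtype=np.int64)
    x_val = np.array([v for _, v in items], dtype=np.float64)
    return i_idx, j_idx, x_val


def train_embeddings(
    corpus: Corpus,
    method: str = "word2vec_skipgram",
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float | None = None,
    vocab: Vocabulary | None = None,
) -> EmbeddingMatrix:
    """Train the fixed embedding matrix E on a preprocessed corpus.

    Deterministic given ``seed`` (single-threaded).  ``vocab`` may be
    supplied to pin the token ordering; otherwise it is built from the
    corpus.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if vocab is None:
        vocab = build_vocabulary(corpus)
    data, offsets = _encode(corpus, vocab)
    if data.shape[0] < window:
        raise ValueError("corpus smaller than window")
    v = vocab.size
    rng = np.random.default_rng(seed)
    kernel_seed = int(seed) % (2**31 - 1)

    if method == "glove":
        lr = 0.05 if learning_rate is None else learning_rate
        i_idx, j_idx, x_val = _cooccurrence(data, offsets, window)
        w_main = (rng.random((v, dim)) - 0.5) / dim
        w_ctx = (rng.random((v, dim)) - 0.5) / dim
        b_main = np.zeros(v)
        b_ctx = np.zeros(v)
        _kernels.train_glove(
            i_idx, j_idx, x_val, w_main, w_ctx, b_main, b_ctx,
            epochs, lr, 10.0, 0.75, kernel_seed,
        )
        matrix = w_main + w_ctx
    else:
        alpha0 = 0.025 if learning_rate is None else learning_rate
        min_alpha = 1e-4
        syn0 = (rng.random((v, dim)) - 0.5) / dim
        syn1 = np.zeros((v, dim))
        neg_cdf = _negative_cdf(vocab)
        if method == "fasttext":
            n_buckets = max(1009, min(100_003, 30 * v))
            sub_idx, sub_off = _subword_csr(vocab, n_buckets)
            syn_sub = (rng.random((n_buckets, dim)) - 0.5) / dim
            _kernels.train_sgns_subword(
                data, offsets, syn0, syn1, syn_sub, sub_idx, sub_off,
                window, negative, epochs, alpha0, min_alpha, neg_cdf,
                kernel_seed,
            )
            # word vector = training-time input representation
            matrix = syn0.copy()
            for wi in range(v):
                grams = sub_idx[sub_off[wi] : sub_off[wi + 1]]
                if grams.size:
                    matrix[wi] = (syn0[wi] + syn_sub[grams].sum(axis=0)) / (
                        1 + grams.size
                    )
        else:
            cbow = 1 if method == "word2vec_cbow" else 0
            _kernels.train_sgns(
                data, offsets, syn0, syn1, window, negative, epochs,
                alpha0, min_alpha, neg_cdf, cbow, kernel_seed,
            )
            matrix = syn0
    return EmbeddingMatrix(matrix=matrix, vocab=vocab, method=method, dim=dim)


def cosine(space, a: str, b: str) -> float:
    """Cosine similarity between two tokens in an embedding space (raw
    matrix or projected model — anything exposing ``vector(token)``)."""
    va = np.asarray(space.vector(a), dtype=np.float64)
    vb = np.asarray(space.vector(b), dtype=np.float64)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("degenerate vector")
    return float(va @ vb / (na * nb))


def save_vectors(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write the word2vec text format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{emb.vocab.size} {emb.dim}\n")
        for i, tok in enumerate(emb.vocab.tokens):
            vals = " ".join(f"{x:.8g}" for x in emb.matrix[i])
            fh.write(f"{tok} {vals}\n")


def load_vectors(path: str | Path, method: str = "external") -> EmbeddingMatrix:
    """Read the word2vec text format; header/row mismatches raise with the
    offending line number.  Loaded vocabularies carry zero frequencies."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: line 1: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"{path}: line 1: expected header 'v e'")
    v, e = int(header[0]), int(header[1])
    if len(lines) - 1 != v:
        raise ValueError(
            f"{path}: header declares {v} rows, found {len(lines) - 1}"
        )
    tokens: list[str] = []
    matrix = np.empty((v, e))
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.rstrip().split(" ")
        if len(parts) != e + 1:
            raise ValueError(
                f"{path}: line {lineno}: expected {e} values, "
                f"got {len(parts) - 1}"
            )
        tokens.append(parts[0])
        matrix[lineno - 2] = [float(x) for x in parts[1:]]
    vocab = Vocabulary(
        tokens=tokens,
        index_of={t: i for i, t in enumerate(tokens)},
        freq={t: 0 for t in tokens},
    )
    return EmbeddingMatrix(matrix=matrix, vocab=vocab, method=method, dim=e)
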