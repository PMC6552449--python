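"""The adapted embedding space: a trainable low-rank projection S over E.

The adapted representation of a word with one-hot column ``M`` is
``P = S . E . M`` — i.e. the projection matrix ``S`` (shape s x e, s < e)
applied to that word's fixed pretrained embedding row.  Training (see
:mod:`chvmine.training`) updates only ``S``; because every word passes
through the same projection, all embeddings are adapted indirectly,
including words that never appear in the labeled seed pairs.

A checkpoint is a directory holding the E vectors (word2vec text format),
the S matrix (``"s e"`` header then one row of floats per line), and a JSON
metadata file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingMatrix, load_vectors, save_vectors


@dataclass
class ProjectedVector:
    values: np.ndarray
    token: str


@dataclass
class ProjectionModel:
    """Trainable projection S of a fixed embedding matrix E.

    ``diagonal_only`` marks the log-linear baseline: S is square diagonal
    (a per-feature reweighting of raw E) and training touches only its
    diagonal.  ``trainable_embedding``, when set by the embedding-update
    comparison baseline, is a model-local copy of E that training modifies
    in place of S; the original E is never written to.
    """

    S: np.ndarray
    embedding: EmbeddingMatrix
    rng_seed: int = 0
    diagonal_only: bool = False
    trainable_embedding: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        s, e = self.S.shape
        if e != self.embedding.dim:
            raise ValueError("S column count must equal embedding dim")
        if not self.diagonal_only and s >= e:
            raise ValueError("projection must reduce dimension")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S contains NaN/Inf")

    @property
    def s(self) -> int:
        return self.S.shape[0]

    @property
    def e(self) -> int:
        return self.S.shape[1]

    @property
    def vocab(self):
        return self.embedding.vocab

    @property
    def effective_E(self) -> np.ndarray:
        if self.trainable_embedding is not None:
            return self.trainable_embedding
        return self.embedding.matrix

    def vector(self, token: str) -> np.ndarray:
        """Projected vector of ``token`` (the P = S.E.M product)."""
        try:
            row = self.effective_E[self.vocab.index_of[token]]
        except KeyError:
            raise ValueError(f"out-of-vocabulary: {token!r}") from None
        return self.S @ row

    def project_all(self) -> np.ndarray:
        """Projected vectors for the whole vocabulary, shape (v, s)."""
        return self.effective_E @ self.S.T

    def copy(self) -> "ProjectionModel":
        return ProjectionModel(
            S=self.S.copy(),
            embedding=self.embedding,
            rng_seed=self.rng_seed,
            diagonal_only=self.diagonal_only,
            trainable_embedding=None
            if self.trainable_embedding is None
            else self.trainable_embedding.copy(),
        )


def _uniform_bound(s: int, e: int) -> float:
    # symmetric Glorot-style range for a (s, e) weight matrix
    return float(np.sqrt(6.0 / (s + e)))


def default_projection_size(e: int) -> int:
    """Default s: a substantial reduction of e (40%, rounded to a multiple
    of 10, never below 10, always < e) — small enough to regularize, large
    enough to preserve the unsupervised geometry the ranking signal
    sharpens."""
    s = max(10, int(round(e * 0.4 / 10)) * 10)
    return min(s, e - 1)


def init_projection(
    E: EmbeddingMatrix, s: int, seed: int = 0
) -> ProjectionModel:
    """Fresh projection with entries i.i.d. uniform on [-a, a],
    a = sqrt(6/(s+e)); reproducible given ``seed``."""
    e = E.dim
    if s < 1:
        raise ValueError("projection size must be >= 1")
    if s >= e:
        raise ValueError("projection must reduce dimension")
    a = _uniform_bound(s, e)
    rng = np.random.default_rng(seed)
    S = rng.uniform(-a, a, size=(s, e))
    return ProjectionModel(S=S, embedding=E, rng_seed=seed)


def init_loglinear(E: EmbeddingMatrix) -> ProjectionModel:
    """The projection-size-0 baseline: a bias-free linear reweighting of the
    raw embedding features (S = I, trained diagonally)."""
    return ProjectionModel(
        S=np.eye(E.dim), embedding=E, rng_seed=0, diagonal_only=True
    )


def project(model: ProjectionModel, token: str) -> ProjectedVector:
    return ProjectedVector(values=model.vector(token), token=token)


def expand_projection(
    model: ProjectionModel, s_new: int, seed: int = 0
) -> ProjectionModel:
    """Grow S by appending freshly initialized rows, keeping the original
    rows bit-identical — the adapting rule for enlarging the subspace as
    the labeled pair set grows."""
    if s_new <= model.s:
        raise ValueError("s_new must exceed the current projection size")
    if s_new >= model.e:
        raise ValueError("projection must reduce dimension")
    a = _uniform_bound(s_new, model.e)
    rng = np.random.default_rng(seed)
    extra = rng.uniform(-a, a, size=(s_new - model.s, model.e))
    return ProjectionModel(
        S=np.vstack([model.S.copy(), extra]),
        embedding=model.embedding,
        rng_seed=seed,
    )


def save_checkpoint(model: ProjectionModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_vectors(model.embedding, directory / "vectors.txt")
    with open(directory / "S.txt", "w", encoding="utf-8") as fh:
        fh.write(f"{model.s} {model.e}\n")
        for row in model.S:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")
    meta = {
        "s": model.s,
        "e": model.e,
        "seed": model.rng_seed,
        "method": model.embedding.method,
        "diagonal_only": model.diagonal_only,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(directory: str | Path) -> ProjectionModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    E = load_vectors(directory / "vectors.txt", method=meta.get("method", "external"))
    lines = (directory / "S.txt").read_text().splitlines()
    s, e = (int(x) for x in lines[0].split())
    S = np.array([[float(x) for x in line.split()] for line in lines[1 : s + 1]])
    if S.shape != (s, e):
        raise ValueError(f"{directory}/S.txt: shape mismatch")
    return ProjectionModel(
        S=S,
        embedding=E,
        rng_seed=int(meta.get("seed", 0)),
        diagonal_only=bool(meta.get("diagonal_only", False)),
    )
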