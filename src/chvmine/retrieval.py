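"""Ranked candidate retrieval in the adapted space, plus the entropy
criterion for spotting consumer terms that match no professional term.

Candidates are scored by cosine similarity between projected vectors (or
raw embedding rows, if an :class:`~chvmine.embeddings.EmbeddingMatrix` is
passed instead of a projection model).  Ties break by higher corpus
frequency, then lexicographically, so every ranking is a strict total
order and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import softmax
from scipy.stats import entropy as _shannon_entropy

from .corpus_io import SPECIAL_TOKENS, SeedPairSet


@dataclass
class CandidateList:
    """Per-query ranked (token, similarity) list, best first."""

    query: str
    entries: list[tuple[str, float]]
    k: int

    def __len__(self) -> int:
        return len(self.entries)

    def tokens(self) -> list[str]:
        return [t for t, _ in self.entries]

    def rank_of(self, token: str) -> int | None:
        """1-based rank of ``token`` in the list, or None if absent."""
        for i, (t, _) in enumerate(self.entries, start=1):
            if t == token:
                return i
        return None


def _space_vectors(space, tokens: list[str]) -> np.ndarray:
    return np.array([space.vector(t) for t in tokens], dtype=np.float64)


def default_pool(space) -> list[str]:
    """Full vocabulary minus special tokens — the inference-time universe."""
    return [t for t in space.vocab.tokens if t not in SPECIAL_TOKENS]


def rank_candidates(
    space, query: str, k: int = 10, pool: list[str] | None = None
) -> CandidateList:
    """Top-``k`` pool members by cosine to ``query`` in ``space``.

    The query itself and the special tokens are never returned.  ``space``
    is a ProjectionModel (adapted space) or an EmbeddingMatrix (raw space).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab = space.vocab
    if query not in vocab.index_of:
        raise ValueError(f"out-of-vocabulary: {query!r}")
    if pool is None:
        pool = default_pool(space)
    cands = [t for t in pool if t != query and t not in SPECIAL_TOKENS]
    if not cands:
        if pool == [query] or set(pool) == {query}:
            return CandidateList(query=query, entries=[], k=k)
        raise ValueError("empty candidate pool")
    V = _space_vectors(space, cands)
    q = np.asarray(space.vector(query), dtype=np.float64)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0.0] = 1.0
    sims = V @ q / (norms * max(qn, 1e-300))
    freqs = np.array([vocab.freq.get(t, 0) for t in cands], dtype=float)
    lex = {t: i for i, t in enumerate(sorted(cands))}
    lex_rank = np.array([lex[t] for t in cands])
    order = np.lexsort((lex_rank, -freqs, -sims))[:k]
    return CandidateList(
        query=query,
        entries=[(cands[i], float(sims[i])) for i in order],
        k=k,
    )


def new_term_entropy(
    space,
    consumer_term: str,
    professional_terms: list[str],
    temperature: float = 1.0,
) -> float:
    """Shannon entropy (nats) of the softmax-normalized similarities from a
    consumer term to every professional term.

    A peaked distribution (entropy near 0) means the term aligns with one
    existing professional concept; entropy near log(n) means it matches
    none in particular and a new professional term may be needed.
    """
    if len(set(professional_terms)) < 2:
        raise ValueError("need at least 2 professional terms")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    c = np.asarray(space.vector(consumer_term), dtype=np.float64)
    V = _space_vectors(space, list(professional_terms))
    cn = np.linalg.norm(c)
    norms = np.linalg.norm(V, axis=1)
    if cn == 0.0 or np.any(norms == 0.0):
        raise ValueError("degenerate vector")
    sims = V @ c / (norms * cn)
    p = softmax(sims / temperature)
    return float(_shannon_entropy(p))


def export_review_sheet(
    queries: list[str],
    space,
    k: int,
    path: str | Path,
    pool: list[str] | None = None,
) -> None:
    """Write the human-review TSV: one row per (query, candidate) with a
    blank ``decision`` column for reviewers to fill."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query\trank\tcandidate\tsimilarity\tdecision\n")
        for q in queries:
            cl = rank_candidates(space, q, k=k, pool=pool)
            for rank, (tok, sim) in enumerate(cl.entries, start=1):
                fh.write(f"{q}\t{rank}\t{tok}\t{sim:.6f}\t\n")


def import_review_sheet(path: str | Path) -> SeedPairSet:
    """Read back a filled review sheet: rows whose decision marks
    acceptance (``accept``/``yes``/``y``/``1``) become seed pairs."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("query\t"):
        raise ValueError(f"{path}: line 1: expected review-sheet header")
    accepted = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"{path}: line {lineno}: malformed row")
        query, _rank, cand, _sim, decision = fields[:5]
        if decision.strip().lower() in ("accept", "yes", "y", "1"):
            accepted.append((query, cand, "review"))
    return SeedPairSet(pairs=accepted, provenance=str(path))
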