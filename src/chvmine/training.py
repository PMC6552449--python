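"""Supervised fine-tuning of the projection S against seed pairs.

Supervision is rank-based: for a query word ω_v with labeled synonyms
Syn(ω_v), each synonym ω_r carries a *desired* rank rank*(ω_r) (position in
the labeled set, most frequent first), while its *current* rank rank(ω_r) is
its position when the candidate pool is sorted by cosine similarity to ω_v
in the projected space.  The ranking loss

    L = Σ_{ω_v} Σ_{ω_r ∈ Syn(ω_v)} |rank(ω_r) − rank*(ω_r)|

is not differentiable, so training minimizes a similarity-value surrogate:
with f(ω_v) the descending sorted similarities of the pool to ω_v, the
target for ω_r is the similarity value sitting at its desired position,
and the per-pair loss is

    ℓ = ( f(ω_v)[rank*(ω_r)] − cos_proj(ω_v, ω_r) )²

where the target value is treated as a constant (refreshed once per epoch,
no gradient flows through it).  Plain mini-batch SGD on S; the pretrained
matrix E is never modified (a joint-update baseline flag exists for
comparison experiments and operates on a model-local copy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import SPECIAL_TOKENS, SeedPairSet, Vocabulary
from .projection import ProjectionModel

_NEG_SENTINEL = -2.0  # below any cosine; parks the query at the list tail


@dataclass
class TrainConfig:
    learning_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    candidate_pool_size: int = 1000
    seed: int = 0
    loss_variant: str = "absolute"  # ranking-loss monitor: absolute | squared
    bidirectional: bool = True
    # comparison baseline: train the embedding rows themselves (no
    # projection update); only labeled words move, nothing transfers
    update_embeddings: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.epochs < 0 or self.candidate_pool_size <= 0:
            raise ValueError("epochs/pool size must be non-negative/positive")
        if self.loss_variant not in ("absolute", "squared"):
            raise ValueError("loss_variant must be 'absolute' or 'squared'")


@dataclass
class RankingState:
    """Desired ranks plus, after :func:`refresh_state`, the current ranks
    and sorted similarity lists over the candidate pool."""

    queries: dict[str, list[tuple[str, int]]]  # query -> [(synonym, rank*)]
    pool_tokens: list[str]
    pool_pos: dict[str, int]
    pool_freq: np.ndarray
    pool_lex: np.ndarray
    sorted_sims: dict[str, np.ndarray] = field(default_factory=dict)
    current_rank: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def pool_size(self) -> int:
        return len(self.pool_tokens)

    def n_examples(self) -> int:
        return sum(len(v) for v in self.queries.values())


def build_candidate_pool(
    vocab: Vocabulary,
    seed_pairs: SeedPairSet,
    size: int = 1000,
    extra_tokens: tuple[str, ...] = (),
) -> list[str]:
    """Top-``size`` most frequent tokens plus every seed-pair member (and
    extras), special tokens excluded; ordered frequency-descending then
    lexicographic."""
    keep = set(vocab.top_tokens(size))
    keep |= {t for t in seed_pairs.members() if t in vocab.index_of}
    keep |= {t for t in extra_tokens if t in vocab.index_of}
    keep -= set(SPECIAL_TOKENS)
    return sorted(keep, key=lambda t: (-vocab.freq[t], t))


def assign_desired_ranks(
    seed_pairs: SeedPairSet,
    vocab: Vocabulary,
    bidirectional: bool = True,
    pool_size: int = 1000,
    extra_tokens: tuple[str, ...] = (),
) -> RankingState:
    """Desired ranks 1..k per query, synonyms ordered by corpus frequency
    descending (ties lexicographic).  With ``bidirectional`` the consumer
    terms are also used as queries of their professional counterparts."""
    if len(seed_pairs) == 0:
        raise ValueError("no supervision")
    missing = sorted(t for t in seed_pairs.members() if t not in vocab.index_of)
    if missing:
        raise ValueError(f"pair members out of vocabulary: {missing}")
    directed: dict[str, list[str]] = {}
    for p, c, _ in seed_pairs:
        directed.setdefault(p, []).append(c)
        if bidirectional:
            directed.setdefault(c, []).append(p)
    queries: dict[str, list[tuple[str, int]]] = {}
    for q, syns in directed.items():
        uniq = dict.fromkeys(syns)
        ordered = sorted(uniq, key=lambda t: (-vocab.freq[t], t))
        queries[q] = [(s, r + 1) for r, s in enumerate(ordered)]
    pool_tokens = build_candidate_pool(
        vocab, seed_pairs, pool_size, extra_tokens
    )
    lex_order = {t: i for i, t in enumerate(sorted(pool_tokens))}
    return RankingState(
        queries=queries,
        pool_tokens=pool_tokens,
        pool_pos={t: i for i, t in enumerate(pool_tokens)},
        pool_freq=np.array([vocab.freq[t] for t in pool_tokens], dtype=float),
        pool_lex=np.array([lex_order[t] for t in pool_tokens]),
    )


def _pool_matrix(model: ProjectionModel, state: RankingState) -> np.ndarray:
    ids = [model.vocab.index_of[t] for t in state.pool_tokens]
    return model.effective_E[ids]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return X / norms


def refresh_state(model: ProjectionModel, state: RankingState) -> None:
    """Recompute projected similarities over the pool: fills ``sorted_sims``
    (the f(ω_v) lists) and ``current_rank``.  Ties break by higher pool
    frequency, then lexicographic, making rank a strict total order."""
    Ep = _pool_matrix(model, state)
    U = _unit_rows(Ep @ model.S.T)
    state.sorted_sims.clear()
    state.current_rank.clear()
    for q, syns in state.queries.items():
        qi = state.pool_pos[q]
        sims = U @ U[qi]
        sims[qi] = _NEG_SENTINEL
        order = np.lexsort((state.pool_lex, -state.pool_freq, -sims))
        pos_of = np.empty(len(order), dtype=np.int64)
        pos_of[order] = np.arange(len(order))
        state.sorted_sims[q] = sims[order]
        for syn, _rank_star in syns:
            state.current_rank[(q, syn)] = int(pos_of[state.pool_pos[syn]]) + 1


def ranking_loss(model: ProjectionModel, state: RankingState,
                 variant: str = "absolute") -> float:
    """Monitoring-only rank displacement loss; zero iff every synonym sits
    exactly at its desired position."""
    if not state.queries:
        raise ValueError("no supervision")
    if not state.current_rank:
        refresh_state(model, state)
    total = 0.0
    for q, syns in state.queries.items():
        for syn, rank_star in syns:
            d = abs(state.current_rank[(q, syn)] - rank_star)
            total += d * d if variant == "squared" else d
    return float(total)


def _projected_cosine(model: ProjectionModel, a: str, b: str) -> float:
    u = model.vector(a)
    w = model.vector(b)
    return float(u @ w / (np.linalg.norm(u) * np.linalg.norm(w)))


def surrogate_loss(
    model: ProjectionModel, state: RankingState, query: str, synonym: str
) -> float:
    """ℓ = (f(ω_v)[rank*] − cos_proj(ω_v, ω_r))², target treated constant."""
    if query not in state.sorted_sims:
        refresh_state(model, state)
    rank_star = dict(state.queries[query])[synonym]
    f_q = state.sorted_sims[query]
    if rank_star > state.pool_size - 1:
        raise ValueError("pool too small")
    target = float(f_q[rank_star - 1])
    c = _projected_cosine(model, query, synonym)
    return (target - c) ** 2


def surrogate_grad_S(
    S: np.ndarray, a: np.ndarray, b: np.ndarray, target: float
) -> tuple[float, np.ndarray]:
    """Loss and analytic gradient of (target − cos(Sa, Sb))² w.r.t. S."""
    u = S @ a
    w = S @ b
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    c = float(u @ w / (nu * nw))
    coef = -2.0 * (target - c)
    dcu = w / (nu * nw) - (c / nu**2) * u
    dcw = u / (nu * nw) - (c / nw**2) * w
    grad = coef * (np.outer(dcu, a) + np.outer(dcw, b))
    return (target - c) ** 2, grad


def _batch_step(
    model: ProjectionModel,
    A: np.ndarray,
    B: np.ndarray,
    targets: np.ndarray,
    lr: float,
    emb_rows_a: np.ndarray | None = None,
    emb_rows_b: np.ndarray | None = None,
) -> float:
    """One SGD step on the mean surrogate loss of a batch; returns the mean
    loss at the pre-step parameters."""
    S = model.S
    U = A @ S.T
    W = B @ S.T
    nu = np.linalg.norm(U, axis=1)
    nw = np.linalg.norm(W, axis=1)
    c = np.einsum("ij,ij->i", U, W) / (nu * nw)
    coef = -2.0 * (targets - c)
    dcu = W / (nu * nw)[:, None] - (c / nu**2)[:, None] * U
    dcw = U / (nu * nw)[:, None] - (c / nw**2)[:, None] * W
    n = len(targets)
    if model.trainable_embedding is not None:
        # no-projection baseline: the embedding rows are the parameters,
        # so only labeled words receive updates — nothing transfers
        ga = (coef[:, None] * dcu) @ S / n
        gb = (coef[:, None] * dcw) @ S / n
        np.add.at(model.trainable_embedding, emb_rows_a, -lr * ga)
        np.add.at(model.trainable_embedding, emb_rows_b, -lr * gb)
    else:
        gS = ((coef[:, None] * dcu).T @ A + (coef[:, None] * dcw).T @ B) / n
        if model.diagonal_only:
            np.fill_diagonal(S, np.diag(S) - lr * np.diag(gS))
        else:
            S -= lr * gS
    return float(np.mean((targets - c) ** 2))


def _state_mrr(state: RankingState) -> float:
    """MRR over training queries using the first labeled synonym reached."""
    recips = []
    for q, syns in state.queries.items():
        best = min(state.current_rank[(q, syn)] for syn, _ in syns)
        recips.append(1.0 / best)
    return float(np.mean(recips))


def fit(
    model: ProjectionModel,
    seed_pairs: SeedPairSet,
    config: TrainConfig,
    heldout_pairs: SeedPairSet | None = None,
    log_path: str | Path | None = None,
) -> ProjectionModel:
    """Fine-tune S by mini-batch SGD on the surrogate loss.

    Per epoch: (1) recompute projected vectors and the sorted-similarity
    lists over the candidate pool (freezing the per-pair targets), (2) one
    shuffled pass of SGD, (3) log surrogate loss, ranking loss, and train
    (plus optional held-out) MRR as a JSON-lines record.  Deterministic
    given ``config.seed``; the input E is never modified.
    """
    if len(seed_pairs) == 0:
        raise ValueError("no supervision")
    vocab = model.vocab
    out = model.copy()
    if config.update_embeddings and out.trainable_embedding is None:
        out.trainable_embedding = model.embedding.matrix.copy()
    extra = tuple(heldout_pairs.members()) if heldout_pairs else ()
    state = assign_desired_ranks(
        seed_pairs,
        vocab,
        bidirectional=config.bidirectional,
        pool_size=config.candidate_pool_size,
        extra_tokens=extra,
    )
    held_state = None
    if heldout_pairs is not None and len(heldout_pairs) > 0:
        held_state = assign_desired_ranks(
            heldout_pairs,
            vocab,
            bidirectional=config.bidirectional,
            pool_size=config.candidate_pool_size,
            extra_tokens=tuple(seed_pairs.members()),
        )
    if config.epochs == 0:
        return out
    rng = np.random.default_rng(config.seed)
    E_idx = {t: vocab.index_of[t] for t in state.pool_tokens}
    log_records = []
    for epoch in range(config.epochs):
        refresh_state(out, state)
        # frozen per-epoch targets: similarity value at the desired slot
        examples: list[tuple[str, str, float]] = []
        for q, syns in state.queries.items():
            f_q = state.sorted_sims[q]
            for syn, rank_star in syns:
                if rank_star > state.pool_size - 1:
                    raise ValueError("pool too small")
                examples.append((q, syn, float(f_q[rank_star - 1])))
        order = rng.permutation(len(examples))
        losses = []
        Eeff = out.effective_E
        for lo in range(0, len(order), config.batch_size):
            batch = [examples[k] for k in order[lo : lo + config.batch_size]]
            rows_a = np.array([E_idx[q] for q, _, _ in batch])
            rows_b = np.array([E_idx[r] for _, r, _ in batch])
            A = Eeff[rows_a]
            B = Eeff[rows_b]
            t = np.array([t for _, _, t in batch])
            losses.append(
                _batch_step(
                    out, A, B, t, config.learning_rate,
                    emb_rows_a=rows_a, emb_rows_b=rows_b,
                )
            )
        if not np.all(np.isfinite(out.S)):
            raise ValueError(
                "training diverged (NaN in S); try a smaller learning rate"
            )
        rec = {
            "epoch": epoch,
            "surrogate_loss": float(np.mean(losses)),
            "ranking_loss": ranking_loss(out, state, config.loss_variant),
            "train_mrr": _state_mrr(state),
        }
        if held_state is not None:
            refresh_state(out, held_state)
            rec["heldout_mrr"] = _state_mrr(held_state)
        log_records.append(rec)
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    out.last_log = log_records  # type: ignore[attr-defined]
    return out


def iterate_with_review(
    model: ProjectionModel,
    seed_pairs: SeedPairSet,
    accepted_pairs: SeedPairSet,
    config: TrainConfig,
    expand_to: int | None = None,
    expand_seed: int = 0,
) -> tuple[ProjectionModel, SeedPairSet]:
    """One turn of the human-in-the-loop cycle: merge reviewer-accepted
    pairs into the seed set, optionally enlarge the projection, refit."""
    union = seed_pairs.union(accepted_pairs)
    base = model
    if expand_to is not None:
        from .projection import expand_projection

        base = expand_projection(model, expand_to, seed=expand_seed)
    refit = fit(base, union, config)
    return refit, union
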