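"""Mean-reciprocal-rank evaluation and the experiment harness.

MRR over a query sample Q is the mean of 1/rank_i where rank_i is the rank
position of the first relevant synonym for the i-th query; a query whose
synonyms never appear in its candidate list contributes 0.  The harness
reproduces the two experimental designs around the method: before/after
fine-tuning across embedding methods and dimensions, and a sweep over
projection sizes including the size-0 log-linear baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus_io import Corpus, SeedPairSet, Vocabulary
from .embeddings import train_embeddings
from .projection import (
    default_projection_size,
    init_loglinear,
    init_projection,
)
from .retrieval import CandidateList, rank_candidates
from .training import TrainConfig, build_candidate_pool, fit


@dataclass
class EvalResult:
    mrr: float
    n_queries: int
    per_query_rank: dict[str, float]  # rank of first relevant, inf if absent

    def mean_first_rank(self) -> float:
        """Mean rank of the first relevant synonym over queries where one
        was found (reported separately from MRR; they are not the same
        statistic)."""
        finite = [r for r in self.per_query_rank.values() if math.isfinite(r)]
        return float(np.mean(finite)) if finite else math.inf


def mrr(
    gold: SeedPairSet, ranked: Mapping[str, CandidateList]
) -> EvalResult:
    """MRR of ``ranked`` lists against the gold pairs.

    Queries are the gold professional terms; a query's relevant set is all
    its gold synonyms, and only the first one encountered in the list
    counts.
    """
    if len(gold) == 0:
        raise ValueError("empty gold set")
    per_query: dict[str, float] = {}
    recips = []
    for q in gold.professionals():
        if q not in ranked:
            raise ValueError(f"no candidate list for query {q!r}")
        relevant = set(gold.synonyms_of(q))
        rank: float = math.inf
        for i, (tok, _) in enumerate(ranked[q].entries, start=1):
            if tok in relevant:
                rank = i
                break
        per_query[q] = rank
        recips.append(0.0 if math.isinf(rank) else 1.0 / rank)
    return EvalResult(
        mrr=float(np.mean(recips)),
        n_queries=len(per_query),
        per_query_rank=per_query,
    )


def evaluation_pool(
    vocab: Vocabulary,
    seed_pairs: SeedPairSet,
    professional_terms: list[str] | None = None,
    top_n: int = 1000,
) -> list[str]:
    """The candidate-concept collection: professional-term list plus all
    seed-pair members plus the top-N frequent tokens."""
    return build_candidate_pool(
        vocab, seed_pairs, size=top_n,
        extra_tokens=tuple(professional_terms or ()),
    )


def sample_eval_pairs(
    seed_pairs: SeedPairSet, n_eval: int, seed: int
) -> tuple[SeedPairSet, SeedPairSet]:
    """Reproducible without-replacement split of ``n_eval`` pairs for
    evaluation; the remainder is available for training."""
    if n_eval > len(seed_pairs):
        raise ValueError(
            f"n_eval={n_eval} exceeds available pairs ({len(seed_pairs)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seed_pairs), size=n_eval, replace=False)
    chosen = set(int(i) for i in idx)
    eval_pairs = [p for i, p in enumerate(seed_pairs.pairs) if i in chosen]
    rest = [p for i, p in enumerate(seed_pairs.pairs) if i not in chosen]
    return (
        SeedPairSet(pairs=eval_pairs, provenance="eval-sample"),
        SeedPairSet(pairs=rest, provenance="train-remainder"),
    )


def evaluate(
    space,
    gold: SeedPairSet,
    pool: list[str] | None = None,
    k: int = 100,
    reverse: bool = False,
) -> EvalResult:
    """Rank candidates for every gold query in ``space`` and score MRR.

    Default direction is professional→consumer; ``reverse`` swaps it.
    """
    if reverse:
        gold = SeedPairSet(
            pairs=[(c, p, ctx) for p, c, ctx in gold.pairs],
            provenance=gold.provenance + ":reversed",
        )
    ranked = {
        q: rank_candidates(space, q, k=k, pool=pool)
        for q in gold.professionals()
    }
    return mrr(gold, ranked)


def evaluate_protocol(
    seed_pairs: SeedPairSet,
    space,
    n_eval: int = 100,
    seed: int = 0,
    pool: list[str] | None = None,
    k: int = 100,
) -> EvalResult:
    """Sample ``n_eval`` pairs without replacement (reproducible by seed)
    and score MRR on them; the sample is the *evaluation* set and must be
    excluded from any training performed in the same run (use
    :func:`sample_eval_pairs` to obtain both sides)."""
    eval_pairs, _rest = sample_eval_pairs(seed_pairs, n_eval, seed)
    if pool is None:
        pool = evaluation_pool(space.vocab, seed_pairs)
    return evaluate(space, eval_pairs, pool=pool, k=k)


def bidirectional_mrr(space, gold: SeedPairSet, pool: list[str], k: int = 100) -> float:
    """MRR pooled over both query directions (professional→consumer and
    consumer→professional), weighted by query count."""
    fwd = evaluate(space, gold, pool=pool, k=k)
    rev = evaluate(space, gold, pool=pool, k=k, reverse=True)
    n = fwd.n_queries + rev.n_queries
    return (fwd.mrr * fwd.n_queries + rev.mrr * rev.n_queries) / n


def before_after_experiment(
    seed: int,
    generator_config=None,
    embed_method: str = "word2vec_skipgram",
    embed_dim: int = 50,
    embed_epochs: int = 5,
    train_fraction: float = 0.7,
    train_config: TrainConfig | None = None,
    projection_size: int | None = None,
) -> dict:
    """One full study run: generate a synthetic corpus, pretrain embeddings,
    fine-tune the projection on a concept-level train split, and measure
    held-out bidirectional MRR before (raw E) and after (adapted space).

    Also reports pre-fine-tuning top-10 gold-partner recovery and the
    new-term-entropy means of orphan vs partnered consumer tokens in the
    pretrained space.  Returns a plain dict of numbers keyed by metric.
    """
    from .synthetic import (
        GeneratorConfig,
        generate_corpus,
        orphan_consumer_tokens,
        split_pairs,
    )
    from .corpus_io import build_vocabulary
    from .retrieval import new_term_entropy, rank_candidates

    gcfg = generator_config or GeneratorConfig(seed=seed)
    corpus, pairs, terms = generate_corpus(gcfg)
    vocab = build_vocabulary(corpus)
    emb = train_embeddings(
        corpus, method=embed_method, dim=embed_dim, epochs=embed_epochs,
        seed=seed, vocab=vocab,
    )
    train, held = split_pairs(pairs, train_fraction, seed=seed)
    pool = evaluation_pool(vocab, pairs, terms)
    before = bidirectional_mrr(emb, held, pool)
    s = projection_size or default_projection_size(embed_dim)
    cfg = train_config or TrainConfig(seed=seed)
    tuned = fit(init_projection(emb, s, seed=seed), train, cfg)
    after = bidirectional_mrr(tuned, held, pool)
    hits = sum(
        1 for p, c, _ in pairs if c in rank_candidates(emb, p, k=10, pool=pool).tokens()
    )
    orphans = orphan_consumer_tokens(gcfg)
    partnered = sorted({c for _, c, ctx in pairs if ctx == "synthetic"})
    h_orphan = (
        float(np.mean([new_term_entropy(emb, o, terms) for o in orphans]))
        if orphans
        else math.nan
    )
    h_partnered = float(
        np.mean([new_term_entropy(emb, c, terms) for c in partnered])
    )
    return {
        "seed": seed,
        "n_pairs": len(pairs),
        "n_held_pairs": len(held),
        "mrr_before": before,
        "mrr_after": after,
        "relative_improvement": (after - before) / before,
        "top10_recovery": hits / len(pairs),
        "entropy_orphan_mean": h_orphan,
        "entropy_partnered_mean": h_partnered,
        "_objects": {
            "corpus": corpus, "pairs": pairs, "terms": terms, "vocab": vocab,
            "embedding": emb, "train": train, "held": held, "pool": pool,
            "model": tuned,
        },
    }


def run_experiment_grid(
    corpus: Corpus,
    seed_pairs: SeedPairSet,
    methods: list[str],
    dims: list[int],
    projection_sizes: list[int] | None = None,
    train_config: TrainConfig | None = None,
    heldout_pairs: SeedPairSet | None = None,
    embed_epochs: int = 5,
    window: int = 5,
    seed: int = 0,
    vocab: Vocabulary | None = None,
) -> pd.DataFrame:
    """Before/after MRR per (method, dim), plus an optional projection-size
    sweep (size 0 = log-linear baseline) run on the last trained embedding.

    Returns a tidy DataFrame with columns
    ``method, dim, projection_size, stage, mrr``; evaluation uses
    ``heldout_pairs`` when given, else the training pairs themselves.
    """
    cfg = train_config or TrainConfig(seed=seed)
    gold = heldout_pairs if heldout_pairs is not None else seed_pairs
    rows = []
    last_emb = None
    for method in methods:
        for dim in dims:
            emb = train_embeddings(
                corpus, method=method, dim=dim, window=window,
                epochs=embed_epochs, seed=seed, vocab=vocab,
            )
            last_emb = emb
            pool = evaluation_pool(emb.vocab, seed_pairs.union(gold))
            before = evaluate(emb, gold, pool=pool).mrr
            s = default_projection_size(dim)
            model = init_projection(emb, s, seed=seed)
            tuned = fit(model, seed_pairs, cfg, heldout_pairs=heldout_pairs)
            after = evaluate(tuned, gold, pool=pool).mrr
            rows.append((method, dim, s, "before", before))
            rows.append((method, dim, s, "after", after))
    if projection_sizes and last_emb is not None:
        pool = evaluation_pool(last_emb.vocab, seed_pairs.union(gold))
        for s in projection_sizes:
            if s == 0:
                model = init_loglinear(last_emb)
            else:
                model = init_projection(last_emb, s, seed=seed)
            tuned = fit(model, seed_pairs, cfg, heldout_pairs=heldout_pairs)
            score = evaluate(tuned, gold, pool=pool).mrr
            rows.append(
                (last_emb.method, last_emb.dim, s, "projection_sweep", score)
            )
    return pd.DataFrame(
        rows, columns=["method", "dim", "projection_size", "stage", "mrr"]
    )
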