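"""MRR semantics, the evaluation protocol, and the experiment grid."""

import math

import numpy as np
import pytest

from chvmine.corpus_io import SeedPairSet
from chvmine.evaluation import (
    evaluate,
    evaluate_protocol,
    evaluation_pool,
    mrr,
    run_experiment_grid,
    sample_eval_pairs,
)
from chvmine.retrieval import CandidateList
from chvmine.training import TrainConfig


def _ranked(query, tokens):
    sims = np.linspace(0.9, 0.1, num=len(tokens))
    return CandidateList(
        query=query, entries=list(zip(tokens, sims)), k=len(tokens)
    )


class TestMrr:
    def test_all_at_rank_one(self):
        gold = SeedPairSet(pairs=[("p1", "c1", ""), ("p2", "c2", "")])
        ranked = {"p1": _ranked("p1", ["c1", "x"]), "p2": _ranked("p2", ["c2", "y"])}
        assert mrr(gold, ranked).mrr == 1.0

    def test_closed_form_seven_twelfths(self):
        gold = SeedPairSet(
            pairs=[("p1", "c1", ""), ("p2", "c2", ""), ("p3", "c3", "")]
        )
        ranked = {
            "p1": _ranked("p1", ["c1", "x", "y", "z"]),
            "p2": _ranked("p2", ["x", "c2", "y", "z"]),
            "p3": _ranked("p3", ["x", "y", "z", "c3"]),
        }
        res = mrr(gold, ranked)
        assert res.mrr == pytest.approx(7 / 12)
        assert res.per_query_rank == {"p1": 1, "p2": 2, "p3": 4}

    def test_first_relevant_only_counts_once(self):
        gold = SeedPairSet(pairs=[("p", "c1", ""), ("p", "c2", "")])
        ranked = {"p": _ranked("p", ["x", "c2", "c1"])}
        assert mrr(gold, ranked).mrr == pytest.approx(1 / 2)

    def test_absent_synonym_contributes_zero(self):
        gold = SeedPairSet(pairs=[("p1", "c1", ""), ("p2", "c2", "")])
        ranked = {"p1": _ranked("p1", ["c1"]), "p2": _ranked("p2", ["x", "y"])}
        res = mrr(gold, ranked)
        assert res.mrr == pytest.approx(0.5)
        assert math.isinf(res.per_query_rank["p2"])

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(25):
            n_q = int(rng.integers(1, 20))
            pool = [f"w{i}" for i in range(int(rng.integers(5, 50)))]
            gold_pairs, ranked = [], {}
            for qi in range(n_q):
                q = f"q{qi}"
                syns = list(
                    rng.choice(pool, size=int(rng.integers(1, 4)), replace=False)
                )
                gold_pairs.extend((q, s, "") for s in syns)
                perm = list(rng.permutation(pool))[: int(rng.integers(1, len(pool)))]
                ranked[q] = _ranked(q, perm)
            gold = SeedPairSet(pairs=gold_pairs)
            got = mrr(gold, ranked)
            expected = []
            for q in gold.professionals():
                rel = set(gold.synonyms_of(q))
                rank = next(
                    (i for i, t in enumerate(ranked[q].tokens(), 1) if t in rel),
                    None,
                )
                expected.append(0.0 if rank is None else 1.0 / rank)
            assert got.mrr == pytest.approx(float(np.mean(expected)))

    def test_monotone_under_promotion(self):
        gold = SeedPairSet(pairs=[("p", "c", "")])
        worse = {"p": _ranked("p", ["x", "y", "c"])}
        better = {"p": _ranked("p", ["x", "c", "y"])}
        assert mrr(gold, better).mrr > mrr(gold, worse).mrr

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError, match="empty gold"):
            mrr(SeedPairSet(pairs=[]), {})


def test_random_ranking_mrr_matches_expectation(rng):
    # single-synonym queries against uniformly shuffled pools of size P:
    # E[1/rank] = (sum_{r<=P} 1/r) / P
    P, n_q = 20, 3000
    pool = [f"w{i}" for i in range(P)]
    recips = []
    for _ in range(n_q):
        perm = rng.permutation(P)
        rank = int(np.where(perm == 0)[0][0]) + 1
        recips.append(1.0 / rank)
    closed_form = sum(1.0 / r for r in range(1, P + 1)) / P
    assert float(np.mean(recips)) == pytest.approx(closed_form, abs=0.015)


class TestEvaluateProtocol:
    def test_sample_is_reproducible_and_disjoint(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        ev1, rest1 = sample_eval_pairs(pairs, 10, seed=3)
        ev2, rest2 = sample_eval_pairs(pairs, 10, seed=3)
        assert ev1.key_set() == ev2.key_set()
        assert not (ev1.key_set() & rest1.key_set())
        assert ev1.key_set() | rest1.key_set() == pairs.key_set()
        r1 = evaluate_protocol(pairs, small_embedding, n_eval=10, seed=3)
        r2 = evaluate_protocol(pairs, small_embedding, n_eval=10, seed=3)
        assert r1.mrr == r2.mrr

    def test_full_sample_evaluates_every_professional(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        res = evaluate_protocol(pairs, small_embedding, n_eval=len(pairs), seed=0)
        assert res.n_queries == len(pairs.professionals())

    def test_oversized_sample_rejected(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_protocol(pairs, small_embedding, n_eval=len(pairs) + 1)


def test_experiment_grid_shape_and_labels(small_gen):
    _cfg, corpus, pairs, _terms = small_gen
    table = run_experiment_grid(
        corpus,
        pairs,
        methods=["word2vec_skipgram"],
        dims=[16],
        projection_sizes=[0, 6],
        train_config=TrainConfig(seed=0, epochs=5),
        embed_epochs=1,
        seed=0,
    )
    assert list(table.columns) == ["method", "dim", "projection_size", "stage", "mrr"]
    ba = table[table.stage.isin(["before", "after"])]
    assert len(ba) == 2 and set(ba.stage) == {"before", "after"}
    sweep = table[table.stage == "projection_sweep"]
    assert sorted(sweep.projection_size) == [0, 6]
    assert ((table.mrr >= 0) & (table.mrr <= 1)).all()
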