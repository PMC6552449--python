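"""Ranking supervision: desired ranks, losses, gradients, and fit."""

import numpy as np
import pytest

from chvmine.corpus_io import Corpus, SeedPairSet, build_vocabulary
from chvmine.embeddings import EmbeddingMatrix
from chvmine.projection import ProjectionModel, init_projection
from chvmine.training import (
    RankingState,
    TrainConfig,
    assign_desired_ranks,
    fit,
    iterate_with_review,
    ranking_loss,
    refresh_state,
    surrogate_grad_S,
    surrogate_loss,
)


def _toy_model(sims: dict[str, float], extra_freq: dict[str, int] | None = None):
    """Embedding where cos(q, token) in the projected space equals the
    requested value exactly (unit vectors in the plane, S a selection)."""
    tokens = ["q"] + sorted(sims)
    msgs = [["q"] + sorted(sims)]
    for tok, n in (extra_freq or {}).items():
        msgs.append([tok] * n)
    vocab = build_vocabulary(Corpus(messages=msgs))
    mat = np.zeros((vocab.size, 3))
    mat[vocab.index_of["q"]] = [1.0, 0.0, 0.0]
    for tok, c in sims.items():
        mat[vocab.index_of[tok]] = [c, np.sqrt(1 - c * c), 0.0]
    emb = EmbeddingMatrix(mat, vocab, "external", 3)
    S = np.hstack([np.eye(2), np.zeros((2, 1))])
    return ProjectionModel(S=S, embedding=emb), vocab


class TestAssignDesiredRanks:
    def test_single_synonym_rank_one(self):
        vocab = build_vocabulary(Corpus(messages=[["p", "c"]]))
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("p", "c", "")]), vocab, bidirectional=False
        )
        assert st.queries == {"p": [("c", 1)]}

    def test_frequency_orders_desired_ranks(self):
        msgs = [["p"], ["lo"] * 500, ["hi"] * 900]
        vocab = build_vocabulary(Corpus(messages=msgs))
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("p", "lo", ""), ("p", "hi", "")]),
            vocab,
            bidirectional=False,
        )
        assert st.queries["p"] == [("hi", 1), ("lo", 2)]

    def test_ranks_are_permutation(self, rng):
        syns = [f"c{i}" for i in range(6)]
        msgs = [["p"]] + [[s] * int(rng.integers(1, 40)) for s in syns]
        vocab = build_vocabulary(Corpus(messages=msgs))
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("p", s, "") for s in syns]), vocab
        )
        assert sorted(r for _, r in st.queries["p"]) == list(range(1, 7))

    def test_out_of_vocabulary_members_listed(self):
        vocab = build_vocabulary(Corpus(messages=[["p"]]))
        with pytest.raises(ValueError, match="ghost"):
            assign_desired_ranks(SeedPairSet(pairs=[("p", "ghost", "")]), vocab)

    def test_empty_seed_set(self):
        vocab = build_vocabulary(Corpus(messages=[["p"]]))
        with pytest.raises(ValueError, match="no supervision"):
            assign_desired_ranks(SeedPairSet(pairs=[]), vocab)


class TestRankingLoss:
    def test_zero_when_all_at_desired_positions(self):
        model, vocab = _toy_model({"c1": 0.9, "c2": 0.5})
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("q", "c1", ""), ("q", "c2", "")]),
            vocab,
            bidirectional=False,
        )
        # c1 and c2 tie on frequency; lexicographic order puts c1 first,
        # matching the similarity order 0.9 > 0.5
        assert ranking_loss(model, st) == 0.0

    def test_displacement_of_three(self):
        model, vocab = _toy_model({"c1": 0.9, "c2": 0.1, "c3": 0.5, "c4": 0.3})
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("q", "c2", "")]), vocab, bidirectional=False
        )
        refresh_state(model, st)
        assert st.current_rank[("q", "c2")] == 4
        assert ranking_loss(model, st) == 3.0
        assert ranking_loss(model, st, variant="squared") == 9.0

    def test_matches_bruteforce_pair_loop(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        model = init_projection(small_embedding, 8, seed=0)
        st = assign_desired_ranks(pairs, small_embedding.vocab)
        got = ranking_loss(model, st)
        expected = 0.0
        for q, syns in st.queries.items():
            for syn, rank_star in syns:
                expected += abs(st.current_rank[(q, syn)] - rank_star)
        assert got == expected


class TestSurrogateLoss:
    def test_zero_at_desired_rank(self):
        model, vocab = _toy_model({"c1": 0.9, "c2": 0.5})
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("q", "c1", "")]), vocab, bidirectional=False
        )
        assert surrogate_loss(model, st, "q", "c1") == pytest.approx(0.0)

    def test_fixed_toy_similarities(self):
        # pool sims to q: (0.9, 0.5, 0.1); synonym sits at 0.5, desired rank 1
        model, vocab = _toy_model({"c1": 0.9, "c2": 0.5, "c3": 0.1})
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("q", "c2", "")]), vocab, bidirectional=False
        )
        assert surrogate_loss(model, st, "q", "c2") == pytest.approx(0.16)

    def test_pool_too_small(self):
        model, vocab = _toy_model({"c1": 0.9})
        st = assign_desired_ranks(
            SeedPairSet(pairs=[("q", "c1", "")]), vocab, bidirectional=False
        )
        st.queries["q"] = [("c1", 5)]  # impossible desired slot
        with pytest.raises(ValueError, match="pool too small"):
            surrogate_loss(model, st, "q", "c1")

    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(20):
            s, e = int(rng.integers(2, 5)), int(rng.integers(5, 9))
            S = rng.normal(size=(s, e))
            a, b = rng.normal(size=e), rng.normal(size=e)
            t = float(rng.uniform(-0.5, 0.9))
            _, grad = surrogate_grad_S(S, a, b, t)
            h = 1e-6
            num = np.zeros_like(S)
            for i in range(s):
                for j in range(e):
                    Sp, Sm = S.copy(), S.copy()
                    Sp[i, j] += h
                    Sm[i, j] -= h
                    lp, _ = surrogate_grad_S(Sp, a, b, t)
                    lm, _ = surrogate_grad_S(Sm, a, b, t)
                    num[i, j] = (lp - lm) / (2 * h)
            denom = max(np.linalg.norm(num), 1e-12)
            assert np.linalg.norm(grad - num) / denom < 1e-4


class TestFit:
    def test_zero_epochs_is_noop(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        model = init_projection(small_embedding, 8, seed=1)
        out = fit(model, pairs, TrainConfig(epochs=0))
        assert np.array_equal(out.S, model.S)

    def test_deterministic_and_embedding_fixed(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        checksum = small_embedding.checksum()
        model = init_projection(small_embedding, 8, seed=1)
        a = fit(model, pairs, TrainConfig(seed=4, epochs=5))
        b = fit(model, pairs, TrainConfig(seed=4, epochs=5))
        assert np.array_equal(a.S, b.S)
        assert not np.array_equal(a.S, model.S)
        assert small_embedding.checksum() == checksum

    def test_surrogate_descent_tracks_ranking_loss(self, small_gen, small_embedding):
        # epochs that reduce the surrogate should mostly not increase the
        # (non-differentiable) ranking loss it stands in for
        _cfg, _corpus, pairs, _terms = small_gen
        model = init_projection(small_embedding, 8, seed=2)
        tuned = fit(model, pairs, TrainConfig(seed=2, epochs=40))
        log = tuned.last_log
        sur = [r["surrogate_loss"] for r in log]
        rl = [r["ranking_loss"] for r in log]
        down = [i for i in range(1, len(log)) if sur[i] < sur[i - 1]]
        ok = sum(1 for i in down if rl[i] <= rl[i - 1])
        assert down and ok / len(down) >= 0.8

    def test_small_seed_set_overfits(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        from chvmine.synthetic import split_pairs

        train, held = split_pairs(pairs, 0.7, seed=0)
        tiny = SeedPairSet(pairs=train.pairs[:8])
        tuned = fit(
            init_projection(small_embedding, 8, seed=0),
            tiny,
            TrainConfig(seed=0, epochs=60),
            heldout_pairs=held,
        )
        last = tuned.last_log[-1]
        assert last["train_mrr"] > last["heldout_mrr"]

    def test_training_log_schema(self, small_gen, small_embedding, tmp_path):
        _cfg, _corpus, pairs, _terms = small_gen
        model = init_projection(small_embedding, 8, seed=1)
        p = tmp_path / "log.jsonl"
        fit(model, pairs, TrainConfig(seed=1, epochs=3), log_path=p)
        import json

        records = [json.loads(line) for line in p.read_text().splitlines()]
        assert [r["epoch"] for r in records] == [0, 1, 2]
        assert all(
            {"surrogate_loss", "ranking_loss", "train_mrr"} <= set(r) for r in records
        )


class TestIterateWithReview:
    def test_empty_accepted_equals_plain_refit(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        model = init_projection(small_embedding, 8, seed=1)
        cfg = TrainConfig(seed=1, epochs=4)
        refit, union = iterate_with_review(
            model, pairs, SeedPairSet(pairs=[]), cfg
        )
        plain = fit(model, pairs, cfg)
        assert np.array_equal(refit.S, plain.S)
        assert union.key_set() == pairs.key_set()

    def test_union_arithmetic(self, small_gen, small_embedding):
        _cfg, _corpus, pairs, _terms = small_gen
        overlap = SeedPairSet(pairs=[pairs.pairs[0], ("P000", "B0000", "new")])
        model = init_projection(small_embedding, 8, seed=1)
        _refit, union = iterate_with_review(
            model, pairs, overlap, TrainConfig(seed=1, epochs=1)
        )
        assert len(union) == len(pairs) + 1
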