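"""Synthetic health-forum-like corpora with planted synonym structure.

The generator emulates the statistical properties the mining method relies
on.  Each concept ``i`` owns one professional token ``P{i}`` and one or more
consumer tokens ``C{i}_{j}`` that occur in the *same* characteristic context
— the surrounding disease/symptom/drug words of a diagnosis — so their
embeddings end up close.  Context tokens are drawn from a shared,
Zipf-weighted pool: just as real symptom words are shared across related
diseases, a context token can serve several concepts, which keeps
distractors heterogeneous rather than interchangeable clones.

Three real-data features are modelled as dials:

* **noise**: any token slot may be replaced by a background token drawn
  from a Zipfian distribution (``noise_rate``);
* **consumer style**: messages mentioning a consumer variant mix in extra
  background tokens (``style_rate``) — lay posts are more casual than
  professional answers.  This contaminates consumer vectors with a
  systematic background component, which is exactly the kind of bias a
  supervised projection can learn to remove;
* **typos and orphans**: a consumer mention may be emitted as a
  single-symbol-substituted variant (itself a gold synonym), and a fraction
  of consumer tokens are orphans with no professional partner, whose
  dedicated contexts overlap no concept's.

Tokens are synthetic symbols (``P007``, ``C007_1``, ``X013``...), keeping
the planted gold structure fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus, SeedPairSet


@dataclass
class GeneratorConfig:
    n_concepts: int = 20
    synonyms_per_concept: int = 2
    vocab_size: int = 500
    n_messages: int = 5000
    message_length: int = 12
    context_size: int = 8  # context tokens per concept (from the shared pool)
    noise_rate: float = 0.1
    typo_rate: float = 0.05
    orphan_rate: float = 0.1
    style_rate: float = 0.35  # extra background mixing in consumer messages
    professional_prob: float = 0.6  # professional vs consumer mention odds
    context_pool_frac: float = 0.5  # pool size / (n_concepts * context_size)
    seed: int = 0

    def total_consumer_slots(self) -> int:
        return self.n_concepts * self.synonyms_per_concept

    def n_orphans(self) -> int:
        return int(round(self.orphan_rate * self.total_consumer_slots()))

    def context_pool_size(self) -> int:
        return max(
            self.context_size,
            int(round(self.n_concepts * self.context_size * self.context_pool_frac)),
        )

    def n_background(self) -> int:
        return self.vocab_size - (
            self.n_concepts * (1 + self.synonyms_per_concept)
            + self.context_pool_size()
            + self.n_orphans() * self.context_size
        )

    def validate(self) -> None:
        if self.n_concepts < 1 or self.synonyms_per_concept < 1:
            raise ValueError(
                "need n_concepts >= 1 and synonyms_per_concept >= 1"
            )
        if self.message_length < 2:
            raise ValueError("message_length must be >= 2")
        for name in ("noise_rate", "typo_rate", "orphan_rate", "style_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 < self.professional_prob < 1.0):
            raise ValueError("professional_prob must lie in (0, 1)")
        if self.n_background() < 0:
            concept = self.n_concepts * (1 + self.synonyms_per_concept)
            ctx = self.context_pool_size() + self.n_orphans() * self.context_size
            raise ValueError(
                "infeasible config: n_concepts*(1+synonyms_per_concept) + "
                f"context vocabulary = {concept} + {ctx} exceeds "
                f"vocab_size = {self.vocab_size}"
            )


def _typo_variant(token: str) -> str:
    # single-symbol substitution, mirroring real-world typo synonyms
    return "K" + token[1:]


def _zipf_p(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, SeedPairSet, list[str]]:
    """Generate (corpus, gold seed pairs, professional-term list).

    Fully reproducible given ``config.seed``.  Gold pairs are every
    non-orphan (P_i, C_i_j), plus each emitted typo variant as an
    additional synonym of its professional term.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    professionals = [f"P{i:03d}" for i in range(config.n_concepts)]
    consumers = {
        (i, j): f"C{i:03d}_{j}"
        for i in range(config.n_concepts)
        for j in range(config.synonyms_per_concept)
    }
    slots = sorted(consumers)
    n_orph = config.n_orphans()
    # first rng draw: orphan slot selection (mirrored by orphan_consumer_tokens)
    orphan_idx = rng.choice(len(slots), size=n_orph, replace=False)
    orphan_slots = {slots[int(i)] for i in orphan_idx}
    orphan_list = sorted(orphan_slots)

    pool_size = config.context_pool_size()
    ctx_pool = [f"X{k:03d}" for k in range(pool_size)]
    pool_p = _zipf_p(pool_size)
    ctx_sets = {
        i: [
            ctx_pool[int(k)]
            for k in rng.choice(
                pool_size, size=config.context_size, replace=False, p=pool_p
            )
        ]
        for i in range(config.n_concepts)
    }
    orphan_contexts = {
        slot: [f"Y{n:03d}_{k}" for k in range(config.context_size)]
        for n, slot in enumerate(orphan_list)
    }

    n_bg = config.n_background()
    background = [f"B{k:04d}" for k in range(n_bg)]
    bg_p = _zipf_p(n_bg) if n_bg else None

    topics: list[tuple[str, object]] = [
        ("concept", i) for i in range(config.n_concepts)
    ] + [("orphan", slot) for slot in orphan_list]

    used_typos: dict[tuple[int, int], str] = {}
    messages: list[list[str]] = []
    L = config.message_length
    for _ in range(config.n_messages):
        kind, ref = topics[int(rng.integers(len(topics)))]
        if kind == "concept":
            i = int(ref)  # type: ignore[arg-type]
            paired = [s for s in slots if s[0] == i and s not in orphan_slots]
            if not paired or rng.random() < config.professional_prob:
                target = professionals[i]
                contam = config.noise_rate
            else:
                slot = paired[int(rng.integers(len(paired)))]
                target = consumers[slot]
                if config.typo_rate > 0 and rng.random() < config.typo_rate:
                    target = _typo_variant(target)
                    used_typos[slot] = target
                contam = min(config.noise_rate + config.style_rate, 0.95)
            ctx_set = ctx_sets[i]
        else:
            slot = ref  # type: ignore[assignment]
            target = consumers[slot]
            ctx_set = orphan_contexts[slot]
            contam = min(config.noise_rate + config.style_rate, 0.95)
        msg = []
        target_pos = int(rng.integers(L))
        for pos in range(L):
            if pos == target_pos:
                msg.append(target)
            elif n_bg and rng.random() < contam:
                msg.append(background[int(rng.choice(n_bg, p=bg_p))])
            else:
                msg.append(ctx_set[int(rng.integers(len(ctx_set)))])
        messages.append(msg)

    pairs = [
        (professionals[i], consumers[(i, j)], "synthetic")
        for (i, j) in slots
        if (i, j) not in orphan_slots
    ]
    pairs += [
        (professionals[i], typo, "synthetic-typo")
        for (i, _j), typo in sorted(used_typos.items())
        if (i, _j) not in orphan_slots
    ]
    corpus = Corpus(
        messages=messages, source_label=f"synthetic(seed={config.seed})"
    )
    return corpus, SeedPairSet(pairs=pairs, provenance="generator"), professionals


def orphan_consumer_tokens(config: GeneratorConfig) -> list[str]:
    """The consumer tokens generated without a professional partner (for
    the same config/seed as :func:`generate_corpus`)."""
    rng = np.random.default_rng(config.seed)
    slots = sorted(
        (i, j)
        for i in range(config.n_concepts)
        for j in range(config.synonyms_per_concept)
    )
    orphan_idx = rng.choice(len(slots), size=config.n_orphans(), replace=False)
    return sorted(
        f"C{slots[int(k)][0]:03d}_{slots[int(k)][1]}" for k in orphan_idx
    )


def split_pairs(
    pairs: SeedPairSet, train_fraction: float, seed: int = 0
) -> tuple[SeedPairSet, SeedPairSet]:
    """Concept-level train/held-out split: all synonyms of one professional
    term land on the same side.  Disjoint and reproducible by seed."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    professionals = pairs.professionals()
    n_train = int(round(train_fraction * len(professionals)))
    if n_train == 0 or n_train == len(professionals):
        raise ValueError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(professionals))
    train_profs = {professionals[int(i)] for i in order[:n_train]}
    train = [p for p in pairs.pairs if p[0] in train_profs]
    held = [p for p in pairs.pairs if p[0] not in train_profs]
    return (
        SeedPairSet(pairs=train, provenance=f"{pairs.provenance}:train"),
        SeedPairSet(pairs=held, provenance=f"{pairs.provenance}:heldout"),
    )
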