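"""Corpus reading, preprocessing, vocabulary building, and seed-pair I/O.

A corpus is a sequence of messages, each a sequence of tokens.  Tokenization
is upstream: files are UTF-8 plain text with one message per line and
whitespace-separated tokens.  Preprocessing replaces URLs with a shared
``URL`` token and rare tokens (corpus frequency strictly below a threshold,
default 30) with a shared ``UNKNOW`` token, after which a vocabulary with
exact frequencies can be built.

Seed pairs — manually verified (professional term, consumer term) synonym
pairs with optional free-text context — travel as TSV with a
``professional<TAB>consumer<TAB>context`` header.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

URL_TOKEN = "URL"
UNKNOW_TOKEN = "UNKNOW"
SPECIAL_TOKENS = (URL_TOKEN, UNKNOW_TOKEN)

# scheme://... or www.-prefixed tokens count as URLs
_URL_RE = re.compile(r"^(?:[A-Za-z][A-Za-z0-9+.\-]*://|www\.)")


@dataclass
class Corpus:
    """An ordered collection of tokenized messages."""

    messages: list[list[str]]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    def token_count(self) -> int:
        return sum(len(m) for m in self.messages)


@dataclass
class Vocabulary:
    """Token <-> contiguous integer id map with corpus frequencies.

    Tokens are ordered by descending corpus frequency, ties broken
    lexicographically; the two special tokens are always present (with their
    true counts, possibly zero).  The one-hot representation of a word is the
    indicator column over this ordering.
    """

    tokens: list[str]
    index_of: dict[str, int]
    freq: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def __len__(self) -> int:
        return len(self.tokens)

    def top_tokens(self, n: int, *, exclude_special: bool = True) -> list[str]:
        """The ``n`` most frequent tokens (ordering is frequency-major)."""
        out = []
        for t in self.tokens:
            if exclude_special and t in SPECIAL_TOKENS:
                continue
            out.append(t)
            if len(out) == n:
                break
        return out


@dataclass
class SeedPairSet:
    """Labeled professional <-> consumer synonym pairs.

    ``pairs`` holds (professional, consumer, context) triples; the
    (professional, consumer) combination is unique.  Both members must be
    single tokens of the working vocabulary (multi-token terms are merged
    upstream by :func:`merge_terms`).
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for p, c, ctx in self.pairs:
            if (p, c) in seen:
                warnings.warn(f"duplicate seed pair ({p!r}, {c!r}) dropped")
                continue
            seen.add((p, c))
            deduped.append((p, c, ctx))
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def key_set(self) -> set[tuple[str, str]]:
        return {(p, c) for p, c, _ in self.pairs}

    def professionals(self) -> list[str]:
        seen = dict.fromkeys(p for p, _, _ in self.pairs)
        return list(seen)

    def consumers(self) -> list[str]:
        seen = dict.fromkeys(c for _, c, _ in self.pairs)
        return list(seen)

    def members(self) -> set[str]:
        return {t for p, c, _ in self.pairs for t in (p, c)}

    def synonyms_of(self, professional: str) -> list[str]:
        return [c for p, c, _ in self.pairs if p == professional]

    def union(self, other: "SeedPairSet") -> "SeedPairSet":
        extra = [t for t in other.pairs if (t[0], t[1]) not in self.key_set()]
        return SeedPairSet(
            pairs=self.pairs + extra,
            provenance=f"{self.provenance}+{other.provenance}".strip("+"),
        )


def is_url(token: str) -> bool:
    return bool(_URL_RE.match(token))


def preprocess(corpus: Corpus, min_count: int = 30) -> Corpus:
    """Replace URL tokens and rare tokens across the corpus.

    Every token matching the URL pattern becomes ``URL``; every remaining
    token whose corpus-wide count is *strictly* less than ``min_count``
    becomes ``UNKNOW``.  Message count and per-message token counts are
    conserved, and the operation is idempotent for a fixed ``min_count``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not corpus.messages:
        raise ValueError("empty corpus")
    url_replaced = [
        [URL_TOKEN if is_url(t) else t for t in msg] for msg in corpus.messages
    ]
    counts: Counter[str] = Counter(t for msg in url_replaced for t in msg)
    out = [
        [
            t
            if t in SPECIAL_TOKENS or counts[t] >= min_count
            else UNKNOW_TOKEN
            for t in msg
        ]
        for msg in url_replaced
    ]
    return Corpus(messages=out, source_label=corpus.source_label)


def build_vocabulary(corpus: Corpus) -> Vocabulary:
    """Exact token frequencies, ids ordered by frequency desc then token."""
    if not corpus.messages:
        raise ValueError("empty corpus")
    counts: Counter[str] = Counter(t for msg in corpus.messages for t in msg)
    for sp in SPECIAL_TOKENS:
        counts.setdefault(sp, 0)
    tokens = sorted(counts, key=lambda t: (-counts[t], t))
    return Vocabulary(
        tokens=tokens,
        index_of={t: i for i, t in enumerate(tokens)},
        freq=dict(counts),
    )


def select_professional_terms(
    vocab: Vocabulary, term_list: Sequence[str], min_freq: int = 1000
) -> list[str]:
    """Terms of ``term_list`` present in the vocabulary with frequency
    strictly greater than ``min_freq``, ordered by frequency descending,
    ties lexicographic."""
    if min_freq < 0:
        raise ValueError("min_freq must be >= 0")
    kept = dict.fromkeys(
        t for t in term_list if t in vocab.index_of and vocab.freq[t] > min_freq
    )
    return sorted(kept, key=lambda t: (-vocab.freq[t], t))


def merge_terms(corpus: Corpus, term_list: Sequence[str]) -> Corpus:
    """Join each multi-token term (whitespace inside) into one
    underscore-joined token throughout the corpus, longest term first."""
    multi = sorted(
        (tuple(t.split()) for t in term_list if len(t.split()) > 1),
        key=len,
        reverse=True,
    )
    if not multi:
        return corpus
    out_messages = []
    for msg in corpus.messages:
        out: list[str] = []
        i = 0
        while i < len(msg):
            for parts in multi:
                if tuple(msg[i : i + len(parts)]) == parts:
                    out.append("_".join(parts))
                    i += len(parts)
                    break
            else:
                out.append(msg[i])
                i += 1
        out_messages.append(out)
    return Corpus(messages=out_messages, source_label=corpus.source_label)


def apply_tokenizer(
    lines: Iterable[str], tokenizer: Callable[[str], list[str]] | None = None
) -> Corpus:
    """Build a corpus from raw lines using an injected tokenizer
    (whitespace splitting by default)."""
    tok = tokenizer or str.split
    return Corpus(messages=[tok(line) for line in lines])


# ---------------------------------------------------------------------------
# file formats


def read_corpus(path: str | Path) -> Corpus:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return Corpus(
        messages=[line.split() for line in lines if line.strip()],
        source_label=str(path),
    )


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    Path(path).write_text(
        "".join(" ".join(msg) + "\n" for msg in corpus.messages), encoding="utf-8"
    )


def read_term_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


def write_term_list(terms: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(t + "\n" for t in terms), encoding="utf-8")


_SEED_HEADER = "professional\tconsumer\tcontext"


def read_seed_pairs(path: str | Path) -> SeedPairSet:
    """Read a seed-pair TSV (header ``professional  consumer  context``).

    Malformed rows raise with their line number; duplicate pairs are dropped
    with a warning.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[:2] != ["professional", "consumer"]:
        raise ValueError(f"{path}: line 1: expected header {_SEED_HEADER!r}")
    pairs: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            fields.append("")
        if len(fields) != 3 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}: line {lineno}: malformed row {line!r}")
        pairs.append((fields[0], fields[1], fields[2]))
    return SeedPairSet(pairs=pairs, provenance=str(path))


def write_seed_pairs(pair_set: SeedPairSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_SEED_HEADER + "\n")
        for p, c, ctx in pair_set.pairs:
            fh.write(f"{p}\t{c}\t{ctx}\n")
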