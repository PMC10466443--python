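"""Independent oracles used by the test suite.

The proximity oracle re-derives phrase matching from first principles:
exhaustive enumeration of every token window within the slop-bounded length,
with window validity decided by Hall's marriage condition on the term/position
bipartite graph (a deliberately different algorithm from the engine's
backtracking assignment search).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

from sdohscan.query import PhraseQuery, TermPattern, Token


def _window_valid(
    terms: Sequence[TermPattern], norms: Sequence[str], start: int, end: int
) -> bool:
    """Hall's condition: every subset S of terms must be matchable by at
    least |S| distinct positions inside the window."""
    positions = range(start, end + 1)
    match_sets = [
        {p for p in positions if t.matches(norms[p])} for t in terms
    ]
    for size in range(1, len(terms) + 1):
        for subset in combinations(match_sets, size):
            neighborhood: set[int] = set()
            for s in subset:
                neighborhood |= s
            if len(neighborhood) < size:
                return False
    return True


def brute_force_spans(
    phrase: PhraseQuery, tokens: Sequence[Token]
) -> set[tuple[int, int]]:
    """All minimal matching windows (start, end), by exhaustive enumeration."""
    norms = [t.norm for t in tokens]
    n = len(norms)
    k = len(phrase.terms)
    valid: set[tuple[int, int]] = set()
    if phrase.slop == 0:
        for s in range(n - k + 1):
            if all(t.matches(norms[s + j]) for j, t in enumerate(phrase.terms)):
                valid.add((s, s + k - 1))
        return valid  # fixed-length windows cannot nest
    max_len = k + phrase.slop
    for s in range(n):
        for e in range(s, min(n, s + max_len)):
            if _window_valid(phrase.terms, norms, s, e):
                valid.add((s, e))
    return {
        w
        for w in valid
        if not any(v != w and w[0] <= v[0] and v[1] <= w[1] for v in valid)
    }


def make_tokens(words: Sequence[str]) -> list[Token]:
    return [Token(surface=w, norm=w.lower(), pos=i) for i, w in enumerate(words)]


#: Small vocabulary for random proximity instances; two-letter words so that
#: one-letter wildcard stems are genuine prefixes of several words.
ORACLE_VOCAB = ["aa", "ab", "ac", "ba", "bb", "bc", "ca", "cb", "cc", "da"]


def random_instance(rng) -> tuple[PhraseQuery, list[Token]]:
    """Random (phrase, token sequence) pair: length <= 30, 2-4 terms,
    slop <= 10, with a mix of exact and wildcard terms."""
    length = int(rng.integers(0, 31))
    words = [ORACLE_VOCAB[int(i)] for i in rng.integers(len(ORACLE_VOCAB), size=length)]
    k = int(rng.integers(2, 5))
    terms = []
    for _ in range(k):
        word = ORACLE_VOCAB[int(rng.integers(len(ORACLE_VOCAB)))]
        if rng.random() < 0.3:
            terms.append(TermPattern(stem=word[0], wildcard=True))
        else:
            terms.append(TermPattern(stem=word))
    slop = int(rng.integers(0, 11))
    return PhraseQuery(terms=tuple(terms), slop=slop), make_tokens(words)
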