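"""Tokenizer, parser and renderer for the narrative search-rule dialect.

The shipped social-risk rules are written in a small Lucene-flavoured Boolean
dialect: quoted phrases with an optional ``~N`` proximity (slop) suffix, bare
terms with an optional trailing ``*`` wildcard, infix ``OR`` / ``AND`` and a
single document-level ``NOT`` splitting the rule into an include and an
exclude side.  Published rule text additionally uses two conventions this
parser accepts: a ``~Nth`` suffix (read as slop ``N``; the ``th`` is a display
artifact) and a comma between quoted phrases (read as ``OR``).

Both rule text and note text pass through the same lossy normalization:
Unicode curly quotes and apostrophes are mapped to their ASCII forms, case is
folded to lower, and tokens are maximal runs of letters/digits with internal
apostrophes preserved; every other character is a separator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Union

from .domains import DOMAINS

__all__ = [
    "Token",
    "TermPattern",
    "PhraseQuery",
    "Disjunction",
    "Conjunction",
    "Exclusion",
    "QueryExpr",
    "Rule",
    "ParseError",
    "tokenize",
    "normalize_text",
    "parse_rule",
    "parse_expr",
    "render_rule",
    "render_expr",
    "load_default_rules",
    "rule_vocabulary",
]

# Curly quote / apostrophe forms seen in published rule text and EHR exports.
_QUOTE_MAP = str.maketrans(
    {
        "“": '"',  # “
        "”": '"',  # ”
        "„": '"',  # „
        "‘": "'",  # ‘
        "’": "'",  # ’
        "‚": "'",  # ‚
    }
)

_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)


def normalize_text(text: str) -> str:
    """Map curly quotes/apostrophes to ASCII (the rest of normalization —
    case folding and separator stripping — happens during tokenization)."""
    return text.translate(_QUOTE_MAP)


@dataclass(frozen=True)
class Token:
    """One note token: the surface slice, its lowercase norm, and its 0-based
    position in the token stream (positions, not characters, are what
    proximity windows are measured in)."""

    surface: str
    norm: str
    pos: int


def tokenize(text: str) -> list[Token]:
    """Split free text into normalized tokens.

    Tokens are maximal runs of letters/digits, keeping internal apostrophes
    ("doesn't" stays one token); digit runs are tokens in their own right.
    Empty input yields an empty list.
    """
    normalized = normalize_text(text)
    return [
        Token(surface=m.group(), norm=m.group().lower(), pos=i)
        for i, m in enumerate(_TOKEN_RE.finditer(normalized))
    ]


@dataclass(frozen=True)
class TermPattern:
    """A single-token pattern: exact norm equality, or prefix match when the
    source term ended with ``*``."""

    stem: str
    wildcard: bool = False

    def __post_init__(self) -> None:
        if not self.stem:
            raise ValueError("TermPattern stem must be non-empty")

    def matches(self, norm: str) -> bool:
        if self.wildcard:
            return norm.startswith(self.stem)
        return norm == self.stem


@dataclass(frozen=True)
class PhraseQuery:
    """An ordered list of term patterns with a proximity allowance.

    ``slop == 0`` requires the terms adjacent and in order; ``slop > 0``
    requires all terms (in any order) inside some token window of length at
    most ``len(terms) + slop``.  A single-term phrase behaves exactly like its
    term pattern.
    """

    terms: tuple[TermPattern, ...]
    slop: int = 0

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("PhraseQuery needs at least one term")
        if self.slop < 0:
            raise ValueError("slop must be non-negative")


@dataclass(frozen=True)
class Disjunction:
    children: tuple["QueryExpr", ...]


@dataclass(frozen=True)
class Conjunction:
    children: tuple["QueryExpr", ...]


@dataclass(frozen=True)
class Exclusion:
    """Document-level veto: the rule fires when the include side matches and
    the exclude side matches nowhere in the note."""

    include: "QueryExpr"
    exclude: "QueryExpr"


QueryExpr = Union[PhraseQuery, Disjunction, Conjunction, Exclusion]


def _dedup_flatten(cls, children) -> "QueryExpr":
    """Flatten nested same-type Boolean nodes, drop structural duplicates,
    collapse a singleton to its child."""
    flat: list[QueryExpr] = []
    for child in children:
        if isinstance(child, cls):
            flat.extend(child.children)
        else:
            flat.append(child)
    seen: list[QueryExpr] = []
    for child in flat:
        if child not in seen:
            seen.append(child)
    if len(seen) == 1:
        return seen[0]
    return cls(children=tuple(seen))


def disjunction(children) -> QueryExpr:
    return _dedup_flatten(Disjunction, children)


def conjunction(children) -> QueryExpr:
    return _dedup_flatten(Conjunction, children)


@dataclass(frozen=True)
class Rule:
    """A named domain rule together with its source text and parsed tree.

    Equality is structural (domain + tree); the verbatim source text is kept
    for provenance but not compared, so a rule equals its canonical re-render.
    """

    domain: str
    expr: QueryExpr
    source_text: str = field(compare=False, default="")

    @property
    def include_expr(self) -> QueryExpr:
        return self.expr.include if isinstance(self.expr, Exclusion) else self.expr

    @property
    def exclude_expr(self) -> QueryExpr | None:
        return self.expr.exclude if isinstance(self.expr, Exclusion) else None

    @property
    def include_entries(self) -> int:
        return _entry_count(self.include_expr)

    @property
    def exclude_entries(self) -> int:
        exc = self.exclude_expr
        return 0 if exc is None else _entry_count(exc)


def _entry_count(expr: QueryExpr) -> int:
    return len(expr.children) if isinstance(expr, Disjunction) else 1


class ParseError(ValueError):
    """Raised on malformed rule text; ``offset`` is the character offset in
    the normalized rule string where the problem was detected."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# Lexer

_LPAREN, _RPAREN, _COMMA, _OR, _AND, _NOT, _PHRASE, _TERM, _EOF = range(9)

_WORD_RE = re.compile(r"[0-9A-Za-z']+")
_SLOP_RE = re.compile(r"~(\d+)(?:th)?", re.IGNORECASE)


@dataclass(frozen=True)
class _Lexed:
    kind: int
    value: object
    offset: int


def _lex(text: str) -> Iterator[_Lexed]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            yield _Lexed(_LPAREN, ch, i)
            i += 1
        elif ch == ")":
            yield _Lexed(_RPAREN, ch, i)
            i += 1
        elif ch == ",":
            yield _Lexed(_COMMA, ch, i)
            i += 1
        elif ch == '"':
            close = text.find('"', i + 1)
            if close < 0:
                raise ParseError("unbalanced quote", i)
            interior = text[i + 1 : close]
            terms = tuple(
                TermPattern(stem=t.norm, wildcard=False) for t in tokenize(interior)
            )
            if not terms:
                raise ParseError("empty phrase", i)
            j = close + 1
            slop = 0
            m = _SLOP_RE.match(text, j)
            if m:
                slop = int(m.group(1))
                j = m.end()
            yield _Lexed(_PHRASE, PhraseQuery(terms=terms, slop=slop), i)
            i = j
        else:
            m = _WORD_RE.match(text, i)
            if not m:
                raise ParseError(f"unexpected character {ch!r}", i)
            word = m.group()
            j = m.end()
            upper = word.upper()
            if upper in ("OR", "AND", "NOT"):
                kind = {"OR": _OR, "AND": _AND, "NOT": _NOT}[upper]
                yield _Lexed(kind, upper, i)
            else:
                wildcard = j < n and text[j] == "*"
                if wildcard:
                    j += 1
                yield _Lexed(_TERM, TermPattern(stem=word.lower(), wildcard=wildcard), i)
            i = j
    yield _Lexed(_EOF, None, n)


# ---------------------------------------------------------------------------
# Parser (recursive descent; NOT is legal only once, at the top level)


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = list(_lex(text))
        self.i = 0

    @property
    def cur(self) -> _Lexed:
        return self.tokens[self.i]

    def advance(self) -> _Lexed:
        tok = self.cur
        self.i += 1
        return tok

    def parse(self) -> QueryExpr:
        include = self.parse_or()
        expr: QueryExpr = include
        if self.cur.kind == _NOT:
            self.advance()
            exclude = self.parse_or()
            if self.cur.kind == _NOT:
                raise ParseError("NOT may appear at most once", self.cur.offset)
            expr = Exclusion(include=include, exclude=exclude)
        if self.cur.kind != _EOF:
            raise ParseError("unexpected trailing input", self.cur.offset)
        return expr

    def parse_or(self) -> QueryExpr:
        children = [self.parse_and()]
        while self.cur.kind in (_OR, _COMMA):
            self.advance()
            children.append(self.parse_and())
        return disjunction(children)

    def parse_and(self) -> QueryExpr:
        children = [self.parse_atom()]
        while self.cur.kind == _AND:
            self.advance()
            children.append(self.parse_atom())
        return conjunction(children)

    def parse_atom(self) -> QueryExpr:
        tok = self.cur
        if tok.kind == _LPAREN:
            self.advance()
            inner = self.parse_or()
            if self.cur.kind == _NOT:
                raise ParseError(
                    "NOT is only allowed at the top level", self.cur.offset
                )
            if self.cur.kind != _RPAREN:
                raise ParseError("unbalanced parenthesis", tok.offset)
            self.advance()
            return inner
        if tok.kind == _PHRASE:
            self.advance()
            return tok.value  # type: ignore[return-value]
        if tok.kind == _TERM:
            self.advance()
            return PhraseQuery(terms=(tok.value,), slop=0)  # type: ignore[arg-type]
        raise ParseError("expected a term, phrase or '('", tok.offset)


def parse_expr(text: str) -> QueryExpr:
    """Parse a rule expression string into a query tree."""
    return _Parser(normalize_text(text)).parse()


def parse_rule(domain: str, rule_text: str) -> Rule:
    """Parse one domain rule; the returned :class:`Rule` keeps the verbatim
    source text alongside the canonicalized tree."""
    return Rule(domain=domain, source_text=rule_text, expr=parse_expr(rule_text))


# ---------------------------------------------------------------------------
# Renderer

_KEYWORDS = frozenset({"OR", "AND", "NOT"})


def _render_phrase(p: PhraseQuery) -> str:
    if len(p.terms) == 1 and p.slop == 0:
        term = p.terms[0]
        if term.wildcard:
            return f"{term.stem}*"
        if term.stem.upper() not in _KEYWORDS:
            return term.stem
        return f'"{term.stem}"'
    if any(t.wildcard for t in p.terms):
        raise ValueError("wildcards inside multi-term phrases cannot be rendered")
    body = " ".join(t.stem for t in p.terms)
    return f'"{body}"~{p.slop}' if p.slop else f'"{body}"'


def _render(expr: QueryExpr, parenthesize: bool) -> str:
    if isinstance(expr, PhraseQuery):
        return _render_phrase(expr)
    if isinstance(expr, Disjunction):
        body = " OR ".join(_render(c, True) for c in expr.children)
    elif isinstance(expr, Conjunction):
        body = " AND ".join(_render(c, True) for c in expr.children)
    else:  # Exclusion — handled at top level only
        raise ValueError("Exclusion may only appear at the root of a rule")
    return f"({body})" if parenthesize else body


def render_expr(expr: QueryExpr) -> str:
    """Render a query tree to canonical single-line text that reparses to a
    structurally equal tree (slop printed as ``~N``, straight quotes)."""
    if isinstance(expr, Exclusion):
        inc = _render(expr.include, not isinstance(expr.include, PhraseQuery))
        exc = _render(expr.exclude, not isinstance(expr.exclude, PhraseQuery))
        return f"{inc} NOT {exc}"
    return _render(expr, False)


def render_rule(rule: Rule) -> str:
    return render_expr(rule.expr)


# ---------------------------------------------------------------------------
# Shipped rule set

def load_default_rules() -> dict[str, Rule]:
    """Load the seven packaged domain rules, keyed by domain name."""
    rules: dict[str, Rule] = {}
    for domain in DOMAINS:
        text = (
            resources.files("sdohscan.rules")
            .joinpath(f"{domain}.rule")
            .read_text(encoding="utf-8")
            .strip()
        )
        rules[domain] = parse_rule(domain, text)
    return rules


def _expr_terms(expr: QueryExpr) -> Iterator[TermPattern]:
    if isinstance(expr, PhraseQuery):
        yield from expr.terms
    elif isinstance(expr, (Disjunction, Conjunction)):
        for child in expr.children:
            yield from _expr_terms(child)
    else:
        yield from _expr_terms(expr.include)
        yield from _expr_terms(expr.exclude)


def rule_vocabulary(rules: dict[str, Rule] | None = None) -> list[TermPattern]:
    """Every term pattern appearing in any rule, include or exclude side.

    Used to build filler vocabularies guaranteed not to trigger any rule:
    a word is safe iff no returned pattern matches it.
    """
    if rules is None:
        rules = load_default_rules()
    patterns: list[TermPattern] = []
    for rule in rules.values():
        for term in _expr_terms(rule.expr):
            if term not in patterns:
                patterns.append(term)
    return patterns
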