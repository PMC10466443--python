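"""Evaluate domain rules against tokenized clinical notes.

The unit of matching is the individual note.  A phrase with slop ``s`` matches
any minimal token window of length at most ``len(terms) + s`` containing all
its terms (in order and adjacent when ``s == 0``, in any order otherwise).
``NOT`` is document-scoped: one exclusion hit anywhere in the note vetoes the
whole note for that rule.  Patient-level flags are the OR over the patient's
eligible notes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .domains import DEFAULT_ELIGIBLE_NOTE_TYPES
from .query import (
    Conjunction,
    Disjunction,
    Exclusion,
    PhraseQuery,
    QueryExpr,
    Rule,
    TermPattern,
    Token,
    tokenize,
)

__all__ = [
    "ClinicalNote",
    "Span",
    "MatchResult",
    "CorpusClassification",
    "phrase_matches",
    "evaluate",
    "classify_note",
    "classify_patient_unstructured",
    "classify_corpus",
]


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    note_type: str
    date: _dt.date
    text: str


@dataclass(frozen=True)
class Span:
    """Evidence window in token positions (inclusive ends)."""

    start: int
    end: int
    matched_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("Span start must not exceed end")


@dataclass(frozen=True)
class MatchResult:
    note_id: str
    patient_id: str
    domain: str
    include_hit: bool
    exclude_hit: bool
    positive: bool
    evidence: tuple[Span, ...] = ()


class _NoteIndex:
    """Per-note inverted index: norm -> sorted token positions, with cached
    wildcard (prefix) lookups.  Built once per note, shared across rules."""

    __slots__ = ("norms", "positions", "_wildcard_cache")

    def __init__(self, tokens: Sequence[Token]) -> None:
        self.norms = [t.norm for t in tokens]
        positions: dict[str, list[int]] = {}
        for i, norm in enumerate(self.norms):
            positions.setdefault(norm, []).append(i)
        self.positions = positions
        self._wildcard_cache: dict[str, tuple[int, ...]] = {}

    def term_positions(self, term: TermPattern) -> tuple[int, ...]:
        if not term.wildcard:
            return tuple(self.positions.get(term.stem, ()))
        cached = self._wildcard_cache.get(term.stem)
        if cached is None:
            hits: list[int] = []
            for norm, pos in self.positions.items():
                if norm.startswith(term.stem):
                    hits.extend(pos)
            cached = tuple(sorted(hits))
            self._wildcard_cache[term.stem] = cached
        return cached


def _find_assignment(
    terms: Sequence[TermPattern], norms: Sequence[str], positions: Sequence[int]
) -> tuple[int, ...] | None:
    """Injective assignment of phrase terms to token positions, or None."""

    def backtrack(ti: int, used: tuple[int, ...]) -> tuple[int, ...] | None:
        if ti == len(terms):
            return used
        for p in positions:
            if p not in used and terms[ti].matches(norms[p]):
                result = backtrack(ti + 1, used + (p,))
                if result is not None:
                    return result
        return None

    return backtrack(0, ())


def _phrase_spans(phrase: PhraseQuery, index: _NoteIndex) -> list[Span]:
    terms = phrase.terms
    k = len(terms)
    norms = index.norms
    pos_lists = [index.term_positions(t) for t in terms]
    if any(not pl for pl in pos_lists):
        return []

    if phrase.slop == 0:
        spans = []
        for p in pos_lists[0]:
            if p + k <= len(norms) and all(
                terms[j].matches(norms[p + j]) for j in range(1, k)
            ):
                spans.append(
                    Span(start=p, end=p + k - 1, matched_terms=tuple(norms[p : p + k]))
                )
        return spans

    max_len = k + phrase.slop
    candidates = sorted({p for pl in pos_lists for p in pl})
    windows: list[tuple[int, int, tuple[int, ...]]] = []
    for ci, s in enumerate(candidates):
        for e in candidates[ci:]:
            if e - s + 1 > max_len:
                break
            inside = [p for p in candidates if s <= p <= e]
            assignment = _find_assignment(terms, norms, inside)
            if assignment is not None:
                windows.append((s, e, assignment))
                break
    # keep minimal windows only (drop any strictly containing another)
    minimal = [
        (s, e, a)
        for (s, e, a) in windows
        if not any(
            (s2, e2) != (s, e) and s <= s2 and e2 <= e for (s2, e2, _) in windows
        )
    ]
    return [
        Span(start=s, end=e, matched_terms=tuple(norms[p] for p in sorted(a)))
        for (s, e, a) in minimal
    ]


def phrase_matches(phrase: PhraseQuery, tokens: Sequence[Token]) -> list[Span]:
    """All minimal evidence windows for one phrase over a token stream."""
    return _phrase_spans(phrase, _NoteIndex(tokens))


def _evaluate(expr: QueryExpr, index: _NoteIndex) -> tuple[bool, list[Span]]:
    if isinstance(expr, PhraseQuery):
        spans = _phrase_spans(expr, index)
        return bool(spans), spans
    if isinstance(expr, Disjunction):
        hit = False
        evidence: list[Span] = []
        for child in expr.children:
            child_hit, child_spans = _evaluate(child, index)
            if child_hit:
                hit = True
                evidence.extend(child_spans)
        return hit, evidence
    if isinstance(expr, Conjunction):
        evidence = []
        for child in expr.children:
            child_hit, child_spans = _evaluate(child, index)
            if not child_hit:
                return False, []
            evidence.extend(child_spans)
        return True, evidence
    if isinstance(expr, Exclusion):
        inc_hit, inc_spans = _evaluate(expr.include, index)
        if not inc_hit:
            return False, []
        exc_hit, _ = _evaluate(expr.exclude, index)
        return (not exc_hit), inc_spans
    raise TypeError(f"not a query expression: {expr!r}")


def evaluate(expr: QueryExpr, tokens: Sequence[Token]) -> tuple[bool, list[Span]]:
    """Boolean outcome plus include-side evidence spans for one expression.

    For an exclusion the include-side spans are returned only when the note
    is positive (include hit and no exclusion hit anywhere in the note).
    """
    return _evaluate(expr, _NoteIndex(tokens))


def _classify_indexed(rule: Rule, note: ClinicalNote, index: _NoteIndex) -> MatchResult:
    include_hit, evidence = _evaluate(rule.include_expr, index)
    exclude_hit = False
    if include_hit and rule.exclude_expr is not None:
        exclude_hit, _ = _evaluate(rule.exclude_expr, index)
    positive = include_hit and not exclude_hit
    return MatchResult(
        note_id=note.note_id,
        patient_id=note.patient_id,
        domain=rule.domain,
        include_hit=include_hit,
        exclude_hit=exclude_hit,
        positive=positive,
        evidence=tuple(evidence),
    )


def classify_note(rule: Rule, note: ClinicalNote) -> MatchResult:
    """Apply one domain rule to one note; empty text is simply negative."""
    return _classify_indexed(rule, note, _NoteIndex(tokenize(note.text)))


def classify_patient_unstructured(
    rules: Mapping[str, Rule],
    notes: Sequence[ClinicalNote],
    eligible_types: frozenset[str] | set[str] = DEFAULT_ELIGIBLE_NOTE_TYPES,
) -> dict[str, bool]:
    """Patient-level domain flags: OR over the patient's eligible notes.

    All notes must belong to one patient; a patient with zero notes gets all
    flags false (callers wanting the "no notes" report use
    :func:`classify_corpus`).
    """
    patient_ids = {n.patient_id for n in notes}
    if len(patient_ids) > 1:
        raise ValueError(f"notes span multiple patients: {sorted(patient_ids)}")
    flags = {domain: False for domain in rules}
    for note in notes:
        if note.note_type not in eligible_types:
            continue
        index = _NoteIndex(tokenize(note.text))
        for domain, rule in rules.items():
            if not flags[domain]:
                flags[domain] = _classify_indexed(rule, note, index).positive
    return flags


@dataclass
class CorpusClassification:
    """Note- and patient-level output of a corpus run.

    ``matches`` keeps every note x domain result whose include side hit
    (positives plus exclusion-vetoed notes — the rows a reviewer would want);
    ``flags`` maps patient -> domain -> bool; ``no_notes`` lists cohort
    patients with no eligible notes at all.
    """

    flags: dict[str, dict[str, bool]]
    matches: list[MatchResult] = field(default_factory=list)
    no_notes: list[str] = field(default_factory=list)

    def positive_patients(self, domain: str) -> set[str]:
        return {pid for pid, f in self.flags.items() if f[domain]}


def classify_corpus(
    rules: Mapping[str, Rule],
    notes: Iterable[ClinicalNote],
    eligible_types: frozenset[str] | set[str] = DEFAULT_ELIGIBLE_NOTE_TYPES,
    patients: Iterable[str] | None = None,
) -> CorpusClassification:
    """Run every rule over every eligible note of a corpus.

    ``patients`` optionally supplies the full cohort so that patients without
    any eligible note are still reported (with all-false flags) in
    ``no_notes``.
    """
    flags: dict[str, dict[str, bool]] = {}
    seen_with_notes: set[str] = set()
    matches: list[MatchResult] = []
    if patients is not None:
        for pid in patients:
            flags[pid] = {domain: False for domain in rules}
    for note in notes:
        flags.setdefault(note.patient_id, {domain: False for domain in rules})
        if note.note_type not in eligible_types:
            continue
        seen_with_notes.add(note.patient_id)
        index = _NoteIndex(tokenize(note.text))
        for domain, rule in rules.items():
            result = _classify_indexed(rule, note, index)
            if result.include_hit:
                matches.append(result)
            if result.positive:
                flags[note.patient_id][domain] = True
    no_notes = sorted(set(flags) - seen_with_notes)
    return CorpusClassification(flags=flags, matches=matches, no_notes=no_notes)
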