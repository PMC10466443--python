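"""Phrase matching, rule evaluation and patient-level aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdohscan.domains import DOMAINS
from sdohscan.engine import (
    classify_corpus,
    classify_note,
    classify_patient_unstructured,
    evaluate,
    phrase_matches,
)
from sdohscan.query import Disjunction, PhraseQuery, TermPattern, parse_expr
from sdohscan.synth import TABLE_FALSE_POSITIVE, TABLE_TRUE_POSITIVE, filler_vocabulary

from .oracles import brute_force_spans, make_tokens, random_instance


def phrase(*stems, slop=0):
    return PhraseQuery(terms=tuple(TermPattern(stem=s) for s in stems), slop=slop)


class TestPhraseMatches:
    def test_adjacent_pair_matches_any_slop(self):
        tokens = make_tokens("pt reports social isolation at home".split())
        spans = phrase_matches(phrase("social", "isolation", slop=10), tokens)
        assert [(s.start, s.end) for s in spans] == [(2, 3)]
        assert spans[0].matched_terms == ("social", "isolation")

    def test_terms_too_far_apart(self):
        words = ["social"] + ["filler"] * 11 + ["isolation"]
        spans = phrase_matches(phrase("social", "isolation", slop=10), make_tokens(words))
        assert spans == []
        # brute-force confirmation: no window of length <= 12 holds both
        assert brute_force_spans(phrase("social", "isolation", slop=10), make_tokens(words)) == set()

    def test_digit_token_within_slop(self):
        tokens = make_tokens("isolation precautions for 14 days".split())
        spans = phrase_matches(phrase("isolation", "14", slop=6), tokens)
        assert [(s.start, s.end) for s in spans] == [(0, 3)]

    def test_slop_zero_requires_order_and_adjacency(self):
        tokens = make_tokens("isolation social".split())
        assert phrase_matches(phrase("social", "isolation"), tokens) == []
        assert phrase_matches(phrase("isolation", "social"), tokens) != []

    def test_unordered_when_slop_positive(self):
        tokens = make_tokens("lonely feeling today".split())
        assert phrase_matches(phrase("feeling", "lonely", slop=10), tokens) != []

    def test_wildcard_prefix(self):
        tokens = make_tokens("patient currently unemployed again".split())
        q = PhraseQuery(terms=(TermPattern("unemploy", wildcard=True),), slop=0)
        assert [(s.start, s.end) for s in phrase_matches(q, tokens)] == [(2, 2)]

    @settings(max_examples=300)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """Random phrases/token streams: engine == window-enumeration oracle."""
        rng = np.random.default_rng(seed)
        q, tokens = random_instance(rng)
        got = {(s.start, s.end) for s in phrase_matches(q, tokens)}
        assert got == brute_force_spans(q, tokens)


class TestEvaluate:
    def test_housing_confusable_is_positive(self, rules):
        hit, spans = evaluate(rules["housing"].expr, make_tokens("volunteers at the animal shelter".split()))
        assert hit and spans

    def test_food_exclusion_vetoes_note(self, rules):
        tokens = make_tokens("denies food insecurity at this time".split())
        hit, spans = evaluate(rules["food"].expr, tokens)
        assert not hit
        # the include side alone does hit
        inc_hit, _ = evaluate(rules["food"].include_expr, tokens)
        assert inc_hit

    def test_education_true_positive(self, rules):
        hit, _ = evaluate(rules["education"].expr, make_tokens("never went to school and cannot read".split()))
        assert hit

    def test_conjunction_requires_both(self):
        expr = parse_expr('"home safety" AND "home environment"')
        assert evaluate(expr, make_tokens("home safety review done".split()))[0] is False
        both = make_tokens("home safety and home environment assessed".split())
        hit, spans = evaluate(expr, both)
        assert hit and len(spans) == 2


class TestClassifyNote:
    @pytest.mark.parametrize("domain", DOMAINS)
    def test_published_snippets_flag_positive(self, rules, make_note, domain):
        """Both printed example columns (true and false positives) were
        rule hits; adjudication happens downstream in review."""
        for text in (TABLE_TRUE_POSITIVE[domain], TABLE_FALSE_POSITIVE[domain]):
            assert classify_note(rules[domain], make_note(text)).positive

    def test_employment_cannot_tell_son_from_patient(self, rules, make_note):
        assert classify_note(rules["employment"], make_note("Currently unemployed")).positive
        assert classify_note(rules["employment"], make_note("Unemployed son")).positive

    def test_stress_test_is_excluded(self, rules, make_note):
        result = classify_note(rules["stress"], make_note("cardiac stress test ordered"))
        assert not result.positive

    def test_empty_note_is_negative(self, rules, make_note):
        result = classify_note(rules["food"], make_note(""))
        assert not result.positive and not result.include_hit

    def test_positive_implies_evidence(self, rules, make_note):
        result = classify_note(rules["food"], make_note("referred to food pantry"))
        assert result.positive and result.evidence

    def test_exclusion_phrases_alone_in_filler_are_negative(self, rules, make_note):
        """Every NOT-list entry, embedded in rule-disjoint filler, never
        produces a positive for its own (or any) domain."""
        vocab = filler_vocabulary()
        for domain, rule in rules.items():
            from sdohscan.synth import snippet_bank

            for neg in snippet_bank(domain).negation:
                text = f"{' '.join(vocab[:5])} {neg} {' '.join(vocab[5:10])}"
                for d2, r2 in rules.items():
                    assert not classify_note(r2, make_note(text)).positive


class TestFillerMonotonicity:
    @given(
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
        st.sampled_from(sorted(DOMAINS)),
    )
    def test_filler_padding_never_flips_outcome(self, rules, n_before, n_after, domain):
        """Padding with rule-disjoint filler preserves positives and cannot
        create an include hit from nothing."""
        vocab = filler_vocabulary()
        before = " ".join(vocab[i % len(vocab)] for i in range(n_before))
        after = " ".join(vocab[-(i % len(vocab)) - 1] for i in range(n_after))
        from sdohscan.engine import ClinicalNote
        import datetime as dt

        def note(text):
            return ClinicalNote("n", "p", "progress note", dt.date(2018, 1, 1), text)

        positive_text = TABLE_TRUE_POSITIVE[domain]
        padded = f"{before} {positive_text} {after}".strip()
        assert classify_note(rules[domain], note(padded)).positive

        neutral = f"{before} {after}".strip()
        assert not classify_note(rules[domain], note(neutral)).include_hit


class TestPatientAggregation:
    def test_or_over_notes(self, rules, make_note):
        notes = [make_note("routine followup", note_id=f"n{i}") for i in range(9)]
        notes.append(make_note("referred to food pantry", note_id="n9"))
        flags = classify_patient_unstructured(rules, notes)
        assert flags["food"] and not flags["housing"]

    def test_zero_notes_all_false_and_reported(self, rules):
        flags = classify_patient_unstructured(rules, [])
        assert not any(flags.values())
        out = classify_corpus(rules, [], patients=["p1"])
        assert out.no_notes == ["p1"] and not any(out.flags["p1"].values())

    def test_food_insecurity_none_still_flags(self, rules, make_note):
        """'Food insecurity: none' matches the include side and no published
        exclusion covers it — the reason manual review exists."""
        flags = classify_patient_unstructured(rules, [make_note("Food insecurity: none")])
        assert flags["food"]

    def test_ineligible_note_types_are_ignored(self, rules, make_note):
        notes = [make_note("referred to food pantry", note_type="other")]
        flags = classify_patient_unstructured(rules, notes)
        assert not flags["food"]

    def test_multiple_patients_rejected(self, rules, make_note):
        notes = [make_note("a", patient_id="p1"), make_note("b", patient_id="p2")]
        with pytest.raises(ValueError):
            classify_patient_unstructured(rules, notes)
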