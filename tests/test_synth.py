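"""Synthetic cohort generator: determinism, calibration, planted evidence."""

import numpy as np
import pytest

from sdohscan.coding import select_diabetes_cohort
from sdohscan.domains import DOMAINS
from sdohscan.engine import classify_corpus, classify_note
from sdohscan.query import load_default_rules, rule_vocabulary
from sdohscan.review import cohen_kappa, proportional_agreement
from sdohscan.synth import (
    SynthConfig,
    filler_vocabulary,
    generate_cohort,
    simulate_review,
    snippet_bank,
    true_positive_units,
)

SMALL = SynthConfig(n_patients=400, seed=17)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SMALL)


@pytest.fixture(scope="module")
def rules_mod():
    return load_default_rules()


class TestConfig:
    def test_rates_validated_before_generation(self):
        with pytest.raises(ValueError):
            SynthConfig(n_patients=10, narrative_doc_rate=1.5)
        with pytest.raises(ValueError):
            SynthConfig(n_patients=0)
        with pytest.raises(ValueError):
            SynthConfig(true_prevalence={"not_a_domain": 0.1})


class TestSnippetBank:
    def test_food_bank_contains_published_example(self):
        bank = snippet_bank("food")
        assert "Diet remains problem with severe food insecurity" in bank.true_positive

    def test_housing_confusables_contain_published_example(self):
        assert "Volunteers at the animal shelter" in snippet_bank("housing").confusable

    def test_stress_negations_embed_not_list_phrase(self):
        assert any("stressed importance" in t for t in snippet_bank("stress").negation)

    def test_unknown_domain_rejected(self):
        with pytest.raises(KeyError):
            snippet_bank("transportation")

    def test_every_tp_template_is_detectable(self, rules_mod, make_note):
        for domain in DOMAINS:
            for template in snippet_bank(domain).true_positive:
                assert classify_note(rules_mod[domain], make_note(template)).positive

    def test_templates_never_cross_domains(self, rules_mod, make_note):
        """TP/confusable snippets trigger exactly their own domain; negation
        snippets trigger none."""
        for domain in DOMAINS:
            bank = snippet_bank(domain)
            for kind, templates in (
                ("tp", bank.true_positive),
                ("fp", bank.confusable),
                ("neg", bank.negation),
            ):
                expected = {domain} if kind in ("tp", "fp") else set()
                for template in templates:
                    hits = {
                        d
                        for d in DOMAINS
                        if classify_note(rules_mod[d], make_note(template)).positive
                    }
                    assert hits == expected, (domain, kind, template)


class TestFillerVocabulary:
    def test_disjoint_from_all_rule_terms(self):
        patterns = rule_vocabulary()
        for word in filler_vocabulary():
            assert not any(p.matches(word) for p in patterns), word


class TestGeneration:
    def test_deterministic_for_seed(self):
        a = generate_cohort(SynthConfig(n_patients=60, seed=5))
        b = generate_cohort(SynthConfig(n_patients=60, seed=5))
        assert a.notes == b.notes
        assert a.diagnoses == b.diagnoses
        assert a.encounters == b.encounters
        assert a.truth == b.truth
        c = generate_cohort(SynthConfig(n_patients=60, seed=6))
        assert c.notes != a.notes

    def test_every_patient_satisfies_cohort_criteria(self, small_cohort):
        selected = select_diabetes_cohort(
            small_cohort.encounters, small_cohort.diagnoses, SMALL.window
        )
        assert selected == set(small_cohort.patient_ids)

    def test_tp_plants_only_on_true_cases(self, small_cohort):
        for gt in small_cohort.truth:
            for plant in gt.plants:
                if plant.kind == "true_positive":
                    assert gt.cases[plant.domain]
                if plant.kind == "negation":
                    assert not gt.cases[plant.domain]

    def test_rate_recovery_within_three_se(self):
        """Structured and narrative-detectable prevalence land within 3
        binomial SE of the configured products."""
        config = SynthConfig(
            n_patients=500,
            true_prevalence={d: 0.05 for d in DOMAINS},
            structured_doc_rate=0.1,
            narrative_doc_rate=0.8,
            seed=1,
        )
        cohort = generate_cohort(config)
        n = config.n_patients
        narrative_target = 0.05 * 0.8
        structured_target = 0.05 * 0.1
        from sdohscan.coding import load_default_code_map

        cmap = load_default_code_map()
        z_patients = {d: set() for d in DOMAINS}
        for rec in cohort.diagnoses:
            for domain in DOMAINS:
                if cmap.matches(domain, rec.code):
                    z_patients[domain].add(rec.patient_id)
        for domain in DOMAINS:
            tp_patients = sum(
                any(p.kind == "true_positive" and p.domain == domain for p in gt.plants)
                for gt in cohort.truth
            )
            se = np.sqrt(narrative_target * (1 - narrative_target) / n)
            assert abs(tp_patients / n - narrative_target) <= 3 * se
            se_s = np.sqrt(structured_target * (1 - structured_target) / n)
            assert abs(len(z_patients[domain]) / n - structured_target) <= 3 * se_s

    def test_no_narrative_rate_means_only_planted_noise(self, rules_mod):
        config = SynthConfig(n_patients=150, narrative_doc_rate=0.0, seed=2)
        cohort = generate_cohort(config)
        out = classify_corpus(rules_mod, cohort.notes, patients=cohort.patient_ids)
        planted_fp = {
            (p.note_id, p.domain)
            for gt in cohort.truth
            for p in gt.plants
            if p.kind == "confusable"
        }
        positives = {(m.note_id, m.domain) for m in out.matches if m.positive}
        assert positives == planted_fp


class TestPlantedRecall:
    def test_every_tp_plant_is_detected(self, small_cohort, rules_mod):
        out = classify_corpus(
            rules_mod, small_cohort.notes, patients=small_cohort.patient_ids
        )
        positives = {(m.note_id, m.domain) for m in out.matches if m.positive}
        for unit in true_positive_units(small_cohort.truth):
            assert unit in positives

    def test_negation_plants_are_never_positive(self, small_cohort, rules_mod):
        out = classify_corpus(
            rules_mod, small_cohort.notes, patients=small_cohort.patient_ids
        )
        positives = {(m.note_id, m.domain) for m in out.matches if m.positive}
        for gt in small_cohort.truth:
            for plant in gt.plants:
                if plant.kind == "negation":
                    assert (plant.note_id, plant.domain) not in positives


@pytest.fixture(scope="module")
def flagged(small_cohort, rules_mod):
    out = classify_corpus(
        rules_mod, small_cohort.notes, patients=small_cohort.patient_ids
    )
    return [m for m in out.matches if m.positive]


class TestSimulatedReview:
    def test_zero_error_rate_gives_kappa_one(self, small_cohort, flagged):
        l1, l2 = simulate_review(small_cohort.truth, flagged, 0.0, seed=3)
        v1 = [l.is_confirmed for l in l1]
        v2 = [l.is_confirmed for l in l2]
        stats = cohen_kappa(v1, v2)
        assert not stats.kappa_undefined and stats.kappa == 1.0

    def test_agreement_recovers_error_rate(self, small_cohort, flagged):
        """With flip rate e the expected agreement is (1-e)^2 + e^2."""
        e = 0.02
        agreements = []
        total = 0
        for rep in range(30):
            l1, l2 = simulate_review(small_cohort.truth, flagged, e, seed=100 + rep)
            v1 = [l.is_confirmed for l in l1]
            v2 = [l.is_confirmed for l in l2]
            agreements.append(proportional_agreement(v1, v2) * len(v1))
            total += len(v1)
        expected = (1 - e) ** 2 + e**2
        observed = sum(agreements) / total
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) <= 3 * se

    def test_half_error_rate_gives_zero_kappa(self, small_cohort, flagged):
        """Monte-Carlo: at flip rate 0.5 the reviewers are independent."""
        kappas = []
        for rep in range(60):
            l1, l2 = simulate_review(small_cohort.truth, flagged, 0.5, seed=500 + rep)
            stats = cohen_kappa(
                [l.is_confirmed for l in l1], [l.is_confirmed for l in l2]
            )
            if not stats.kappa_undefined:
                kappas.append(stats.kappa)
        kappas = np.asarray(kappas)
        se = kappas.std(ddof=1) / np.sqrt(len(kappas))
        assert abs(kappas.mean()) <= 3 * se

    def test_deterministic(self, small_cohort, flagged):
        a = simulate_review(small_cohort.truth, flagged, 0.1, seed=7)
        b = simulate_review(small_cohort.truth, flagged, 0.1, seed=7)
        assert a == b
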