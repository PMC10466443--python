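"""Synthetic EHR cohort generator with planted social-risk evidence.

Generates notes, diagnoses and encounters for a configurable cohort in which
every patient satisfies the primary-care diabetes criteria, together with a
ground-truth inventory of what was planted where.  Per domain, a patient is a
true case with the configured prevalence; true cases independently receive a
structured Z code (``structured_doc_rate``) and/or a narrative true-positive
snippet (``narrative_doc_rate``).  Confusable snippets — phrases a rule flags
but a reviewer rejects — and exclusion-protected negation snippets are
planted at their own rates.  Filler text is drawn from a vocabulary disjoint
from every rule term, and each planted snippet is placed in a note of its
own, so planted-evidence properties (recall 1 on plants, exact planted PPV)
hold by construction rather than probabilistically.

The default rates put structured prevalence in the sub-1% range and
narrative-detectable prevalence several-fold higher, emulating the
documentation gap the pipeline is built to measure.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .coding import STUDY_WINDOW, DiagnosisRecord, Encounter, load_default_code_map
from .domains import DOMAINS
from .engine import ClinicalNote, MatchResult
from .query import Conjunction, Disjunction, PhraseQuery, QueryExpr, load_default_rules, rule_vocabulary
from .review import CONFIRMED, NOT_CONFIRMED, ReviewLabel

__all__ = [
    "SynthConfig",
    "PlantedSnippet",
    "GroundTruth",
    "SynthCohort",
    "SnippetBank",
    "snippet_bank",
    "filler_vocabulary",
    "generate_cohort",
    "simulate_review",
    "true_positive_units",
]

#: Published example snippets a rule should flag and a reviewer confirm.
TABLE_TRUE_POSITIVE: dict[str, str] = {
    "social_connections": "Pt has difficulties with her mother and social isolation",
    "employment": "Currently unemployed",
    "housing": "Pt with unstable housing situation, homeless",
    "food": "Diet remains problem with severe food insecurity",
    "education": "Never went to school and cannot read",
    "finance": "Pt has low income subsidy, financial difficulties",
    "stress": "Feeling very stressed",
}

#: Published example snippets a rule flags but a reviewer rejects.
TABLE_FALSE_POSITIVE: dict[str, str] = {
    "social_connections": "She is deeply concerned about her son's social isolation",
    "employment": "Unemployed son",
    "housing": "Volunteers at the animal shelter",
    "food": "Food insecurity: none",
    "education": "Cannot read fine print as well, notes older glasses work better at near",
    "finance": "Withdrawn cognition: poverty of thought",
    "stress": "Wife is stressed or complaining",
}

_DIABETES_CODES = ("E11.9", "E11.65", "E11.8", "E10.9", "E10.65")

_ELIGIBLE_NOTE_TYPES = (
    "progress note",
    "telephone encounter",
    "history and physical",
    "assessment and plan",
)

# Candidate filler words; anything matching a rule term (exactly, or by a
# wildcard stem prefix) is filtered out at build time.
_FILLER_CANDIDATES = (
    "patient clinic visit followup medication insulin metformin glucose "
    "hemoglobin blood pressure stable continues reviewed discussed plan dose "
    "daily morning evening tablet refill pharmacy diabetes mellitus control "
    "improved carbohydrate walking activity weight examination abdomen soft "
    "nontender heart regular rhythm lungs clear auscultation extremities "
    "edema neuro intact alert oriented assessment continue current regimen "
    "recheck weeks months return sooner needed symptoms reports chronic "
    "hypertension lisinopril atorvastatin cholesterol renal function "
    "creatinine within normal limits ordered results pending goals adherence "
    "counseled immunizations influenza vaccine administered screening "
    "retinopathy referral ophthalmology podiatry foot monofilament sensation "
    "pulses palpable skin warm dry mood affect appropriate sleep appetite "
    "energy fatigue mild moderate severe worsening unchanged since last "
    "appointment spoke caller message advised hydration monitor values "
    "fasting postprandial readings logbook brought tolerating denies "
    "medications exercise test"
).split()


@lru_cache(maxsize=1)
def filler_vocabulary() -> tuple[str, ...]:
    """Filler words guaranteed not to match any rule term, so filler text can
    never create or veto a rule hit."""
    patterns = rule_vocabulary()
    safe = tuple(
        w for w in _FILLER_CANDIDATES if not any(p.matches(w) for p in patterns)
    )
    assert len(safe) >= 50, "filler vocabulary unexpectedly small"
    return safe


def _phrase_text(expr: QueryExpr) -> str:
    """Flatten a query entry into text that satisfies it (adjacent terms
    satisfy any slop; for a conjunction, all branches are emitted)."""
    if isinstance(expr, PhraseQuery):
        return " ".join(t.stem for t in expr.terms)
    if isinstance(expr, (Conjunction, Disjunction)):
        return " ".join(_phrase_text(c) for c in expr.children)
    raise TypeError(f"cannot build snippet text for {expr!r}")


@dataclass(frozen=True)
class SnippetBank:
    domain: str
    true_positive: tuple[str, ...]
    confusable: tuple[str, ...]
    negation: tuple[str, ...]


@lru_cache(maxsize=None)
def snippet_bank(domain: str) -> SnippetBank:
    """Snippet templates for one domain: published true/false-positive
    examples plus one synthetic snippet per include entry, and one
    exclusion-protected snippet per NOT-list entry.

    Every true-positive template is checked against the full rule at build
    time and kept only if the rule actually flags it, so planted recall is 1
    by construction.  (One include entry is self-vetoing: once punctuation is
    stripped, the food rule's "Food insecure?" exclusion tokenizes exactly
    like its "food insecure" include phrase, so that phrase alone can never
    fire and yields no template.)
    """
    if domain not in DOMAINS:
        raise KeyError(f"unknown domain: {domain!r}")
    from .engine import ClinicalNote, classify_note  # local: avoid import cycle

    rule = load_default_rules()[domain]

    def detectable(text: str) -> bool:
        probe = ClinicalNote("probe", "probe", "progress note", _dt.date(2018, 1, 1), text)
        return classify_note(rule, probe).positive

    include = rule.include_expr
    entries = include.children if isinstance(include, Disjunction) else (include,)
    true_pos = [TABLE_TRUE_POSITIVE[domain]]
    true_pos.extend(
        text for e in entries if detectable(text := _phrase_text(e))
    )
    negation: list[str] = []
    exclude = rule.exclude_expr
    if exclude is not None:
        exc_entries = (
            exclude.children if isinstance(exclude, Disjunction) else (exclude,)
        )
        negation.extend(_phrase_text(e) for e in exc_entries)
    return SnippetBank(
        domain=domain,
        true_positive=tuple(true_pos),
        confusable=(TABLE_FALSE_POSITIVE[domain],),
        negation=tuple(negation),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; generation is a pure function of this object."""

    n_patients: int = 4283
    notes_per_patient: float = 7.07
    true_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "social_connections": 0.058,
            "employment": 0.058,
            "housing": 0.032,
            "food": 0.030,
            "education": 0.010,
            "finance": 0.033,
            "stress": 0.065,
        }
    )
    structured_doc_rate: float = 0.12
    narrative_doc_rate: float = 0.8
    fp_snippet_rate: float = 0.02
    negation_rate: float = 0.01
    reviewer_error_rate: float = 0.02
    seed: int = 0
    window: tuple[_dt.date, _dt.date] = STUDY_WINDOW

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.notes_per_patient <= 0:
            raise ValueError("notes_per_patient must be positive")
        unknown = set(self.true_prevalence) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains in true_prevalence: {sorted(unknown)}")
        rates = dict(self.true_prevalence)
        rates.update(
            structured_doc_rate=self.structured_doc_rate,
            narrative_doc_rate=self.narrative_doc_rate,
            fp_snippet_rate=self.fp_snippet_rate,
            negation_rate=self.negation_rate,
            reviewer_error_rate=self.reviewer_error_rate,
        )
        for name, value in rates.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.window[0] > self.window[1]:
            raise ValueError("window start must not exceed end")


@dataclass(frozen=True)
class PlantedSnippet:
    domain: str
    kind: str  # "true_positive" | "confusable" | "negation"
    note_id: str
    template: str


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    cases: Mapping[str, bool]  # domain -> true case?
    plants: tuple[PlantedSnippet, ...] = ()


@dataclass
class SynthCohort:
    config: SynthConfig
    notes: list[ClinicalNote]
    diagnoses: list[DiagnosisRecord]
    encounters: list[Encounter]
    truth: list[GroundTruth]

    @property
    def patient_ids(self) -> list[str]:
        return [gt.patient_id for gt in self.truth]


def _rand_date(rng: np.random.Generator, window: tuple[_dt.date, _dt.date]) -> _dt.date:
    span = (window[1] - window[0]).days
    return window[0] + _dt.timedelta(days=int(rng.integers(span + 1)))


def _filler(rng: np.random.Generator, vocab: Sequence[str], n_words: int) -> str:
    idx = rng.integers(len(vocab), size=max(n_words, 1))
    return " ".join(vocab[i] for i in idx)


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate the full synthetic cohort; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    vocab = filler_vocabulary()
    code_map = load_default_code_map()
    banks = {domain: snippet_bank(domain) for domain in DOMAINS}
    domain_codes = {
        domain: tuple(sorted(code_map.stems(domain))) for domain in DOMAINS
    }

    notes: list[ClinicalNote] = []
    diagnoses: list[DiagnosisRecord] = []
    encounters: list[Encounter] = []
    truth: list[GroundTruth] = []
    span_days = (config.window[1] - config.window[0]).days

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        # Cohort criteria hold by construction: >=2 completed primary-care
        # visits on distinct dates plus a dated E10/E11 diagnosis.
        n_visits = 2 + int(rng.poisson(0.8))
        offsets = rng.choice(span_days + 1, size=n_visits, replace=False)
        for off in sorted(int(o) for o in offsets):
            encounters.append(
                Encounter(
                    patient_id=pid,
                    department_class="primary care",
                    date=config.window[0] + _dt.timedelta(days=off),
                    completed=True,
                )
            )
        if rng.random() < 0.25:
            encounters.append(
                Encounter(pid, "specialty", _rand_date(rng, config.window), True)
            )
        if rng.random() < 0.10:
            encounters.append(
                Encounter(pid, "primary care", _rand_date(rng, config.window), False)
            )
        dx_code = _DIABETES_CODES[int(rng.integers(len(_DIABETES_CODES)))]
        diagnoses.append(DiagnosisRecord(pid, dx_code, _rand_date(rng, config.window)))

        patient_notes: list[ClinicalNote] = []
        n_notes = int(rng.poisson(config.notes_per_patient))
        for j in range(n_notes):
            if rng.random() < 0.9:
                note_type = _ELIGIBLE_NOTE_TYPES[int(rng.integers(4))]
            else:
                note_type = "other"
            patient_notes.append(
                ClinicalNote(
                    note_id=f"{pid}-N{j:03d}",
                    patient_id=pid,
                    note_type=note_type,
                    date=_rand_date(rng, config.window),
                    text=_filler(rng, vocab, 5 + int(rng.poisson(35))),
                )
            )

        plants: list[PlantedSnippet] = []

        def plant(domain: str, kind: str, templates: tuple[str, ...]) -> None:
            template = templates[int(rng.integers(len(templates)))]
            note_id = f"{pid}-S{len(plants):02d}"
            text = " ".join(
                (
                    _filler(rng, vocab, 4 + int(rng.poisson(8))),
                    template,
                    _filler(rng, vocab, 4 + int(rng.poisson(8))),
                )
            )
            patient_notes.append(
                ClinicalNote(
                    note_id=note_id,
                    patient_id=pid,
                    note_type=_ELIGIBLE_NOTE_TYPES[int(rng.integers(4))],
                    date=_rand_date(rng, config.window),
                    text=text,
                )
            )
            plants.append(
                PlantedSnippet(domain=domain, kind=kind, note_id=note_id, template=template)
            )

        cases: dict[str, bool] = {}
        for domain in DOMAINS:
            prevalence = config.true_prevalence.get(domain, 0.0)
            is_case = bool(rng.random() < prevalence)
            cases[domain] = is_case
            if is_case and rng.random() < config.structured_doc_rate:
                code = domain_codes[domain][int(rng.integers(len(domain_codes[domain])))]
                diagnoses.append(
                    DiagnosisRecord(pid, code, _rand_date(rng, config.window))
                )
            if is_case and rng.random() < config.narrative_doc_rate:
                plant(domain, "true_positive", banks[domain].true_positive)
            if rng.random() < config.fp_snippet_rate:
                plant(domain, "confusable", banks[domain].confusable)
            if (
                not is_case
                and banks[domain].negation
                and rng.random() < config.negation_rate
            ):
                plant(domain, "negation", banks[domain].negation)

        notes.extend(patient_notes)
        truth.append(GroundTruth(patient_id=pid, cases=cases, plants=tuple(plants)))

    return SynthCohort(
        config=config,
        notes=notes,
        diagnoses=diagnoses,
        encounters=encounters,
        truth=truth,
    )


def true_positive_units(truth: Sequence[GroundTruth]) -> set[tuple[str, str]]:
    """(note_id, domain) pairs carrying a planted true-positive snippet —
    the note-level ground truth the simulated reviewers consult."""
    return {
        (p.note_id, p.domain)
        for gt in truth
        for p in gt.plants
        if p.kind == "true_positive"
    }


def simulate_review(
    truth: Sequence[GroundTruth],
    matches: Sequence[MatchResult],
    reviewer_error_rate: float,
    seed: int,
) -> tuple[list[ReviewLabel], list[ReviewLabel]]:
    """Two simulated reviewers labelling every flagged note.

    Each reviewer reports the note-level ground truth with an independent
    flip probability ``reviewer_error_rate``; deterministic for a fixed seed.
    """
    if not 0 <= reviewer_error_rate <= 1:
        raise ValueError("reviewer_error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tp_units = true_positive_units(truth)
    labels1: list[ReviewLabel] = []
    labels2: list[ReviewLabel] = []
    for m in matches:
        if not m.positive:
            continue
        actual = (m.note_id, m.domain) in tp_units
        for reviewer, out in (("R1", labels1), ("R2", labels2)):
            observed = actual ^ (rng.random() < reviewer_error_rate)
            out.append(
                ReviewLabel(
                    unit_id=m.note_id,
                    domain=m.domain,
                    reviewer_id=reviewer,
                    label=CONFIRMED if observed else NOT_CONFIRMED,
                )
            )
    return labels1, labels2
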