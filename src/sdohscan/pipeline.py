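"""End-to-end study driver: cohort -> both documentation arms -> validation.

Ties the modules together the way the analysis is meant to be run: select the
primary-care diabetes cohort, classify every patient from structured codes
and from narrative rule hits, review-validate the rule hits (simulated
reviewers on synthetic data, label files on real extracts), and emit the
prevalence table, overlap decomposition, per-domain PPV and reviewer
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .coding import (
    classify_patients_structured,
    load_default_code_map,
    select_diabetes_cohort,
)
from .compare import OverlapSummary, PrevalenceRow, overlap_summary, prevalence_table
from .domains import DOMAINS
from .engine import CorpusClassification, MatchResult, classify_corpus
from .query import load_default_rules
from .review import (
    AgreementStats,
    PPVResult,
    ReviewLabel,
    cohen_kappa,
    ppv,
    proportional_agreement,
    sample_for_review,
)
from .synth import SynthCohort, SynthConfig, generate_cohort, simulate_review

__all__ = ["StudyResult", "run_synthetic_study", "confirmed_patient_flags"]


def confirmed_patient_flags(
    matches: Sequence[MatchResult],
    labels: Sequence[ReviewLabel],
    patients: Sequence[str],
    reviewer_id: str | None = None,
    domains: Sequence[str] = DOMAINS,
) -> dict[str, dict[str, bool]]:
    """Patient-level flags restricted to review-confirmed notes: a patient
    counts for a domain when at least one of their flagged notes was
    confirmed by the adjudicating reviewer."""
    verdict: dict[tuple[str, str], bool] = {}
    for label in labels:
        if reviewer_id is not None and label.reviewer_id != reviewer_id:
            continue
        verdict[(label.unit_id, label.domain)] = label.is_confirmed
    flags = {pid: {domain: False for domain in domains} for pid in patients}
    for m in matches:
        if m.positive and verdict.get((m.note_id, m.domain), False):
            if m.patient_id in flags:
                flags[m.patient_id][m.domain] = True
    return flags


@dataclass
class StudyResult:
    cohort: list[str]
    classification: CorpusClassification
    structured_flags: dict[str, dict[str, bool]]
    prevalence: list[PrevalenceRow]
    prevalence_mode: str  # "review_confirmed" | "raw"
    prevalence_raw: list[PrevalenceRow]
    overlaps: list[OverlapSummary]
    ppv_by_domain: dict[str, PPVResult]
    agreement_by_domain: dict[str, AgreementStats] = field(default_factory=dict)
    p_o_by_domain: dict[str, float] = field(default_factory=dict)
    labels: tuple[list[ReviewLabel], list[ReviewLabel]] | None = None


def run_synthetic_study(
    config: SynthConfig,
    review_fraction: float = 0.10,
    cohort: SynthCohort | None = None,
) -> StudyResult:
    """Generate (or reuse) a synthetic cohort and run the whole analysis.

    Reviewer 1 labels every flagged note (the adjudicating pass used for PPV
    and confirmed prevalence); interrater agreement is computed on a
    ``review_fraction`` per-domain sample re-labelled by reviewer 2.
    Derived seeds stay within config.seed + 2.
    """
    if cohort is None:
        cohort = generate_cohort(config)
    rules = load_default_rules()
    code_map = load_default_code_map()

    selected = select_diabetes_cohort(cohort.encounters, cohort.diagnoses, config.window)
    patients = sorted(selected)
    classification = classify_corpus(rules, cohort.notes, patients=patients)
    positives = [m for m in classification.matches if m.positive]

    structured_flags = classify_patients_structured(
        cohort.diagnoses, code_map, patients=patients
    )

    labels1, labels2 = simulate_review(
        cohort.truth, positives, config.reviewer_error_rate, seed=config.seed + 1
    )

    ppv_by_domain: dict[str, PPVResult] = {}
    for domain in DOMAINS:
        flagged = [m for m in positives if m.domain == domain]
        ppv_by_domain[domain] = ppv(flagged, labels1, reviewer_id="R1")

    confirmed_flags = confirmed_patient_flags(
        positives, labels1, patients, reviewer_id="R1"
    )
    raw_flags = classification.flags
    prevalence_confirmed = prevalence_table(
        structured_flags, confirmed_flags, set(patients), domains=DOMAINS
    )
    prevalence_raw = prevalence_table(
        structured_flags, raw_flags, set(patients), domains=DOMAINS
    )

    overlaps = [
        overlap_summary(
            domain,
            classification.positive_patients(domain),
            {pid for pid, f in structured_flags.items() if f[domain]},
        )
        for domain in DOMAINS
    ]

    # Interrater agreement on a per-domain sample re-read by reviewer 2.
    sampled = sample_for_review(positives, review_fraction, seed=config.seed + 2)
    lab1 = {(l.unit_id, l.domain): l.is_confirmed for l in labels1}
    lab2 = {(l.unit_id, l.domain): l.is_confirmed for l in labels2}
    agreement_by_domain: dict[str, AgreementStats] = {}
    p_o_by_domain: dict[str, float] = {}
    for domain in DOMAINS:
        units = [(m.note_id, m.domain) for m in sampled if m.domain == domain]
        if not units:
            continue
        v1 = [lab1[u] for u in units]
        v2 = [lab2[u] for u in units]
        agreement_by_domain[domain] = cohen_kappa(v1, v2)
        p_o_by_domain[domain] = proportional_agreement(v1, v2)

    return StudyResult(
        cohort=patients,
        classification=classification,
        structured_flags=structured_flags,
        prevalence=prevalence_confirmed,
        prevalence_mode="review_confirmed",
        prevalence_raw=prevalence_raw,
        overlaps=overlaps,
        ppv_by_domain=ppv_by_domain,
        agreement_by_domain=agreement_by_domain,
        p_o_by_domain=p_o_by_domain,
        labels=(labels1, labels2),
    )
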