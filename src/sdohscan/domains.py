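"""The seven social-risk domains covered by the shipped rule set.

Each domain pairs a free-text narrative rule (``rules/<domain>.rule``) with a
grouping of ICD-10-CM Z codes (``data/domain_codes.csv``): housing instability,
food insecurity, unemployment, financial strain, low education/illiteracy,
social isolation, and psychosocial stress.
"""

from __future__ import annotations

DOMAINS: tuple[str, ...] = (
    "social_connections",
    "employment",
    "housing",
    "food",
    "education",
    "finance",
    "stress",
)

#: Human-readable labels, mainly for reports.
DOMAIN_LABELS: dict[str, str] = {
    "social_connections": "Social connections/isolation",
    "employment": "Employment",
    "housing": "Housing",
    "food": "Food",
    "education": "Education",
    "finance": "Finance",
    "stress": "Stress",
}

#: Note categories searched by default: the four narrative-rich types kept by
#: the pipeline. Anything else ("other") is ignored unless explicitly enabled.
DEFAULT_ELIGIBLE_NOTE_TYPES: frozenset[str] = frozenset(
    {
        "progress note",
        "telephone encounter",
        "history and physical",
        "assessment and plan",
    }
)

NOTE_TYPES: tuple[str, ...] = (
    "progress note",
    "telephone encounter",
    "history and physical",
    "assessment and plan",
    "other",
)
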