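"""Structured-vs-narrative comparison: prevalence table and overlap split.

The headline output of the pipeline is a per-domain table of patient counts
and percentages documented in structured data (Z codes) versus narrative
notes (rule hits, optionally restricted to review-confirmed patients), plus
the decomposition of rule-positive patients into those with and without a
corresponding structured code.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PrevalenceRow",
    "OverlapSummary",
    "pct",
    "prevalence_table",
    "overlap_summary",
    "prevalence_frame",
]


def pct(n: int, denominator: int) -> float:
    """Percentage rounded to two decimals, half-up (presentation rounding)."""
    if denominator == 0:
        return 0.0
    exact = Decimal(n * 100) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceRow:
    domain: str
    n_structured: int
    pct_structured: float
    n_unstructured: int
    pct_unstructured: float
    cohort_n: int


@dataclass(frozen=True)
class OverlapSummary:
    """Partition of rule-positive patients by structured documentation."""

    domain: str
    n_nlp_positive: int
    n_with_structured_code: int
    n_without_structured_code: int

    def __post_init__(self) -> None:
        if (
            self.n_with_structured_code + self.n_without_structured_code
            != self.n_nlp_positive
        ):
            raise ValueError("overlap partition does not sum to the positive count")


def _positive_set(
    flags: Mapping[str, Mapping[str, bool]], domain: str, cohort: set[str]
) -> set[str]:
    outside = set(flags) - cohort
    if outside:
        raise ValueError(
            f"flags reference {len(outside)} patients outside the cohort, "
            f"e.g. {sorted(outside)[:5]}"
        )
    return {pid for pid, f in flags.items() if f.get(domain, False)}


def prevalence_table(
    structured_flags: Mapping[str, Mapping[str, bool]],
    unstructured_flags: Mapping[str, Mapping[str, bool]],
    cohort: set[str],
    domains: Iterable[str] | None = None,
) -> list[PrevalenceRow]:
    """One row per domain; percentages are over the full cohort size.

    Patients missing from a flag map count as negative; flags for patients
    outside the cohort raise.
    """
    if domains is None:
        seen: list[str] = []
        for f in list(structured_flags.values()) + list(unstructured_flags.values()):
            for domain in f:
                if domain not in seen:
                    seen.append(domain)
        domains = seen
    n = len(cohort)
    rows = []
    for domain in domains:
        n_structured = len(_positive_set(structured_flags, domain, cohort))
        n_unstructured = len(_positive_set(unstructured_flags, domain, cohort))
        rows.append(
            PrevalenceRow(
                domain=domain,
                n_structured=n_structured,
                pct_structured=pct(n_structured, n),
                n_unstructured=n_unstructured,
                pct_unstructured=pct(n_unstructured, n),
                cohort_n=n,
            )
        )
    return rows


def overlap_summary(
    domain: str, nlp_positive: set[str], structured_positive: set[str]
) -> OverlapSummary:
    """Split rule-positive patients by presence of a structured code."""
    overlap = nlp_positive & structured_positive
    return OverlapSummary(
        domain=domain,
        n_nlp_positive=len(nlp_positive),
        n_with_structured_code=len(overlap),
        n_without_structured_code=len(nlp_positive) - len(overlap),
    )


def prevalence_frame(rows: Iterable[PrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])
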