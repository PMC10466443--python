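"""Chart-review validation statistics.

Rule hits are validated by human review: a sample of flagged notes per domain
is re-read, the rule's positive predictive value (PPV) is the confirmed
fraction of flagged units, and two-reviewer reliability is summarized by
observed proportional agreement p_o and Cohen kappa
(kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e taken from the
two reviewers' marginal label rates).  When both reviewers are constant and
identical, p_e = 1 and kappa is reported as undefined rather than a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .engine import MatchResult

__all__ = [
    "ReviewLabel",
    "PPVResult",
    "AgreementStats",
    "sample_for_review",
    "ppv",
    "ppv_from_counts",
    "proportional_agreement",
    "cohen_kappa",
]

CONFIRMED = "confirmed"
NOT_CONFIRMED = "not_confirmed"


@dataclass(frozen=True)
class ReviewLabel:
    unit_id: str  # note id (default review unit) or patient id
    domain: str
    reviewer_id: str
    label: str  # "confirmed" | "not_confirmed"

    def __post_init__(self) -> None:
        if self.label not in (CONFIRMED, NOT_CONFIRMED):
            raise ValueError(f"unknown review label: {self.label!r}")

    @property
    def is_confirmed(self) -> bool:
        return self.label == CONFIRMED


@dataclass(frozen=True)
class PPVResult:
    n_flagged: int
    n_confirmed: int
    ppv: float | None  # None when nothing was flagged
    ci_low: float | None
    ci_high: float | None

    @property
    def undefined(self) -> bool:
        return self.ppv is None

    @property
    def ppv_pct(self) -> float | None:
        return None if self.ppv is None else 100.0 * self.ppv


@dataclass(frozen=True)
class AgreementStats:
    """2x2 concordance of two aligned binary label lists.

    ``a`` both positive, ``b`` reviewer-1-only, ``c`` reviewer-2-only,
    ``d`` both negative.
    """

    n_units: int
    a: int
    b: int
    c: int
    d: int
    p_o: float
    p_e: float
    kappa: float | None
    kappa_undefined: bool


def sample_for_review(
    positives: Sequence[MatchResult], fraction: float, seed: int
) -> list[MatchResult]:
    """Per-domain simple random sample (without replacement) of flagged
    results, of size ceil(fraction * n) per domain; deterministic in seed and
    stable in the input order within each domain."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    by_domain: dict[str, list[int]] = {}
    for i, result in enumerate(positives):
        by_domain.setdefault(result.domain, []).append(i)
    chosen: list[int] = []
    for domain in sorted(by_domain):
        indices = by_domain[domain]
        size = math.ceil(fraction * len(indices))
        picked = rng.choice(len(indices), size=size, replace=False)
        chosen.extend(indices[i] for i in sorted(picked))
    return [positives[i] for i in sorted(chosen)]


def ppv_from_counts(n_confirmed: int, n_flagged: int) -> PPVResult:
    """PPV with a 95% Wilson score interval from raw counts."""
    if n_flagged == 0:
        return PPVResult(0, 0, None, None, None)
    if not 0 <= n_confirmed <= n_flagged:
        raise ValueError("confirmed count must lie in [0, flagged count]")
    low, high = proportion_confint(n_confirmed, n_flagged, alpha=0.05, method="wilson")
    return PPVResult(
        n_flagged=n_flagged,
        n_confirmed=n_confirmed,
        ppv=n_confirmed / n_flagged,
        ci_low=float(low),
        ci_high=float(high),
    )


def ppv(
    flagged: Iterable[MatchResult | str],
    labels: Iterable[ReviewLabel],
    reviewer_id: str | None = None,
) -> PPVResult:
    """PPV of a rule over flagged units given adjudicated labels.

    Every flagged unit must carry a label (from ``reviewer_id`` when given);
    an unlabeled flagged unit raises.
    """
    unit_ids = [
        unit.note_id if isinstance(unit, MatchResult) else unit for unit in flagged
    ]
    verdict: dict[str, bool] = {}
    for label in labels:
        if reviewer_id is not None and label.reviewer_id != reviewer_id:
            continue
        verdict[label.unit_id] = label.is_confirmed
    missing = [uid for uid in unit_ids if uid not in verdict]
    if missing:
        raise ValueError(f"{len(missing)} flagged units lack review labels")
    n_confirmed = sum(verdict[uid] for uid in unit_ids)
    return ppv_from_counts(n_confirmed, len(unit_ids))


def _as_bools(labels: Sequence) -> list[bool]:
    out = []
    for item in labels:
        if isinstance(item, ReviewLabel):
            out.append(item.is_confirmed)
        elif isinstance(item, str):
            if item not in (CONFIRMED, NOT_CONFIRMED):
                raise ValueError(f"unknown review label: {item!r}")
            out.append(item == CONFIRMED)
        else:
            out.append(bool(item))
    return out


def proportional_agreement(l1: Sequence, l2: Sequence) -> float:
    """Fraction of aligned units receiving identical labels."""
    b1, b2 = _as_bools(l1), _as_bools(l2)
    if len(b1) != len(b2):
        raise ValueError("label lists differ in length")
    if not b1:
        raise ValueError("label lists are empty")
    return sum(x == y for x, y in zip(b1, b2)) / len(b1)


def cohen_kappa(l1: Sequence, l2: Sequence) -> AgreementStats:
    """Chance-corrected agreement of two aligned binary label lists.

    With both reviewers constant and equal the chance agreement p_e is
    exactly 1 and kappa is flagged undefined (p_o = 1 in that case).
    """
    b1, b2 = _as_bools(l1), _as_bools(l2)
    if len(b1) != len(b2):
        raise ValueError("label lists differ in length")
    if not b1:
        raise ValueError("label lists are empty")
    n = len(b1)
    a = sum(x and y for x, y in zip(b1, b2))
    b = sum(x and not y for x, y in zip(b1, b2))
    c = sum((not x) and y for x, y in zip(b1, b2))
    d = n - a - b - c
    p_o = (a + d) / n
    p1, p2 = (a + b) / n, (a + c) / n
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    # p_e hits 1 exactly iff both reviewers are constant and identical
    degenerate = a == n or d == n
    kappa = None if degenerate else (p_o - p_e) / (1 - p_e)
    return AgreementStats(
        n_units=n,
        a=a,
        b=b,
        c=c,
        d=d,
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        kappa_undefined=degenerate,
    )
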