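"""Per-record conformance counts and batch-level scores.

The integrity assessment counts, for each record i, the number X_i of
mandatory items left blank; the coding assessment counts the number Y_i of
coded items that do not conform with their code range. Batch scores are

    S_i = (1 - sum(X_i) / (n * k_integrity)) * 100
    S_c = (1 - sum(Y_i) / (n * k_coding))   * 100
    S_t = w1 * S_i + w2 * S_c              (default weights 0.5 / 0.5)

carried internally in exact rational arithmetic and rounded half-up to whole
points only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import TYPE_CHECKING, Iterable, Sequence

from .model import (
    MISSING,
    CodingRule,
    MandatoryItemRule,
    OutpatientRecord,
    Requirement,
    get_field,
)

if TYPE_CHECKING:  # pragma: no cover
    from .registry import CodeSetRegistry


class EmptyBatchError(ValueError):
    """Raised for an empty batch: the batch scores divide by n."""


@dataclass
class RecordAssessment:
    """Per-record assessment outcome.

    ``mandatory_flags`` and ``coding_flags`` align positionally with the
    active configuration's rule lists; True means satisfied/compliant.
    ``star_level`` is filled by the star-rating stage (None until then).
    """

    record_id: str | None
    missing_count: int  # X_i
    noncompliant_count: int  # Y_i
    mandatory_flags: tuple[bool, ...]
    coding_flags: tuple[bool, ...]
    star_level: int | None = None


@dataclass
class BatchAssessment:
    """Batch-level scores and star distribution."""

    n: int
    k_integrity: int
    k_coding: int
    integrity_score: float  # S_i, 0-100
    coding_score: float  # S_c, 0-100
    total_score: float  # S_t, 0-100 (full precision)
    star_counts: dict[int, int] = field(default_factory=dict)
    batch_star: int | None = None


def assess_mandatory(
    record: OutpatientRecord, rules: Sequence[MandatoryItemRule]
) -> tuple[int, tuple[bool, ...]]:
    """Evaluate the mandatory-item rules on one record.

    Returns ``(X_i, flags)`` where flags[j] is True iff rule j is satisfied:
    a NON_BLANK scalar is non-missing, an AT_LEAST_ONE list is non-empty.
    """
    if not rules:
        raise ValueError("mandatory rule list must be non-empty")
    flags = []
    for rule in rules:
        value = get_field(record, rule.field_path)
        if rule.requirement is Requirement.AT_LEAST_ONE:
            flags.append(len(value) > 0)
        else:
            flags.append(value is not MISSING)
    flags_t = tuple(flags)
    return flags_t.count(False), flags_t


def assess_coding(
    record: OutpatientRecord,
    rules: Sequence[CodingRule],
    registry: "CodeSetRegistry",
) -> tuple[int, tuple[bool, ...]]:
    """Evaluate the code-range rules on one record.

    An item with codes present is compliant iff every code is a member of
    the bound code set. An item with no code is noncompliant when the rule
    requires presence (strict), compliant otherwise (checked-if-present).
    Returns ``(Y_i, flags)``.
    """
    if not rules:
        raise ValueError("coding rule list must be non-empty")
    flags = []
    for rule in rules:
        codeset = registry[rule.codeset_id]
        value = get_field(record, rule.field_path)
        codes = value if isinstance(value, list) else ([] if value is MISSING else [value])
        if not codes:
            flags.append(not rule.require_present)
        else:
            flags.append(all(code in codeset for code in codes))
    flags_t = tuple(flags)
    return flags_t.count(False), flags_t


def _batch_score(counts: Iterable[int], k: int, what: str) -> float:
    counts = list(counts)
    n = len(counts)
    if n == 0:
        raise EmptyBatchError(f"cannot compute the {what} score of an empty batch")
    if k < 1:
        raise ValueError("k must be >= 1")
    total = 0
    for c in counts:
        if not 0 <= c <= k:
            raise ValueError(f"per-record count {c} outside [0, {k}]")
        total += c
    return float((1 - Fraction(total, n * k)) * 100)


def integrity_score(missing_counts: Iterable[int], k_integrity: int) -> float:
    """Batch integrity score S_i from per-record missing counts X_i."""
    return _batch_score(missing_counts, k_integrity, "integrity")


def coding_score(noncompliant_counts: Iterable[int], k_coding: int) -> float:
    """Batch coding-standard score S_c from per-record counts Y_i."""
    return _batch_score(noncompliant_counts, k_coding, "coding")


def total_score(
    integrity: float, coding: float, weights: tuple[float, float] = (0.5, 0.5)
) -> float:
    """Weighted total score S_t = w1*S_i + w2*S_c, full precision."""
    if not (0 <= integrity <= 100 and 0 <= coding <= 100):
        raise ValueError("component scores must lie in [0, 100]")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return weights[0] * integrity + weights[1] * coding


def display_score(score: float) -> int:
    """Round a score half-up to whole points for display (80.5 -> 81)."""
    return int(Decimal(repr(score)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
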