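"""Star rating of records against a cumulative ordered standard scheme.

Each record is graded 0-5 stars: level L requires the first ``threshold(L)``
standards of the scheme to hold simultaneously (defaults 5/7/9/11/14 out of
14 standards). A record failing the one-star prefix is zero-star. The batch
star level is a reconstruction — the count-weighted mean of record star
levels, rounded half-up — reported alongside the full distribution.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

from .model import RuleConfig, StarScheme, StarStandard  # noqa: F401  (re-export)
from .scoring import EmptyBatchError, RecordAssessment

#: Cumulative prefix lengths of the default 14-standard scheme.
DEFAULT_THRESHOLDS = {1: 5, 2: 7, 3: 9, 4: 11, 5: 14}


def evaluate_standards(
    assessment: RecordAssessment, scheme: StarScheme, config: RuleConfig
) -> tuple[bool, ...]:
    """Evaluate every scheme standard on one record's assessment flags.

    Standard j holds iff all of its referenced mandatory items are satisfied
    and all of its referenced coding items are compliant. Pure function of
    the flags; the assessment must come from the same configuration.
    """
    results = []
    for standard in scheme.standards:
        ok = all(
            assessment.mandatory_flags[config.mandatory_index(item)]
            for item in standard.mandatory_items
        ) and all(
            assessment.coding_flags[config.coding_index(item)]
            for item in standard.coding_items
        )
        results.append(ok)
    return tuple(results)


def star_level(standard_bools: Sequence[bool], scheme: StarScheme) -> int:
    """Largest level whose threshold-length prefix of standards all hold.

    0 if the one-star prefix is not fully satisfied; a false standard inside
    a prefix blocks that level regardless of later standards.
    """
    if len(standard_bools) != len(scheme.standards):
        raise ValueError(
            f"expected {len(scheme.standards)} standard outcomes, "
            f"got {len(standard_bools)}"
        )
    level = 0
    for lvl in range(1, scheme.max_level + 1):
        prefix = scheme.thresholds[lvl]
        if all(standard_bools[:prefix]):
            level = lvl
        else:
            break
    return level


def rate_record(
    assessment: RecordAssessment, scheme: StarScheme, config: RuleConfig
) -> int:
    """Evaluate the scheme and store the star level on the assessment."""
    level = star_level(evaluate_standards(assessment, scheme, config), scheme)
    assessment.star_level = level
    return level


def batch_star(star_counts: Mapping[int, int]) -> int:
    """Overall star level of an upload batch.

    Reconstruction: the count-weighted mean record star level, rounded
    half-up to an integer level. Always report the full distribution next
    to this single figure.
    """
    n = sum(star_counts.values())
    if n < 1:
        raise EmptyBatchError("cannot star-rate an empty batch")
    if any(c < 0 for c in star_counts.values()):
        raise ValueError("star counts must be non-negative")
    mean = Fraction(sum(level * count for level, count in star_counts.items()), n)
    as_decimal = Decimal(mean.numerator) / Decimal(mean.denominator)
    return int(as_decimal.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
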