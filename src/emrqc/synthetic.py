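"""Synthetic outpatient-record batches with exact known ground truth.

Records are constructed backwards from a target star level: every rule
referenced by the standards inside the target level's prefix is satisfied
("pinned"), and for targets below the top level one rule of the next
standard is deliberately violated. Rules outside the pinned prefix and the
violation point may be corrupted at configurable rates (missing items,
out-of-range codes), so batch scores vary while star levels stay exact.

The generator keeps its own field-level bookkeeping of what it corrupted
and derives the expected per-record assessment from that bookkeeping alone;
re-running the real assessment pipeline on the generated records must
reproduce it exactly (the package's primary end-to-end check).

All content comes from synthetic fixture vocabularies; no real patient data
and no official standard codes are used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

from .model import (
    CodingRule,
    MandatoryItemRule,
    OutpatientRecord,
    RuleConfig,
    StarStandard,
    is_list_path,
)
from .registry import CodeSetRegistry, default_rule_config, fixture_codeset_registry
from .scoring import (
    BatchAssessment,
    RecordAssessment,
    coding_score,
    integrity_score,
    total_score,
)
from .star import batch_star


class GenerationError(ValueError):
    """The requested ground truth is unreachable under the configuration."""


@dataclass
class BatchSpec:
    """Specification of a synthetic batch.

    ``star_counts`` gives the exact number of records per target star level;
    ``missingness`` and ``invalid_code_rate`` corrupt only star-irrelevant
    items, so the realized star distribution equals ``star_counts`` exactly
    while the integrity/coding scores vary.
    """

    star_counts: dict[int, int]
    missingness: float = 0.0
    invalid_code_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.star_counts or sum(self.star_counts.values()) < 1:
            raise ValueError("star_counts must have a positive total")
        if any(c < 0 for c in self.star_counts.values()):
            raise ValueError("star counts must be non-negative")
        if any(level < 0 for level in self.star_counts):
            raise ValueError("star levels must be >= 0")
        for rate in (self.missingness, self.invalid_code_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n(self) -> int:
        return sum(self.star_counts.values())


@dataclass
class GeneratedBatch:
    """A synthetic batch together with its expected assessment."""

    records: list[OutpatientRecord]
    assessments: list[RecordAssessment]  # expected, from generator bookkeeping
    expected: BatchAssessment


# Synthetic term vocabularies for non-coded items (invented fixtures).
_TERM_VOCAB = {
    "four_diagnosis": (
        "pale tongue with thin white coating",
        "wiry pulse",
        "dark complexion",
        "weak voice on inquiry",
        "tenderness on palpation",
    ),
    "tcm_symptoms": ("cough", "night sweats", "dizziness", "fatigue", "insomnia"),
    "syndrome_types": (
        "qi deficiency",
        "blood stasis",
        "damp heat",
        "yin deficiency",
    ),
    "treatments": (
        "tonify qi",
        "invigorate blood",
        "clear heat and drain damp",
        "nourish yin",
    ),
}
_PATHOLOGICAL = ("cold", "heat", "deficiency", "excess")
_DIAGNOSES = ("lung distension", "wasting thirst", "headache", "stomach ache")
_LOCATIONS = ("Chengdu", "Mianyang", "Leshan", "Deyang")


@dataclass
class _FieldState:
    present: bool = True
    valid: bool = True  # meaningful only for code-bearing fields


def _rules_by_field(config: RuleConfig):
    mandatory: dict[str, list[MandatoryItemRule]] = {}
    coding: dict[str, list[CodingRule]] = {}
    for rule in config.mandatory_rules:
        mandatory.setdefault(rule.field_path, []).append(rule)
    for rule in config.coding_rules:
        coding.setdefault(rule.field_path, []).append(rule)
    return mandatory, coding


def _standard_fields(standard: StarStandard, config: RuleConfig) -> set[str]:
    fields = set()
    for item in standard.mandatory_items:
        fields.add(config.mandatory_rules[config.mandatory_index(item)].field_path)
    for item in standard.coding_items:
        fields.add(config.coding_rules[config.coding_index(item)].field_path)
    return fields


def generate_record(
    target_star: int,
    config: RuleConfig | None = None,
    registry: CodeSetRegistry | None = None,
    rng: random.Random | None = None,
    missingness: float = 0.0,
    invalid_code_rate: float = 0.0,
    record_id: str = "R00001",
) -> tuple[OutpatientRecord, RecordAssessment]:
    """Generate one record whose star level is exactly ``target_star``.

    Returns the record and the expected assessment derived from the
    generator's own bookkeeping. For a target below the top level, one rule
    of the first standard beyond the target's prefix is deliberately
    violated, so the star level cannot exceed the target.
    """
    config = config or default_rule_config()
    registry = registry or fixture_codeset_registry()
    registry.validate_config(config)
    rng = rng or random.Random(0)
    scheme = config.star_scheme
    if not 0 <= target_star <= scheme.max_level:
        raise GenerationError(f"target star {target_star} outside 0..{scheme.max_level}")

    prefix_len = scheme.thresholds.get(target_star, 0)
    pinned_standards = scheme.standards[:prefix_len]
    violated = (
        scheme.standards[prefix_len] if target_star < scheme.max_level else None
    )

    mandatory_by_field, coding_by_field = _rules_by_field(config)
    all_fields = sorted(set(mandatory_by_field) | set(coding_by_field))
    states = {f: _FieldState() for f in all_fields}

    pinned_mandatory: set[str] = set()
    pinned_coding: set[str] = set()
    for standard in pinned_standards:
        pinned_mandatory.update(standard.mandatory_items)
        pinned_coding.update(standard.coding_items)
    pinned_fields = {
        config.mandatory_rules[config.mandatory_index(i)].field_path
        for i in pinned_mandatory
    } | {
        config.coding_rules[config.coding_index(i)].field_path for i in pinned_coding
    }

    violated_fields: set[str] = set()
    if violated is not None:
        violated_fields = _standard_fields(violated, config)
        _apply_violation(violated, config, states, pinned_fields, rng)

    # Star-irrelevant corruption outside the pinned prefix and the violation
    # point. A field may be dropped only if no pinned rule references it; a
    # present code field may be invalidated as long as none of its coding
    # rules is pinned (presence alone satisfies a pinned mandatory rule).
    pinned_coding_fields = {
        config.coding_rules[config.coding_index(i)].field_path for i in pinned_coding
    }
    for f in all_fields:
        if f in violated_fields:
            continue
        if f not in pinned_fields and rng.random() < missingness:
            states[f].present = False
            continue
        if (
            f in coding_by_field
            and states[f].present
            and f not in pinned_coding_fields
            and rng.random() < invalid_code_rate
        ):
            states[f].valid = False

    record = _materialize(record_id, states, coding_by_field, registry, rng)
    assessment = _expected_assessment(record_id, states, config, target_star)
    return record, assessment


def _apply_violation(
    violated: StarStandard,
    config: RuleConfig,
    states: dict[str, _FieldState],
    pinned_fields: set[str],
    rng: random.Random,
) -> None:
    """Break exactly one rule of the violated standard without touching
    pinned fields."""
    candidates: list[tuple[str, str]] = []  # (mode, field)
    for item in violated.mandatory_items:
        f = config.mandatory_rules[config.mandatory_index(item)].field_path
        if f not in pinned_fields:
            candidates.append(("drop", f))
    for item in violated.coding_items:
        f = config.coding_rules[config.coding_index(item)].field_path
        if f not in pinned_fields:
            candidates.append(("invalidate", f))
    if not candidates:
        raise GenerationError(
            f"standard {violated.name!r} shares every field with the pinned "
            "prefix; the target star level is unreachable"
        )
    mode, f = candidates[rng.randrange(len(candidates))]
    if mode == "drop":
        states[f].present = False
    else:
        states[f].valid = False


def _valid_code_pool(
    field_path: str, coding_by_field, registry: CodeSetRegistry
) -> list[str]:
    pools = [
        registry[rule.codeset_id].codes for rule in coding_by_field[field_path]
    ]
    common = frozenset.intersection(*pools)
    if not common:
        raise GenerationError(
            f"no code satisfies every code set bound to field {field_path!r}"
        )
    return sorted(common)


def _invalid_code(field_path: str, coding_by_field, registry, rng) -> str:
    taken = set()
    for rule in coding_by_field[field_path]:
        taken |= registry[rule.codeset_id].codes
    code = f"INVALID-{rng.randrange(10_000):04d}"
    while code in taken:  # fixture sets never contain these, but stay safe
        code += "!"
    return code


def _materialize(
    record_id: str,
    states: Mapping[str, _FieldState],
    coding_by_field,
    registry: CodeSetRegistry,
    rng: random.Random,
) -> OutpatientRecord:
    record = OutpatientRecord(record_id=record_id)
    for f in sorted(states):
        state = states[f]
        if not state.present:
            continue
        if f in coding_by_field:
            pool = _valid_code_pool(f, coding_by_field, registry)
            codes = [rng.choice(pool)]
            if is_list_path(f) and rng.random() < 0.5:
                codes.append(rng.choice(pool))
            if not state.valid:
                codes[rng.randrange(len(codes))] = _invalid_code(
                    f, coding_by_field, registry, rng
                )
            value = codes if is_list_path(f) else codes[0]
        else:
            value = _fill_plain(f, rng)
        _set_field(record, f, value)
    return record


def _fill_plain(field_path: str, rng: random.Random):
    if field_path in _TERM_VOCAB:
        vocab = _TERM_VOCAB[field_path]
        count = rng.randint(1, min(3, len(vocab)))
        return list(rng.sample(vocab, count))
    if field_path == "age":
        return rng.randint(0, 99)
    if field_path == "location":
        return rng.choice(_LOCATIONS)
    if field_path == "pathological_nature":
        return rng.choice(_PATHOLOGICAL)
    if field_path == "tcm_diagnosis":
        return rng.choice(_DIAGNOSES)
    if field_path == "name":
        return f"Patient {rng.randrange(100_000):05d}"
    if field_path == "id_number":
        return "".join(str(rng.randrange(10)) for _ in range(18))
    if field_path == "dominant_disease_flag":
        return rng.choice(("yes", "no"))
    if is_list_path(field_path):
        return [f"{field_path} entry {rng.randrange(100)}"]
    return f"{field_path} value {rng.randrange(100)}"


def _set_field(record: OutpatientRecord, path: str, value) -> None:
    if path.startswith("admin_codes."):
        record.admin_codes[path.split(".", 1)[1]] = value
    else:
        setattr(record, path, value)


def _expected_assessment(
    record_id: str,
    states: Mapping[str, _FieldState],
    config: RuleConfig,
    target_star: int,
) -> RecordAssessment:
    """Expected flags derived purely from the generator's field bookkeeping."""
    mandatory_flags = tuple(
        states[rule.field_path].present for rule in config.mandatory_rules
    )
    coding_flags = []
    for rule in config.coding_rules:
        state = states[rule.field_path]
        if not state.present:
            coding_flags.append(not rule.require_present)
        else:
            coding_flags.append(state.valid)
    coding_flags = tuple(coding_flags)
    return RecordAssessment(
        record_id=record_id,
        missing_count=mandatory_flags.count(False),
        noncompliant_count=coding_flags.count(False),
        mandatory_flags=mandatory_flags,
        coding_flags=coding_flags,
        star_level=target_star,
    )


def generate_batch(
    spec: BatchSpec,
    config: RuleConfig | None = None,
    registry: CodeSetRegistry | None = None,
) -> GeneratedBatch:
    """Generate a batch matching a :class:`BatchSpec` exactly.

    Reproducible for a fixed seed. The expected batch assessment is computed
    from the generated ground-truth missing/noncompliant counts through the
    batch score formulas; expected star counts equal the spec counts.
    """
    config = config or default_rule_config()
    registry = registry or fixture_codeset_registry()
    rng = random.Random(spec.seed)
    targets = [
        level for level in sorted(spec.star_counts) for _ in range(spec.star_counts[level])
    ]
    rng.shuffle(targets)
    records, assessments = [], []
    for i, target in enumerate(targets, 1):
        record, assessment = generate_record(
            target,
            config=config,
            registry=registry,
            rng=rng,
            missingness=spec.missingness,
            invalid_code_rate=spec.invalid_code_rate,
            record_id=f"R{i:06d}",
        )
        records.append(record)
        assessments.append(assessment)
    si = integrity_score([a.missing_count for a in assessments], config.k_integrity)
    sc = coding_score([a.noncompliant_count for a in assessments], config.k_coding)
    counts = {level: 0 for level in range(config.star_scheme.max_level + 1)}
    for level in targets:
        counts[level] += 1
    expected = BatchAssessment(
        n=len(records),
        k_integrity=config.k_integrity,
        k_coding=config.k_coding,
        integrity_score=si,
        coding_score=sc,
        total_score=total_score(si, sc, config.weights),
        star_counts=counts,
        batch_star=batch_star(counts),
    )
    return GeneratedBatch(records=records, assessments=assessments, expected=expected)
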