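"""Data model for TCM outpatient EMR conformance testing.

Defines the structured outpatient record, the rule vocabulary (mandatory-item
rules, coding rules, code sets, the star scheme) and the normalization applied
to raw field values on ingest.

Missingness convention: a value that is absent, empty, or whitespace-only is
canonically missing and represented as ``None``. List-valued items never
contain missing entries; an empty list means the item is missing.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

#: Canonical representation of a missing value.
MISSING = None

#: Default delimiter joining multi-valued items in flat (CSV) storage.
DEFAULT_DELIMITER = "|"


def normalize_value(raw: Any) -> str | None:
    """Normalize one raw scalar value.

    Strips surrounding whitespace; absent (``None``), empty, and
    whitespace-only inputs all normalize to ``None`` (missing).
    Idempotent: ``normalize_value(normalize_value(x)) == normalize_value(x)``.
    """
    if raw is None:
        return MISSING
    text = str(raw).strip()
    return text if text else MISSING


def normalize_list(raw: Any, delimiter: str = DEFAULT_DELIMITER) -> list[str]:
    """Normalize a multi-valued item to a list of non-missing entries.

    Accepts a delimited string, an iterable of raw values, or ``None``.
    Blank entries are dropped; an empty result means the item is missing.
    """
    if raw is None:
        return []
    if isinstance(raw, str):
        parts: Iterable[Any] = raw.split(delimiter)
    elif isinstance(raw, Iterable):
        parts = raw
    else:
        parts = [raw]
    out = []
    for part in parts:
        value = normalize_value(part)
        if value is not MISSING:
            out.append(value)
    return out


#: Administrative coded items carried in ``OutpatientRecord.admin_codes``.
#: These come from the health-industry value-set standard (WS 445.11-2014)
#: and are not themselves mandatory record content.
ADMIN_ITEMS = (
    "ethnicity",
    "medical_insurance_type",
    "disease_severity",
    "id_type",
    "diagnosis_type",
    "payment_method",
    "nationality",
)


@dataclass
class OutpatientRecord:
    """One outpatient encounter's structured fields.

    Scalar text fields hold normalized text or ``None`` (missing); list
    fields hold normalized non-empty entries ([] = missing). ``age`` is a
    non-negative integer or ``None``.
    """

    record_id: str | None = MISSING
    location: str | None = MISSING
    pathological_nature: str | None = MISSING
    four_diagnosis: list[str] = field(default_factory=list)
    tcm_symptoms: list[str] = field(default_factory=list)
    tcm_symptom_codes: list[str] = field(default_factory=list)
    tcm_diagnosis: str | None = MISSING
    syndrome_types: list[str] = field(default_factory=list)
    syndrome_type_codes: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)
    treatment_codes: list[str] = field(default_factory=list)
    name: str | None = MISSING
    id_number: str | None = MISSING
    age: int | None = MISSING
    gender_code: str | None = MISSING
    dominant_disease_flag: str | None = MISSING
    dominant_disease_codes: list[str] = field(default_factory=list)
    admin_codes: dict[str, str] = field(default_factory=dict)


#: Record fields that hold lists of values.
LIST_FIELDS = frozenset(
    {
        "four_diagnosis",
        "tcm_symptoms",
        "tcm_symptom_codes",
        "syndrome_type_codes",
        "syndrome_types",
        "treatments",
        "treatment_codes",
        "dominant_disease_codes",
    }
)

#: Scalar record fields (normalized text, or int for age).
SCALAR_FIELDS = frozenset(
    {
        "record_id",
        "location",
        "pathological_nature",
        "tcm_diagnosis",
        "name",
        "id_number",
        "age",
        "gender_code",
        "dominant_disease_flag",
    }
)


class FieldPathError(KeyError):
    """A rule references a field path that does not exist on the record type."""


def get_field(record: OutpatientRecord, path: str) -> Any:
    """Resolve a field path on a record.

    Plain attribute names resolve directly; ``admin_codes.<item>`` resolves
    into the administrative code map (missing keys yield ``None``).
    """
    if path.startswith("admin_codes."):
        item = path.split(".", 1)[1]
        if item not in ADMIN_ITEMS:
            raise FieldPathError(f"unknown administrative item {item!r}")
        return record.admin_codes.get(item, MISSING)
    if path in LIST_FIELDS or path in SCALAR_FIELDS:
        return getattr(record, path)
    raise FieldPathError(f"unknown record field {path!r}")


def is_list_path(path: str) -> bool:
    return path in LIST_FIELDS


class Requirement(enum.Enum):
    """Mandatory-item requirement kinds."""

    NON_BLANK = "non_blank"  # scalar field must be non-missing
    AT_LEAST_ONE = "at_least_one"  # list field must be non-empty


@dataclass(frozen=True)
class MandatoryItemRule:
    """One mandatory-item (integrity) rule: a named field must be filled."""

    item_name: str
    field_path: str
    requirement: Requirement

    def __post_init__(self) -> None:
        if self.requirement is Requirement.NON_BLANK and is_list_path(self.field_path):
            raise ValueError(
                f"rule {self.item_name!r}: NON_BLANK applies only to scalar fields"
            )
        if self.requirement is Requirement.AT_LEAST_ONE and not is_list_path(
            self.field_path
        ):
            raise ValueError(
                f"rule {self.item_name!r}: AT_LEAST_ONE applies only to list fields"
            )


@dataclass(frozen=True)
class CodingRule:
    """One code-range (coding) rule: codes in a field must belong to a code set.

    ``require_present`` controls how a missing code is judged: strict rules
    (items that are also mandatory record content) count a missing code as
    noncompliant; lenient rules (administrative value sets) are checked only
    when a value is supplied.
    """

    item_name: str
    field_path: str
    codeset_id: str
    standard_source: str = ""
    require_present: bool = True


@dataclass
class CodeSet:
    """A named set of valid codes standing in for one standard's code range.

    Codes are compared by exact, case-sensitive string equality after
    whitespace normalization.
    """

    codeset_id: str
    entries: dict[str, str]  # code -> display term ("" if none given)
    source_label: str = ""

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for code, term in self.entries.items():
            ncode = normalize_value(code)
            if ncode is MISSING:
                continue
            normalized[ncode] = normalize_value(term) or ""
        if not normalized:
            raise ValueError(f"code set {self.codeset_id!r}: a code range cannot be empty")
        self.entries = normalized

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class StarStandard:
    """One star-rating standard: a conjunction of named rule flags.

    The standard holds iff every referenced mandatory item is satisfied and
    every referenced coding item is compliant.
    """

    name: str
    mandatory_items: tuple[str, ...] = ()
    coding_items: tuple[str, ...] = ()


@dataclass
class StarScheme:
    """Ordered star-rating standards with cumulative prefix thresholds.

    ``thresholds[L]`` is the number of leading standards that must all hold
    for a record to earn at least L stars. Thresholds are strictly increasing
    and the top level's threshold equals the number of standards.
    """

    standards: tuple[StarStandard, ...]
    thresholds: dict[int, int]

    def __post_init__(self) -> None:
        self.standards = tuple(self.standards)
        levels = sorted(self.thresholds)
        if not levels or levels != list(range(1, levels[-1] + 1)):
            raise ValueError("star thresholds must cover consecutive levels 1..L")
        prev = 0
        for level in levels:
            t = self.thresholds[level]
            if t <= prev:
                raise ValueError("star thresholds must be strictly increasing")
            prev = t
        if prev != len(self.standards):
            raise ValueError(
                "top star threshold must equal the number of standards "
                f"({prev} != {len(self.standards)})"
            )

    @property
    def max_level(self) -> int:
        return max(self.thresholds)


@dataclass
class RuleConfig:
    """The full assessment configuration.

    Ordered mandatory rules (integrity), ordered coding rules, the star
    scheme, and the weight pair combining the integrity and coding scores
    into the total score.
    """

    mandatory_rules: tuple[MandatoryItemRule, ...]
    coding_rules: tuple[CodingRule, ...]
    star_scheme: StarScheme
    weights: tuple[float, float] = (0.5, 0.5)
    delimiter: str = DEFAULT_DELIMITER

    def __post_init__(self) -> None:
        self.mandatory_rules = tuple(self.mandatory_rules)
        self.coding_rules = tuple(self.coding_rules)
        if not self.mandatory_rules:
            raise ValueError("at least one mandatory rule is required")
        if not self.coding_rules:
            raise ValueError("at least one coding rule is required")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights}")
        for rules, label in (
            (self.mandatory_rules, "mandatory"),
            (self.coding_rules, "coding"),
        ):
            names = [r.item_name for r in rules]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {label} rule item names")
        self._mandatory_index = {
            r.item_name: i for i, r in enumerate(self.mandatory_rules)
        }
        self._coding_index = {r.item_name: i for i, r in enumerate(self.coding_rules)}
        self._check_scheme()

    def _check_scheme(self) -> None:
        for standard in self.star_scheme.standards:
            for item in standard.mandatory_items:
                if item not in self._mandatory_index:
                    raise ValueError(
                        f"star standard {standard.name!r} references unknown "
                        f"mandatory item {item!r}"
                    )
            for item in standard.coding_items:
                if item not in self._coding_index:
                    raise ValueError(
                        f"star standard {standard.name!r} references unknown "
                        f"coding item {item!r}"
                    )

    @property
    def k_integrity(self) -> int:
        return len(self.mandatory_rules)

    @property
    def k_coding(self) -> int:
        return len(self.coding_rules)

    def mandatory_index(self, item_name: str) -> int:
        return self._mandatory_index[item_name]

    def coding_index(self, item_name: str) -> int:
        return self._coding_index[item_name]


@dataclass
class ParseWarning:
    """A non-fatal issue encountered while ingesting one raw record."""

    record_id: str | None
    message: str


# ---------------------------------------------------------------------------
# Raw-field ingest

#: Default mapping of flat source column names to record field paths.
DEFAULT_FIELD_MAPPING: dict[str, str] = {
    "record_id": "record_id",
    "location": "location",
    "pathological_nature": "pathological_nature",
    "four_diagnosis": "four_diagnosis",
    "tcm_symptoms": "tcm_symptoms",
    "tcm_symptom_codes": "tcm_symptom_codes",
    "tcm_diagnosis": "tcm_diagnosis",
    "syndrome_types": "syndrome_types",
    "syndrome_type_codes": "syndrome_type_codes",
    "treatments": "treatments",
    "treatment_codes": "treatment_codes",
    "name": "name",
    "id_number": "id_number",
    "age": "age",
    "gender_code": "gender_code",
    "dominant_disease_flag": "dominant_disease_flag",
    "dominant_disease_codes": "dominant_disease_codes",
    **{f"{item}_code": f"admin_codes.{item}" for item in ADMIN_ITEMS},
}


def parse_record(
    raw_fields: Mapping[str, Any],
    field_mapping: Mapping[str, str] | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> tuple[OutpatientRecord, list[ParseWarning]]:
    """Build a normalized record from raw named values.

    ``field_mapping`` binds source names to record field paths; unmapped
    source names are ignored. Multi-valued cells are split on ``delimiter``
    with blank entries dropped. A malformed age (non-integer or negative)
    leaves the field missing and records a parse warning.
    """
    mapping = DEFAULT_FIELD_MAPPING if field_mapping is None else field_mapping
    record = OutpatientRecord()
    warnings: list[ParseWarning] = []
    # JSON-object inputs may carry the administrative codes as a nested map
    raw_admin = raw_fields.get("admin_codes")
    if isinstance(raw_admin, Mapping):
        for item, raw in raw_admin.items():
            value = normalize_value(raw)
            if item in ADMIN_ITEMS and value is not MISSING:
                record.admin_codes[item] = value
    for source, target in mapping.items():
        if source not in raw_fields:
            continue
        raw = raw_fields[source]
        if target.startswith("admin_codes."):
            item = target.split(".", 1)[1]
            if item not in ADMIN_ITEMS:
                raise FieldPathError(f"unknown administrative item {item!r}")
            value = normalize_value(raw)
            if value is not MISSING:
                record.admin_codes[item] = value
        elif target in LIST_FIELDS:
            setattr(record, target, normalize_list(raw, delimiter))
        elif target == "age":
            record.age = _parse_age(raw, record, warnings)
        elif target in SCALAR_FIELDS:
            setattr(record, target, normalize_value(raw))
        else:
            raise FieldPathError(f"unknown record field {target!r}")
    # age warning carries the record id even when age precedes it in mapping order
    for warning in warnings:
        warning.record_id = record.record_id
    return record, warnings


def _parse_age(
    raw: Any, record: OutpatientRecord, warnings: list[ParseWarning]
) -> int | None:
    value = normalize_value(raw)
    if value is MISSING:
        return MISSING
    try:
        age = int(value)
    except ValueError:
        warnings.append(ParseWarning(record.record_id, f"malformed age {value!r}"))
        return MISSING
    if age < 0:
        warnings.append(ParseWarning(record.record_id, f"negative age {age}"))
        return MISSING
    return age


def serialize_record(
    record: OutpatientRecord,
    field_mapping: Mapping[str, str] | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> dict[str, str]:
    """Flatten a record to source-named text cells (inverse of parse_record).

    Missing scalars and empty lists serialize to empty strings.
    """
    mapping = DEFAULT_FIELD_MAPPING if field_mapping is None else field_mapping
    row: dict[str, str] = {}
    for source, target in mapping.items():
        value = get_field(record, target)
        if target in LIST_FIELDS:
            row[source] = delimiter.join(value)
        elif value is MISSING:
            row[source] = ""
        else:
            row[source] = str(value)
    return row


def record_to_json_object(record: OutpatientRecord) -> dict[str, Any]:
    """Record as a JSON-ready object (lists kept as lists)."""
    return dataclasses.asdict(record)
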