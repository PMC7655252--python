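"""Default rule sets, rule-configuration loading, and code-set management.

The default configuration carries the 16 mandatory items of the outpatient
record standard (integrity assessment), the 13 coded items checked against
their code ranges (9 administrative value sets from the health-industry
standard WS 445.11-2014 plus 4 national TCM terminology standards), equal
0.5/0.5 score weights, and the default 14-standard star scheme.

The official standards' code tables are licensed/governmental content and
are NOT shipped; users load real code tables at runtime from two-column
(code, term) delimited files. The package ships small synthetic fixture
code sets, used by the synthetic generator and the test suite only.
"""

from __future__ import annotations

import csv
import warnings as _warnings
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import (
    DEFAULT_DELIMITER,
    CodeSet,
    CodingRule,
    MandatoryItemRule,
    Requirement,
    RuleConfig,
    StarScheme,
    StarStandard,
)
from .star import DEFAULT_THRESHOLDS

WS_445 = "WS 445.11-2014 (health-industry value sets)"
GB_THERAPEUTIC = "Clinic terminology of TCM diagnosis and treatment — Therapeutic methods"
GB_SYNDROMES = "Clinic terminology of TCM diagnosis and treatment — Syndromes"
GB_DISEASES = "Clinic terminology of TCM diagnosis and treatment — Diseases"
GB_DISEASE_ZHENG = "Classification and codes of diseases and Zheng of TCM"


class ConfigError(ValueError):
    """A rule configuration document is invalid or inconsistent."""


class CodeSetRegistry:
    """A lookup of code sets by codeset_id."""

    def __init__(self, codesets: Mapping[str, CodeSet] | None = None):
        self._codesets: dict[str, CodeSet] = dict(codesets or {})

    def add(self, codeset: CodeSet) -> None:
        self._codesets[codeset.codeset_id] = codeset

    def __getitem__(self, codeset_id: str) -> CodeSet:
        try:
            return self._codesets[codeset_id]
        except KeyError:
            raise ConfigError(f"unknown code set {codeset_id!r}") from None

    def __contains__(self, codeset_id: str) -> bool:
        return codeset_id in self._codesets

    def ids(self) -> list[str]:
        return sorted(self._codesets)

    def validate_config(self, config: RuleConfig) -> None:
        """Check that every coding rule's code set resolves here."""
        for rule in config.coding_rules:
            if rule.codeset_id not in self:
                raise ConfigError(
                    f"coding rule {rule.item_name!r} references unknown "
                    f"code set {rule.codeset_id!r}"
                )


# ---------------------------------------------------------------------------
# Default rules

def default_mandatory_rules() -> tuple[MandatoryItemRule, ...]:
    """The 16 mandatory items of the outpatient record, in standard order."""
    nb, alo = Requirement.NON_BLANK, Requirement.AT_LEAST_ONE
    return (
        MandatoryItemRule("Location", "location", nb),
        MandatoryItemRule("Pathological nature", "pathological_nature", nb),
        MandatoryItemRule("Four diagnosis", "four_diagnosis", alo),
        MandatoryItemRule("TCM symptom code", "tcm_symptom_codes", alo),
        MandatoryItemRule("TCM symptom", "tcm_symptoms", alo),
        MandatoryItemRule("TCM diagnosis", "tcm_diagnosis", nb),
        MandatoryItemRule("TCM syndrome type", "syndrome_types", alo),
        MandatoryItemRule("TCM syndrome type code", "syndrome_type_codes", alo),
        MandatoryItemRule("TCM treatment", "treatments", alo),
        MandatoryItemRule("TCM treatment code", "treatment_codes", alo),
        MandatoryItemRule("Name", "name", nb),
        MandatoryItemRule("ID number", "id_number", nb),
        MandatoryItemRule("Age", "age", nb),
        MandatoryItemRule("Gender code", "gender_code", nb),
        MandatoryItemRule(
            "Identification of dominant diseases in TCM", "dominant_disease_flag", nb
        ),
        MandatoryItemRule(
            "Code of dominant diseases in TCM", "dominant_disease_codes", alo
        ),
    )


def default_coding_rules() -> tuple[CodingRule, ...]:
    """The 13 coded items checked against code ranges.

    Nine administrative items draw their value sets from WS 445.11-2014;
    four TCM items draw on the national terminology standards. Items whose
    presence is already mandated by the integrity assessment are strict
    (missing code = noncompliant); administrative-only items are checked
    only when a value is supplied.
    """
    return (
        CodingRule("Ethnicity code", "admin_codes.ethnicity", "ethnicity",
                   WS_445, require_present=False),
        CodingRule("Code of medical insurance type", "admin_codes.medical_insurance_type",
                   "medical_insurance_type", WS_445, require_present=False),
        CodingRule("Level of disease severity", "admin_codes.disease_severity",
                   "disease_severity", WS_445, require_present=False),
        CodingRule("Biological gender code", "gender_code", "gender", WS_445),
        CodingRule("Code of ID type", "admin_codes.id_type", "id_type",
                   WS_445, require_present=False),
        CodingRule("Code of dominant diseases in TCM", "dominant_disease_codes",
                   "dominant_disease", WS_445),
        CodingRule("Type of diagnosis", "admin_codes.diagnosis_type", "diagnosis_type",
                   WS_445, require_present=False),
        CodingRule("Code of payment method", "admin_codes.payment_method",
                   "payment_method", WS_445, require_present=False),
        CodingRule("Nationality code", "admin_codes.nationality", "nationality",
                   WS_445, require_present=False),
        CodingRule("TCM treatment code", "treatment_codes", "tcm_treatment",
                   GB_THERAPEUTIC),
        CodingRule("TCM syndrome type code", "syndrome_type_codes", "tcm_syndrome",
                   GB_SYNDROMES),
        CodingRule("TCM symptom code", "tcm_symptom_codes", "tcm_symptom",
                   GB_DISEASES),
        CodingRule("TCM disease and Zheng classification code", "dominant_disease_codes",
                   "tcm_disease_zheng", GB_DISEASE_ZHENG),
    )


def default_star_scheme() -> StarScheme:
    """The default 14-standard cumulative star scheme.

    The original scheme's standard-by-standard table is not publicly
    reproduced; this default preserves the cumulative 5/7/9/11/14 structure
    over the mandatory and coding items: demographics first, then clinical
    findings, then coded terminology validity. It is pure configuration and
    can be replaced wholesale in a rule-configuration document.
    """
    s = StarStandard
    return StarScheme(
        standards=(
            s("Name recorded", mandatory_items=("Name",)),
            s("ID number recorded", mandatory_items=("ID number",)),
            s("Age recorded", mandatory_items=("Age",)),
            s("Gender code recorded", mandatory_items=("Gender code",)),
            s("Location recorded", mandatory_items=("Location",)),
            s("Pathological nature recorded", mandatory_items=("Pathological nature",)),
            s("Four-diagnosis finding recorded", mandatory_items=("Four diagnosis",)),
            s("TCM symptom recorded", mandatory_items=("TCM symptom",)),
            s("TCM symptom code present and valid",
              mandatory_items=("TCM symptom code",),
              coding_items=("TCM symptom code",)),
            s("TCM diagnosis recorded", mandatory_items=("TCM diagnosis",)),
            s("Syndrome type present and coded validly",
              mandatory_items=("TCM syndrome type", "TCM syndrome type code"),
              coding_items=("TCM syndrome type code",)),
            s("TCM treatment recorded", mandatory_items=("TCM treatment",)),
            s("TCM treatment code present and valid",
              mandatory_items=("TCM treatment code",),
              coding_items=("TCM treatment code",)),
            s("Dominant-disease code present and valid",
              mandatory_items=("Code of dominant diseases in TCM",),
              coding_items=("Code of dominant diseases in TCM",
                            "TCM disease and Zheng classification code")),
        ),
        thresholds=dict(DEFAULT_THRESHOLDS),
    )


def default_rule_config() -> RuleConfig:
    """The full default configuration: 16 mandatory rules, 13 coding rules,
    0.5/0.5 weights, default star scheme. Deterministic and stable."""
    return RuleConfig(
        mandatory_rules=default_mandatory_rules(),
        coding_rules=default_coding_rules(),
        star_scheme=default_star_scheme(),
        weights=(0.5, 0.5),
    )


# ---------------------------------------------------------------------------
# Synthetic fixture code sets

def fixture_codeset_registry() -> CodeSetRegistry:
    """Small synthetic code sets for every default codeset_id.

    These are invented fixture vocabularies for testing and synthetic data
    generation only; they are not the content of any official standard. The
    two dominant-disease sets share identical entries so that one recorded
    code can satisfy (or violate) both rules bound to that field coherently.
    """
    dominant = {f"ZB{i:02d}": f"dominant disease {i}" for i in range(1, 7)}
    tables: dict[str, dict[str, str]] = {
        "ethnicity": {f"{i:02d}": f"ethnic group {i}" for i in range(1, 9)},
        "medical_insurance_type": {str(i): f"insurance type {i}" for i in range(1, 6)},
        "disease_severity": {str(i): level for i, level in
                             enumerate(("mild", "moderate", "severe", "critical"), 1)},
        "gender": {"1": "male", "2": "female", "9": "unknown"},
        "id_type": {"01": "resident ID card", "02": "passport", "03": "military ID",
                    "99": "other"},
        "dominant_disease": dominant,
        "diagnosis_type": {"1": "initial", "2": "revisit", "3": "referral"},
        "payment_method": {f"{i:02d}": f"payment method {i}" for i in range(1, 7)},
        "nationality": {"CHN": "China", "USA": "United States", "JPN": "Japan",
                        "GBR": "United Kingdom"},
        "tcm_treatment": {f"ZF{i:03d}": f"therapeutic method {i}" for i in range(1, 13)},
        "tcm_syndrome": {f"ZH{i:03d}": f"syndrome {i}" for i in range(1, 13)},
        "tcm_symptom": {f"ZZ{i:03d}": f"symptom {i}" for i in range(1, 17)},
        "tcm_disease_zheng": dict(dominant),
    }
    registry = CodeSetRegistry()
    for codeset_id, entries in tables.items():
        registry.add(CodeSet(codeset_id, entries, source_label="synthetic fixture"))
    return registry


# ---------------------------------------------------------------------------
# File loading

def load_codeset(
    path: str | Path,
    codeset_id: str,
    delimiter: str = "\t",
    has_header: bool = False,
    source_label: str = "",
) -> CodeSet:
    """Load a code set from a two-column delimited (code, term) UTF-8 file.

    Rows with a blank code are skipped; duplicate codes are collapsed with a
    warning. An empty file is an error: a code range cannot be empty.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    duplicates = 0
    with path.open(encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for i, row in enumerate(reader):
            if has_header and i == 0:
                continue
            if not row:
                continue
            code = row[0].strip()
            term = row[1].strip() if len(row) > 1 else ""
            if not code:
                continue
            if code in entries:
                duplicates += 1
                continue
            entries[code] = term
    if duplicates:
        _warnings.warn(
            f"code set {codeset_id!r}: {duplicates} duplicate code rows collapsed",
            stacklevel=2,
        )
    if not entries:
        raise ConfigError(f"code set file {path} is empty: a code range cannot be empty")
    return CodeSet(codeset_id, entries, source_label=source_label or str(path))


def load_codeset_dir(
    directory: str | Path, delimiter: str = "\t", has_header: bool = False
) -> CodeSetRegistry:
    """Load every ``*.tsv``/``*.csv`` file in a directory as one code set.

    The file stem is the codeset_id; ``.csv`` files use comma delimiters
    regardless of ``delimiter``.
    """
    directory = Path(directory)
    registry = CodeSetRegistry()
    paths = sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.csv"))
    for path in paths:
        sep = "," if path.suffix == ".csv" else delimiter
        registry.add(load_codeset(path, path.stem, delimiter=sep, has_header=has_header))
    return registry


def write_fixture_codesets(directory: str | Path) -> list[Path]:
    """Write the synthetic fixture code sets as TSV files (one per set)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    registry = fixture_codeset_registry()
    written = []
    for codeset_id in registry.ids():
        path = directory / f"{codeset_id}.tsv"
        with path.open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            for code, term in sorted(registry[codeset_id].entries.items()):
                writer.writerow([code, term])
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Rule-configuration documents (YAML or JSON; YAML is a JSON superset here)

_REQUIREMENTS = {r.value: r for r in Requirement}


def load_rule_config(path: str | Path) -> RuleConfig:
    """Load a rule-configuration document, falling back to defaults.

    Any omitted section (mandatory_rules, coding_rules, star_scheme, weights,
    delimiter) keeps its default; an empty document equals
    ``default_rule_config()``. Schema problems raise :class:`ConfigError`
    naming the offending key.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return rule_config_from_dict(doc)


def rule_config_from_dict(doc: Mapping[str, Any]) -> RuleConfig:
    """Build a RuleConfig from a parsed document; omitted parts use defaults."""
    known = {"mandatory_rules", "coding_rules", "star_scheme", "weights", "delimiter"}
    for key in doc:
        if key not in known:
            raise ConfigError(f"unknown configuration key {key!r}")

    mandatory = (
        tuple(_parse_mandatory_rule(item) for item in _rule_list(doc, "mandatory_rules"))
        if "mandatory_rules" in doc
        else default_mandatory_rules()
    )
    coding = (
        tuple(_parse_coding_rule(item) for item in _rule_list(doc, "coding_rules"))
        if "coding_rules" in doc
        else default_coding_rules()
    )
    scheme = (
        _parse_star_scheme(doc["star_scheme"])
        if "star_scheme" in doc
        else default_star_scheme()
    )
    weights = _parse_weights(doc.get("weights"))
    delimiter = doc.get("delimiter", DEFAULT_DELIMITER)
    if not isinstance(delimiter, str) or not delimiter:
        raise ConfigError("'delimiter' must be a non-empty string")
    try:
        return RuleConfig(
            mandatory_rules=mandatory,
            coding_rules=coding,
            star_scheme=scheme,
            weights=weights,
            delimiter=delimiter,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _rule_list(doc: Mapping[str, Any], key: str) -> list[Mapping[str, Any]]:
    value = doc[key]
    if not isinstance(value, list) or not value:
        raise ConfigError(f"{key!r} must be a non-empty list")
    for item in value:
        if not isinstance(item, dict):
            raise ConfigError(f"every entry of {key!r} must be a mapping")
    return value


def _require(item: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in item:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return item[key]


def _parse_mandatory_rule(item: Mapping[str, Any]) -> MandatoryItemRule:
    where = f"mandatory rule {item.get('item', '?')!r}"
    req_text = str(_require(item, "requirement", where))
    if req_text not in _REQUIREMENTS:
        raise ConfigError(
            f"{where}: unknown requirement {req_text!r} "
            f"(expected one of {sorted(_REQUIREMENTS)})"
        )
    try:
        return MandatoryItemRule(
            item_name=str(_require(item, "item", where)),
            field_path=str(_require(item, "field", where)),
            requirement=_REQUIREMENTS[req_text],
        )
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_coding_rule(item: Mapping[str, Any]) -> CodingRule:
    where = f"coding rule {item.get('item', '?')!r}"
    return CodingRule(
        item_name=str(_require(item, "item", where)),
        field_path=str(_require(item, "field", where)),
        codeset_id=str(_require(item, "codeset", where)),
        standard_source=str(item.get("source", "")),
        require_present=bool(item.get("require_present", True)),
    )


def _parse_star_scheme(doc: Any) -> StarScheme:
    if not isinstance(doc, dict):
        raise ConfigError("'star_scheme' must be a mapping")
    standards_doc = _require(doc, "standards", "star_scheme")
    if not isinstance(standards_doc, list) or not standards_doc:
        raise ConfigError("star_scheme 'standards' must be a non-empty list")
    standards = []
    for item in standards_doc:
        if not isinstance(item, dict):
            raise ConfigError("every star standard must be a mapping")
        standards.append(
            StarStandard(
                name=str(_require(item, "name", "star standard")),
                mandatory_items=tuple(item.get("mandatory", ()) or ()),
                coding_items=tuple(item.get("coding", ()) or ()),
            )
        )
    thresholds_doc = _require(doc, "thresholds", "star_scheme")
    if not isinstance(thresholds_doc, dict):
        raise ConfigError("star_scheme 'thresholds' must be a mapping of level -> count")
    try:
        thresholds = {int(k): int(v) for k, v in thresholds_doc.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"star_scheme thresholds: {exc}") from exc
    try:
        return StarScheme(standards=tuple(standards), thresholds=thresholds)
    except ValueError as exc:
        raise ConfigError(f"star_scheme: {exc}") from exc


def _parse_weights(doc: Any) -> tuple[float, float]:
    if doc is None:
        return (0.5, 0.5)
    if isinstance(doc, dict):
        try:
            pair = (float(doc["integrity"]), float(doc["coding"]))
        except KeyError as exc:
            raise ConfigError(f"'weights' mapping missing key {exc}") from exc
    elif isinstance(doc, (list, tuple)) and len(doc) == 2:
        pair = (float(doc[0]), float(doc[1]))
    else:
        raise ConfigError(
            "'weights' must be a [integrity, coding] pair or a mapping with "
            "'integrity' and 'coding'"
        )
    if abs(sum(pair) - 1.0) > 1e-9:
        raise ConfigError(f"'weights' must sum to 1, got {pair}")
    return pair


def rule_config_to_dict(config: RuleConfig) -> dict[str, Any]:
    """Serialize a RuleConfig to the document form (inverse of loading)."""
    return {
        "weights": {"integrity": config.weights[0], "coding": config.weights[1]},
        "delimiter": config.delimiter,
        "mandatory_rules": [
            {
                "item": r.item_name,
                "field": r.field_path,
                "requirement": r.requirement.value,
            }
            for r in config.mandatory_rules
        ],
        "coding_rules": [
            {
                "item": r.item_name,
                "field": r.field_path,
                "codeset": r.codeset_id,
                "source": r.standard_source,
                "require_present": r.require_present,
            }
            for r in config.coding_rules
        ],
        "star_scheme": {
            "thresholds": {
                str(level): count
                for level, count in sorted(config.star_scheme.thresholds.items())
            },
            "standards": [
                {
                    "name": s.name,
                    "mandatory": list(s.mandatory_items),
                    "coding": list(s.coding_items),
                }
                for s in config.star_scheme.standards
            ],
        },
    }
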