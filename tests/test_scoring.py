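"""Per-record counting and batch score formulas."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emrqc.model import OutpatientRecord
from emrqc.scoring import (
    EmptyBatchError,
    assess_coding,
    assess_mandatory,
    coding_score,
    display_score,
    integrity_score,
    total_score,
)
from emrqc.synthetic import generate_record


def test_fully_populated_record_has_no_missing_items(perfect_record, config):
    x, flags = assess_mandatory(perfect_record, config.mandatory_rules)
    assert x == 0 and all(flags)


def test_empty_record_misses_every_mandatory_item(config):
    x, flags = assess_mandatory(OutpatientRecord(), config.mandatory_rules)
    assert x == 16 and not any(flags)


def test_missing_count_matches_deliberate_gaps(perfect_record, config):
    perfect_record.age = None
    perfect_record.tcm_symptom_codes = []
    x, flags = assess_mandatory(perfect_record, config.mandatory_rules)
    assert x == 2
    failed = {
        rule.item_name
        for rule, ok in zip(config.mandatory_rules, flags)
        if not ok
    }
    assert failed == {"Age", "TCM symptom code"}


def test_gender_code_membership(perfect_record, config, registry):
    perfect_record.gender_code = "1"
    y, flags = assess_coding(perfect_record, config.coding_rules, registry)
    assert y == 0
    perfect_record.gender_code = "7"  # outside the fixture range {1,2,9}
    y, _ = assess_coding(perfect_record, config.coding_rules, registry)
    assert y == 1


def test_missing_strict_code_is_noncompliant(perfect_record, config, registry):
    perfect_record.gender_code = None
    y, flags = assess_coding(perfect_record, config.coding_rules, registry)
    assert y == 1
    idx = config.coding_index("Biological gender code")
    assert flags[idx] is False


def test_missing_admin_code_is_not_counted(perfect_record, config, registry):
    perfect_record.admin_codes.pop("ethnicity")
    y, flags = assess_coding(perfect_record, config.coding_rules, registry)
    assert y == 0
    assert flags[config.coding_index("Ethnicity code")] is True


def test_any_invalid_member_spoils_the_item(perfect_record, config, registry):
    valid = sorted(registry["tcm_syndrome"].codes)[0]
    perfect_record.syndrome_type_codes = [valid, "ZZZ"]
    y, flags = assess_coding(perfect_record, config.coding_rules, registry)
    assert y == 1
    assert flags[config.coding_index("TCM syndrome type code")] is False


@pytest.mark.parametrize(
    "counts, k, expected",
    [
        ([0, 0, 0], 16, 100.0),
        ([1, 3], 4, 50.0),
        ([4, 4, 4], 4, 0.0),
        ([13, 0], 13, 50.0),
        ([1, 1, 1, 1], 2, 50.0),
    ],
)
def test_batch_score_formula(counts, k, expected):
    assert integrity_score(counts, k) == expected
    assert coding_score(counts, k) == expected


def test_empty_batch_is_an_error_not_a_silent_100():
    with pytest.raises(EmptyBatchError):
        integrity_score([], 16)
    with pytest.raises(EmptyBatchError):
        coding_score([], 13)


def test_counts_outside_range_rejected():
    with pytest.raises(ValueError):
        integrity_score([17], 16)


@pytest.mark.parametrize(
    "si, sc, full, shown",
    [
        (75, 86, 80.5, 81),
        (100, 100, 100.0, 100),
        (0, 100, 50.0, 50),
    ],
)
def test_total_score_and_display_rounding(si, sc, full, shown):
    st_ = total_score(si, sc)
    assert st_ == full
    assert display_score(st_) == shown


def test_total_score_respects_weights():
    assert total_score(80, 60, (0.7, 0.3)) == pytest.approx(74.0)
    with pytest.raises(ValueError):
        total_score(80, 60, (0.7, 0.4))


def test_display_rounds_half_up_not_bankers():
    assert display_score(80.5) == 81
    assert display_score(79.5) == 80
    assert display_score(79.49) == 79


# ---------------------------------------------------------------------------
# Properties

counts_batches = st.integers(1, 16).flatmap(
    lambda k: st.tuples(
        st.just(k), st.lists(st.integers(0, k), min_size=1, max_size=50)
    )
)


@given(counts_batches)
def test_scores_bounded_and_permutation_invariant(kc):
    k, counts = kc
    s = integrity_score(counts, k)
    assert 0.0 <= s <= 100.0
    shuffled = sorted(counts, reverse=True)
    assert integrity_score(shuffled, k) == s


@given(counts_batches)
def test_filling_one_missing_item_strictly_raises_the_score(kc):
    k, counts = kc
    improvable = [i for i, c in enumerate(counts) if c > 0]
    if not improvable:
        return
    better = list(counts)
    better[improvable[0]] -= 1
    assert integrity_score(better, k) > integrity_score(counts, k)


@given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 1))
def test_total_score_linearity(si, sc, a):
    lhs = total_score(a * si, a * sc)
    assert lhs == pytest.approx(a * total_score(si, sc), abs=1e-9)


def _brute_force_scores(records, config, registry):
    """Independent recount: walk every record x rule pair one by one."""
    from emrqc.model import MISSING, Requirement, get_field

    x_total = y_total = 0
    for record in records:
        for rule in config.mandatory_rules:
            value = get_field(record, rule.field_path)
            if rule.requirement is Requirement.AT_LEAST_ONE:
                ok = isinstance(value, list) and len(value) > 0
            else:
                ok = value is not MISSING
            x_total += 0 if ok else 1
        for rule in config.coding_rules:
            value = get_field(record, rule.field_path)
            codes = value if isinstance(value, list) else (
                [] if value is MISSING else [value]
            )
            if not codes:
                ok = not rule.require_present
            else:
                valid = registry[rule.codeset_id].codes
                ok = all(c in valid for c in codes)
            y_total += 0 if ok else 1
    n = len(records)
    si = (1 - x_total / (n * config.k_integrity)) * 100
    sc = (1 - y_total / (n * config.k_coding)) * 100
    return si, sc


def test_scores_match_brute_force_recount_on_random_batches(config, registry):
    """Eq-based batch scores equal an independent record-by-record recount."""
    from emrqc.scoring import assess_coding, assess_mandatory

    rng = random.Random(2024)
    for _ in range(30):
        n = rng.randint(1, 50)
        records = [
            generate_record(
                rng.randint(0, 5), config=config, registry=registry, rng=rng,
                missingness=rng.random(), invalid_code_rate=rng.random(),
            )[0]
            for _ in range(n)
        ]
        xs = [assess_mandatory(r, config.mandatory_rules)[0] for r in records]
        ys = [assess_coding(r, config.coding_rules, registry)[0] for r in records]
        si = integrity_score(xs, config.k_integrity)
        sc = coding_score(ys, config.k_coding)
        bf_si, bf_sc = _brute_force_scores(records, config, registry)
        assert si == pytest.approx(bf_si, abs=1e-9)
        assert sc == pytest.approx(bf_sc, abs=1e-9)
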