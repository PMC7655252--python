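"""Star rating: prefix semantics, scheme evaluation, batch aggregation."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emrqc.model import StarScheme, StarStandard
from emrqc.scoring import EmptyBatchError, RecordAssessment
from emrqc.star import batch_star, evaluate_standards, star_level


def _plain_scheme(n_standards, thresholds):
    return StarScheme(
        standards=tuple(
            StarStandard(f"standard {i}") for i in range(1, n_standards + 1)
        ),
        thresholds=thresholds,
    )


FOURTEEN = _plain_scheme(14, {1: 5, 2: 7, 3: 9, 4: 11, 5: 14})


def _oracle_level(bools, scheme):
    """Brute force: highest level whose full prefix is satisfied."""
    best = 0
    for level in sorted(scheme.thresholds):
        if all(bools[: scheme.thresholds[level]]):
            best = level
    return best


@pytest.mark.parametrize(
    "true_count, expected",
    [(14, 5), (13, 4), (11, 4), (10, 3), (9, 3), (7, 2), (5, 1), (4, 0), (0, 0)],
)
def test_star_level_leading_run(true_count, expected):
    bools = [True] * true_count + [False] * (14 - true_count)
    assert star_level(bools, FOURTEEN) == expected


def test_one_star_needs_only_first_five():
    bools = [True] * 5 + [False] + [True] * 8
    assert star_level(bools, FOURTEEN) == 1


def test_broken_early_standard_forces_zero_stars():
    bools = [True] * 14
    bools[2] = False
    assert star_level(bools, FOURTEEN) == 0


def test_length_mismatch_is_an_error():
    with pytest.raises(ValueError):
        star_level([True] * 13, FOURTEEN)


def test_degenerate_scheme_exhaustive():
    """Thresholds 1..5 over 5 standards: level = leading all-true run."""
    scheme = _plain_scheme(5, {1: 1, 2: 2, 3: 3, 4: 4, 5: 5})
    for bools in itertools.product([False, True], repeat=5):
        expected = 0
        for b in bools:
            if not b:
                break
            expected += 1
        assert star_level(bools, scheme) == expected == _oracle_level(bools, scheme)


def test_random_flag_vectors_match_prefix_oracle():
    rng = random.Random(99)
    for _ in range(1000):
        bools = [rng.random() < 0.7 for _ in range(14)]
        assert star_level(bools, FOURTEEN) == _oracle_level(bools, FOURTEEN)


@given(st.lists(st.booleans(), min_size=14, max_size=14), st.integers(0, 13))
def test_flipping_a_standard_true_never_lowers_the_level(bools, idx):
    before = star_level(bools, FOURTEEN)
    bools = list(bools)
    bools[idx] = True
    assert star_level(bools, FOURTEEN) >= before


@given(st.lists(st.booleans(), min_size=14, max_size=14))
def test_prefix_consistency(bools):
    level = star_level(bools, FOURTEEN)
    for lvl, threshold in FOURTEEN.thresholds.items():
        assert (level >= lvl) == all(bools[:threshold])


def test_scheme_threshold_invariants_enforced():
    with pytest.raises(ValueError):
        _plain_scheme(5, {1: 3, 2: 2, 3: 3, 4: 4, 5: 5})  # not increasing
    with pytest.raises(ValueError):
        _plain_scheme(6, {1: 1, 2: 2, 3: 3, 4: 4, 5: 5})  # top != |standards|


# ---------------------------------------------------------------------------
# Default scheme over real assessment flags

def _assessment_from_flags(config, mandatory_ok, coding_ok):
    mandatory_flags = tuple(
        r.item_name in mandatory_ok for r in config.mandatory_rules
    )
    coding_flags = tuple(r.item_name in coding_ok for r in config.coding_rules)
    return RecordAssessment(
        record_id="r",
        missing_count=mandatory_flags.count(False),
        noncompliant_count=coding_flags.count(False),
        mandatory_flags=mandatory_flags,
        coding_flags=coding_flags,
    )


def test_evaluate_standards_all_true_and_all_false(config):
    scheme = config.star_scheme
    every_m = {r.item_name for r in config.mandatory_rules}
    every_c = {r.item_name for r in config.coding_rules}
    assert evaluate_standards(
        _assessment_from_flags(config, every_m, every_c), scheme, config
    ) == (True,) * 14
    assert evaluate_standards(
        _assessment_from_flags(config, set(), set()), scheme, config
    ) == (False,) * 14


def test_evaluate_standards_two_star_prefix(config):
    """Flags satisfying exactly the first 7 default standards -> [T*7, F*7]."""
    scheme = config.star_scheme
    mandatory_ok = {
        "Name", "ID number", "Age", "Gender code", "Location",
        "Pathological nature", "Four diagnosis",
    }
    outcome = evaluate_standards(
        _assessment_from_flags(config, mandatory_ok, set()), scheme, config
    )
    assert outcome == (True,) * 7 + (False,) * 7
    assert star_level(outcome, scheme) == 2


def test_standard_with_coding_item_requires_validity(config):
    scheme = config.star_scheme
    every_m = {r.item_name for r in config.mandatory_rules}
    every_c = {r.item_name for r in config.coding_rules} - {"TCM symptom code"}
    outcome = evaluate_standards(
        _assessment_from_flags(config, every_m, every_c), scheme, config
    )
    assert outcome[8] is False  # standard 9: symptom code present and valid
    assert star_level(outcome, scheme) == 2


# ---------------------------------------------------------------------------
# Batch star (reconstruction: count-weighted mean, half-up)

@pytest.mark.parametrize(
    "counts, expected",
    [
        ({5: 10}, 5),
        ({0: 3}, 0),
        ({2: 1, 4: 1}, 3),
        ({0: 1, 5: 1}, 3),  # mean 2.5 rounds half-up
        ({1: 3, 2: 1}, 1),  # mean 1.25
    ],
)
def test_batch_star_weighted_mean(counts, expected):
    assert batch_star(counts) == expected


def test_batch_star_empty_batch_is_error():
    with pytest.raises(EmptyBatchError):
        batch_star({0: 0, 5: 0})
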