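"""Typed validation: totality, completeness, exact-match registries."""

import random
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcase.model import AttributeDef, AttributeValue, RegistryDef
from fluxcase.typesystem import validate_value

DRUGS = {"drugs": RegistryDef("drugs", entries=("Itraconazole", "Fluconazole"))}


def codes(outcome):
    assert isinstance(outcome, list), f"expected errors, got {outcome!r}"
    return [e.code for e in outcome]


@pytest.mark.parametrize(
    "attr, raw, expected_value",
    [
        (AttributeDef("age", "integer", min=0, max=120), "35", 35),
        (AttributeDef("age", "integer"), "-7", -7),
        (AttributeDef("t", "real", min=0), "36.6", 36.6),
        (AttributeDef("t", "real"), "1e3", 1000.0),
        (AttributeDef("s", "choice", choices=("present", "absent")), "present", "present"),
        (AttributeDef("d", "register", registry="drugs"), "Fluconazole", "Fluconazole"),
        (AttributeDef("n", "text"), "free text, with comma", "free text, with comma"),
    ],
)
def test_accepts_valid_scalars(attr, raw, expected_value):
    outcome = validate_value(attr, raw, DRUGS)
    assert isinstance(outcome, AttributeValue)
    assert outcome.value == expected_value


def test_date_parses_to_calendar_date():
    import datetime

    outcome = validate_value(AttributeDef("d", "date"), "1980-06-01")
    assert outcome.value == datetime.date(1980, 6, 1)


@pytest.mark.parametrize(
    "attr, raw, expected_codes",
    [
        (AttributeDef("age", "integer", min=0, max=120), "150", ["out-of-range"]),
        (AttributeDef("age", "integer", min=0, max=120), "abc", ["type-mismatch"]),
        (AttributeDef("age", "integer"), "1_0", ["type-mismatch"]),
        (AttributeDef("t", "real"), "12,5", ["type-mismatch"]),
        (AttributeDef("t", "real"), "nan", ["type-mismatch"]),
        (AttributeDef("d", "date"), "31/12/1999", ["bad-date"]),
        (AttributeDef("d", "date"), "2001-02-30", ["bad-date"]),
        (AttributeDef("s", "choice", choices=("present", "absent")), "Present", ["not-in-choices"]),
        (AttributeDef("r", "register", registry="drugs"), "Itraconazol", ["not-in-registry"]),
        (AttributeDef("x", "text", required=True), "", ["missing-required"]),
        (AttributeDef("x", "integer"), ["1"], ["type-mismatch"]),
    ],
)
def test_rejects_invalid_scalars(attr, raw, expected_codes):
    assert codes(validate_value(attr, raw, DRUGS)) == expected_codes


def test_registry_near_miss_is_mentioned_never_accepted():
    attr = AttributeDef("drug", "register", registry="drugs")
    outcome = validate_value(attr, "Itraconazol", DRUGS)
    assert codes(outcome) == ["not-in-registry"]
    assert "Itraconazole" in outcome[0].message  # suggestion in the message


def test_absent_optional_is_none_not_error():
    assert validate_value(AttributeDef("x", "integer"), "") is None
    assert validate_value(AttributeDef("x", "integer"), None) is None


TABLE = AttributeDef(
    "family",
    "table",
    columns=(("relative", "text"), ("condition", "text"), ("onset_year", "integer")),
)


def test_table_accepts_valid_rows():
    rows = [
        {"relative": "mother", "condition": "nmo", "onset_year": "1990"},
        {"relative": "aunt", "condition": "ms", "onset_year": "1985"},
        {"relative": "brother", "condition": "none", "onset_year": "2001"},
    ]
    outcome = validate_value(TABLE, rows)
    assert isinstance(outcome, AttributeValue)
    assert len(outcome.value) == 3
    assert outcome.value[0]["onset_year"] == 1990


def test_table_errors_carry_row_index_and_are_complete():
    """k independently bad cells yield exactly k errors, each with its row."""
    rows = [
        {"relative": "mother", "condition": "nmo", "onset_year": "199O"},
        {"relative": "aunt", "condition": "ms", "onset_year": "1985"},
        {"relative": "uncle", "condition": "ms", "onset_year": "bad", "extra": "x"},
    ]
    outcome = validate_value(TABLE, rows)
    assert codes(outcome) == ["bad-table-row"] * 3
    assert sorted(e.row_index for e in outcome) == [1, 3, 3]


def test_computed_attributes_are_not_validated():
    from fluxcase.formula import parse_formula

    attr = AttributeDef("bmi", "computed", formula=parse_formula("a + b"))
    with pytest.raises(TypeError):
        validate_value(attr, "1")


def _random_text(rng, alphabet):
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))


@pytest.mark.parametrize("kind", ["integer", "real", "text", "date", "choice", "register"])
def test_totality_fuzz(kind):
    """1000 random raw strings per kind: value or errors, never a crash."""
    rng = random.Random(hash(kind) % (2**31))
    attr = AttributeDef(
        "fuzzed",
        kind,
        min=0 if kind in ("integer", "real") else None,
        max=100 if kind in ("integer", "real") else None,
        choices=("yes", "no") if kind == "choice" else (),
        registry="drugs" if kind == "register" else None,
    )
    alphabet = string.printable
    for _ in range(1000):
        raw = _random_text(rng, alphabet)
        outcome = validate_value(attr, raw, DRUGS)
        assert outcome is None or isinstance(outcome, (AttributeValue, list))


@settings(derandomize=True, max_examples=200)
@given(st.text(max_size=30))
def test_totality_arbitrary_unicode(raw):
    for kind in ("integer", "real", "date"):
        outcome = validate_value(AttributeDef("x", kind), raw)
        assert outcome is None or isinstance(outcome, (AttributeValue, list))


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=-(10**9), max_value=10**9))
def test_integer_text_round_trip(value):
    outcome = validate_value(AttributeDef("x", "integer"), str(value))
    assert isinstance(outcome, AttributeValue) and outcome.value == value


def test_determinism():
    attr = AttributeDef("r", "register", registry="drugs")
    results = {str(validate_value(attr, "Itraconazol", DRUGS)) for _ in range(5)}
    assert len(results) == 1
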