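"""Cohort loading, validation rules, descriptive statistics, scaling."""

import io
import logging

import numpy as np
import pytest

import inkmap as im
from inkmap.cohort import CohortError, INDICATOR_NAMES, TABLE_VARIABLES


def test_fixture_shape_and_groups(cohort):
    assert cohort.n_subjects == 19
    assert cohort.n_variables == 45
    assert cohort.variable_names == TABLE_VARIABLES
    assert sum(g == "AD" for g in cohort.groups) == 8
    assert sum(g == "INPH" for g in cohort.groups) == 11
    assert cohort.subject_ids[0] == "Demenza 1"


def test_csv_round_trip(cohort, tmp_path):
    p = tmp_path / "cohort.csv"
    cohort.to_csv(p)
    again = im.load_cohort(p)
    assert again.subject_ids == cohort.subject_ids
    assert again.variable_names == cohort.variable_names
    assert np.array_equal(again.values, cohort.values)


def test_missing_trailing_cell_filled_with_zero(cohort, tmp_path, caplog):
    """A truncated row (the 47-variable table prints one) loads with the
    trailing cell as 0 and a logged warning."""
    text = (im.load_fixture().to_frame().to_csv(index=False)).splitlines()
    # drop the last cell of the INPH 7 row
    i = next(k for k, ln in enumerate(text) if ln.startswith("INPH 7 pr"))
    assert text[i].endswith(",0")
    text[i] = text[i][: -2]
    with caplog.at_level(logging.WARNING, logger="inkmap.cohort"):
        table = im.load_cohort(io.StringIO("\n".join(text)))
    assert table.column("Sensazione")[i - 1] == 0
    assert np.array_equal(table.values, cohort.values)
    assert any("missing trailing cell" in r.message for r in caplog.records)


@pytest.mark.parametrize(
    "cell,err",
    [("x", "non-integer"), ("-1", "negative"), ("2.5", "non-integer")],
)
def test_bad_cells_rejected(cell, err):
    text = f"subject_id,group,v1,v2\na,AD,1,{cell}\nb,INPH,0,1\n"
    with pytest.raises(CohortError, match=err):
        im.load_cohort(io.StringIO(text))


def test_interior_blank_cell_rejected():
    text = "subject_id,group,v1,v2\na,AD,,1\nb,INPH,0,1\n"
    with pytest.raises(CohortError, match="blank cell"):
        im.load_cohort(io.StringIO(text))


def test_unknown_group_rejected():
    text = "subject_id,group,v1\na,AD,1\nb,CONTROL,0\n"
    with pytest.raises(CohortError, match="unknown group"):
        im.load_cohort(io.StringIO(text))


def test_empty_file_is_io_error():
    with pytest.raises(OSError):
        im.load_cohort(io.StringIO(""))


def test_duplicate_subject_ids_rejected():
    text = "subject_id,group,v1\na,AD,1\na,INPH,0\n"
    with pytest.raises(CohortError, match="duplicate"):
        im.load_cohort(io.StringIO(text))


# ---------------------------------------------------------------------------
# protocol rules


def test_first_subject_satisfies_all_rules(cohort):
    rep = im.validate_protocol(cohort)
    assert all(v.subject_id != "Demenza 1" for v in rep.violations)


def test_determinant_rule_flags_exactly_one_subject(cohort):
    rep = im.validate_protocol(cohort)
    det = [v for v in rep.violations if v.rule == "determinant_sum"]
    assert [(v.subject_id, v.expected, v.observed) for v in det] == [
        ("INPH 8 pr", 11, 10)
    ]
    assert rep.summary == {
        "localization_sum": 0, "determinant_sum": 1, "form_split": 0,
    }


def test_constructed_localization_violation(cohort):
    values = cohort.values.copy()
    j = cohort.variable_names.index("G")
    values[0, j] += 1  # G + D + Dd + DG now exceeds the response count
    broken = im.CohortTable(
        list(cohort.subject_ids), list(cohort.groups),
        list(cohort.variable_names), values,
    )
    rep = im.validate_protocol(broken)
    loc = [v for v in rep.violations if v.rule == "localization_sum"]
    assert [v.subject_id for v in loc] == ["Demenza 1"]


def test_rule_with_missing_variable_is_config_error():
    table = im.CohortTable(["a", "b"], ["AD", "INPH"], ["v1"], [[1], [2]])
    with pytest.raises(CohortError, match="requires missing variable"):
        im.validate_protocol(table)


def test_validation_is_order_independent(cohort):
    perm = np.arange(19)[::-1]
    shuffled = im.CohortTable(
        [cohort.subject_ids[i] for i in perm],
        [cohort.groups[i] for i in perm],
        list(cohort.variable_names),
        cohort.values[perm],
    )
    assert im.validate_protocol(shuffled).summary == im.validate_protocol(cohort).summary


# ---------------------------------------------------------------------------
# descriptive statistics


def test_response_count_summary(cohort):
    r = im.descriptive_stats(cohort).row("Numero Risposte")
    assert round(r["mean"], 2) == 10.32
    assert round(r["sd"], 2) == 3.83  # n-1 convention
    assert (r["min"], r["max"]) == (4, 18)


def test_population_sd_convention_differs(cohort):
    r = im.descriptive_stats(cohort, ddof=0).row("Numero Risposte")
    assert round(r["sd"], 2) == 3.73


def test_constant_column_stats():
    table = im.CohortTable(["a", "b", "c"], ["AD", "AD", "INPH"], ["v1"],
                           [[7], [7], [7]])
    r = im.descriptive_stats(table).row("v1")
    assert r["sd"] == 0 and r["min"] == r["max"] == r["mean"] == 7


def test_empty_table_errors():
    table = im.CohortTable([], [], ["v1"], np.zeros((0, 1), dtype=int))
    with pytest.raises(CohortError):
        im.descriptive_stats(table)


# ---------------------------------------------------------------------------
# min-max scaling


def test_scaling_maps_range_to_unit_interval(cohort, scaled45):
    col = scaled45.column("Numero Risposte")
    raw = cohort.column("Numero Risposte")
    assert col[raw == 4] == pytest.approx(0.0)
    assert col[raw == 18] == pytest.approx(1.0)
    assert col[raw == 11] == pytest.approx(0.5)  # (11 - 4) / (18 - 4)


def test_constant_column_scales_to_zero():
    table = im.CohortTable(["a", "b"], ["AD", "INPH"], ["v1", "v2"],
                           [[3, 1], [3, 2]])
    scaled = im.minmax_scale(table)
    assert np.all(scaled.column("v1") == 0.0)


def test_inverse_transform_recovers_integers(cohort, scaled45):
    assert np.array_equal(scaled45.inverse(), cohort.values)


def test_scaling_needs_two_subjects():
    table = im.CohortTable(["a"], ["AD"], ["v1"], [[1]])
    with pytest.raises(CohortError):
        im.minmax_scale(table)


# ---------------------------------------------------------------------------
# group indicators


def test_append_indicators(cohort, cohort47):
    assert cohort47.n_variables == 47
    assert cohort47.variable_names[-2:] == list(INDICATOR_NAMES)
    assert cohort47.column("INPH")[0] == 0 and cohort47.column("DEMENZA")[0] == 1
    assert np.array_equal(cohort47.column("INPH") + cohort47.column("DEMENZA"),
                          np.ones(19, dtype=int))


def test_indicators_refuse_single_group():
    table = im.CohortTable(["a", "b"], ["AD", "AD"], ["v1"], [[1], [2]])
    with pytest.raises(CohortError, match="both groups"):
        im.append_group_indicators(table)


def test_indicators_refuse_double_application(cohort47):
    with pytest.raises(CohortError, match="already present"):
        im.append_group_indicators(cohort47)


# ---------------------------------------------------------------------------
# property: scaling and serialization hold for arbitrary integer tables

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    hnp.arrays(
        dtype=np.int64,
        shape=st.tuples(st.integers(2, 8), st.integers(1, 6)),
        elements=st.integers(0, 30),
    )
)
def test_scaling_round_trip_property(values):
    n, p = values.shape
    table = im.CohortTable(
        [f"s{i}" for i in range(n)],
        ["AD" if i % 2 else "INPH" for i in range(n)],
        [f"v{j}" for j in range(p)],
        values,
    )
    scaled = im.minmax_scale(table)
    assert scaled.values.min() >= 0.0 and scaled.values.max() <= 1.0
    # non-constant columns reach both 0 and 1; constant columns stay 0
    for j in range(p):
        col = scaled.values[:, j]
        if values[:, j].min() == values[:, j].max():
            assert np.all(col == 0.0)
        else:
            assert col.min() == 0.0 and col.max() == 1.0
    assert np.array_equal(scaled.inverse(), values)
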