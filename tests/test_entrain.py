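import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from circashift import (
    classify_shift,
    cross_dataset_integration,
    dual_oscillating,
    entrainment_summary,
    fold_phase_shift,
    licensed_oscillators,
    phase_shift_records,
    signed_phase_difference,
)


@pytest.mark.parametrize(
    "delta, expected",
    [(14, 10), (0, 0), (12, 12), (-14, 10), (20, 4), (26, 2), (24, 0), (-38, 10)],
)
def test_fold_worked_examples(delta, expected):
    assert fold_phase_shift(delta, 24) == pytest.approx(expected)


def test_fold_errors():
    with pytest.raises(ValueError, match="tau"):
        fold_phase_shift(3, 0)
    with pytest.raises(ValueError, match="finite"):
        fold_phase_shift(float("nan"))


@given(st.floats(-48, 48, allow_nan=False))
def test_fold_properties(delta):
    """Even, 24-periodic, bounded by 12, equals the brute-force rule."""
    folded = fold_phase_shift(delta)
    assert 0 <= folded <= 12
    assert fold_phase_shift(-delta) == pytest.approx(folded)
    assert fold_phase_shift(delta + 24) == pytest.approx(folded)
    m = abs(delta) % 24
    assert folded == pytest.approx(min(m, 24 - m))


@pytest.mark.parametrize(
    "folded, label",
    [
        (3.9, "phase_locked"),
        (4.0, "phase_locked"),
        (4.0001, "intermediate"),
        (7.9999, "intermediate"),
        (8.0, "phase_inverted"),
        (10, "phase_inverted"),
        (12, "phase_inverted"),
        (0, "phase_locked"),
    ],
)
def test_classify_bins_and_boundaries(folded, label):
    assert classify_shift(folded) == label


def test_classify_rejects_out_of_window():
    with pytest.raises(ValueError):
        classify_shift(12.5)
    with pytest.raises(ValueError):
        classify_shift(-0.1)


def test_classification_partitions_the_window():
    """Every folded value maps to exactly one class; dense-grid check
    against an independent interval-membership oracle."""
    for folded in np.arange(0, 12.0001, 0.003):
        label = classify_shift(float(folded))
        oracle = (
            "phase_locked"
            if folded <= 4
            else ("intermediate" if folded < 8 else "phase_inverted")
        )
        assert label == oracle


def _fits(qs, condition="NRF"):
    return pd.DataFrame(
        {
            "condition": condition,
            "q_value": pd.Series(qs),
            "acrophase": 0.0,
        }
    ).rename_axis("feature_id")


def test_dual_oscillating_toy_sets():
    fits_a = _fits({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.9})
    fits_b = _fits({"a": 0.9, "b": 0.01, "c": 0.02, "d": 0.01}, "DRF")
    sets = dual_oscillating(fits_a, fits_b, 0.05)
    assert set(sets.dual) == {"b", "c"}
    assert set(sets.only_a) == {"a"}
    assert set(sets.only_b) == {"d"}


def test_dual_oscillating_disjoint_and_mismatch():
    fits_a = _fits({"a": 0.01, "b": 0.5})
    fits_b = _fits({"a": 0.5, "b": 0.01}, "DRF")
    assert len(dual_oscillating(fits_a, fits_b).dual) == 0
    with pytest.raises(ValueError, match="universes"):
        dual_oscillating(fits_a, _fits({"a": 0.5, "z": 0.01}))


def test_dual_set_grows_monotonically_with_threshold():
    rng = np.random.default_rng(0)
    qa = {f"g{i}": q for i, q in enumerate(rng.uniform(0, 0.2, 200))}
    qb = {f"g{i}": q for i, q in enumerate(rng.uniform(0, 0.2, 200))}
    tight = set(dual_oscillating(_fits(qa), _fits(qb, "DRF"), 0.01).dual)
    loose = set(dual_oscillating(_fits(qa), _fits(qb, "DRF"), 0.05).dual)
    assert tight <= loose


def _records(folded_values):
    return pd.DataFrame(
        {
            "folded_shift": folded_values,
            "entrainment_class": [classify_shift(v) for v in folded_values],
        },
        index=[f"g{i}" for i in range(len(folded_values))],
    )


def test_summary_percentages_and_histogram():
    summary = entrainment_summary(_records([1.0, 2.0, 3.0, 10.0]))
    assert summary.n_dual == 4
    assert summary.percentages["phase_inverted"] == 25.00
    assert summary.percentages["phase_locked"] == 75.00
    assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=0.01)
    assert summary.histogram[1] == 1 and summary.histogram[10] == 1

    inverted = entrainment_summary(_records([8.0, 9.5, 11.0, 12.0]))
    assert inverted.percentages["phase_inverted"] == 100.00
    assert sum(inverted.histogram[8:]) == 4  # all mass in bins 8-12
    assert inverted.histogram[-1] == 2  # final bin [11, 12] is closed


def test_summary_empty_sentinel_and_permutation_invariance():
    empty = entrainment_summary(_records([]))
    assert empty.is_empty and empty.n_dual == 0
    values = [0.5, 4.5, 9.0, 9.5, 11.0]
    a = entrainment_summary(_records(values))
    b = entrainment_summary(_records(values[::-1]))
    assert a.counts == b.counts and a.histogram == b.histogram


def test_cross_dataset_toy_example():
    per, counts, fractions = cross_dataset_integration(
        {"X": {"a": 5.0, "b": 3.0, "c": 9.0}, "Y": {"a": 6.0, "d": 2.0}},
        threshold=4,
    )
    assert per.loc["X", "n_shifted"] == 2  # {a, c}
    assert per.loc["Y", "n_shifted"] == 1  # {a}
    assert per.loc["X", "pct_shifted"] == 66.67
    assert per.loc["Y", "pct_shifted"] == 50.00
    assert counts.loc["X", "Y"] == 1 and counts.loc["Y", "X"] == 1
    assert fractions.loc["X", "Y"] == pytest.approx(0.5)
    assert fractions.loc["Y", "X"] == pytest.approx(1.0)


def test_cross_dataset_strict_threshold_and_duplicates():
    per, *_ = cross_dataset_integration({"X": {"a": 4.0, "b": 4.0001}}, threshold=4)
    assert per.loc["X", "n_shifted"] == 1  # exactly 4.0 is excluded
    with pytest.raises(ValueError, match="duplicate"):
        cross_dataset_integration([("X", {"a": 5.0}), ("X", {"b": 5.0})])


def test_cross_dataset_fractions_match_count_oracle():
    rng = np.random.default_rng(8)
    tables = {
        name: {f"g{i}": float(rng.uniform(0, 12)) for i in range(rng.integers(10, 40))}
        for name in "ABC"
    }
    per, counts, fractions = cross_dataset_integration(tables, threshold=4)
    for name, table in tables.items():
        expected = sum(v > 4 for v in table.values())
        assert per.loc[name, "n_shifted"] == expected
        assert per.loc[name, "fraction_shifted"] == pytest.approx(
            expected / len(table)
        )


def test_licensed_oscillators_symmetric_difference():
    fits_a = _fits({"a": 0.01, "b": 0.01, "c": 0.5})
    fits_b = _fits({"a": 0.5, "b": 0.01, "c": 0.01}, "DRF")
    licensed = licensed_oscillators(fits_a, fits_b, 0.05)
    assert set(licensed["NRF"]) == {"a"}
    assert set(licensed["DRF"]) == {"c"}  # rhythmic in both ("b") excluded


def test_phase_shift_records_provenance_and_fallback():
    fits_a = pd.DataFrame(
        {"q_value": [0.01, 0.01], "acrophase": [2.0, 4.0], "condition": "NRF"},
        index=["x", "y"],
    )
    fits_b = pd.DataFrame(
        {"q_value": [0.01, 0.01], "acrophase": [12.0, 5.0], "condition": "DRF"},
        index=["x", "y"],
    )
    comparisons = pd.DataFrame(
        {"delta_phase": [10.2, np.nan], "converged": [True, False]},
        index=["x", "y"],
    )
    records = phase_shift_records(["x", "y"], fits_a, fits_b, comparisons)
    assert records.loc["x", "shift_source"] == "joint_fit"
    assert records.loc["x", "signed_shift"] == pytest.approx(10.2)
    assert records.loc["y", "shift_source"] == "acrophase_diff"
    assert records.loc["y", "signed_shift"] == pytest.approx(1.0)
    assert records.loc["x", "entrainment_class"] == "phase_inverted"


@given(st.floats(0, 24, exclude_max=True), st.floats(0, 24, exclude_max=True))
def test_signed_difference_wraps_and_folds_consistently(pa, pb):
    d = signed_phase_difference(pa, pb)
    assert -12 < d <= 12
    assert fold_phase_shift(d) == pytest.approx(abs(d), abs=1e-9)
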