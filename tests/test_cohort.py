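"""Transition coding, derived covariates and model-frame assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from medchurn.cohort import (
    ModelSpec,
    TransitionGroup,
    build_model_frame,
    classify_group,
    count_transitions,
    lag_and_initial,
    normalize_income,
    transition_profiles,
    within_means,
)
from medchurn.panel_io import from_dataframe
from medchurn.synthetic_data import default_config, generate_dataset

from conftest import make_manual_panel


class TestTransitions:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ([1, 1, 1, 1, 1], 0),
            ([0, 0, 1, 1, 1], 1),
            ([1, 1, 1, 0, 0], 1),
            ([1, 0, 1, 0, 1], 4),
            ([1], 0),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_transitions(seq) == expected

    def test_exhaustive_against_bruteforce(self):
        """All 2^6 length-6 sequences agree with an adjacent-pair oracle."""
        for seq in itertools.product((0, 1), repeat=6):
            brute = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
            if any(seq):
                assert count_transitions(list(seq)) == brute
                assert classify_group(brute) == (
                    TransitionGroup.NONE if brute == 0
                    else TransitionGroup.SINGLE if brute == 1
                    else TransitionGroup.MULTIPLE
                )

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([0, 2, 1])

    def test_never_enrolled_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert count_transitions([0, 0, 0]) == 0

    def test_classify_group(self):
        assert classify_group(0) is TransitionGroup.NONE
        assert classify_group(1) is TransitionGroup.SINGLE
        assert classify_group(3) is TransitionGroup.MULTIPLE
        with pytest.raises(ValueError):
            classify_group(-1)

    def test_profiles_match_sequences(self):
        df = make_manual_panel(
            {"a": {"medicaid": [1, 1, 1, 1, 1]},
             "b": {"medicaid": [0, 1, 1, 1, 1]},
             "c": {"medicaid": [1, 0, 1, 0, 1]}}
        )
        prof = transition_profiles(from_dataframe(df))
        assert prof.loc["a", "n_transitions"] == 0
        assert prof.loc["b", "group"] is TransitionGroup.SINGLE
        assert prof.loc["c", "multi_transition"] == 1


class TestDerivedCovariates:
    def test_within_means_examples(self):
        df = make_manual_panel({"a": {"employed": [1, 0, 1, 0, 0], "healthy": [1, 1, 1, 1, 1]}})
        m = within_means(from_dataframe(df))
        assert m.loc["a", "mean_employed"] == pytest.approx(0.4)
        assert m.loc["a", "mean_healthy"] == pytest.approx(1.0)

    def test_within_means_oracle_random(self):
        rng = np.random.default_rng(0)
        seqs = {f"p{i}": {"employed": rng.integers(0, 2, 6).tolist()} for i in range(50)}
        ds = from_dataframe(make_manual_panel(seqs, T=6))
        m = within_means(ds, ["employed"])
        for pid, cols in seqs.items():
            assert m.loc[pid, "mean_employed"] == pytest.approx(sum(cols["employed"]) / 6)

    def test_within_means_unknown_variable(self, small_dataset):
        with pytest.raises(KeyError):
            within_means(small_dataset, ["age"])  # not round-varying

    def test_income_normalization(self):
        df = make_manual_panel({"a": {"income": [10, 20, 30, 20, 20]}}, T=5)
        ratio = normalize_income(from_dataframe(df))
        assert ratio.tolist() == pytest.approx([0.5, 1.0, 1.5, 1.0, 1.0])

    def test_income_grand_mean_exactly_one(self, small_dataset):
        assert normalize_income(small_dataset).mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_income_rejected(self):
        df = make_manual_panel({"a": {"income": [0, 0, 0, 0, 0]}})
        with pytest.raises(ValueError, match="income"):
            normalize_income(from_dataframe(df))


class TestLagInitial:
    def test_example(self):
        df = make_manual_panel({"a": {"er_visits": [2, 0, 1, 3, 0]}})
        ds = from_dataframe(df)
        lag, initial = lag_and_initial(ds.person("a"), "er_visits")
        assert lag.tolist() == [2, 0, 1, 3]
        assert initial == 2

    def test_positional_oracle_random(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 9, 6).tolist()
        df = make_manual_panel({"a": {"rx_fills": y}}, T=6)
        lag, initial = lag_and_initial(from_dataframe(df).person("a"), "rx_fills")
        for t in range(2, 7):
            assert lag[t - 2] == y[t - 2]
        assert initial == y[0]

    def test_single_round_errors(self):
        df = make_manual_panel({"a": {}}, T=1)
        with pytest.raises(ValueError):
            lag_and_initial(from_dataframe(df).person("a"), "er_visits")


@pytest.fixture(scope="module")
def dataset():
    ds, _ = generate_dataset(default_config(n_persons=100, seed=13))
    return ds


class TestModelFrames:

    def test_row_counts(self, dataset):
        static = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        dynamic = build_model_frame(dataset, "er_visits", ModelSpec.DYNAMIC)
        assert static.n_obs == 100 * 6
        assert dynamic.n_obs == 100 * 5

    def test_column_nesting(self, dataset):
        cols = {
            spec: set(build_model_frame(dataset, "er_visits", spec).columns)
            for spec in ModelSpec
        }
        base, cre, dyn = (cols[ModelSpec.STATIC_BASE], cols[ModelSpec.STATIC_CRE],
                          cols[ModelSpec.DYNAMIC])
        assert cre - base == {"mean_employed", "mean_healthy"}
        # dynamic adds the lag/initial terms and re-bases the round dummies
        assert {"lag_er_visits", "initial_er_visits"} <= dyn
        assert base - {"round_2"} <= cre | base
        assert (cre - {"round_2"}) <= dyn | {"round_2"}

    def test_dynamic_excludes_round_one(self, dataset):
        dynamic = build_model_frame(dataset, "outpatient_visits", ModelSpec.DYNAMIC)
        assert (dynamic.rounds >= 2).all()

    def test_lag_and_initial_columns_align(self):
        df = make_manual_panel({"a": {"er_visits": [2, 0, 1, 3, 0]},
                                "b": {"er_visits": [0, 0, 0, 0, 0]}})
        ds = from_dataframe(df)
        frame = build_model_frame(ds, "er_visits", ModelSpec.DYNAMIC)
        a_rows = frame.X[frame.X.index.isin(ds.data[ds.data.person_id == "a"].index)]
        assert a_rows["lag_er_visits"].tolist() == [2, 0, 1, 3]
        assert a_rows["initial_er_visits"].tolist() == [2, 2, 2, 2]

    def test_h_log1p_option(self):
        df = make_manual_panel({"a": {"er_visits": [2, 0, 1, 3, 0]}})
        frame = build_model_frame(from_dataframe(df), "er_visits", ModelSpec.DYNAMIC,
                                  h_form="log1p")
        assert frame.X["lag_er_visits"].tolist() == pytest.approx(np.log1p([2, 0, 1, 3]).tolist())

    def test_round_dummies_reference(self, dataset):
        static = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_BASE)
        dynamic = build_model_frame(dataset, "er_visits", ModelSpec.DYNAMIC)
        assert "round_1" not in static.columns and "round_2" in static.columns
        assert "round_2" not in dynamic.columns and "round_3" in dynamic.columns

    def test_unknown_outcome(self, dataset):
        with pytest.raises(KeyError):
            build_model_frame(dataset, "dental_visits", ModelSpec.STATIC_BASE)

    def test_rows_grouped_by_person(self, dataset):
        frame = build_model_frame(dataset, "er_visits", ModelSpec.STATIC_CRE)
        # person codes must be contiguous blocks
        changes = np.count_nonzero(np.diff(frame.person_index))
        assert changes == frame.n_persons - 1
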