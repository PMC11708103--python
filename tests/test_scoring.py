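"""Main-indicator scoring, PMC/depression indices, levels, and ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmcindex import (
    IndicatorSchema,
    MainIndicator,
    ScoringError,
    SubIndicator,
    classify_level,
    compute_depression,
    compute_pmc,
    evaluate,
    evaluate_main_scores,
    main_score_table,
    rank_policies,
    score_main,
    sub_indicator_averages,
)

# -- independent integer-arithmetic oracle --------------------------------


def cents_half_up(k: int, T: int) -> int:
    """Half-up rounding of 100*k/T via pure integer arithmetic."""
    return (200 * k + T) // (2 * T)


def pmc_oracle(binaries_by_main: list[list[int]]) -> float:
    """Direct composite-index evaluation: per-main mean (2 dp, half-up),
    then summed.  A sum of exact 2-dp values needs no further rounding."""
    total = sum(cents_half_up(sum(row), len(row)) for row in binaries_by_main)
    return total / 100


def small_schema(n_subs: list[int]) -> IndicatorSchema:
    return IndicatorSchema(
        mains=tuple(
            MainIndicator(
                id=f"X{i + 1}",
                subs=tuple(SubIndicator(id=f"X{i + 1}:{j + 1}") for j in range(n)),
            )
            for i, n in enumerate(n_subs)
        )
    )


# -- score_main -----------------------------------------------------------


class TestScoreMain:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1] * 7 + [0], 0.88),  # 7/8
            ([0, 0, 0], 0.00),
            ([1] * 5 + [0] * 7, 0.42),  # 5/12
            ([1] * 5 + [0] * 3, 0.63),  # 5/8: half rounds up, not to even
            ([1] + [0] * 7, 0.13),  # 1/8: half rounds up
            ([1], 1.00),
        ],
    )
    def test_known_ratios(self, row, expected):
        assert score_main(row) == expected

    def test_empty_row_rejected(self):
        with pytest.raises(ScoringError):
            score_main([])

    def test_non_binary_rejected(self):
        with pytest.raises(ScoringError, match="non-binary"):
            score_main([0, 2, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ScoringError):
            score_main([0, 1], T=3)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True)
    def test_matches_integer_oracle(self, row):
        assert score_main(row) == cents_half_up(sum(row), len(row)) / 100


# -- main_score_table -----------------------------------------------------


class TestMainScoreTable:
    def test_single_two_agency_coding(self, schema):
        row = {v: 0 for v in schema.binary_variables()}
        row.update({"X2:1": 1})
        m = pd.DataFrame([row], index=["P"])
        assert main_score_table(m, schema).loc["P", "X2"] == 0.33

    def test_identity_one_main_one_sub(self):
        s = small_schema([1])
        m = pd.DataFrame({"X1:1": [1]}, index=["P"])
        assert main_score_table(m, s).values.tolist() == [[1.00]]

    def test_all_ones_matrix(self, schema):
        m = pd.DataFrame(
            np.ones((3, 45), dtype=int), columns=schema.binary_variables()
        )
        assert (main_score_table(m, schema).values == 1.0).all()

    def test_column_mismatch_lists_offenders(self, schema):
        m = pd.DataFrame({"X1:1": [1], "bogus": [0]})
        with pytest.raises(ScoringError, match="bogus"):
            main_score_table(m, schema)

    def test_reproduces_published_table(self, coded_matrix, schema, table4):
        rebuilt = main_score_table(coded_matrix, schema)
        pd.testing.assert_frame_equal(rebuilt, table4, check_like=False)


# -- compute_pmc / depression / level -------------------------------------


class TestCompositeIndex:
    def test_high_scoring_policy(self, table4):
        assert compute_pmc(table4.loc["P2"]) == 7.63

    def test_low_scoring_policy(self, table4):
        assert compute_pmc(table4.loc["P8"]) == 4.21

    def test_all_zero_row(self):
        assert compute_pmc({f"X{i}": 0.0 for i in range(1, 11)}) == 0.00

    def test_missing_cell_named(self):
        row = pd.Series({"X1": 0.5, "X2": np.nan})
        with pytest.raises(ScoringError, match="X2"):
            compute_pmc(row)

    @pytest.mark.parametrize(
        "pmc, expected", [(7.63, 2.37), (4.33, 5.67), (10.00, 0.00)]
    )
    def test_depression(self, pmc, expected):
        assert compute_depression(pmc) == expected

    def test_depression_out_of_range(self):
        with pytest.raises(ScoringError):
            compute_depression(10.5)

    @pytest.mark.parametrize(
        "pmc, level",
        [
            (6.91, "Good"),
            (5.79, "Acceptable"),
            (7.00, "Excellent"),  # boundary belongs to the higher class
            (6.00, "Good"),
            (5.00, "Acceptable"),
            (4.99, "Poor"),
            (0.00, "Poor"),
            (10.00, "Excellent"),
        ],
    )
    def test_level_thresholds(self, pmc, level):
        assert classify_level(pmc) == level

    def test_level_out_of_range(self):
        with pytest.raises(ScoringError):
            classify_level(10.01)


# -- ranking --------------------------------------------------------------


class TestRanking:
    def test_published_extremes(self, table5):
        ranks = rank_policies(table5["pmc"], method="ordinal")
        assert ranks[table5.index.get_loc("P2")] == 1
        assert ranks[table5.index.get_loc("P8")] == 13

    def test_tie_shares_rank_by_default(self):
        assert rank_policies([5.0, 5.0]) == [1, 1]
        assert rank_policies([5.0, 5.0, 4.0]) == [1, 1, 3]

    def test_ordinal_breaks_ties_by_position(self):
        assert rank_policies([5.0, 5.0, 4.0], method="ordinal") == [1, 2, 3]

    def test_against_sort_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.random(100).round(2)
        expected = [1 + int((vals > v).sum()) for v in vals]
        assert rank_policies(vals) == expected

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            rank_policies([])


# -- sub-indicator averages ------------------------------------------------


class TestSubAverages:
    def test_known_fractions(self):
        m = pd.DataFrame(
            {"a": [1] * 12 + [0], "b": [1] + [0] * 12, "c": [1] * 13}
        )
        avg = sub_indicator_averages(m)
        assert avg["a"] == 0.92  # 12/13
        assert avg["b"] == 0.08  # 1/13
        assert avg["c"] == 1.00

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            sub_indicator_averages(pd.DataFrame(columns=["a"]))


# -- full pipeline ---------------------------------------------------------


class TestEvaluate:
    def test_reproduces_published_results(self, coded_matrix, schema, table5):
        res = evaluate(coded_matrix, schema)
        ref = table5.loc[res.index]
        assert (res["pmc"] == ref["pmc"]).all()
        assert (res["depression"] == ref["depression"]).all()
        assert (res["level"] == ref["level"]).all()

    def test_perfect_policy(self, schema):
        m = pd.DataFrame(
            np.ones((1, 45), dtype=int),
            columns=schema.binary_variables(),
            index=["P"],
        )
        res = evaluate(m, schema)
        assert res.loc["P"].tolist() == [10.00, 0.00, "Excellent", 1]

    def test_disclosure_only_policy(self, schema):
        row = {v: 0 for v in schema.binary_variables()}
        row["X10"] = 1
        res = evaluate(pd.DataFrame([row], index=["P"]), schema)
        assert res.loc["P", "pmc"] == 1.00
        assert res.loc["P", "level"] == "Poor"

    def test_reduced_max_score(self, table4, table5):
        """Dropping the constant disclosure column and scoring out of 9."""
        res = evaluate_main_scores(table4.drop(columns=["X10"]), max_score=9)
        assert (res["pmc"] == table5.loc[res.index, "pmc"] - 1.00).all()
        assert (res["depression"] == 9 - res["pmc"]).all()


# -- properties ------------------------------------------------------------


binary_grid = st.integers(1, 6).flatmap(
    lambda n_mains: st.tuples(
        st.just(n_mains),
        st.lists(
            st.lists(st.integers(0, 1), min_size=1, max_size=5),
            min_size=n_mains,
            max_size=n_mains,
        ),
    )
)


class TestProperties:
    @given(binary_grid)
    @settings(derandomize=True, max_examples=200)
    def test_pmc_matches_direct_oracle(self, grid):
        """Pipeline result equals a direct integer-arithmetic evaluation."""
        _, rows = grid
        n_subs = [len(r) for r in rows]
        s = small_schema(n_subs)
        flat = {v: x for main, r in zip(s.mains, rows) for v, x in zip(main.variable_ids, r)}
        res = evaluate(pd.DataFrame([flat], index=["P"]), s, max_score=len(rows))
        assert res.loc["P", "pmc"] == pytest.approx(pmc_oracle(rows))

    @given(st.lists(st.lists(st.integers(0, 1), min_size=1, max_size=5),
                    min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=200)
    def test_conservation_and_bounds(self, rows):
        """pmc + depression == #mains; every main score in [0, 1]."""
        s = small_schema([len(r) for r in rows])
        flat = {v: x for main, r in zip(s.mains, rows) for v, x in zip(main.variable_ids, r)}
        m = pd.DataFrame([flat], index=["P"])
        table = main_score_table(m, s)
        assert ((table.values >= 0) & (table.values <= 1)).all()
        res = evaluate(m, s)
        assert res.loc["P", "pmc"] + res.loc["P", "depression"] == len(rows)

    def test_monotone_under_flips(self, schema, coded_matrix):
        """Setting any unset binary variable never decreases the PMC index."""
        base = evaluate(coded_matrix, schema)["pmc"]
        rng = np.random.default_rng(11)
        zeros = np.argwhere(coded_matrix.values == 0)
        for i, j in zeros[rng.choice(len(zeros), size=60, replace=False)]:
            flipped = coded_matrix.copy()
            flipped.iloc[i, j] = 1
            res = evaluate(flipped, schema)["pmc"]
            assert res.iloc[i] >= base.iloc[i]
            assert (res.drop(res.index[i]) == base.drop(base.index[i])).all()
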