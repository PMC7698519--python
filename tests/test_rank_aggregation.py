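"""Inclusive percentiles, pipeline adapters, and average/weighted aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinarray.rank_aggregation import (
    adapter_kea3,
    adapter_ptmsea,
    adapter_uka,
    aggregate_groups,
    combine_pipelines,
    inclusive_percentile_rank,
    round_percent,
    top_k_table,
    unweighted_average,
    weighted_average,
)


class TestInclusivePercentile:
    def test_three_scores_span_endpoints(self):
        assert inclusive_percentile_rank({"a": 1, "b": 2, "c": 3}) == {
            "a": 0.0,
            "b": 50.0,
            "c": 100.0,
        }

    def test_full_tie_centers_at_50(self):
        pct = inclusive_percentile_rank({"a": 5, "b": 5, "c": 5})
        assert all(v == 50.0 for v in pct.values())

    def test_single_score_ranks_100(self):
        assert inclusive_percentile_rank({"only": 0.2}) == {"only": 100.0}

    def test_maximum_attains_100(self):
        pct = inclusive_percentile_rank({"low": 1, "mid": 4, "top": 9})
        assert pct["top"] == 100.0

    def test_nan_scores_named_in_error(self):
        with pytest.raises(ValueError, match="bad"):
            inclusive_percentile_rank({"ok": 1.0, "bad": float("nan")})

    @given(st.dictionaries(st.text(min_size=1, max_size=4), st.floats(-100, 100), min_size=1, max_size=20))
    @settings(max_examples=80, deadline=None)
    def test_bounds_and_monotonicity(self, scores):
        pct = inclusive_percentile_rank(scores)
        assert all(0.0 <= v <= 100.0 for v in pct.values())
        items = sorted(scores.items(), key=lambda kv: kv[1])
        ranks = [pct[k] for k, _ in items]
        assert all(a <= b + 1e-9 for a, b in zip(ranks, ranks[1:]))


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(95.5, 96), (64.5, 64), (70.5, 70), (89.5, 90), (91.5, 92), (82.25, 82), (66.75, 67)],
    )
    def test_half_even_display_rounding(self, value, expected):
        assert round_percent(value) == expected

    def test_snaps_float_error_near_half(self):
        assert round_percent(95.49999999999) == 96


class TestAdapters:
    def test_uka_absolute_median_final_score(self):
        rows = pd.DataFrame({"kinase": ["A", "B", "C"], "median_final_score": [-3.2, 0.0, 4.0]})
        out = adapter_uka(rows).set_index("kinase_id")["raw_score"]
        assert out["A"] == pytest.approx(3.2)
        assert out["B"] == 0.0

    def test_uka_sign_irrelevant_to_ranking(self):
        rows = pd.DataFrame({"kinase": ["neg", "pos"], "median_final_score": [-5.0, 4.0]})
        scores = adapter_uka(rows)
        pct = inclusive_percentile_rank(dict(zip(scores["kinase_id"], scores["raw_score"])))
        assert pct == {"neg": 100.0, "pos": 0.0}

    def test_uka_missing_column_is_format_error(self):
        with pytest.raises(ValueError):
            adapter_uka(pd.DataFrame({"kinase": ["A"]}))

    def test_ptmsea_reciprocal_and_tyrosine_filter(self):
        rows = pd.DataFrame(
            {
                "kinase": ["TK1", "TK2", "STK1"],
                "fdr.pvalue.totalGeoMeanLFC": [0.5, 1.0, 0.01],
                "is_tyrosine_kinase": [True, True, False],
            }
        )
        out = adapter_ptmsea(rows).set_index("kinase_id")["raw_score"]
        assert out["TK1"] == pytest.approx(2.0)
        assert out["TK2"] == pytest.approx(1.0)
        assert "STK1" not in out.index

    def test_ptmsea_zero_statistic_ranked_top_with_warning(self):
        rows = pd.DataFrame(
            {"kinase": ["Z", "A"], "fdr.pvalue.totalGeoMeanLFC": [0.0, 0.5], "is_tyrosine_kinase": True}
        )
        with pytest.warns(UserWarning):
            out = adapter_ptmsea(rows)
        pct = inclusive_percentile_rank(dict(zip(out["kinase_id"], out["raw_score"])))
        assert pct["Z"] == 100.0

    @staticmethod
    def _kea3_tables(fdr_by_db):
        tables = {}
        for db, fdr in fdr_by_db.items():
            for cut in (0.2, 0.3, 0.4):
                tables[(db, cut)] = pd.DataFrame({"kinase": ["K"], "fdr": [fdr]})
        return tables

    def test_kea3_uniform_fdr(self):
        out = adapter_kea3(self._kea3_tables({"ChengKSIN": 0.1, "PTMsigDB": 0.1, "PhosDAll": 0.1}))
        assert out.loc[0, "raw_score"] == pytest.approx(1.0)
        out1 = adapter_kea3(self._kea3_tables({"ChengKSIN": 1.0, "PTMsigDB": 1.0, "PhosDAll": 1.0}))
        assert out1.loc[0, "raw_score"] == pytest.approx(0.0)

    def test_kea3_mean_then_log(self):
        out = adapter_kea3(self._kea3_tables({"ChengKSIN": 0.1, "PTMsigDB": 0.01, "PhosDAll": 0.001}))
        assert out.loc[0, "raw_score"] == pytest.approx(1.431798275933005, rel=1e-12)

    def test_kea3_absent_database_omitted_with_warning(self):
        tables = self._kea3_tables({"ChengKSIN": 0.1, "PTMsigDB": 0.1, "PhosDAll": 0.1})
        for cut in (0.2, 0.3, 0.4):  # second kinase present in one database only
            tables[("ChengKSIN", cut)] = pd.DataFrame(
                {"kinase": ["K", "K2"], "fdr": [0.1, 0.01]}
            )
        with pytest.warns(UserWarning):
            out = adapter_kea3(tables).set_index("kinase_id")["raw_score"]
        assert out["K2"] == pytest.approx(2.0)


class TestAverages:
    def test_unweighted_examples_from_published_rows(self):
        assert round_percent(unweighted_average({"KRSA": 100, "UKA": 80})) == 90
        assert round_percent(unweighted_average({"KRSA": 100, "UKA": None})) == 100
        assert round_percent(unweighted_average({"KRSA": 96, "KEA3": 98})) == 97

    def test_weighted_examples_from_published_rows(self):
        assert round_percent(weighted_average({"a": 87, "b": 95, "c": 36, "d": 82}, 4)) == 75
        assert round_percent(weighted_average({"a": 100, "b": 77, "c": 90}, 4)) == 67
        assert weighted_average({"a": 80.0, "b": 80.0, "c": 80.0, "d": 80.0}, 4) == 80.0

    def test_zero_reporting_pipelines_rejected(self):
        with pytest.raises(ValueError):
            unweighted_average({"a": None})
        with pytest.raises(ValueError):
            weighted_average({"a": 50}, 0)

    @given(
        vals=st.lists(st.floats(0, 100), min_size=1, max_size=4),
        total=st.integers(4, 6),
    )
    @settings(max_examples=80, deadline=None)
    def test_weighted_never_exceeds_unweighted(self, vals, total):
        per = {f"p{i}": v for i, v in enumerate(vals)}
        uw = unweighted_average(per)
        w = weighted_average(per, total)
        assert w <= uw + 1e-9
        assert w == pytest.approx(uw * len(vals) / total)


def _pct_frame(rows):
    return pd.DataFrame(rows, columns=["pipeline_id", "context_id", "kinase_id", "percentile"])


class TestCombineAndGroups:
    def test_missing_is_not_zero(self):
        pct = _pct_frame([("KRSA", "c", "K1", 100.0), ("UKA", "c", "K2", 50.0)])
        out = combine_pipelines(pct, total_pipelines=2).set_index("kinase_id")
        assert out.loc["K1", "unweighted_avg"] == 100.0
        assert out.loc["K1", "weighted_avg"] == 50.0

    def test_permutation_invariance(self):
        rows = [("KRSA", "c", "K", 80.0), ("UKA", "c", "K", 60.0), ("KEA3", "c", "K", 40.0)]
        a = combine_pipelines(_pct_frame(rows), 4)
        b = combine_pipelines(_pct_frame(rows[::-1]), 4)
        pd.testing.assert_frame_equal(
            a.sort_index(axis=1), b.sort_index(axis=1), check_like=True
        )

    def test_singleton_group_identical_to_cell_line(self):
        rows = [("KRSA", "c1", "K", 80.0), ("UKA", "c1", "K", 60.0)]
        single = combine_pipelines(_pct_frame(rows), 2)
        grouped = aggregate_groups(_pct_frame(rows), {"g": ["c1"]}, 2)
        assert grouped.loc[0, "unweighted_avg"] == single.loc[0, "unweighted_avg"]

    def test_equal_percentiles_across_members_preserved(self):
        rows = [("KRSA", "c1", "K", 70.0), ("KRSA", "c2", "K", 70.0)]
        grouped = aggregate_groups(_pct_frame(rows), {"g": ["c1", "c2"]}, 1)
        assert grouped.loc[0, "KRSA"] == 70.0

    def test_group_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        rows = []
        for pipe in ("KRSA", "UKA", "PTMSEA"):
            for ctx in ("A", "B"):
                for kin in ("K1", "K2", "K3"):
                    if rng.random() < 0.8:
                        rows.append((pipe, ctx, kin, float(rng.integers(0, 101))))
        frame = _pct_frame(rows)
        grouped = aggregate_groups(frame, {"g": ["A", "B"]}, total_pipelines=4)
        # independent brute-force recomputation over the raw score table
        for kin in ("K1", "K2", "K3"):
            per_pipe = {}
            for pipe in ("KRSA", "UKA", "PTMSEA"):
                vals = [
                    p for pp, ctx, kk, p in rows if pp == pipe and kk == kin and ctx in ("A", "B")
                ]
                if vals:
                    per_pipe[pipe] = sum(vals) / len(vals)
            if not per_pipe:
                continue
            expect_uw = sum(per_pipe.values()) / len(per_pipe)
            expect_w = sum(per_pipe.values()) / 4
            row = grouped[grouped["kinase_id"] == kin].iloc[0]
            assert row["unweighted_avg"] == pytest.approx(expect_uw)
            assert row["weighted_avg"] == pytest.approx(expect_w)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_groups(_pct_frame([("KRSA", "c", "K", 1.0)]), {"g": []}, 1)


class TestTopK:
    def _rankings(self):
        rows = [("c", kin, 100 - i) for i, kin in enumerate("ABCDEFGHIJKL")]
        frame = pd.DataFrame(rows, columns=["context_id", "kinase_id", "unweighted_avg"])
        return frame

    def test_descending_top_10_of_12(self):
        top = top_k_table(self._rankings(), k=10)
        assert len(top) == 10
        assert list(top["rank"]) == list(range(1, 11))
        assert top["unweighted_avg"].is_monotonic_decreasing

    def test_ties_broken_alphabetically(self):
        frame = pd.DataFrame(
            [("c", "ZZ", 90.0), ("c", "AA", 90.0), ("c", "MM", 10.0)],
            columns=["context_id", "kinase_id", "unweighted_avg"],
        )
        top = top_k_table(frame, k=2)
        assert list(top["kinase_id"]) == ["AA", "ZZ"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_k_table(self._rankings(), k=0)
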