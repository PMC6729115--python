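"""Dropout-record representations, conversions and summaries."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import attriphase as ap
from attriphase.data import sniff_format

from conftest import random_dataset


def wide_frame(rows):
    """Build a wide response DataFrame from per-participant answer tuples."""
    return pd.DataFrame(
        {f"Q{j + 1}": [r[j] for r in rows.values()] for j in range(len(next(iter(rows.values()))))},
        index=pd.Index(rows.keys(), name="participant_id"),
    )


class TestFromResponseMatrix:
    def test_first_gap_rule_and_completion(self):
        m = wide_frame({"a": ("A", "B", "C", None, None), "b": ("A", "B", "C", "D", "E")})
        ds = ap.from_response_matrix(m, ap.SurveyDesign(5))
        assert ds.exit_question(0) == 4
        assert ds.exit_question(1) == ap.COMPLETED

    def test_nonmonotone_row_raises_by_default(self):
        m = wide_frame({"a": ("A", None, "C")})
        with pytest.raises(ap.NonmonotoneError):
            ap.from_response_matrix(m, ap.SurveyDesign(3))

    def test_nonmonotone_row_coerced_with_warning(self):
        m = wide_frame({"a": ("A", None, "C")})
        with pytest.warns(UserWarning, match="coerced 1"):
            ds = ap.from_response_matrix(m, ap.SurveyDesign(3), nonmonotone_policy="coerce")
        assert ds.exit_question(0) == 2

    def test_column_count_and_duplicate_ids_rejected(self):
        m = wide_frame({"a": ("A", "B")})
        with pytest.raises(ValueError, match="columns"):
            ap.from_response_matrix(m, ap.SurveyDesign(3))
        m2 = wide_frame({"a": ("A", "B"), "b": ("A", "B")})
        m2.index = ["a", "a"]
        with pytest.raises(ValueError, match="duplicate"):
            ap.from_response_matrix(m2, ap.SurveyDesign(2))


class TestConversions:
    @pytest.mark.parametrize(
        "exit_q,expected",
        [(2, (0, 1, 1)), (ap.COMPLETED, (0, 0, 0)), (1, (1, 1, 1))],
    )
    def test_cumulative_flag_definition(self, exit_q, expected):
        ds = ap.DropoutDataset.from_records([("a", exit_q)], ap.SurveyDesign(3))
        got = tuple(ap.to_cumulative(ds)["dropped_by"])
        assert got == expected

    @pytest.mark.parametrize(
        "exit_q,rows",
        [(2, [(1, 0), (2, 1)]), (ap.COMPLETED, [(1, 0), (2, 0), (3, 0)]), (1, [(1, 1)])],
    )
    def test_person_period_rows(self, exit_q, rows):
        ds = ap.DropoutDataset.from_records([("a", exit_q)], ap.SurveyDesign(3))
        pp = ap.to_person_period(ds)
        assert list(zip(pp["question"], pp["event"])) == rows

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_recovers_exits(self, seed):
        ds = random_dataset(np.random.default_rng(seed), n=25, K=5)
        back_c = ap.dataset_from_cumulative(ap.to_cumulative(ds), ds.design)
        back_p = ap.dataset_from_person_period(ap.to_person_period(ds), ds.design)
        for back in (back_c, back_p):
            assert dict(back.records()) == dict(ds.records())


class TestSummarize:
    def test_conditional_hand_count(self, small_dataset):
        s = ap.summarize(small_dataset, mode="conditional")
        assert s.n_at_risk.tolist() == [10, 8, 6]
        assert s.n_dropped.tolist() == [2, 2, 0]
        np.testing.assert_allclose(s.proportion, [0.2, 0.25, 0.0])

    def test_marginal_hand_count(self, small_dataset):
        s = ap.summarize(small_dataset, mode="marginal")
        np.testing.assert_allclose(s.proportion, [0.2, 0.2, 0.0])

    def test_no_dropout_gives_zero_proportions(self):
        ds = ap.DropoutDataset.from_records(
            [(i, ap.COMPLETED) for i in range(4)], ap.SurveyDesign(3)
        )
        np.testing.assert_allclose(ap.summarize(ds).proportion, 0.0)

    def test_zero_at_risk_is_undefined_not_zero(self):
        ds = ap.DropoutDataset.from_records([("a", 1), ("b", 1)], ap.SurveyDesign(3))
        s = ap.summarize(ds)
        assert s.proportion[0] == 1.0 and np.isnan(s.proportion[1:]).all()

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_and_hazard_identity(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n=30, K=5)
        s = ap.summarize(ds)
        assert s.n_dropped.sum() + int(ds.completed.sum()) == ds.n_participants
        assert np.all(s.n_at_risk[1:] == s.n_at_risk[:-1] - s.n_dropped[:-1])
        # conditional proportion == brute-force per-question hazard
        exits = dict(ds.records())
        for q in range(1, 6):
            at_risk = [p for p, e in exits.items() if e == ap.COMPLETED or e >= q]
            dropped = [p for p, e in exits.items() if e == q]
            if at_risk:
                assert s.proportion[q - 1] == pytest.approx(len(dropped) / len(at_risk))


class TestCsvInterfaces:
    def test_records_round_trip(self, small_dataset):
        buf = io.StringIO()
        ap.write_records_csv(small_dataset, buf)
        buf.seek(0)
        back = ap.read_records_csv(buf, small_dataset.design)
        assert dict(back.records()) == {str(k): v for k, v in small_dataset.records()}

    def test_person_period_round_trip(self, small_dataset):
        buf = io.StringIO()
        ap.write_person_period_csv(small_dataset, buf)
        buf.seek(0)
        back = ap.read_person_period_csv(buf, small_dataset.design)
        assert dict(back.records()) == {str(k): v for k, v in small_dataset.records()}

    def test_wide_csv_blank_cells_are_unanswered(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("participant_id,Q1,Q2,Q3\na,x,y,z\nb,x,,\n")
        ds = ap.read_wide_csv(p)
        assert ds.design.n_questions == 3
        assert dict(ds.records()) == {"a": ap.COMPLETED, "b": 2}

    def test_format_sniffing(self, tmp_path):
        cases = {
            "r.csv": ("participant_id,exit_question\na,2\n", "records"),
            "p.csv": ("participant_id,question,event\na,1,0\n", "person-period"),
            "w.csv": ("participant_id,Q1,Q2,Q3\na,1,2,3\n", "wide"),
        }
        for name, (text, expected) in cases.items():
            f = tmp_path / name
            f.write_text(text)
            assert sniff_format(f) == expected


def test_design_requires_two_questions():
    with pytest.raises(ValueError):
        ap.SurveyDesign(1)
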