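"""Cohort aggregation, quantiles, and trial CSV I/O."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialfragility import (
    CsvSchemaError,
    EndpointRank,
    NonOneToOneError,
    builtin_table1,
    load_trials_csv,
    quantile,
    summarize_cohort,
    summary_as_dict,
    write_summary,
    write_trials_csv,
)
from .conftest import TABLE1_EXPECTED_FI


def weibull_quantile_oracle(values, q):
    """Brute-force (n+1)-position linear interpolation on a sorted copy."""
    xs = sorted(values)
    n = len(xs)
    pos = (n + 1) * q
    if pos <= 1:
        return xs[0]
    if pos >= n:
        return xs[-1]
    lo = int(pos)
    frac = pos - lo
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1])


class TestBuiltinCohort:
    def test_six_records_with_expected_totals(self):
        records = builtin_table1()
        assert len(records) == 6
        by_label = {r.study_label: r for r in records}
        assert by_label["Wang Z"].table.grand_total == 280
        assert by_label["SILIUS"].table.experimental.events == 37
        assert by_label["Geissler EK"].endpoint_rank is EndpointRank.SECONDARY
        assert all(r.allocation_ratio == "1:1" for r in records)
        assert sum(r.endpoint_rank is EndpointRank.PRIMARY for r in records) == 5

    def test_reported_p_is_metadata_only(self):
        by_label = {r.study_label: r for r in builtin_table1()}
        # Wang's published 0.011 is a log-rank p; the Fisher baseline differs
        assert by_label["Wang Z"].reported_p == pytest.approx(0.011)
        assert by_label["Geissler EK"].reported_p is None


class TestQuantile:
    @pytest.mark.parametrize(
        "values, q, expected",
        [
            ([0, 0, 0, 1, 7, 19], 0.5, 0.5),
            ([0, 0, 0, 1, 7, 19], 0.25, 0.0),
            ([0, 0, 0, 1, 7, 19], 0.75, 10.0),  # position 5.25: 7 + 0.25*12
            ([205, 226, 234, 280, 508, 602], 0.5, 257.0),
            ([205, 226, 234, 280, 508, 602], 0.25, 220.75),
            ([42], 0.0, 42.0),
            ([42], 0.9, 42.0),
            ([3, 1], 0.0, 1.0),  # position below 1 clamps
            ([3, 1], 1.0, 3.0),
        ],
    )
    def test_point_values(self, values, q, expected):
        assert quantile(values, q) == pytest.approx(expected, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            quantile([], 0.5)
        with pytest.raises(ValueError):
            quantile([1.0], 1.5)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, values, q):
        assert quantile(values, q) == pytest.approx(
            weibull_quantile_oracle(values, q), rel=1e-12, abs=1e-9
        )


class TestSummarizeCohort:
    def test_cohort_summary_statistics(self):
        s = summarize_cohort(builtin_table1())
        assert s.n_trials == 6
        assert s.median_fi == pytest.approx(0.5)
        assert s.fi_iqr == pytest.approx((0.0, 10.0))
        assert s.median_n == pytest.approx(257.0)
        assert s.n_iqr[0] == pytest.approx(220.75)
        assert s.n_fi_zero_primary == 3

    def test_per_trial_results_keyed_correctly(self):
        s = summarize_cohort(builtin_table1())
        fis = {rec.study_label: res.fragility_index for rec, res in s.per_trial}
        assert fis == TABLE1_EXPECTED_FI

    def test_permutation_invariant(self):
        records = builtin_table1()
        rng = np.random.default_rng(0)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a, b = summarize_cohort(records), summarize_cohort(shuffled)
        assert (a.median_fi, a.fi_iqr, a.median_n, a.n_iqr, a.n_fi_zero_primary) == (
            b.median_fi, b.fi_iqr, b.median_n, b.n_iqr, b.n_fi_zero_primary
        )

    def test_non_1to1_record_rejected_by_name(self):
        records = builtin_table1()
        bad = records[2].__class__(**{**records[2].__dict__, "allocation_ratio": "2:1"})
        with pytest.raises(NonOneToOneError, match="Lee JH"):
            summarize_cohort(records[:2] + [bad])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestCsvIO:
    def test_round_trip_identity(self, tmp_path):
        records = builtin_table1()
        out = tmp_path / "trials.csv"
        write_trials_csv(records, out)
        assert load_trials_csv(out) == records

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study_label,exp_total\nfoo,10\n")
        with pytest.raises(CsvSchemaError, match="missing required columns"):
            load_trials_csv(p)

    def test_events_exceeding_total_names_the_line(self, tmp_path):
        records = builtin_table1()
        out = tmp_path / "trials.csv"
        write_trials_csv(records, out)
        lines = out.read_text().splitlines()
        lines[3] = lines[3].replace(",114,69,", ",114,9999,")
        out.write_text("\n".join(lines) + "\n")
        with pytest.raises(CsvSchemaError, match="line 4"):
            load_trials_csv(out)

    def test_bad_endpoint_rank_rejected(self, tmp_path):
        records = builtin_table1()
        out = tmp_path / "trials.csv"
        write_trials_csv(records, out)
        txt = out.read_text().replace("primary", "exploratory", 1)
        out.write_text(txt)
        with pytest.raises(CsvSchemaError, match="line 2"):
            load_trials_csv(out)

    def test_write_summary_json_and_csv(self, tmp_path):
        s = summarize_cohort(builtin_table1())
        jpath, cpath = tmp_path / "s.json", tmp_path / "s.csv"
        write_summary(s, jpath, format="json")
        write_summary(s, cpath, format="csv")
        doc = json.loads(jpath.read_text())
        assert doc["median_fi"] == 0.5
        assert doc["n_fi_zero_primary"] == 3
        assert len(doc["per_trial"]) == 6
        wang = next(r for r in doc["per_trial"] if r["study_label"] == "Wang Z")
        assert wang["fi"] == 19 and wang["fq_percent"] == "6.79%"
        header = cpath.read_text().splitlines()[0]
        for col in ("fi", "fq_percent", "baseline_p", "converged"):
            assert col in header.split(",")
        with pytest.raises(ValueError):
            write_summary(s, tmp_path / "s.xml", format="xml")

    def test_summary_dict_shape(self):
        doc = summary_as_dict(summarize_cohort(builtin_table1()))
        assert doc["n_trials"] == 6 and doc["fi_iqr"] == [0.0, 10.0]
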