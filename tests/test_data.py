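"""Data preparation: censoring substitution, trimming, exclusion, summaries, IO."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpexposure.data import (
    ConcentrationRecord,
    ConsumptionRecord,
    exclude_incomplete,
    frame_to_concentration,
    concentration_to_frame,
    consumption_to_frame,
    frame_to_consumption,
    read_concentration_csv,
    read_consumption_csv,
    substitute_censored,
    summarize,
    trim_implausible,
    write_concentration_csv,
    write_consumption_csv,
)


class TestSubstituteCensored:
    def test_half_lod_for_censored_sccp(self, censored_sccp_record):
        (out,) = substitute_censored([censored_sccp_record])
        assert out.value == 16.0
        assert out.censored is True  # flag retained for censoring-rate reporting

    def test_uncensored_record_unchanged(self):
        rec = ConcentrationRecord("s2", "corn", "SCCP", 283.0, False, 32.0)
        assert substitute_censored([rec]) == [rec]

    def test_batch_of_censored_mccp_records(self):
        recs = [
            ConcentrationRecord(f"m{i}", "soybean", "MCCP", None, True, 16.0)
            for i in range(10)
        ]
        out = substitute_censored(recs)
        assert len(out) == 10
        assert np.mean([r.value for r in out]) == 8.0

    def test_custom_fraction(self, censored_sccp_record):
        (out,) = substitute_censored([censored_sccp_record], fraction=1.0)
        assert out.value == 32.0

    def test_invalid_lod_rejected_with_sample_id(self):
        with pytest.raises(ValueError, match="bad-sample"):
            ConcentrationRecord("bad-sample", "corn", "SCCP", None, True, 0.0)

    @given(
        lods=st.lists(st.floats(0.1, 1000), min_size=1, max_size=20),
        fraction=st.floats(0.1, 1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_idempotent(self, lods, fraction):
        recs = [
            ConcentrationRecord(f"s{i}", "corn", "SCCP", None, True, lod)
            for i, lod in enumerate(lods)
        ]
        once = substitute_censored(recs, fraction)
        twice = substitute_censored(once, fraction)
        assert once == twice


class TestTrimImplausible:
    def test_matches_bruteforce_percentile_filter(self, uniform_intake_records):
        out = trim_implausible(uniform_intake_records, 1, 99)
        intakes = np.array([r.intake for r in uniform_intake_records])
        lo, hi = np.percentile(intakes, 1), np.percentile(intakes, 99)
        survivors = [r for r in uniform_intake_records if lo <= r.intake <= hi]
        assert out == survivors
        assert len(out) < len(uniform_intake_records)

    def test_identical_intakes_untouched(self):
        recs = [
            ConsumptionRecord(f"i{k}", "corn", 10.0, 60.0, "M", 30.0) for k in range(20)
        ]
        assert trim_implausible(recs) == recs

    def test_full_range_is_identity(self, uniform_intake_records):
        assert trim_implausible(uniform_intake_records, 0, 100) == uniform_intake_records

    def test_percentiles_computed_per_oil_type(self):
        # oil B's extreme values must not shift oil A's trimming bounds
        a = [ConsumptionRecord(f"a{k}", "corn", float(k), 60.0, "F", 30.0) for k in range(1, 101)]
        b = [ConsumptionRecord(f"b{k}", "sesame", 1000.0 * k, 60.0, "F", 30.0) for k in range(1, 101)]
        out = trim_implausible(a + b, 1, 99)
        out_a = [r for r in out if r.oil_type == "corn"]
        assert out_a == trim_implausible(a, 1, 99)

    def test_interior_values_never_removed(self, uniform_intake_records):
        out = trim_implausible(uniform_intake_records, 5, 95)
        intakes = np.array([r.intake for r in uniform_intake_records])
        lo, hi = np.percentile(intakes, 5), np.percentile(intakes, 95)
        kept = {r.individual_id for r in out}
        for r in uniform_intake_records:
            if lo <= r.intake <= hi:
                assert r.individual_id in kept

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trim_implausible([])


class TestExcludeIncomplete:
    def test_missing_body_weight_drops_individual(self):
        recs = [
            ConsumptionRecord("i1", "corn", 10.0, None, "F", 30.0),
            ConsumptionRecord("i1", "peanut", 5.0, 60.0, "F", 30.0),
            ConsumptionRecord("i2", "corn", 10.0, 60.0, "M", 40.0),
        ]
        out = exclude_incomplete(recs)
        assert {r.individual_id for r in out} == {"i2"}

    def test_complete_table_is_identity(self, uniform_intake_records):
        assert exclude_incomplete(uniform_intake_records) == uniform_intake_records

    def test_mixed_table_enumeration(self):
        recs = []
        for i in range(5):
            sex = None if i == 1 else "F"
            age = None if i == 3 else 30.0
            recs.append(ConsumptionRecord(f"i{i}", "corn", 10.0, 60.0, sex, age))
        out = exclude_incomplete(recs)
        assert {r.individual_id for r in out} == {"i0", "i2", "i4"}


class TestSummarize:
    def test_basic_statistics(self):
        s = summarize([1, 2, 3])
        assert (s.mean, s.median, s.min, s.max, s.n) == (2, 2, 1, 3, 3)

    def test_single_value(self):
        s = summarize([5], percentiles=(50, 95))
        assert s.mean == s.median == s.min == s.max == s.p95 == 5

    def test_lognormal_moments_close_to_closed_form(self, rng):
        mu, sigma, n = 1.0, 0.4, 1000
        draws = rng.lognormal(mu, sigma, n)
        s = summarize(draws)
        true_mean = math.exp(mu + sigma**2 / 2)
        true_var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        se_mean = math.sqrt(true_var / n)
        assert abs(s.mean - true_mean) < 3 * se_mean
        # median SE via asymptotic order-statistic variance at the median
        true_median = math.exp(mu)
        f_med = math.exp(-((math.log(true_median) - mu) ** 2) / (2 * sigma**2)) / (
            true_median * sigma * math.sqrt(2 * math.pi)
        )
        se_med = 1.0 / (2 * f_med * math.sqrt(n))
        assert abs(s.median - true_median) < 3 * se_med

    def test_permutation_invariant(self, rng):
        vals = rng.random(50).tolist()
        shuffled = list(vals)
        rng.shuffle(shuffled)
        assert summarize(vals) == summarize(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestCsvRoundTrip:
    def test_concentration_round_trip(self, tmp_path, censored_sccp_record):
        recs = [
            censored_sccp_record,
            ConcentrationRecord("s2", "corn", "MCCP", 120.5, False, 16.0),
        ]
        path = tmp_path / "conc.csv"
        write_concentration_csv(recs, path)
        assert read_concentration_csv(path) == recs

    def test_consumption_round_trip(self, tmp_path):
        recs = [
            ConsumptionRecord("i1", "corn", 10.0, 60.0, "F", 30.0),
            ConsumptionRecord("i2", "sesame", 0.0, 55.5, None, None),
        ]
        path = tmp_path / "cons.csv"
        write_consumption_csv(recs, path)
        assert read_consumption_csv(path) == recs

    def test_nd_marker_read_as_censored(self, tmp_path):
        path = tmp_path / "conc.csv"
        path.write_text(
            "sample_id,oil_type,analyte,value,censored,lod\n"
            "s1,corn,SCCP,ND,True,32\n"
        )
        (rec,) = read_concentration_csv(path)
        assert rec.censored and rec.value is None

    def test_frame_round_trip_preserves_fields(self):
        recs = [ConsumptionRecord("i1", "corn", 1.25, 61.0, "M", 44.0)]
        assert frame_to_consumption(consumption_to_frame(recs)) == recs
        crecs = [ConcentrationRecord("s1", "corn", "SCCP", 55.0, False, 32.0)]
        assert frame_to_concentration(concentration_to_frame(crecs)) == crecs
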