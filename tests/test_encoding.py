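"""Time-period mapping, dummy coding, vocabulary and token encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrisk.encoding import (
    EncodingError, LookbackError, TimePeriodScheme, age_at, build_static_codec,
    build_vocabulary, encode_static, encode_temporal, period_of,
)
from tests.conftest import make_events, make_patients

INDEX = pd.Timestamp("2015-06-01")


def brute_force_period(days_prior: int) -> int | None:
    """Independent interval-list oracle for the 21-period scheme."""
    if days_prior < 7:
        return None
    intervals = [(7 + 180 * k, 7 + 180 * (k + 1) - 1, k + 1) for k in range(20)]
    for lo, hi, period in intervals:
        if lo <= days_prior <= hi:
            return period
    return 21


class TestPeriodOf:
    @pytest.mark.parametrize("days_prior,expected", [
        (0, None), (3, None), (6, None),          # 7-day buffer
        (7, 1), (186, 1), (187, 2),               # slide boundaries
        (3606, 20), (3607, 21), (4500, 21),       # remote history
    ])
    def test_boundaries(self, days_prior, expected):
        event = INDEX - pd.Timedelta(days=days_prior)
        assert period_of(event, INDEX) == expected

    def test_event_after_index_raises(self):
        with pytest.raises(LookbackError):
            period_of(INDEX + pd.Timedelta(days=1), INDEX)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=8000))
    def test_partition_matches_interval_oracle(self, days_prior):
        """The 21-period map tiles [7, inf) with no gaps or overlaps."""
        event = INDEX - pd.Timedelta(days=days_prior)
        assert period_of(event, INDEX) == brute_force_period(days_prior)


class TestAge:
    def test_exact_birthday(self):
        assert age_at("1950-06-01", "2015-06-01") == 65.0

    def test_fractional(self):
        assert age_at("1950-06-01", "2015-12-01") == pytest.approx(65.5, abs=0.01)

    def test_leap_day_birth(self):
        assert age_at("1952-02-29", "2015-03-01") == pytest.approx(63.0, abs=0.01)


class TestStaticCodec:
    def patients(self):
        rows = []
        levels = ["Married"] * 5 + ["Divorced"] * 3 + ["Single"] * 2 + \
                 ["Widowed", "Separated", "Unknown"]
        for i, m in enumerate(levels):
            rows.append({"id": f"p{i}", "marital_status": m,
                         "lgbt_status": "Unknown" if i else "Yes"})
        return make_patients(rows)

    def test_n_minus_one_indicators(self):
        codec = build_static_codec(self.patients(), ["marital_status"])
        # six levels -> five indicator columns after the age column
        assert len(codec.columns) == 1 + 5
        assert codec.levels["marital_status"][0] == "Married"  # reference = modal level

    def test_reference_category_encodes_all_zeros(self):
        pats = self.patients()
        codec = build_static_codec(pats, ["marital_status"])
        vec = encode_static(pats.iloc[0], INDEX, codec)
        assert np.all(vec[1:] == 0)

    def test_dummy_round_trip(self):
        pats = self.patients()
        codec = build_static_codec(pats, ["marital_status", "lgbt_status"])
        for _, row in pats.iterrows():
            vec = encode_static(row, INDEX, codec)
            assert codec.decode("marital_status", vec) == row["marital_status"]
            assert codec.decode("lgbt_status", vec) == row["lgbt_status"]

    def test_unseen_category_rejected_with_names(self):
        pats = self.patients()
        codec = build_static_codec(pats, ["marital_status"])
        alien = pats.iloc[0].copy()
        alien["marital_status"] = "Betrothed"
        with pytest.raises(EncodingError, match="marital_status.*Betrothed"):
            encode_static(alien, INDEX, codec)


class TestVocabulary:
    def events_with_prevalence(self, code, k, n=1000):
        rows = [(f"p{i}", code, "2014-01-01") for i in range(k)]
        rows += [(f"p{i}", "depression", "2014-01-01") for i in range(50)]
        return make_events(rows), [f"p{i}" for i in range(n)]

    @pytest.mark.parametrize("carriers,included", [(4, False), (5, True), (6, True)])
    def test_drug_prevalence_threshold_inclusive(self, carriers, included):
        events, cohort = self.events_with_prevalence("ssri_fill", carriers)
        vocab = build_vocabulary(events, cohort, drug_features={"ssri_fill"})
        assert ("ssri_fill" in vocab.code_to_id) is included

    def test_rare_diagnosis_kept(self):
        events, cohort = self.events_with_prevalence("rare_dx", 1)
        vocab = build_vocabulary(events, cohort, drug_features={"ssri_fill"})
        assert "rare_dx" in vocab.code_to_id

    def test_outpatient_visits_not_features(self):
        events = make_events([("p0", "outpatient_visit", "2014-01-01"),
                              ("p0", "depression", "2014-01-01")])
        vocab = build_vocabulary(events, ["p0"])
        assert "outpatient_visit" not in vocab.code_to_id

    def test_empty_cohort_rejected(self):
        with pytest.raises(EncodingError):
            build_vocabulary(make_events([]), [])

    def test_csv_round_trip(self, tmp_path):
        events, cohort = self.events_with_prevalence("ssri_fill", 10)
        vocab = build_vocabulary(events, cohort, drug_features={"ssri_fill"})
        vocab.to_csv(tmp_path / "vocab.csv")
        from ehrisk.encoding import FeatureVocabulary
        again = FeatureVocabulary.from_csv(tmp_path / "vocab.csv")
        assert again.code_to_id == vocab.code_to_id


class TestEncodeTemporal:
    def vocab(self):
        from ehrisk.encoding import FeatureVocabulary
        return FeatureVocabulary(code_to_id={"depression": 1, "anxiety": 2})

    def test_presence_semantics_deduplicates(self):
        events = make_events([("p0", "depression", "2015-05-01"),
                              ("p0", "depression", "2015-04-15")])  # same period
        tokens = encode_temporal(events, INDEX, self.vocab())
        assert tokens == [(1, 1)]

    def test_same_feature_two_periods_two_tokens(self):
        events = make_events([("p0", "depression", "2015-05-01"),
                              ("p0", "depression", "2000-01-01")])
        tokens = encode_temporal(events, INDEX, self.vocab())
        assert tokens == [(1, 1), (1, 21)]

    def test_empty_and_buffer_only(self):
        assert encode_temporal(make_events([]), INDEX, self.vocab()) == []
        events = make_events([("p0", "depression", "2015-05-30")])  # 2 days prior
        assert encode_temporal(events, INDEX, self.vocab()) == []

    def test_order_invariance(self):
        rows = [("p0", "depression", "2015-05-01"), ("p0", "anxiety", "2014-01-01"),
                ("p0", "depression", "2010-02-01")]
        a = encode_temporal(make_events(rows), INDEX, self.vocab())
        b = encode_temporal(make_events(rows[::-1]), INDEX, self.vocab())
        assert a == b
        assert a == sorted(a, key=lambda t: (t[1], t[0]))  # sorted by (period, feature)

    def test_cap_drops_oldest_periods(self):
        rows = [("p0", "depression", str(INDEX - pd.Timedelta(days=7 + 180 * k)))
                for k in range(20)]
        tokens = encode_temporal(make_events(rows), INDEX, self.vocab(), max_tokens=5)
        assert [p for _, p in tokens] == [1, 2, 3, 4, 5]
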