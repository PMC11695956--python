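"""PSQI component scoring against an independently transcribed scoring table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxiscreen import (
    FULL_FEATURE_NAMES,
    TOP5_FEATURE_NAMES,
    QuestionnaireRecord,
    encode_full,
    encode_top5,
    score_psqi,
)
from oxiscreen.questionnaire import ITEM_KEYS


def items(**overrides):
    """A benign baseline questionnaire: asleep fast, 8 h of 8.5 h in bed."""
    base = {
        "1": "22:30", "2": 10.0, "3": "07:00", "4": 8.0,
        **{f"5_{i}": 0.0 for i in range(1, 11)},
        "6": 0.0, "7": 0.0, "8": 0.0, "9": 0.0,
    }
    base.update(overrides)
    return base


# ------------------------- independent transcription of the scoring table


def oracle_components(latency_min, q5_1, hours, in_bed_h, disturb_sum, q6, q7, q8, q9):
    if latency_min <= 15:
        lat = 0
    elif latency_min <= 30:
        lat = 1
    elif latency_min <= 60:
        lat = 2
    else:
        lat = 3
    lat_total = lat + q5_1
    c2 = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}[lat_total]

    if hours > 7:
        c3 = 0
    elif hours >= 6:
        c3 = 1
    elif hours >= 5:
        c3 = 2
    else:
        c3 = 3

    eff = 100.0 * hours / in_bed_h
    if eff >= 85:
        c4 = 0
    elif eff >= 75:
        c4 = 1
    elif eff >= 65:
        c4 = 2
    else:
        c4 = 3

    if disturb_sum == 0:
        c5 = 0
    elif disturb_sum <= 9:
        c5 = 1
    elif disturb_sum <= 18:
        c5 = 2
    else:
        c5 = 3

    day = q8 + q9
    c7 = {0: 0, 1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}[day]
    return (q6, c2, c3, c4, c5, q7, c7)


class TestScoring:
    def test_best_case_all_zero(self):
        s = score_psqi(items())
        assert s.components == (0, 0, 0, 0, 0, 0, 0)
        assert s.global_score == 0

    def test_worst_case_all_three(self):
        s = score_psqi(
            items(
                **{"2": 120.0, "4": 3.0, "1": "21:00", "3": "07:00"},
                **{f"5_{i}": 3.0 for i in range(1, 11)},
                **{"6": 3.0, "7": 3.0, "8": 3.0, "9": 3.0},
            )
        )
        assert s.components == (3, 3, 3, 3, 3, 3, 3)
        assert s.global_score == 21

    def test_published_worked_example(self):
        # fairly-good quality, 45-min latency with twice-weekly trouble,
        # 6 h slept of 8 h in bed -> quality 1, latency 2, duration 1,
        # efficiency 75% banded 1
        s = score_psqi(items(**{"6": 1.0, "2": 45.0, "5_1": 2.0, "4": 6.0, "1": "23:00", "3": "07:00"}))
        assert s.components[0] == 1
        assert s.components[1] == 2
        assert s.components[2] == 1
        assert s.components[3] == 1

    def test_exhaustive_component_grid_matches_oracle(self):
        latencies = [0, 10, 15, 16, 30, 31, 60, 61, 120]
        hour_vals = [3.0, 4.9, 5.0, 5.9, 6.0, 7.0, 7.1]
        in_bed = 10.0  # bed 21:00, rise 07:00
        for lat in latencies:
            for q5_1 in range(4):
                for hours in hour_vals:
                    for q5x in (0, 1, 2, 3):
                        disturb = 9 * q5x
                        s = score_psqi(
                            items(
                                **{"2": float(lat), "5_1": float(q5_1), "4": hours,
                                   "1": "21:00", "3": "07:00"},
                                **{f"5_{i}": float(q5x) for i in range(2, 11)},
                            )
                        )
                        expect = oracle_components(lat, q5_1, hours, in_bed, disturb, 0, 0, 0, 0)
                        assert s.components == expect, (lat, q5_1, hours, q5x)
                        assert s.global_score == sum(expect)

    def test_daytime_and_medication_grid(self):
        for q7 in range(4):
            for q8 in range(4):
                for q9 in range(4):
                    s = score_psqi(items(**{"7": float(q7), "8": float(q8), "9": float(q9)}))
                    expect = oracle_components(10, 0, 8.0, 8.5, 0, 0, q7, q8, q9)
                    assert s.components == expect

    def test_midnight_wrap_in_bed_interval(self):
        # 23:30 to 06:30 is 7 h in bed; 6.5 h asleep -> efficiency 92.9% -> 0
        s = score_psqi(items(**{"1": "23:30", "3": "06:30", "4": 6.5}))
        assert s.components[3] == 0

    def test_missing_item_rejected(self):
        bad = items()
        del bad["5_7"]
        with pytest.raises(ValueError, match="incomplete PSQI"):
            score_psqi(bad)

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError, match="invalid times"):
            score_psqi(items(**{"1": "07:00", "3": "07:00"}))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        lat=st.floats(0, 300),
        q=st.tuples(*[st.integers(0, 3) for _ in range(14)]),
        hours=st.floats(0.5, 12),
        bed=st.floats(18, 30),
        span=st.floats(4, 12),
    )
    def test_global_score_bounds_under_fuzz(self, lat, q, hours, bed, span):
        it = items(
            **{"2": lat, "4": hours, "1": bed % 24, "3": (bed + span) % 24},
            **{f"5_{i}": float(q[i - 1]) for i in range(1, 11)},
            **{"6": float(q[10]), "7": float(q[11]), "8": float(q[12]), "9": float(q[13])},
        )
        s = score_psqi(it)
        assert 0 <= s.global_score <= 21
        assert all(0 <= c <= 3 for c in s.components)
        assert s.global_score == sum(s.components)


def record(**kw):
    return QuestionnaireRecord(
        case_id="q1",
        sex=kw.get("sex", "male"),
        age=kw.get("age", 55.0),
        bmi=kw.get("bmi", 27.0),
        hypertension=kw.get("htn", 1),
        diabetes=0,
        cardiovascular_disease=0,
        psqi_items=items(**kw.get("items", {})),
    )


class TestEncoding:
    def test_full_vector_length_and_names(self):
        v = encode_full(record())
        assert len(v) == 32
        assert len(FULL_FEATURE_NAMES) == 32
        assert "psqi_item_5_5" in FULL_FEATURE_NAMES
        assert FULL_FEATURE_NAMES[-1] == "psqi_global"

    def test_deterministic(self):
        np.testing.assert_array_equal(encode_full(record()), encode_full(record()))

    def test_top5_subset_of_full(self):
        r = record(items={"5_5": 3.0})
        full = encode_full(r)
        top5 = encode_top5(r)
        assert len(top5) == 5
        assert top5[3] == 3.0  # snoring slot
        for name, val in zip(TOP5_FEATURE_NAMES, top5):
            assert full[FULL_FEATURE_NAMES.index(name)] == val

    def test_incomplete_record_rejected(self):
        bad = items()
        bad["6"] = float("nan")
        with pytest.raises(ValueError, match="incomplete PSQI"):
            QuestionnaireRecord(
                case_id="x", sex="female", age=40.0, bmi=22.0,
                hypertension=0, diabetes=0, cardiovascular_disease=0,
                psqi_items=bad,
            )

    def test_item_key_cover(self):
        assert len(ITEM_KEYS) == 18
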