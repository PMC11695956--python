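"""Pittsburgh Sleep Quality Index scoring and the questionnaire feature vectors.

The PSQI asks about the past month of sleep with 18 self-rated entries:
bed time (q1), minutes to fall asleep (q2), rise time (q3), hours of actual
sleep (q4), ten trouble-frequency items (q5.1-q5.10, each 0-3), subjective
quality (q6), sleeping-medication use (q7), trouble staying awake (q8) and
lack of enthusiasm (q9). Scoring follows the published instrument
(Buysse et al., 1989): seven components each on 0-3 — subjective quality,
latency, duration, habitual efficiency, disturbance, medication, daytime
dysfunction — summed into a 0-21 global score.

The screening model consumes 6 clinical features (sex, age, BMI,
hypertension, diabetes, cardiovascular disease) plus 26 PSQI features
(18 items, 7 components, global), or a reduced 5-feature form built from
the risk factors that dominate questionnaire-based apnea screening:
age, sex, BMI, self-reported snoring (q5.5) and hypertension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_KEYS",
    "QuestionnaireRecord",
    "PSQIScores",
    "score_psqi",
    "encode_full",
    "encode_top5",
    "records_from_csv",
    "FULL_FEATURE_NAMES",
    "TOP5_FEATURE_NAMES",
]

ITEM_KEYS: tuple[str, ...] = (
    "1", "2", "3", "4",
    "5_1", "5_2", "5_3", "5_4", "5_5", "5_6", "5_7", "5_8", "5_9", "5_10",
    "6", "7", "8", "9",
)

_ORDINAL_KEYS = ITEM_KEYS[4:]  # q5.x and q6-q9 are coded 0-3

COMPONENT_NAMES = (
    "quality",
    "latency",
    "duration",
    "efficiency",
    "disturbance",
    "medication",
    "daytime",
)


@dataclass
class QuestionnaireRecord:
    """One screening-form record: demographics, history and 18 PSQI items.

    ``psqi_items`` maps the keys of :data:`ITEM_KEYS` to raw responses:
    q1/q3 are clock times ("HH:MM" or fractional hours 0-24), q2 is minutes,
    q4 is hours, and the remaining 14 items are coded 0-3.
    """

    case_id: str
    sex: str  # "male" | "female"
    age: float
    bmi: float
    hypertension: int
    diabetes: int
    cardiovascular_disease: int
    psqi_items: dict[str, float | str]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        missing = [k for k in ITEM_KEYS if k not in self.psqi_items or _is_na(self.psqi_items[k])]
        if missing:
            raise ValueError(f"incomplete PSQI: missing items {missing}")
        extra = set(self.psqi_items) - set(ITEM_KEYS)
        if extra:
            raise ValueError(f"unknown PSQI items {sorted(extra)}")


def _is_na(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(float(v)))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class PSQIScores:
    """Seven component scores (each 0-3) and the 0-21 global score."""

    components: tuple[int, int, int, int, int, int, int]
    global_score: int

    def as_dict(self) -> dict[str, int]:
        d = {f"psqi_comp_{n}": c for n, c in zip(COMPONENT_NAMES, self.components)}
        d["psqi_global"] = self.global_score
        return d


def _clock_hours(v) -> float:
    """Clock time as fractional hours in [0, 24)."""
    if isinstance(v, str):
        parts = v.strip().split(":")
        try:
            h = float(parts[0])
            m = float(parts[1]) if len(parts) > 1 else 0.0
        except (ValueError, IndexError):
            raise ValueError(f"invalid clock time {v!r}") from None
        v = h + m / 60.0
    v = float(v)
    if not 0 <= v < 24:
        raise ValueError("invalid times")
    return v


def _band(value: float, cuts: tuple[float, ...]) -> int:
    """Score 0..3 from descending threshold cuts: >= cuts[i] scores i."""
    for score, cut in enumerate(cuts):
        if value >= cut:
            return score
    return len(cuts)


def score_psqi(items: dict[str, float | str]) -> PSQIScores:
    """Score the seven PSQI components per the published instrument.

    Raises ``ValueError`` for missing items, out-of-range ordinal codes, or
    a non-positive time-in-bed interval.
    """
    missing = [k for k in ITEM_KEYS if k not in items or _is_na(items[k])]
    if missing:
        raise ValueError(f"incomplete PSQI: missing items {missing}")
    ordinal = {}
    for k in _ORDINAL_KEYS:
        v = float(items[k])
        if v not in (0.0, 1.0, 2.0, 3.0):
            raise ValueError(f"item {k} must be coded 0-3, got {items[k]!r}")
        ordinal[k] = int(v)

    c1 = ordinal["6"]

    latency_min = float(items["2"])
    if latency_min < 0:
        raise ValueError("sleep latency must be non-negative")
    lat_band = 0 if latency_min <= 15 else 1 if latency_min <= 30 else 2 if latency_min <= 60 else 3
    lat_sum = lat_band + ordinal["5_1"]
    c2 = 0 if lat_sum == 0 else (lat_sum + 1) // 2

    hours = float(items["4"])
    if hours < 0:
        raise ValueError("sleep duration must be non-negative")
    c3 = 0 if hours > 7 else 1 if hours >= 6 else 2 if hours >= 5 else 3

    bed = _clock_hours(items["1"])
    rise = _clock_hours(items["3"])
    in_bed = (rise - bed) % 24
    if in_bed <= 0:
        raise ValueError("invalid times")
    efficiency = 100.0 * hours / in_bed
    c4 = _band(efficiency, (85.0, 75.0, 65.0))

    disturb = sum(ordinal[f"5_{i}"] for i in range(2, 11))
    c5 = 0 if disturb == 0 else 1 if disturb <= 9 else 2 if disturb <= 18 else 3

    c6 = ordinal["7"]

    day = ordinal["8"] + ordinal["9"]
    c7 = 0 if day == 0 else (day + 1) // 2

    comps = (c1, c2, c3, c4, c5, c6, c7)
    return PSQIScores(components=comps, global_score=sum(comps))


CLINICAL_FEATURE_NAMES = ("sex", "age", "bmi", "hypertension", "diabetes", "cardiovascular")
ITEM_FEATURE_NAMES = tuple(f"psqi_item_{k}" for k in ITEM_KEYS)
COMPONENT_FEATURE_NAMES = tuple(f"psqi_comp_{n}" for n in COMPONENT_NAMES)

FULL_FEATURE_NAMES: tuple[str, ...] = (
    CLINICAL_FEATURE_NAMES + ITEM_FEATURE_NAMES + COMPONENT_FEATURE_NAMES + ("psqi_global",)
)
TOP5_FEATURE_NAMES: tuple[str, ...] = ("age", "sex", "bmi", "psqi_item_5_5", "hypertension")


def _item_numeric(key: str, v) -> float:
    if key in ("1", "3"):
        # clock times encoded as hours since noon, so typical bed times
        # (21:00-02:00) map to a contiguous 9-14 range
        return (_clock_hours(v) - 12.0) % 24.0
    return float(v)


def encode_full(record: QuestionnaireRecord) -> np.ndarray:
    """The 32-value questionnaire feature vector.

    Order: 6 clinical values (sex male=1/female=0, age, BMI, hypertension,
    diabetes, cardiovascular disease), the 18 items, the 7 components, and
    the global score — names in :data:`FULL_FEATURE_NAMES`.
    """
    scores = score_psqi(record.psqi_items)
    clinical = [
        1.0 if record.sex == "male" else 0.0,
        float(record.age),
        float(record.bmi),
        float(record.hypertension),
        float(record.diabetes),
        float(record.cardiovascular_disease),
    ]
    items = [_item_numeric(k, record.psqi_items[k]) for k in ITEM_KEYS]
    return np.array(clinical + items + list(scores.components) + [scores.global_score], dtype=float)


def encode_top5(record: QuestionnaireRecord) -> np.ndarray:
    """The reduced 5-feature vector: age, sex, BMI, snoring (q5.5), hypertension."""
    full = encode_full(record)
    idx = [FULL_FEATURE_NAMES.index(n) for n in TOP5_FEATURE_NAMES]
    return full[idx]


_CSV_ITEM_COLS = {f"psqi_{k}": k for k in ITEM_KEYS}


def records_from_csv(path) -> list[QuestionnaireRecord]:
    """Load questionnaire records from the documented CSV schema.

    Columns: ``case_id, sex, age, bmi, htn, dm, cvd`` and raw item columns
    ``psqi_1 .. psqi_9`` (with ``psqi_5_1 .. psqi_5_10``). ``sex`` accepts
    male/female or 1/0.
    """
    df = pd.read_csv(path)
    needed = ["case_id", "sex", "age", "bmi", "htn", "dm", "cvd", *_CSV_ITEM_COLS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"questionnaire CSV missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        sex = row["sex"]
        if not isinstance(sex, str):
            sex = "male" if float(sex) == 1 else "female"
        records.append(
            QuestionnaireRecord(
                case_id=str(row["case_id"]),
                sex=sex.strip().lower(),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                hypertension=int(row["htn"]),
                diabetes=int(row["dm"]),
                cardiovascular_disease=int(row["cvd"]),
                psqi_items={k: row[c] for c, k in _CSV_ITEM_COLS.items()},
            )
        )
    return records
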