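"""Score a PSQI questionnaire and build the screening feature vectors.

The record below describes a typical referred snorer: hypertensive man in
his fifties, loud snoring most nights, but falls asleep fast and sleeps
through — so the insomnia-flavoured components (latency, quality) stay
low while the apnea risk factors are prominent.
"""

from oxiscreen import QuestionnaireRecord, encode_full, encode_top5, score_psqi
from oxiscreen.questionnaire import TOP5_FEATURE_NAMES

record = QuestionnaireRecord(
    case_id="clinic-0042",
    sex="male",
    age=56,
    bmi=31.2,
    hypertension=1,
    diabetes=0,
    cardiovascular_disease=0,
    psqi_items={
        "1": "23:00",   # usual bed time
        "2": 10,        # minutes to fall asleep
        "3": "06:30",   # usual rise time
        "4": 6.5,       # hours actually slept
        "5_1": 0, "5_2": 1, "5_3": 2, "5_4": 2,
        "5_5": 3,       # coughs or snores loudly, 3+ times a week
        "5_6": 0, "5_7": 0, "5_8": 0, "5_9": 1, "5_10": 0,
        "6": 1, "7": 0, "8": 2, "9": 1,
    },
)

scores = score_psqi(record.psqi_items)
names = ("quality", "latency", "duration", "efficiency", "disturbance", "medication", "daytime")
for name, comp in zip(names, scores.components):
    print(f"  component {name:<12} {comp}")
print(f"  global PSQI score      {scores.global_score}  (0-21; >5 marks a poor sleeper)")

full = encode_full(record)
top5 = encode_top5(record)
print(f"\nfull feature vector: {len(full)} values")
print("reduced screening vector:", dict(zip(TOP5_FEATURE_NAMES, top5)))
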