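"""Run the whole two-model screening study on a synthetic cohort.

Simulates a clinic-style cohort, extracts questionnaire and oximetry
features, makes a 70/15/15 stratified split, SMOTE-balances the training
partition, trains both classifiers (picking the best of gradient
boosting / random forest / extra trees on the validation set), and runs
the sequential triage over the held-out test cases: questionnaire first,
oximetry grading only for cases flagged as OSA.

A 200-case cohort keeps this demo around a minute; the packaged
acceptance run uses 600 cases.
"""

from dataclasses import replace

from oxiscreen import PRESETS, run_screening_study

params = replace(PRESETS["clinic"], n_cases=200)
res = run_screening_study(params, seed=2)

q, s = res.questionnaire_report, res.saturation_report
print(f"stage 1 (insomnia vs OSA, {res.model_q.algorithm}): "
      f"accuracy {q.accuracy:.3f}, weighted F1 {q.weighted['f1']:.3f}, AUC {q.auc:.3f}")
print(f"stage 2 (severity grading, {res.model_s.algorithm}):  "
      f"accuracy {s.accuracy:.3f}, weighted F1 {s.weighted['f1']:.3f}")
print(f"ODI split-count importance rank: {res.odi_importance_rank + 1} of 128")

n_stage2 = sum(1 for t in res.triage if t.stage2 is not None)
print(f"\ntriage: {len(res.triage)} test cases, {n_stage2} routed to oximetry grading")
for t in res.triage[:5]:
    print(f"  {t.case_id}: stage1={t.stage1} (p_osa={t.p_osa:.2f}) -> {t.final_category}")
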