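"""End-to-end screening study on a synthetic cohort.

Ties the whole package together the way the screening tool is meant to be
used: simulate (or load) a cohort, clean every overnight trace, extract
the 128 oximetry features and the 32 questionnaire features, make one
case-level 70/15/15 stratified split, balance the training partition with
SMOTE, train the two classifiers, run the sequential triage over the
held-out test cases and score everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, models, questionnaire, screening, synthetic
from .oximetry_features import extract_all, feature_names
from .preprocess import PreprocessConfig, clean

__all__ = ["StudyResult", "extract_cohort_features", "run_screening_study"]

SEVERITY_CLASSES = ("none", "mild", "moderate_severe")
STAGE1_CLASSES = ("primary_insomnia", "osa")


@dataclass
class StudyResult:
    """Everything a screening study produces."""

    model_q: models.ModelBundle
    model_s: models.ModelBundle
    questionnaire_report: evaluation.EvalReport
    saturation_report: evaluation.EvalReport
    triage: list = field(default_factory=list)
    test_case_ids: list = field(default_factory=list)
    odi_importance_rank: int = -1


def extract_cohort_features(cohort: synthetic.SyntheticCohort, preprocess_config=None):
    """Clean every trace and build the two feature matrices.

    Returns ``(Xq, y_stage1, Xs, y_severity)`` aligned on case order.
    """
    cfg = preprocess_config or PreprocessConfig()
    Xq, Xs, y1, ys = [], [], [], []
    for case in cohort.cases:
        Xq.append(questionnaire.encode_full(case.questionnaire))
        Xs.append(extract_all(clean(case.record, cfg)).vector())
        y1.append("osa" if case.stage1 == "osa" else "primary_insomnia")
        ys.append(case.severity)
    return np.array(Xq), np.array(y1), np.array(Xs), np.array(ys)


def _fit_task(task, X, y, tr, va, algo, names, seed, smote_k):
    """Train one task; ``algo="auto"`` tries all three ensembles and keeps
    the one with the best validation weighted F1 (first wins ties)."""
    Xb, yb = models.smote_oversample(X[tr], y[tr], k=smote_k, seed=seed)
    candidates = models.ALGORITHMS if algo == "auto" else (algo,)
    best = None
    best_f1 = -1.0
    for a in candidates:
        bundle = models.train_classifier(
            (Xb, yb), (X[va], y[va]), a, seed=seed, task=task, feature_names=names
        )
        classes = sorted(np.unique(y))
        rep = evaluation.evaluate(y[va], bundle.predict(X[va]), classes=classes)
        bundle.metadata["valid_weighted_f1"] = rep.weighted["f1"]
        if rep.weighted["f1"] > best_f1:
            best, best_f1 = bundle, rep.weighted["f1"]
    return best


def run_screening_study(
    params: synthetic.SimParams | None = None,
    seed: int = 1,
    algo_questionnaire: str = "auto",
    algo_saturation: str = "auto",
    smote_k: int = 5,
) -> StudyResult:
    """Simulate a cohort and run the full two-model screening study.

    One case-level split (stratified on severity, which refines the
    stage-1 label) feeds both models, so the held-out 15% is a genuinely
    independent test set for the sequential flow. With the default
    ``"auto"`` each task trains gradient boosting, random forest and
    extra trees and keeps the algorithm with the best validation weighted
    F1, mirroring how a screening study would pick its production model.
    Deterministic for fixed seed and parameters.
    """
    p = params or synthetic.SimParams()
    cohort = synthetic.simulate_cohort(p, seed=seed)
    Xq, y1, Xs, ys = extract_cohort_features(cohort)

    idx = np.arange(len(cohort.cases))
    (tr, _), (va, _), (te, _) = models.stratified_split(idx, ys, seed=seed)

    model_q = _fit_task(
        "questionnaire_binary", Xq, y1, tr, va, algo_questionnaire,
        list(questionnaire.FULL_FEATURE_NAMES), seed, smote_k,
    )
    model_s = _fit_task(
        "saturation_3class", Xs, ys, tr, va, algo_saturation,
        feature_names(), seed, smote_k,
    )

    cases = [
        {
            "case_id": cohort.cases[int(i)].case_id,
            "questionnaire": Xq[int(i)],
            "saturation_features": Xs[int(i)],
        }
        for i in te
    ]
    triage = screening.sequential_screen(cases, model_q, model_s)

    q_report = evaluation.evaluate(
        y1[te],
        model_q.predict(Xq[te]),
        classes=list(STAGE1_CLASSES),
        scores=model_q.predict_proba(Xq[te])[:, list(model_q.classes).index("osa")],
    )
    proba_s = model_s.predict_proba(Xs[te])
    col = [list(model_s.classes).index(c) for c in SEVERITY_CLASSES]
    s_report = evaluation.evaluate(
        ys[te],
        model_s.predict(Xs[te]),
        classes=list(SEVERITY_CLASSES),
        scores=proba_s[:, col],
    )
    ranked = [name for name, _ in models.feature_importance(model_s)]
    return StudyResult(
        model_q=model_q,
        model_s=model_s,
        questionnaire_report=q_report,
        saturation_report=s_report,
        triage=triage,
        test_case_ids=[c["case_id"] for c in cases],
        odi_importance_rank=ranked.index("odi"),
    )
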