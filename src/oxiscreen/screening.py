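"""AHI severity labelling and the sequential two-model triage flow.

Stage 1 applies the questionnaire model to every case, separating primary
insomnia from suspected OSA. Stage 2 applies the saturation model to the
overnight oximetry of the suspected-OSA cases only, grading them into
none / mild / moderate-severe. Cases triaged as insomnia never reach
stage 2, which is the point of the sequence: the cheap questionnaire
filters, the oximetry analysis grades.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .models import ModelBundle
from .oximetry_features import FeatureConfig, extract_all

__all__ = [
    "SeverityLabel",
    "TriageResult",
    "label_severity",
    "sequential_screen",
    "SEVERITY_ORDER",
]


class SeverityLabel(str, Enum):
    """Apnea severity from the AHI: <5 none, 5-15 mild, >=15 moderate-severe."""

    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


SEVERITY_ORDER = (SeverityLabel.NONE, SeverityLabel.MILD, SeverityLabel.MODERATE_SEVERE)


def label_severity(ahi: float) -> SeverityLabel:
    """Severity class from an apnea-hypopnea index in events/hour."""
    if ahi < 0:
        raise ValueError("invalid AHI")
    if ahi < 5:
        return SeverityLabel.NONE
    if ahi < 15:
        return SeverityLabel.MILD
    return SeverityLabel.MODERATE_SEVERE


@dataclass
class TriageResult:
    """Per-case outcome of the sequential screen.

    ``stage2`` (and its probabilities) are present exactly when stage 1
    predicted OSA; the final category is ``stage2`` then, else
    "primary_insomnia".
    """

    case_id: str
    stage1: str  # "primary_insomnia" | "osa"
    p_osa: float
    stage2: SeverityLabel | None = None
    stage2_proba: dict[str, float] | None = None

    @property
    def final_category(self) -> str:
        return self.stage2.value if self.stage2 is not None else "primary_insomnia"


def _severity_argmax(proba: np.ndarray, classes) -> SeverityLabel:
    """Most probable severity; ties resolve toward the more severe class,
    since a screen must not miss moderate-severe disease."""
    order = {c.value: i for i, c in enumerate(SEVERITY_ORDER)}
    best = max(
        range(len(classes)),
        key=lambda i: (proba[i], order.get(str(classes[i]), -1)),
    )
    return SeverityLabel(str(classes[best]))


def sequential_screen(
    cases: list[dict],
    model_q: ModelBundle,
    model_s: ModelBundle,
    threshold: float = 0.5,
    feature_config: FeatureConfig | None = None,
) -> list[TriageResult]:
    """Run the two-stage screen over a batch of cases.

    Each case is a dict with ``case_id``, ``questionnaire`` (feature vector
    matching ``model_q``) and, for any case the questionnaire model routes
    to stage 2, either ``signal`` (a :class:`CleanSignal`) or
    ``saturation_features`` (a precomputed 128-vector). Stage 1 calls a
    case OSA when the predicted OSA probability is at least ``threshold``.
    """
    results = []
    osa_idx = list(model_q.classes).index("osa")
    for case in cases:
        qv = np.asarray(case["questionnaire"], dtype=float)
        p_osa = float(model_q.predict_proba(qv)[0, osa_idx])
        if p_osa < threshold:
            results.append(
                TriageResult(case_id=case["case_id"], stage1="primary_insomnia", p_osa=p_osa)
            )
            continue
        feats = case.get("saturation_features")
        if feats is None:
            sig = case.get("signal")
            if sig is None:
                raise ValueError(
                    f"saturation signal required for stage 2 (case {case['case_id']})"
                )
            feats = extract_all(sig, feature_config).vector()
        proba = model_s.predict_proba(np.asarray(feats, dtype=float))[0]
        severity = _severity_argmax(proba, model_s.classes)
        results.append(
            TriageResult(
                case_id=case["case_id"],
                stage1="osa",
                p_osa=p_osa,
                stage2=severity,
                stage2_proba={str(c): float(p) for c, p in zip(model_s.classes, proba)},
            )
        )
    return results
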