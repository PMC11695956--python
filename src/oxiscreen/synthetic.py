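"""Synthetic overnight oximetry and questionnaire cohorts with known truth.

Every stage of the pipeline is testable without access to restricted
polysomnography archives: the generator emits 1 Hz integer-percent SpO2
traces (stable 95-98% baseline, desaturation events whose hourly rate
equals the case's latent AHI, probe artifacts and dropouts) together with
correlated questionnaire records (OSA odds rise with BMI, age, male sex,
snoring and hypertension; insomnia cases score high on the PSQI latency
and quality components) and a truth table of every latent value.

Desaturation events are piecewise linear (down-ramp, hold at the nadir,
recovery ramp) — the simplest shape that concentrates spectral power in
the 0.01-0.03 Hz band where cyclic apneic desaturation lives. Arrivals
follow a refractory renewal process: exponential inter-event gaps shifted
by a minimum separation, so events never overlap and the requested
events/hour is actually realised up to severe-range rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .questionnaire import ITEM_KEYS, QuestionnaireRecord
from .signal_io import Spo2Record

__all__ = [
    "SimParams",
    "SimCase",
    "SyntheticCohort",
    "simulate_spo2",
    "simulate_questionnaire",
    "simulate_cohort",
    "PRESETS",
]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate a hospital sleep-clinic cohort.

    ``class_mix`` gives the (none, mild, moderate_severe) fractions;
    with ``insomnia_phenotype`` set, the "none" cases are primary-insomnia
    patients and their questionnaires show the insomnia profile. AHI bands
    per class are deliberately separated (0-4 / 6-14 / 16-60 events/h) so
    planted severity is recoverable from the signal.
    """

    n_cases: int = 600
    class_mix: tuple[float, float, float] = (0.331, 0.294, 0.375)
    insomnia_phenotype: bool = True
    recording_hours: float = 6.0

    baseline_mean: float = 96.5
    baseline_sd: float = 0.35
    baseline_ar: float = 0.995

    ahi_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "none": (0.0, 4.0),
            "mild": (6.0, 14.0),
            "moderate_severe": (16.0, 60.0),
        }
    )
    event_depth_range: tuple[float, float] = (4.0, 15.0)
    event_duration_range: tuple[float, float] = (20.0, 60.0)
    min_event_gap_s: float = 12.0

    spike_rate_per_h: float = 2.0
    dropout_rate_per_h: float = 0.5
    dropout_len_range: tuple[float, float] = (10.0, 150.0)
    quantize: bool = True

    # log-odds of OSA in the questionnaire population model
    logodds_bmi: float = 0.13  # per kg/m^2 above 25
    logodds_age_decade: float = 0.35
    logodds_male: float = 0.9
    logodds_snore_level: float = 0.8  # per PSQI q5.5 level
    logodds_htn: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class mix must sum to 1")
        if self.event_depth_range[0] < 4.0:
            raise ValueError("event depth below 4 points is undetectable by ODI4")


# Class mixes from the two cohort structures the generator emulates: a
# sleep-clinic population (insomnia vs graded OSA) and a community study
# dominated by none/mild disease.
PRESETS: dict[str, SimParams] = {
    "clinic": SimParams(class_mix=(0.331, 0.294, 0.375), insomnia_phenotype=True),
    "community": SimParams(class_mix=(0.462, 0.312, 0.226), insomnia_phenotype=False),
}
# aliases matching the cohorts each preset stands in for
PRESETS["tvgh-like"] = PRESETS["clinic"]
PRESETS["shhs-like"] = PRESETS["community"]


def _event_profile(duration: int, depth: float) -> np.ndarray:
    """Piecewise-linear desaturation: 30% ramp down, 40% hold, 30% recovery."""
    down = max(int(round(duration * 0.3)), 1)
    up = max(int(round(duration * 0.3)), 1)
    hold = max(duration - down - up, 1)
    return np.concatenate(
        [
            np.linspace(0.0, depth, down, endpoint=False),
            np.full(hold, depth),
            np.linspace(depth, 0.0, up + 1)[1:],
        ]
    )


def simulate_spo2(
    severity: str = "none",
    hours: float | None = None,
    params: SimParams | None = None,
    seed: int | np.random.Generator = 0,
    event_rate: float | None = None,
    case_id: str = "sim",
):
    """Simulate one overnight 1 Hz SpO2 record.

    Returns ``(record, true_event_count, true_ahi)``. The latent AHI is
    drawn from the severity band (or forced with ``event_rate``) and sets
    the desaturation event rate; artifacts are injected on top, so the
    truth refers to genuine events only. Deterministic per seed.
    """
    p = params or SimParams()
    hours = p.recording_hours if hours is None else hours
    if hours <= 0:
        raise ValueError("invalid duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(hours * 3600))

    # AR(1) baseline with the requested stationary SD
    sigma_eps = p.baseline_sd * np.sqrt(1.0 - p.baseline_ar**2)
    eps = rng.normal(0.0, sigma_eps, n)
    eps[0] = rng.normal(0.0, p.baseline_sd)
    values = p.baseline_mean + lfilter([1.0], [1.0, -p.baseline_ar], eps)

    if event_rate is None:
        lo, hi = p.ahi_bands[severity]
        true_ahi = float(rng.uniform(lo, hi))
    else:
        true_ahi = float(event_rate)
    rate = true_ahi

    count = 0
    if rate > 0:
        dur_mean = float(np.mean(p.event_duration_range))
        slack = max(3600.0 / rate - dur_mean - p.min_event_gap_s, 1.0)
        t = float(rng.exponential(slack))
        while True:
            dur = int(round(rng.uniform(*p.event_duration_range)))
            start = int(round(t))
            if start + dur >= n:
                break
            depth = rng.uniform(*p.event_depth_range)
            prof = _event_profile(dur, depth)
            values[start : start + len(prof)] -= prof
            count += 1
            t += dur + p.min_event_gap_s + rng.exponential(slack)

    # probe artifacts: short spikes to non-physiological values, and dropouts
    n_spikes = rng.poisson(p.spike_rate_per_h * hours)
    for pos in rng.integers(0, n, size=n_spikes):
        width = int(rng.integers(1, 3))
        values[pos : pos + width] = rng.uniform(20.0, 45.0)
    n_drop = rng.poisson(p.dropout_rate_per_h * hours)
    for pos in rng.integers(0, n, size=n_drop):
        length = int(round(rng.uniform(*p.dropout_len_range)))
        values[pos : pos + length] = np.nan

    if p.quantize:
        with np.errstate(invalid="ignore"):
            values = np.round(values)
    values = np.clip(values, 0.0, 100.0)
    rec = Spo2Record(case_id=case_id, fs=1.0, values=values)
    return rec, count, true_ahi


def _categorical(rng, probs, size=None):
    return rng.choice(len(probs), size=size, p=probs)


def _clock(hours: float) -> float:
    return float(hours % 24.0)


def simulate_questionnaire(
    stage1: str,
    covariates: dict,
    rng: np.random.Generator,
    case_id: str = "sim",
) -> QuestionnaireRecord:
    """Draw one questionnaire record consistent with a case's class.

    ``covariates`` carries the clinical fields and snoring level already
    drawn by the population model. Insomnia cases get long latencies, poor
    subjective quality, short sleep and frequent medication; OSA cases get
    breathing-related disturbance and daytime sleepiness.
    """
    insomnia = stage1 == "primary_insomnia"
    osa = stage1 == "osa"

    bedtime = _clock(22.5 + rng.normal(0.0, 0.8))
    in_bed = float(np.clip(rng.normal(8.0, 0.6), 6.0, 10.5))
    rise = _clock(bedtime + in_bed)
    if insomnia:
        latency_min = float(np.clip(rng.lognormal(np.log(45.0), 0.5), 5.0, 180.0))
        sleep_h = float(np.clip(rng.normal(5.2, 0.9), 2.5, in_bed - 0.5))
    else:
        latency_min = float(np.clip(rng.lognormal(np.log(14.0), 0.5), 2.0, 90.0))
        sleep_h = float(np.clip(rng.normal(6.8, 0.7), 4.0, in_bed))
    sleep_h = min(sleep_h, in_bed)

    base = (0.55, 0.25, 0.13, 0.07)
    items: dict[str, float | str] = {
        "1": round(bedtime, 2) % 24.0,
        "2": round(latency_min, 1),
        "3": round(rise, 2) % 24.0,
        "4": round(sleep_h, 2),
        "5_5": float(covariates["snore"]),
    }
    # q5.1 cannot fall asleep within 30 min
    items["5_1"] = float(
        _categorical(rng, (0.10, 0.15, 0.25, 0.50) if insomnia else (0.55, 0.25, 0.12, 0.08))
    )
    # q5.4 cannot breathe comfortably tracks apnea
    items["5_4"] = float(
        _categorical(rng, (0.35, 0.30, 0.20, 0.15) if osa else base)
    )
    for k in ("5_2", "5_3", "5_6", "5_7", "5_8", "5_9", "5_10"):
        items[k] = float(_categorical(rng, base))
    # q6 subjective quality
    items["6"] = float(
        _categorical(rng, (0.05, 0.20, 0.40, 0.35) if insomnia else (0.35, 0.40, 0.18, 0.07))
    )
    # q7 sleeping medication
    items["7"] = float(
        _categorical(rng, (0.30, 0.20, 0.20, 0.30) if insomnia else (0.78, 0.12, 0.06, 0.04))
    )
    # q8/q9 daytime dysfunction, elevated in OSA
    day = (0.28, 0.32, 0.25, 0.15) if osa else (0.50, 0.30, 0.14, 0.06)
    items["8"] = float(_categorical(rng, day))
    items["9"] = float(_categorical(rng, day))

    return QuestionnaireRecord(
        case_id=case_id,
        sex="male" if covariates["male"] else "female",
        age=float(covariates["age"]),
        bmi=float(covariates["bmi"]),
        hypertension=int(covariates["htn"]),
        diabetes=int(covariates["dm"]),
        cardiovascular_disease=int(covariates["cvd"]),
        psqi_items=items,
    )


@dataclass
class SimCase:
    """One simulated case with its latent truth."""

    case_id: str
    stage1: str  # "primary_insomnia" | "osa" (or "control" without phenotype)
    severity: str  # "none" | "mild" | "moderate_severe"
    true_ahi: float
    true_event_count: int
    record: Spo2Record = field(repr=False)
    questionnaire: QuestionnaireRecord = field(repr=False)


@dataclass
class SyntheticCohort:
    """A full simulated dataset: signals, questionnaires, labels, truth."""

    params: SimParams
    cases: list[SimCase] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": c.case_id,
                    "stage1": c.stage1,
                    "severity": c.severity,
                    "true_ahi": c.true_ahi,
                    "true_event_count": c.true_event_count,
                }
                for c in self.cases
            ],
            columns=["case_id", "stage1", "severity", "true_ahi", "true_event_count"],
        )

    def questionnaire_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            q = c.questionnaire
            row = {
                "case_id": q.case_id,
                "sex": q.sex,
                "age": q.age,
                "bmi": q.bmi,
                "htn": q.hypertension,
                "dm": q.diabetes,
                "cvd": q.cardiovascular_disease,
            }
            row.update({f"psqi_{k}": q.psqi_items[k] for k in ITEM_KEYS})
            rows.append(row)
        cols = ["case_id", "sex", "age", "bmi", "htn", "dm", "cvd"] + [f"psqi_{k}" for k in ITEM_KEYS]
        return pd.DataFrame(rows, columns=cols)

    def labels_frame(self) -> pd.DataFrame:
        return self.truth_table()[["case_id", "true_ahi", "severity", "stage1"]].rename(
            columns={"true_ahi": "ahi"}
        )


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept making mean sigmoid(b0 + eta) equal the target fraction."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_cohort(params: SimParams | None = None, seed: int | None = None) -> SyntheticCohort:
    """Simulate a full cohort with correlated signals and questionnaires.

    Clinical covariates are drawn from a base population; OSA status is
    Bernoulli with log-odds linear in BMI, age, sex, snoring level and
    hypertension, with the intercept calibrated so the marginal OSA
    fraction matches ``params.class_mix``. OSA cases split into mild vs
    moderate-severe per the mix; every case's AHI is drawn from its
    severity band and drives the signal generator.
    """
    p = params or SimParams()
    if seed is not None:
        p = replace(p, seed=seed)
    rng = np.random.default_rng(p.seed)
    n = p.n_cases
    cohort = SyntheticCohort(params=p)
    if n == 0:
        return cohort

    age = np.clip(rng.normal(50.0, 15.0, n), 20.0, 85.0)
    male = rng.random(n) < 0.5
    bmi = np.clip(rng.normal(25.5, 4.5, n), 16.0, 45.0)
    htn = rng.random(n) < 0.25
    dm = rng.random(n) < 0.12
    cvd = rng.random(n) < 0.08
    snore = rng.choice(4, size=n, p=(0.30, 0.30, 0.25, 0.15))

    eta = (
        p.logodds_bmi * (bmi - 25.0)
        + p.logodds_age_decade * (age - 50.0) / 10.0
        + p.logodds_male * male
        + p.logodds_snore_level * snore
        + p.logodds_htn * htn
    )
    p_osa_target = p.class_mix[1] + p.class_mix[2]
    b0 = _calibrate_intercept(eta, p_osa_target)
    is_osa = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + eta)))
    p_mild = p.class_mix[1] / p_osa_target
    mild = rng.random(n) < p_mild

    for i in range(n):
        case_id = f"case_{i:04d}"
        if is_osa[i]:
            severity = "mild" if mild[i] else "moderate_severe"
            stage1 = "osa"
        else:
            severity = "none"
            stage1 = "primary_insomnia" if p.insomnia_phenotype else "control"
        rec, count, ahi = simulate_spo2(
            severity=severity, params=p, seed=rng, case_id=case_id
        )
        quest = simulate_questionnaire(
            stage1,
            {
                "age": age[i],
                "male": bool(male[i]),
                "bmi": bmi[i],
                "htn": int(htn[i]),
                "dm": int(dm[i]),
                "cvd": int(cvd[i]),
                "snore": int(snore[i]),
            },
            rng,
            case_id=case_id,
        )
        cohort.cases.append(
            SimCase(
                case_id=case_id,
                stage1=stage1,
                severity=severity,
                true_ahi=ahi,
                true_event_count=count,
                record=rec,
                questionnaire=quest,
            )
        )
    return cohort
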