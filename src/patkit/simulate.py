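"""Synthetic PAT cohorts with known ground truth.

Two generators are provided:

* :func:`simulate_cohort` — full mechanistic sessions: a 2-minute
  baseline built from an AR(1) inter-beat-interval process, 2 practice +
  20 main trials per participant, von Mises phase selection for truly
  interoceptive participants (uniform for the rest), ordinal confidence
  with a sex shift, lognormal trial durations, and injectable QC
  failures (empty dial traces, sparse heart-rate samples, extra trials,
  missing demographics). Every participant's latent state is returned as
  a ground-truth table so pipeline bookkeeping can be audited exactly.

* :func:`simulate_scores` — a score-level shortcut that draws
  consistency scores directly from the two-component Gaussian model the
  classifier assumes. Used for mixture-recovery and statistical
  calibration studies where only the score distribution matters and
  thousands of replicate cohorts are needed.

Defaults emulate the pooled smartphone cohort the pipeline targets:
n = 266 with 163 females; interoceptive prevalence 0.55 (female) vs 0.35
(male); component means near 0.22 / 0.55; resting heart rate in the high
70s bpm, slightly higher in females; confidence about 0.9 points higher
in males.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .session_model import SessionRecord, TrialRecord

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ScoreModel:
    """Gaussian score components (non-interoceptive, interoceptive),
    clipped to [0, 1] on draw."""

    means: tuple[float, float] = (0.22, 0.55)
    sds: tuple[float, float] = (0.07, 0.12)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    n_participants: int = 266
    female_ratio: float = 163.0 / 266.0
    age_mean: float = 27.31
    age_sd: float = 9.96
    age_range: tuple[int, int] = (18, 60)
    # four datasets with the published final-sample proportions
    dataset_probs: tuple[float, ...] = (86 / 266, 116 / 266, 54 / 266, 10 / 266)
    screener_datasets: tuple[int, ...] = (1, 2)

    # interoceptive prevalence per sex; when sex_effect is off both sexes
    # use the pooled rate
    p_interoceptive_female: float = 0.55
    p_interoceptive_male: float = 0.35
    sex_effect: bool = True

    # phase selection
    kappa_interoceptive: float = 1.2
    kappa_screener_log_mean: float = math.log(5.0)
    kappa_screener_log_sd: float = 0.5

    # cardiac model (ms): between-subject mean IBI, AR(1) within subject
    mean_ibi_male: float = 790.0
    mean_ibi_female: float = 760.0
    ibi_between_sd: float = 90.0
    sdnn_target_male: float = 52.0
    sdnn_target_female: float = 58.0
    ar_coef: float = 0.2

    # confidence: per-trial latent normal, rounded and clipped to 0..9
    confidence_mean_male: float = 5.5
    confidence_mean_female: float = 4.6
    confidence_sd: float = 2.0

    # engagement
    dial_turns_mean: float = 27.0
    trial_duration_median_s: float = 20.0
    trial_duration_log_sd: float = 0.45

    # natural trial invalidity (kept small enough that the participant
    # still reaches 17 valid trials)
    natural_invalid_rate: float = 0.9  # Poisson mean, capped at 3

    # participant-level QC failure injections (mutually exclusive)
    p_qc_fail: float = 0.15
    p_extra_trials: float = 0.01
    p_missing_demographics: float = 0.015

    score_model: ScoreModel = field(default_factory=ScoreModel)

    def p_interoceptive(self, sex: str) -> float:
        if not self.sex_effect:
            fr = self.female_ratio
            return fr * self.p_interoceptive_female + (1 - fr) * self.p_interoceptive_male
        return self.p_interoceptive_female if sex == "female" else self.p_interoceptive_male


DEFAULT_SIM = SimConfig()


def _ar1_rr(rng: np.random.Generator, mean_ibi: float, sdnn: float, ar: float, total_ms: float) -> np.ndarray:
    """AR(1) RR series (ms) whose cumulative sum covers total_ms."""
    innov_sd = sdnn * math.sqrt(max(1.0 - ar**2, 1e-6))
    n_max = int(total_ms / max(mean_ibi - 4 * sdnn, 300.0)) + 10
    rr = np.empty(n_max)
    x = mean_ibi + rng.normal(0.0, sdnn)
    t = 0.0
    i = 0
    while t < total_ms and i < n_max:
        x = mean_ibi + ar * (x - mean_ibi) + rng.normal(0.0, innov_sd)
        x = max(x, 300.0)
        rr[i] = x
        t += x
        i += 1
    return rr[:i]


def _beats_from_rr(rr: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(rr)])


def _make_trial(
    rng: np.random.Generator,
    index: int,
    is_practice: bool,
    angle: float,
    mean_ibi: float,
    sdnn: float,
    ar: float,
    config: SimConfig,
    sex: str,
    invalid_mode: Optional[str] = None,
) -> TrialRecord:
    duration_s = float(
        rng.lognormal(math.log(config.trial_duration_median_s), config.trial_duration_log_sd)
    )
    rr = _ar1_rr(rng, mean_ibi, sdnn, ar, duration_s * 1000.0)
    beats = _beats_from_rr(rr)
    hr = list(np.round(60000.0 / rr, 1))
    trial_ibi = float(np.mean(np.diff(beats)))

    # final confirmed delay realizes the intended phase angle on the
    # trial's own mean IBI (plus whole extra cycles, which the modular
    # conversion removes)
    cycles = int(rng.integers(0, 3))
    final_delay = (angle / TWO_PI + cycles) * trial_ibi
    n_turns = max(int(rng.poisson(config.dial_turns_mean)), 2)
    trace = list(np.round(rng.uniform(0.0, 2.0 * trial_ibi, n_turns - 1), 3)) + [
        round(final_delay, 3)
    ]

    conf_mean = (
        config.confidence_mean_female if sex == "female" else config.confidence_mean_male
    )
    confidence = int(np.clip(round(rng.normal(conf_mean, config.confidence_sd)), 0, 9))

    if invalid_mode == "zero_delays":
        trace = []
        final = None
    else:
        final = trace[-1]
    if invalid_mode == "too_few_hr":
        hr = hr[: int(rng.integers(0, 5))]

    return TrialRecord(
        trial_index=index,
        is_practice=is_practice,
        delay_trace=trace,
        final_delay_ms=final,
        beat_times_ms=list(np.round(beats, 3)),
        hr_samples=hr,
        confidence=confidence,
        duration_s=round(duration_s, 3),
        body_map_location=None,
    )


def _make_session(
    rng: np.random.Generator,
    pid: str,
    dataset: int,
    task: str,
    sex: str,
    mean_ibi: float,
    sdnn: float,
    angles: np.ndarray,
    config: SimConfig,
    invalid_modes: dict[int, str],
    n_main: int = 20,
) -> SessionRecord:
    rr = _ar1_rr(rng, mean_ibi, sdnn, config.ar_coef, 120_000.0)
    baseline = list(np.round(_beats_from_rr(rr), 3))
    trials = []
    for j in range(2):
        trials.append(
            _make_trial(
                rng, j + 1, True, float(rng.uniform(0, TWO_PI)), mean_ibi, sdnn,
                config.ar_coef, config, sex,
            )
        )
    for j in range(n_main):
        trials.append(
            _make_trial(
                rng, j + 3, False, float(angles[j]), mean_ibi, sdnn,
                config.ar_coef, config, sex, invalid_modes.get(j),
            )
        )
    return SessionRecord(
        participant_id=pid,
        dataset_id=dataset,
        task=task,
        baseline_duration_s=120.0,
        baseline_beats_ms=baseline,
        trials=trials,
    )


def _draw_angles(
    rng: np.random.Generator, n: int, interoceptive: bool, preferred: float, kappa: float
) -> np.ndarray:
    if interoceptive and kappa > 0:
        return rng.vonmises(preferred, kappa, size=n) % TWO_PI
    return rng.uniform(0.0, TWO_PI, size=n)


def simulate_cohort(
    config: SimConfig = DEFAULT_SIM, seed: int = 0
) -> tuple[list[SessionRecord], pd.DataFrame, pd.DataFrame]:
    """Generate (sessions, demographics, ground_truth) for one cohort.

    ``sessions`` contains every participant's PAT session plus a screener
    session for participants in the screener datasets. ``demographics``
    omits participants injected with the missing-demographics failure.
    ``ground_truth`` has one row per participant with the latent state
    and every injected failure, aligned by participant_id.
    """
    rng = np.random.default_rng(seed)
    n = config.n_participants
    sessions: list[SessionRecord] = []
    demo_rows = []
    truth_rows = []

    for i in range(n):
        pid = f"P{i:04d}"
        sex = "female" if rng.random() < config.female_ratio else "male"
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), *config.age_range))
        dataset = int(rng.choice(len(config.dataset_probs), p=config.dataset_probs)) + 1
        interoceptive = rng.random() < config.p_interoceptive(sex)
        preferred = float(rng.uniform(0.0, TWO_PI))
        mean_ibi = float(
            np.clip(
                rng.normal(
                    config.mean_ibi_female if sex == "female" else config.mean_ibi_male,
                    config.ibi_between_sd,
                ),
                500.0,
                1200.0,
            )
        )
        sdnn = config.sdnn_target_female if sex == "female" else config.sdnn_target_male

        # one injected participant-level failure at most
        u = rng.random()
        if u < config.p_qc_fail:
            injected = "qc_fail"
        elif u < config.p_qc_fail + config.p_extra_trials:
            injected = "extra_trials"
        elif u < config.p_qc_fail + config.p_extra_trials + config.p_missing_demographics:
            injected = "missing_demographics"
        else:
            injected = "none"

        n_main = 20
        invalid_modes: dict[int, str] = {}
        if injected == "qc_fail":
            n_invalid = int(rng.integers(4, 9))  # leaves at most 16 valid
        else:
            n_invalid = min(int(rng.poisson(config.natural_invalid_rate)), 3)
        for j in rng.choice(n_main, size=n_invalid, replace=False):
            invalid_modes[int(j)] = "zero_delays" if rng.random() < 0.5 else "too_few_hr"
        if injected == "extra_trials":
            n_main = 20 + int(rng.integers(1, 5))

        angles = _draw_angles(rng, n_main, interoceptive, preferred, config.kappa_interoceptive)
        sessions.append(
            _make_session(
                rng, pid, dataset, "PAT", sex, mean_ibi, sdnn, angles, config,
                invalid_modes, n_main,
            )
        )

        has_screener = dataset in config.screener_datasets
        screener_kappa = float("nan")
        if has_screener:
            screener_kappa = float(
                rng.lognormal(config.kappa_screener_log_mean, config.kappa_screener_log_sd)
            )
            s_pref = float(rng.uniform(0.0, TWO_PI))
            s_angles = (rng.vonmises(s_pref, screener_kappa, size=20)) % TWO_PI
            sessions.append(
                _make_session(
                    rng, pid, dataset, "screener", sex, mean_ibi, sdnn, s_angles,
                    config, {},
                )
            )

        if injected != "missing_demographics":
            demo_rows.append(
                {"participant_id": pid, "sex": sex, "age_years": age, "dataset_id": dataset}
            )
        truth_rows.append(
            {
                "participant_id": pid,
                "sex": sex,
                "age_years": age,
                "dataset_id": dataset,
                "true_status": "interoceptive" if interoceptive else "non_interoceptive",
                "preferred_phase_rad": preferred,
                "mean_ibi_ms": mean_ibi,
                "sdnn_target_ms": sdnn,
                "injected_failure": injected,
                "n_invalid_trials": n_invalid if injected != "extra_trials" else n_invalid,
                "has_screener": has_screener,
                "screener_kappa": screener_kappa,
            }
        )

    demographics = pd.DataFrame(
        demo_rows, columns=["participant_id", "sex", "age_years", "dataset_id"]
    )
    ground_truth = pd.DataFrame(truth_rows)
    return sessions, demographics, ground_truth


def simulate_scores(
    n: int = 266,
    seed: int = 0,
    config: SimConfig = DEFAULT_SIM,
) -> pd.DataFrame:
    """Score-level cohort draw from the Gaussian score components.

    Returns a DataFrame with columns participant_id, sex, true_status,
    consistency_score. Honors ``config.sex_effect`` and the per-sex
    interoceptive prevalences.
    """
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < config.female_ratio, "female", "male")
    p_int = np.array([config.p_interoceptive(s) for s in sex])
    status = rng.random(n) < p_int
    mu = np.where(status, config.score_model.means[1], config.score_model.means[0])
    sd = np.where(status, config.score_model.sds[1], config.score_model.sds[0])
    scores = np.clip(rng.normal(mu, sd), 0.0, 1.0)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "sex": sex,
            "true_status": np.where(status, "interoceptive", "non_interoceptive"),
            "consistency_score": scores,
        }
    )


def truth_report(ground_truth: pd.DataFrame, labelled: pd.DataFrame) -> dict:
    """Classification recovery against ground truth.

    ``labelled`` needs participant_id and label_bf3/10/30 columns (one
    row per analyzed participant). Returns sensitivity and specificity at
    each BF level, treating 'unclassified' as a non-detection for both.
    """
    merged = labelled.merge(
        ground_truth[["participant_id", "true_status"]], on="participant_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no participant ids in common")
    out: dict = {"n": int(len(merged))}
    truly_int = merged["true_status"] == "interoceptive"
    for level in ("bf3", "bf10", "bf30"):
        lab = merged[f"label_{level}"]
        sens = float((lab[truly_int] == "interoceptive").mean()) if truly_int.any() else float("nan")
        spec = (
            float((lab[~truly_int] == "non_interoceptive").mean())
            if (~truly_int).any()
            else float("nan")
        )
        false_int = (
            float((lab[~truly_int] == "interoceptive").mean()) if (~truly_int).any() else float("nan")
        )
        out[level] = {
            "sensitivity": sens,
            "specificity": spec,
            "false_interoceptive_rate": false_int,
            "unclassified_rate": float((lab == "unclassified").mean()),
        }
    return out


def null_config(config: SimConfig = DEFAULT_SIM) -> SimConfig:
    """The same conditions with the sex effect switched off."""
    return replace(config, sex_effect=False)
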