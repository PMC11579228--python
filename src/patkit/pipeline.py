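"""End-to-end cohort analysis: ingest, QC, score, classify, compare.

``build_cohort`` turns raw session records plus a demographics table into
a participant-level analysis frame (one row per included participant,
with the consistency score, confidence, engagement, cardiac metrics and
screener outcome), recording every exclusion with its reason.
``apply_sample`` carves the analysis samples out of that frame with
declarative predicates, and ``run_report`` runs the full statistical
battery per sample — refitting the mixture classifier within each sample
by default — into a JSON-serializable report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .cardiac import hrv_summary, rr_from_beats
from .mixture import (
    DEFAULT_EM,
    EMConfig,
    MixtureFit,
    classification_table,
    classify_scores,
    fit_gmm2,
)
from .qc import DEFAULT_QC, QCConfig, engagement_summary, select_valid
from .scoring import (
    DEFAULT_SCORING,
    SCREENER_PASS_THRESHOLD,
    ScoringConfig,
    score_session,
    screener_pass,
)
from .session_model import SessionRecord

REPORT_SCHEMA = "pat-report/1"


@dataclass(frozen=True)
class PipelineConfig:
    qc: QCConfig = field(default_factory=lambda: DEFAULT_QC)
    scoring: ScoringConfig = field(default_factory=lambda: DEFAULT_SCORING)
    em: EMConfig = field(default_factory=lambda: DEFAULT_EM)
    belonging_method: str = "tail"
    refit_per_sample: bool = True


DEFAULT_PIPELINE = PipelineConfig()


@dataclass
class CohortResult:
    frame: pd.DataFrame
    exclusions: pd.DataFrame  # participant_id, reason
    fit: Optional[MixtureFit] = None

    def exclusion_counts(self) -> dict[str, int]:
        return self.exclusions["reason"].value_counts().to_dict()


@dataclass(frozen=True)
class SampleSpec:
    """A named, ordered list of row-wise predicates on the cohort frame."""

    name: str
    filters: tuple[tuple[str, Callable[[pd.DataFrame], pd.Series]], ...] = ()


def builtin_samples() -> dict[str, SampleSpec]:
    """The four analysis samples.

    * full — every included participant.
    * full_matched — engagement/demographic matching: at least 18 valid
      trials and no 18-year-old females.
    * screened — screener completed and passed (> 0.42).
    * screened_matched — screened plus the same matching rule (the
      published age-matching rule for this sample is not fully specified;
      this predicate is the configurable stand-in).
    """
    min18 = ("min_18_valid_trials", lambda f: f["n_valid_trials"] >= 18)
    no_f18 = (
        "exclude_females_aged_18",
        lambda f: ~((f["sex"] == "female") & (f["age_years"] == 18)),
    )
    passed = ("screener_pass", lambda f: f["screener_pass"].eq(True))
    return {
        "full": SampleSpec("full"),
        "full_matched": SampleSpec("full_matched", (min18, no_f18)),
        "screened": SampleSpec("screened", (passed,)),
        "screened_matched": SampleSpec("screened_matched", (passed, min18, no_f18)),
    }


FRAME_COLUMNS = [
    "participant_id",
    "dataset_id",
    "sex",
    "age_years",
    "consistency_score",
    "n_scored_trials",
    "mean_confidence",
    "screener_score",
    "screener_pass",
    "total_time_s",
    "mean_time_per_trial_s",
    "mean_dial_turns",
    "n_valid_trials",
    "resting_hr_bpm",
    "sdnn_ms",
    "rmssd_ms",
    "pnn50_pct",
]


def _mean_confidence(trials) -> float:
    vals = [t.confidence for t in trials if t.confidence is not None]
    return float(np.mean(vals)) if vals else float("nan")


def build_cohort(
    sessions: Sequence[SessionRecord],
    demographics: pd.DataFrame,
    config: PipelineConfig = DEFAULT_PIPELINE,
    classify: bool = True,
) -> CohortResult:
    """Assemble the participant-level analysis frame.

    Exclusion rules, applied in order per participant:
    missing_demographics, extra_trials (more than 20 main trials),
    too_few_valid_trials (< 17 valid after the trial filters). With
    multiple PAT completions, the first one providing 17 valid trials is
    used (the first overall if none does).
    """
    demo = demographics.set_index(demographics["participant_id"].astype(str))
    pat_by_pid: dict[str, list[SessionRecord]] = {}
    screener_by_pid: dict[str, SessionRecord] = {}
    for s in sessions:
        if s.task == "PAT":
            pat_by_pid.setdefault(s.participant_id, []).append(s)
        else:
            screener_by_pid.setdefault(s.participant_id, s)

    rows = []
    excluded = []
    for pid, completions in pat_by_pid.items():
        # first available completion with enough valid trials
        session = completions[0]
        trial_set = select_valid(session, config.qc)
        for cand in completions[1:]:
            if trial_set.included:
                break
            cand_set = select_valid(cand, config.qc)
            if cand_set.included:
                session, trial_set = cand, cand_set

        if pid not in demo.index:
            excluded.append({"participant_id": pid, "reason": "missing_demographics"})
            continue
        drow = demo.loc[pid]
        if pd.isna(drow["sex"]) or pd.isna(drow["age_years"]):
            excluded.append({"participant_id": pid, "reason": "missing_demographics"})
            continue
        if session.has_extra_trials:
            excluded.append({"participant_id": pid, "reason": "extra_trials"})
            continue
        if not trial_set.included:
            excluded.append({"participant_id": pid, "reason": "too_few_valid_trials"})
            continue

        score = score_session(session, trial_set, config.scoring)
        engagement = engagement_summary(trial_set, config.qc)
        cardiac = hrv_summary(rr_from_beats(session.baseline_beats_ms))

        s_score = float("nan")
        s_pass = None
        if pid in screener_by_pid:
            s_set = select_valid(screener_by_pid[pid], config.qc)
            if s_set.included:
                s_score = score_session(screener_by_pid[pid], s_set, config.scoring).score
                s_pass = screener_pass(s_score)

        rows.append(
            {
                "participant_id": pid,
                "dataset_id": drow["dataset_id"],
                "sex": drow["sex"],
                "age_years": float(drow["age_years"]),
                "consistency_score": score.score,
                "n_scored_trials": score.n_trials,
                "mean_confidence": _mean_confidence(trial_set.trials),
                "screener_score": s_score,
                "screener_pass": s_pass,
                **engagement.as_dict(),
                **cardiac.as_dict(),
            }
        )

    frame = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["participant_id", "reason"])
    result = CohortResult(frame=frame, exclusions=exclusions)
    if classify and len(frame) >= config.em.min_scores:
        result.fit = attach_labels(frame, config)
    return result


def attach_labels(frame: pd.DataFrame, config: PipelineConfig = DEFAULT_PIPELINE) -> MixtureFit:
    """Fit the mixture on the frame's scores and add label columns in place."""
    fit = fit_gmm2(frame["consistency_score"].to_numpy(), config.em)
    results = classify_scores(
        frame["consistency_score"].to_numpy(), fit, config.belonging_method
    )
    frame["bayes_factor"] = [r.bayes_factor for r in results]
    for level in ("bf3", "bf10", "bf30"):
        frame[f"label_{level}"] = [getattr(r, f"label_{level}") for r in results]
    return fit


def apply_sample(
    frame: pd.DataFrame, spec: SampleSpec
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply a sample spec's predicates in order; returns (subset, attrition log)."""
    current = frame
    attrition = []
    for name, predicate in spec.filters:
        mask = predicate(current).astype(bool)
        attrition.append(
            {"filter": name, "n_before": int(len(current)), "n_after": int(mask.sum())}
        )
        current = current[mask]
    return current, attrition


def _sex_groups(frame: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    f = frame.loc[frame["sex"] == "female", column].dropna().to_numpy()
    m = frame.loc[frame["sex"] == "male", column].dropna().to_numpy()
    return f, m


_RANKSUM_BATTERY = [
    "total_time_s",
    "mean_time_per_trial_s",
    "mean_dial_turns",
    "n_valid_trials",
    "resting_hr_bpm",
    "sdnn_ms",
    "rmssd_ms",
    "pnn50_pct",
    "age_years",
]


def _analyze_sample(
    sample: pd.DataFrame, config: PipelineConfig
) -> dict:
    out: dict = {
        "n": int(len(sample)),
        "n_female": int((sample["sex"] == "female").sum()),
        "n_male": int((sample["sex"] == "male").sum()),
    }
    if out["n_female"] < 2 or out["n_male"] < 2:
        out["skipped"] = "fewer than two participants of each sex"
        return out

    sample = sample.copy()
    if config.refit_per_sample or "label_bf30" not in sample.columns:
        fit = attach_labels(sample, config)
    else:
        fit = None
    if fit is not None:
        out["mixture_fit"] = fit.as_dict()

    f, m = _sex_groups(sample, "consistency_score")
    out["consistency_t"] = stats.pooled_t_test(f, m, names=("female", "male")).as_dict()
    fc, mc = _sex_groups(sample, "mean_confidence")
    out["confidence_t"] = stats.pooled_t_test(fc, mc, names=("female", "male")).as_dict()

    out["classification"] = {}
    for level in ("bf3", "bf10", "bf30"):
        table = classification_table(sample[f"label_{level}"], sample["sex"])
        entry: dict = {"counts": table.to_dict()}
        try:
            entry["chisq"] = stats.chisq_test(table.to_numpy()).as_dict()
        except ValueError as exc:
            entry["chisq"] = {"error": str(exc)}
        out["classification"][level] = entry

    out["rank_sum"] = {}
    for column in _RANKSUM_BATTERY:
        gf, gm = _sex_groups(sample, column)
        try:
            out["rank_sum"][column] = stats.rank_sum_test(
                gf, gm, names=("female", "male")
            ).as_dict()
        except ValueError as exc:
            out["rank_sum"][column] = {"error": str(exc)}

    # residualized consistency comparisons (physiology, then + age)
    for key, covs in (
        ("residual_hr_pnn50_t", ["resting_hr_bpm", "pnn50_pct"]),
        ("residual_hr_pnn50_age_t", ["resting_hr_bpm", "pnn50_pct", "age_years"]),
    ):
        resid = stats.residualize(
            sample["consistency_score"].to_numpy(), sample[covs].to_numpy()
        )
        rs = pd.Series(resid, index=sample.index)
        out[key] = stats.pooled_t_test(
            rs[sample["sex"] == "female"].to_numpy(),
            rs[sample["sex"] == "male"].to_numpy(),
            names=("female", "male"),
        ).as_dict()

    with_screener = sample.dropna(subset=["screener_score"])
    if len(with_screener) >= 3:
        out["screener_pat_spearman"] = stats.spearman(
            with_screener["screener_score"].to_numpy(),
            with_screener["consistency_score"].to_numpy(),
        ).as_dict()
    return out


def run_report(
    frame: pd.DataFrame,
    samples: Optional[dict[str, SampleSpec]] = None,
    config: PipelineConfig = DEFAULT_PIPELINE,
) -> dict:
    """The full statistical battery over the analysis samples.

    Deterministic: the only randomness (EM restarts) is seeded from
    ``config.em.seed``.
    """
    if len(frame) < 4:
        raise ValueError("cohort frame too small for a report")
    samples = samples if samples is not None else builtin_samples()
    report: dict = {
        "schema": REPORT_SCHEMA,
        "provenance": {
            "scoring_method": config.scoring.method,
            "ibi_source": config.scoring.ibi_source,
            "belonging_method": config.belonging_method,
            "em_seed": config.em.seed,
            "em_restarts": config.em.restarts,
            "refit_per_sample": config.refit_per_sample,
            "screener_threshold": SCREENER_PASS_THRESHOLD,
        },
        "samples": {},
    }
    for name, spec in samples.items():
        subset, attrition = apply_sample(frame, spec)
        entry = _analyze_sample(subset, config)
        entry["attrition"] = attrition
        report["samples"][name] = entry
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_to_json(report: dict) -> str:
    """Stable serialization (byte-identical for identical reports)."""
    return json.dumps(report, indent=1, sort_keys=True, default=_json_default, allow_nan=True)
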