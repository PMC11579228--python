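"""Trial-level quality control and engagement metrics.

Main trials with an empty dial trace, or with four or fewer heart-rate
samples, are removed as showing no user engagement. Participants keep their
first ``selected_trials`` (default 17) valid main trials, in original
order, and are excluded when fewer than ``min_valid_trials`` valid trials
exist in total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .session_model import SessionRecord, TrialRecord


class TrialValidity(str, enum.Enum):
    VALID = "valid"
    ZERO_DELAYS = "zero_delays"
    TOO_FEW_HR = "too_few_hr"


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    min_valid_trials: minimum total valid main trials for inclusion.
    selected_trials: number of valid trials scored per participant (K).
    min_hr_samples: a trial needs at least this many HR samples (the
        removal rule drops trials with <= min_hr_samples - 1 samples).
    count_unique_dial_positions: count distinct dial values instead of the
        raw trace length when summarizing engagement.
    """

    min_valid_trials: int = 17
    selected_trials: int = 17
    min_hr_samples: int = 5
    count_unique_dial_positions: bool = False


DEFAULT_QC = QCConfig()


@dataclass
class ValidTrialSet:
    """Outcome of trial selection for one participant's session.

    ``trials`` holds the first K valid main trials in original order (it
    may be shorter than K when the participant is excluded).
    ``validity_flags`` covers every main trial.
    """

    participant_id: str
    trials: list[TrialRecord]
    validity_flags: list[TrialValidity]
    n_valid_total: int
    k: int
    included: bool

    @property
    def exclusion_reason(self) -> str | None:
        return None if self.included else "too_few_valid_trials"


@dataclass(frozen=True)
class EngagementSummary:
    total_time_s: float
    mean_time_per_trial_s: float
    mean_dial_turns: float
    n_valid_trials: int

    def as_dict(self) -> dict[str, float]:
        return {
            "total_time_s": self.total_time_s,
            "mean_time_per_trial_s": self.mean_time_per_trial_s,
            "mean_dial_turns": self.mean_dial_turns,
            "n_valid_trials": self.n_valid_trials,
        }


def flag_trial(trial: TrialRecord, config: QCConfig = DEFAULT_QC) -> TrialValidity:
    """Classify a main trial as valid / zero-delays / too-few-HR.

    A trial is valid iff the dial trace is non-empty and it carries at
    least ``config.min_hr_samples`` heart-rate samples. Practice trials are
    outside the filter's domain.
    """
    if trial.is_practice:
        raise ValueError("flag_trial applies to main trials only")
    if trial.n_dial_positions == 0:
        return TrialValidity.ZERO_DELAYS
    if trial.n_hr_samples < config.min_hr_samples:
        return TrialValidity.TOO_FEW_HR
    return TrialValidity.VALID


def select_valid(session: SessionRecord, config: QCConfig = DEFAULT_QC) -> ValidTrialSet:
    """Drop practice trials, flag each main trial, and keep the first K valid.

    Exclusion (n_valid_total < min_valid_trials) is a return state on the
    ValidTrialSet, not an error.
    """
    main = session.main_trials
    flags = [flag_trial(t, config) for t in main]
    valid = [t for t, f in zip(main, flags) if f is TrialValidity.VALID]
    n_valid = len(valid)
    included = n_valid >= config.min_valid_trials
    return ValidTrialSet(
        participant_id=session.participant_id,
        trials=valid[: config.selected_trials],
        validity_flags=flags,
        n_valid_total=n_valid,
        k=config.selected_trials,
        included=included,
    )


def engagement_summary(
    trial_set: ValidTrialSet, config: QCConfig = DEFAULT_QC
) -> EngagementSummary:
    """Aggregate engagement over the selected valid trials."""
    trials = trial_set.trials
    if not trials:
        raise ValueError("engagement_summary requires a non-empty trial set")

    def dial_turns(t: TrialRecord) -> int:
        if config.count_unique_dial_positions:
            return len(set(t.delay_trace))
        return t.n_dial_positions

    total = sum(t.duration_s for t in trials)
    return EngagementSummary(
        total_time_s=total,
        mean_time_per_trial_s=total / len(trials),
        mean_dial_turns=sum(dial_turns(t) for t in trials) / len(trials),
        n_valid_trials=trial_set.n_valid_total,
    )
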