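"""Data model for phase adjustment task (PAT) and screener sessions.

A session is one participant's run of either the PAT proper or the
structurally identical screener (tone-matching) task: a 2-minute baseline
heartbeat recording followed by two practice trials and nominally twenty
main trials. On each trial the participant turns a virtual dial through a
sequence of tone delays and confirms a final setting, then rates confidence
on a 0-9 scale.

Sessions are stored in a small versioned JSON dialect, ``pat-session/1``
(JSON Schema shipped under :mod:`patkit.schemas`). All timestamps are
integer-or-float milliseconds from session/trial start; durations are in
seconds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Any, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = "pat-session/1"

#: Nominal task structure: two practice trials then twenty main trials.
N_PRACTICE_TRIALS = 2
N_MAIN_TRIALS = 20


class SessionValidationError(ValueError):
    """A session violates an invariant of the pat-session/1 dialect."""


class TrialRecord(BaseModel):
    """One dial-adjustment trial.

    ``delay_trace`` is the ordered sequence of dial-selected tone delays in
    milliseconds; an empty trace means the participant never engaged the
    dial. ``final_delay_ms`` is the confirmed setting and must equal the
    last trace element when the trace is non-empty. ``hr_samples`` are the
    instantaneous heart-rate readings (bpm) shown/recorded during the trial;
    ``beat_times_ms`` the within-trial heartbeat timestamps. Both are
    carried so the engagement filter can be exercised on either signal.
    """

    model_config = ConfigDict(validate_assignment=True)

    trial_index: int = Field(ge=1)
    is_practice: bool = False
    delay_trace: list[float] = Field(default_factory=list)
    final_delay_ms: Optional[float] = None
    beat_times_ms: list[float] = Field(default_factory=list)
    hr_samples: list[float] = Field(default_factory=list)
    confidence: Optional[int] = Field(default=None, ge=0, le=9)
    duration_s: float = Field(gt=0)
    body_map_location: Optional[str] = None  # stored, never analyzed

    @model_validator(mode="after")
    def _check_invariants(self) -> "TrialRecord":
        beats = self.beat_times_ms
        if any(b2 <= b1 for b1, b2 in zip(beats, beats[1:])):
            raise ValueError(
                f"trial {self.trial_index}: beat_times_ms must be strictly increasing"
            )
        if self.delay_trace:
            if self.final_delay_ms is None:
                raise ValueError(
                    f"trial {self.trial_index}: final_delay_ms missing with non-empty delay_trace"
                )
            if self.final_delay_ms != self.delay_trace[-1]:
                raise ValueError(
                    f"trial {self.trial_index}: final_delay_ms must equal last delay_trace element"
                )
        return self

    @property
    def n_dial_positions(self) -> int:
        return len(self.delay_trace)

    @property
    def n_hr_samples(self) -> int:
        return len(self.hr_samples)


class SessionRecord(BaseModel):
    """A full PAT or screener session for one participant."""

    model_config = ConfigDict(validate_assignment=True)

    schema_version: str = Field(default=SCHEMA_VERSION, alias="schema")
    participant_id: str
    dataset_id: Union[int, str]
    task: str = Field(pattern="^(PAT|screener)$")
    baseline_duration_s: float = Field(default=120.0, gt=0)
    baseline_beats_ms: list[float] = Field(default_factory=list)
    trials: list[TrialRecord] = Field(default_factory=list)
    metadata: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_invariants(self) -> "SessionRecord":
        beats = self.baseline_beats_ms
        if any(b2 <= b1 for b1, b2 in zip(beats, beats[1:])):
            raise ValueError("baseline_beats_ms must be strictly increasing")
        seen_main = False
        for t in self.trials:
            if t.is_practice and seen_main:
                raise ValueError("practice trials must precede main trials")
            if not t.is_practice:
                seen_main = True
        return self

    @property
    def main_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.is_practice]

    @property
    def practice_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_practice]

    @property
    def has_extra_trials(self) -> bool:
        """More main trials than the nominal 20 (app malfunction; participant
        is excluded downstream)."""
        return len(self.main_trials) > N_MAIN_TRIALS


class ParticipantRecord(BaseModel):
    """Demographics row. Sex and age are required for inclusion."""

    participant_id: str
    sex: str = Field(pattern="^(male|female|other)$")
    age_years: float = Field(gt=0)
    dataset_id: Union[int, str]
    mental_health: Optional[bool] = None
    physical_health: Optional[bool] = None


_SESSION_KEYS = {
    "schema",
    "participant_id",
    "dataset_id",
    "task",
    "baseline_duration_s",
    "baseline_beats_ms",
    "trials",
    "metadata",
}


def read_session(source: Union[str, Path, IO[str]]) -> SessionRecord:
    """Read and validate a ``pat-session/1`` JSON file.

    Unknown top-level fields are preserved in ``SessionRecord.metadata``.

    Raises
    ------
    SessionValidationError
        On any schema or invariant violation; the message names the
        offending field.
    """
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    if not isinstance(payload, dict):
        raise SessionValidationError("session file must contain a JSON object")
    version = payload.get("schema")
    if version is not None and version != SCHEMA_VERSION:
        raise SessionValidationError(f"unsupported schema version: {version!r}")
    known = {k: v for k, v in payload.items() if k in _SESSION_KEYS}
    extra = {k: v for k, v in payload.items() if k not in _SESSION_KEYS}
    if extra:
        known.setdefault("metadata", {})
        known["metadata"] = {**known["metadata"], **extra}
    try:
        return SessionRecord.model_validate(known)
    except (ValueError, TypeError) as exc:  # pydantic ValidationError is a ValueError
        raise SessionValidationError(str(exc)) from exc


def write_session(session: SessionRecord, path: Union[str, Path, IO[str]]) -> None:
    """Serialize a session as ``pat-session/1`` JSON with stable key order.

    Missing optional values (e.g. confidence) are written as explicit
    ``null`` so that round-tripping preserves every field.
    """
    payload = session.model_dump(by_alias=True)
    text = json.dumps(payload, indent=1)
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def session_to_json(session: SessionRecord) -> str:
    """The exact text ``write_session`` would produce."""
    return json.dumps(session.model_dump(by_alias=True), indent=1)


def tidy_trials(session: SessionRecord) -> pd.DataFrame:
    """One row per trial, in trial order, with the analyzed columns.

    Columns: participant_id, dataset_id, task, trial_index, is_practice,
    delay_count, hr_sample_count, final_delay_ms, confidence, duration_s.
    """
    rows = [
        {
            "participant_id": session.participant_id,
            "dataset_id": session.dataset_id,
            "task": session.task,
            "trial_index": t.trial_index,
            "is_practice": t.is_practice,
            "delay_count": t.n_dial_positions,
            "hr_sample_count": t.n_hr_samples,
            "final_delay_ms": t.final_delay_ms,
            "confidence": t.confidence,
            "duration_s": t.duration_s,
        }
        for t in session.trials
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "dataset_id",
            "task",
            "trial_index",
            "is_practice",
            "delay_count",
            "hr_sample_count",
            "final_delay_ms",
            "confidence",
            "duration_s",
        ],
    )


def read_demographics(path: Union[str, Path, IO[str]]) -> pd.DataFrame:
    """Read the demographics CSV (participant_id,sex,age_years,dataset_id[,...])."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "sex", "age_years", "dataset_id"}
    missing = required - set(df.columns)
    if missing:
        raise SessionValidationError(
            f"demographics file missing columns: {sorted(missing)}"
        )
    return df
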