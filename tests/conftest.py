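import numpy as np
import pytest

from patkit.session_model import SessionRecord, TrialRecord


def make_trial(
    index: int,
    is_practice: bool = False,
    n_delays: int = 12,
    n_hr: int = 20,
    final_delay: float = 350.0,
    ibi_ms: float = 800.0,
    confidence: int = 5,
    duration_s: float = 20.0,
) -> TrialRecord:
    """A well-formed trial with a regular heartbeat and simple dial trace."""
    trace = [100.0 * k for k in range(1, n_delays)] + ([final_delay] if n_delays else [])
    n_beats = max(int(duration_s * 1000 / ibi_ms), 2)
    return TrialRecord(
        trial_index=index,
        is_practice=is_practice,
        delay_trace=trace,
        final_delay_ms=final_delay if trace else None,
        beat_times_ms=[ibi_ms * k for k in range(n_beats)],
        hr_samples=[60000.0 / ibi_ms] * n_hr,
        confidence=confidence,
        duration_s=duration_s,
    )


def make_session(
    trials=None,
    participant_id: str = "P0001",
    task: str = "PAT",
    ibi_ms: float = 800.0,
    n_main: int = 20,
) -> SessionRecord:
    if trials is None:
        trials = [make_trial(1, is_practice=True), make_trial(2, is_practice=True)]
        trials += [make_trial(i + 3) for i in range(n_main)]
    n_beats = int(120_000 / ibi_ms) + 1
    return SessionRecord(
        participant_id=participant_id,
        dataset_id=1,
        task=task,
        baseline_duration_s=120.0,
        baseline_beats_ms=[ibi_ms * k for k in range(n_beats)],
        trials=trials,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant mechanistic cohort shared across tests."""
    from patkit.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_participants=60), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
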