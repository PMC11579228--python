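"""Phase-angle conversion and the consistency score.

Each trial's confirmed tone delay is mapped onto the cardiac cycle as an
angle: ``theta = 2*pi * ((delay mod IBI) / IBI)``, where IBI is the mean
inter-beat interval (per trial by default, baseline as an alternative).
A participant who reliably perceives their heartbeat selects similar
phases across trials; one who cannot selects phases scattered around the
dial. The consistency score summarizes this as the circular mean
resultant length

    R = | sum_j exp(i * theta_j) | / n   in [0, 1],

which is 1 for identical angles and near 0 for angles uniform on the
circle (the expected value under uniformity is sqrt(pi)/(2*sqrt(n)),
about 0.215 at n = 17). A pairwise angular-similarity alternative is
provided for sensitivity analysis.

The screener (tone-matching control) pass rule is score > 0.42, strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cardiac import rr_from_beats
from .qc import ValidTrialSet
from .session_model import SessionRecord

SCREENER_PASS_THRESHOLD = 0.42

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ScoringConfig:
    """method: 'resultant_length' (default) or 'pairwise_similarity';
    ibi_source: 'trial' (mean within-trial IBI) or 'baseline'."""

    method: str = "resultant_length"
    ibi_source: str = "trial"


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class PhaseAngleSeries:
    angles_rad: np.ndarray
    ibi_ms: np.ndarray  # per-trial mean IBI used for the conversion


@dataclass(frozen=True)
class ConsistencyResult:
    score: float
    n_trials: int
    method: str


def trial_phase_angle(final_delay_ms: float, mean_ibi_ms: float) -> float:
    """Map a confirmed delay to a phase angle in [0, 2*pi)."""
    if mean_ibi_ms <= 0:
        raise ValueError("mean_ibi_ms must be positive")
    frac = (final_delay_ms % mean_ibi_ms) / mean_ibi_ms
    angle = TWO_PI * frac
    # guard the half-open interval against float round-up
    return angle if angle < TWO_PI else 0.0


def _trial_mean_ibi(beat_times_ms: Sequence[float]) -> float:
    beats = np.asarray(beat_times_ms, dtype=float)
    if beats.size < 2:
        raise ValueError("need at least 2 within-trial beats for a mean IBI")
    return float(np.mean(np.diff(beats)))


def phase_angles(
    session: SessionRecord,
    trial_set: ValidTrialSet,
    config: ScoringConfig = DEFAULT_SCORING,
) -> PhaseAngleSeries:
    """Per-trial phase angles for the selected valid trials of a session."""
    if config.ibi_source == "baseline":
        base_ibi = float(np.mean(rr_from_beats(session.baseline_beats_ms).rr_ms))
        ibis = [base_ibi] * len(trial_set.trials)
    elif config.ibi_source == "trial":
        ibis = [_trial_mean_ibi(t.beat_times_ms) for t in trial_set.trials]
    else:
        raise ValueError(f"unknown ibi_source: {config.ibi_source!r}")
    angles = [
        trial_phase_angle(t.final_delay_ms, ibi)
        for t, ibi in zip(trial_set.trials, ibis)
    ]
    return PhaseAngleSeries(
        angles_rad=np.asarray(angles, dtype=float), ibi_ms=np.asarray(ibis, dtype=float)
    )


def resultant_length(angles_rad: Sequence[float]) -> float:
    theta = np.asarray(angles_rad, dtype=float)
    return float(np.abs(np.exp(1j * theta).mean()))


def pairwise_similarity(angles_rad: Sequence[float]) -> float:
    """Mean pairwise angular similarity, min-max rescaled to [0, 1].

    The raw statistic is the mean over unordered pairs of
    ``1 - d(theta_i, theta_j)/pi`` with d the circular distance in
    [0, pi]. Its expectation is 1 for identical angles and 1/2 under
    uniform scatter, so the score is rescaled as ``2*(raw - 1/2)`` and
    clipped at 0.
    """
    theta = np.asarray(angles_rad, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    diff = np.abs(theta[:, None] - theta[None, :]) % TWO_PI
    d = np.minimum(diff, TWO_PI - diff)
    iu = np.triu_indices(n, k=1)
    raw = float(np.mean(1.0 - d[iu] / math.pi))
    return max(0.0, 2.0 * (raw - 0.5))


def consistency(
    angles_rad: Sequence[float], config: ScoringConfig = DEFAULT_SCORING
) -> ConsistencyResult:
    """Reduce a participant's trial phase angles to the [0, 1] consistency score."""
    theta = np.asarray(angles_rad, dtype=float)
    if theta.size < 2:
        raise ValueError("need at least 2 angles for a consistency score")
    if config.method == "resultant_length":
        score = resultant_length(theta)
    elif config.method == "pairwise_similarity":
        score = pairwise_similarity(theta)
    else:
        raise ValueError(f"unknown scoring method: {config.method!r}")
    return ConsistencyResult(score=score, n_trials=int(theta.size), method=config.method)


def score_session(
    session: SessionRecord,
    trial_set: ValidTrialSet,
    config: ScoringConfig = DEFAULT_SCORING,
) -> ConsistencyResult:
    """Phase angles then consistency, for a QC'd session."""
    return consistency(phase_angles(session, trial_set, config).angles_rad, config)


def screener_pass(score: float, threshold: float = SCREENER_PASS_THRESHOLD) -> bool:
    """Strictly greater-than pass rule on the screener consistency score."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    return score > threshold
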