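"""Ingest sessions, apply QC, score, and assemble the cohort frame.

Reads the session files and demographics written by 01_simulate_cohort,
runs trial-level quality control (empty dial traces / sparse heart-rate
samples removed, first 17 valid trials kept, participants with <17
excluded), converts confirmed delays to cardiac phase angles and scores
their consistency, computes engagement and time-domain HRV summaries,
and writes the participant-level frame plus the exclusion ledger.
"""

from pathlib import Path

from patkit.pipeline import build_cohort
from patkit.session_model import read_demographics, read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    session_dir = ROOT / "scratch" / "sessions"
    sessions = [read_session(p) for p in sorted(session_dir.glob("*.json"))]
    demographics = read_demographics(ROOT / "scratch" / "demographics.csv")
    result = build_cohort(sessions, demographics)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    result.frame.to_csv(out / "cohort_frame.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)

    print(f"read {len(sessions)} sessions")
    print(f"included {len(result.frame)} participants; exclusions: {result.exclusion_counts()}")
    by_sex = result.frame.groupby("sex")[
        ["consistency_score", "mean_confidence", "resting_hr_bpm", "pnn50_pct"]
    ].mean()
    print(by_sex.round(3))


if __name__ == "__main__":
    main()
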