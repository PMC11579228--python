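"""Run the sex-comparison battery over the four analysis samples.

For each sample (full; matched on engagement/demographics; screened;
screened and matched) this refits the mixture within the sample and
runs: pooled t-tests on consistency and confidence, chi-squared tests
on the classification tables at each Bayes-factor threshold, rank-sum
tests on engagement / heart-rate / age, and t-tests on consistency
residualized for resting HR, pNN50 (and age). Writes the structured
report JSON.
"""

from pathlib import Path

import pandas as pd

from patkit.pipeline import run_report, report_to_json

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    frame = pd.read_csv(ROOT / "results" / "cohort_frame.csv")
    report = run_report(frame)
    (ROOT / "results" / "report.json").write_text(report_to_json(report))

    for name, sample in report["samples"].items():
        if "skipped" in sample:
            print(f"{name}: skipped ({sample['skipped']})")
            continue
        t = sample["consistency_t"]
        fm = t["groups"]["female"]["mean"]
        mm = t["groups"]["male"]["mean"]
        chis = {
            lvl: round(e["chisq"].get("statistic", float("nan")), 2)
            for lvl, e in sample["classification"].items()
        }
        print(
            f"{name}: n={sample['n']} | consistency female {fm:.3f} vs male {mm:.3f}, "
            f"t({t['df']:.0f})={t['statistic']:.2f}, p={t['p_value']:.3f} | "
            f"chi2 {chis}"
        )


if __name__ == "__main__":
    main()
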