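import math

import numpy as np
import pandas as pd
import pytest

from patkit.cardiac import hrv_summary, rr_from_beats
from patkit.mixture import fit_gmm2
from patkit.pipeline import attach_labels, build_cohort
from patkit.qc import select_valid
from patkit.scoring import score_session
from patkit.session_model import session_to_json
from patkit.simulate import (
    ScoreModel,
    SimConfig,
    null_config,
    simulate_cohort,
    simulate_scores,
    truth_report,
)


def _scores(sessions, task="PAT"):
    out = {}
    for s in sessions:
        if s.task != task:
            continue
        ts = select_valid(s)
        if ts.included:
            out[s.participant_id] = score_session(s, ts).score
    return out


class TestDeterminism:
    def test_identical_seed_gives_identical_sessions(self):
        cfg = SimConfig(n_participants=8)
        s1, d1, t1 = simulate_cohort(cfg, seed=5)
        s2, d2, t2 = simulate_cohort(cfg, seed=5)
        assert [session_to_json(a) for a in s1] == [session_to_json(b) for b in s2]
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        cfg = SimConfig(n_participants=4)
        s1, _, _ = simulate_cohort(cfg, seed=5)
        s2, _, _ = simulate_cohort(cfg, seed=6)
        assert session_to_json(s1[0]) != session_to_json(s2[0])


class TestPhaseStructure:
    def test_huge_kappa_drives_scores_to_one(self):
        cfg = SimConfig(
            n_participants=12,
            kappa_interoceptive=1e4,
            p_interoceptive_female=1.0,
            p_interoceptive_male=1.0,
            p_qc_fail=0.0,
            p_extra_trials=0.0,
            p_missing_demographics=0.0,
            natural_invalid_rate=0.0,
        )
        sessions, _, _ = simulate_cohort(cfg, seed=2)
        scores = _scores(sessions)
        assert len(scores) == 12
        assert all(s > 0.98 for s in scores.values())

    def test_zero_kappa_matches_uniform_null(self):
        # kappa = 0 makes everyone draw uniform angles; the cohort mean
        # consistency approaches the uniform-null expectation
        # sqrt(pi)/(2*sqrt(17)) ~ 0.215
        cfg = SimConfig(
            n_participants=120,
            kappa_interoceptive=0.0,
            p_qc_fail=0.0,
            p_extra_trials=0.0,
            p_missing_demographics=0.0,
            natural_invalid_rate=0.0,
        )
        sessions, _, _ = simulate_cohort(cfg, seed=3)
        scores = np.array(list(_scores(sessions).values()))
        assert scores.mean() == pytest.approx(math.sqrt(math.pi) / (2 * math.sqrt(17)), abs=0.03)

    def test_screener_sessions_only_for_screener_datasets(self, small_cohort):
        sessions, _, truth = small_cohort
        with_screener = {s.participant_id for s in sessions if s.task == "screener"}
        assert with_screener == set(
            truth.loc[truth["has_screener"], "participant_id"]
        )


class TestCardiacStructure:
    def test_baseline_sdnn_tracks_target(self):
        # mean observed SDNN across seeds within 15% of the generator target
        cfg = SimConfig(n_participants=1)
        vals = []
        for seed in range(40):
            sessions, _, truth = simulate_cohort(cfg, seed=seed)
            s = next(x for x in sessions if x.task == "PAT")
            vals.append(
                hrv_summary(rr_from_beats(s.baseline_beats_ms)).sdnn_ms
                / truth["sdnn_target_ms"].iloc[0]
            )
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_baseline_covers_two_minutes(self, small_cohort):
        sessions, _, _ = small_cohort
        for s in sessions[:10]:
            assert s.baseline_beats_ms[-1] >= 120_000.0


class TestScoreLevelGenerator:
    def test_component_structure_recovered_at_n1000(self):
        df = simulate_scores(1000, seed=9)
        fit = fit_gmm2(df["consistency_score"].to_numpy())
        model = ScoreModel()
        assert fit.means[0] == pytest.approx(model.means[0], abs=0.02)
        assert fit.means[1] == pytest.approx(model.means[1], abs=0.02)

    def test_sex_effect_off_equalizes_prevalence(self):
        cfg = null_config()
        df = simulate_scores(20000, seed=4, config=cfg)
        rate = df.groupby("sex")["true_status"].apply(
            lambda s: (s == "interoceptive").mean()
        )
        assert rate["female"] == pytest.approx(rate["male"], abs=0.02)

    def test_scores_bounded(self):
        df = simulate_scores(5000, seed=1)
        assert df["consistency_score"].between(0.0, 1.0).all()


@pytest.fixture(scope="module")
def reference_fit():
    """Mixture fit frozen on a mixed-status cohort, used to classify the
    degenerate single-status cohorts below."""
    return fit_gmm2(simulate_scores(1000, seed=99)["consistency_score"].to_numpy())


class TestTruthReport:

    def _labels(self, cfg, seed, fit):
        from patkit.mixture import classify_scores

        sessions, _, _ = simulate_cohort(cfg, seed=seed)
        scores = _scores(sessions)
        df = pd.DataFrame(
            {"participant_id": list(scores), "consistency_score": list(scores.values())}
        )
        results = classify_scores(df["consistency_score"].to_numpy(), fit)
        for level in ("bf3", "bf10", "bf30"):
            df[f"label_{level}"] = [getattr(r, f"label_{level}") for r in results]
        return df

    def test_concentrated_interoceptive_cohort_detected(self, reference_fit):
        cfg = SimConfig(
            n_participants=266,
            kappa_interoceptive=32.0,
            p_interoceptive_female=1.0,
            p_interoceptive_male=1.0,
            p_qc_fail=0.0,
            p_extra_trials=0.0,
            p_missing_demographics=0.0,
        )
        sessions, _, truth = simulate_cohort(cfg, seed=21)
        labelled = self._labels(cfg, 21, reference_fit)
        report = truth_report(truth, labelled)
        assert report["bf3"]["sensitivity"] > 0.9

    def test_null_cohort_rarely_called_interoceptive(self, reference_fit):
        cfg = SimConfig(
            n_participants=266,
            p_interoceptive_female=0.0,
            p_interoceptive_male=0.0,
            p_qc_fail=0.0,
            p_extra_trials=0.0,
            p_missing_demographics=0.0,
        )
        _, _, truth = simulate_cohort(cfg, seed=22)
        labelled = self._labels(cfg, 22, reference_fit)
        report = truth_report(truth, labelled)
        assert report["bf30"]["false_interoceptive_rate"] < 0.05

    def test_perfectly_separated_scores_fully_recovered(self):
        # two delta-like components far apart: no misclassification
        rng = np.random.default_rng(0)
        n = 200
        status = rng.random(n) < 0.5
        scores = np.where(
            status, rng.normal(0.9, 0.005, n), rng.normal(0.1, 0.005, n)
        )
        fit = fit_gmm2(scores)
        frame = pd.DataFrame(
            {
                "participant_id": [f"P{i:04d}" for i in range(n)],
                "consistency_score": scores,
            }
        )
        from patkit.pipeline import DEFAULT_PIPELINE

        attach_labels(frame, DEFAULT_PIPELINE)
        truth = pd.DataFrame(
            {
                "participant_id": frame["participant_id"],
                "true_status": np.where(
                    status, "interoceptive", "non_interoceptive"
                ),
            }
        )
        report = truth_report(truth, frame)
        assert report["bf30"]["sensitivity"] == 1.0
        assert report["bf30"]["specificity"] == 1.0

    def test_id_mismatch_rejected(self):
        truth = pd.DataFrame({"participant_id": ["A"], "true_status": ["interoceptive"]})
        labelled = pd.DataFrame(
            {
                "participant_id": ["B"],
                "label_bf3": ["interoceptive"],
                "label_bf10": ["interoceptive"],
                "label_bf30": ["interoceptive"],
            }
        )
        with pytest.raises(ValueError):
            truth_report(truth, labelled)
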