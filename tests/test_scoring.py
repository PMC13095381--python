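"""Outcome taxonomy, session summaries and rate metrics."""

import numpy as np
import pytest

from reachlearn import (
    SessionSummary,
    TrialRecord,
    auto_classify_reach,
    failure_and_vain_rates,
    outcome_distribution,
    success_rate_by_reach,
    success_rate_by_trial,
    summarize_session,
)
from reachlearn.detect import Reach
from reachlearn.scoring import ScoringError, records_from_labels


def trial(labels, t=0, subject="m1", day=1, **kw):
    return TrialRecord(subject=subject, day=day, trial=t, labels=labels,
                       no_try=not labels, **kw)


def summary_from_counts(counts, n_trials=50, n_no_try=0, n_success_trials=None, n_first=0):
    if n_success_trials is None:
        n_success_trials = counts.get("success", 0)
    return SessionSummary(
        subject="m1", day=1, n_trials=n_trials, n_no_try=n_no_try,
        n_success_trials=n_success_trials, n_first_reach_success_trials=n_first,
        label_counts=dict(counts),
    )


class TestTrialRecord:
    def test_no_try_must_match_empty_labels(self):
        with pytest.raises(ScoringError, match="no_try"):
            TrialRecord(subject="m1", day=1, trial=0, labels=["success"], no_try=True)

    def test_at_most_one_success(self):
        with pytest.raises(ScoringError, match="success"):
            trial(["success", "success"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ScoringError, match="near_miss"):
            trial(["near_miss"])

    def test_first_reach_success_implies_success(self):
        t = trial(["success", "vain"])
        assert t.first_reach_success and t.success
        t2 = trial(["complete_miss", "success"])
        assert t2.success and not t2.first_reach_success


class TestSummarize:
    def test_counting(self):
        trials = (
            [trial([], t=i) for i in range(10)]
            + [trial(["success"], t=10 + i) for i in range(20)]
            + [trial(["complete_miss"], t=30 + i) for i in range(20)]
        )
        s = summarize_session(trials)
        assert s.n_trials == 50
        assert s.n_trials_attempted == 40
        assert s.n_success_trials == 20

    def test_partition_arithmetic(self):
        labels = (
            ["success"] * 5 + ["complete_miss"] * 3 + ["contact_miss"] * 2
            + ["vain"] * 4 + ["other"] * 1
        )
        trials = [trial([lab] if lab != "success" else ["success"], t=i)
                  for i, lab in enumerate(labels)]
        s = summarize_session(trials)
        assert s.n_targeted == 11
        assert s.n_total_reaches == 15
        assert s.n_targeted + s.label_counts["vain"] == s.n_total_reaches

    def test_mixed_subject_day_rejected(self):
        with pytest.raises(ScoringError, match="subject-day"):
            summarize_session([trial(["success"]), trial(["vain", "vain"], subject="m2")])

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            summarize_session([])


class TestRates:
    def test_success_by_trial(self):
        s = summary_from_counts({"success": 20}, n_trials=50, n_no_try=10,
                                n_success_trials=20)
        assert success_rate_by_trial(s) == pytest.approx(50.0)

    def test_all_no_try_is_missing(self):
        s = summary_from_counts({}, n_trials=50, n_no_try=50, n_success_trials=0)
        assert np.isnan(success_rate_by_trial(s))

    def test_success_by_reach(self):
        s = summary_from_counts(
            {"success": 5, "complete_miss": 3, "contact_miss": 2, "other": 1, "vain": 4}
        )
        assert success_rate_by_reach(s) == pytest.approx(100 * 5 / 11)

    def test_zero_targeted_is_missing(self):
        s = summary_from_counts({"vain": 3})
        assert np.isnan(success_rate_by_reach(s))

    def test_failure_and_vain_rates(self):
        s = summary_from_counts(
            {"success": 5, "complete_miss": 3, "contact_miss": 2, "other": 1, "vain": 4}
        )
        rates = failure_and_vain_rates(s)
        assert rates["complete_miss_pct"] == pytest.approx(100 * 3 / 11)
        assert rates["contact_miss_pct"] == pytest.approx(100 * 2 / 11)
        assert rates["vain_pct"] == pytest.approx(100 * 4 / 15)

    def test_no_vain_reaches_rate_zero(self):
        s = summary_from_counts({"success": 2, "complete_miss": 1})
        assert failure_and_vain_rates(s)["vain_pct"] == 0.0

    def test_rates_in_range_or_missing(self, rng):
        for _ in range(200):
            counts = {lab: int(rng.integers(0, 5))
                      for lab in ("success", "complete_miss", "contact_miss", "other", "vain")}
            counts["success"] = min(counts["success"], 1)
            s = summary_from_counts(counts, n_trials=10, n_no_try=int(rng.integers(0, 10)))
            vals = [success_rate_by_trial(s), success_rate_by_reach(s),
                    *failure_and_vain_rates(s).values()]
            for v in vals:
                assert np.isnan(v) or 0.0 <= v <= 100.0

    def test_by_reach_not_above_by_trial_with_extra_attempts(self):
        """Every success trial also contains a miss, so the per-reach rate
        dilutes below the per-trial rate."""
        trials = [trial(["complete_miss", "success"], t=i) for i in range(10)]
        s = summarize_session(trials)
        assert success_rate_by_reach(s) <= success_rate_by_trial(s)


class TestOutcomeDistribution:
    def test_all_success_group(self):
        s = summary_from_counts({"success": 7})
        s.group = "WT"
        dist = outcome_distribution([s], day=1)
        assert dist.loc[0, "success"] == pytest.approx(1.0)
        assert dist.loc[0, "complete_miss"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        summaries = []
        for g in ("WT", "KO"):
            for i in range(4):
                counts = {lab: int(rng.integers(0, 6))
                          for lab in ("success", "complete_miss", "contact_miss", "other")}
                if sum(counts.values()) == 0:
                    counts["other"] = 1
                s = summary_from_counts({**counts, "success": min(counts["success"], 5)})
                s.subject, s.group = f"{g}{i}", g
                summaries.append(s)
        dist = outcome_distribution(summaries, day=1)
        for _, row in dist.iterrows():
            total = row[["success", "complete_miss", "contact_miss", "other"]].sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_pooled_equals_count_weighted_mean(self, rng):
        summaries = []
        fracs, weights = [], []
        for i in range(5):
            counts = {"success": int(rng.integers(1, 5)), "complete_miss": int(rng.integers(0, 5)),
                      "contact_miss": int(rng.integers(0, 5)), "other": int(rng.integers(0, 5))}
            counts["success"] = 1
            s = summary_from_counts(counts)
            s.subject, s.group = f"m{i}", "WT"
            summaries.append(s)
            weights.append(s.n_targeted)
            fracs.append([counts[lab] / s.n_targeted
                          for lab in ("success", "complete_miss", "contact_miss", "other")])
        dist = outcome_distribution(summaries, day=1)
        expected = np.average(fracs, axis=0, weights=weights)
        got = dist.loc[0, ["success", "complete_miss", "contact_miss", "other"]].to_numpy(float)
        assert got == pytest.approx(expected, rel=1e-12)


class TestRecordsFromLabels:
    def test_absent_trials_become_no_try(self):
        import pandas as pd

        labels = pd.DataFrame(
            [{"subject": "m1", "day": 1, "trial": 2, "ordinal": 1, "label": "success"}]
        )
        records = records_from_labels(labels, n_trials=4)
        assert [r.no_try for r in records] == [True, True, False, True]
        assert records[2].labels == ["success"]


class TestAutoClassify:
    def reach(self, xy, start=0):
        xy = np.asarray(xy, dtype=float)
        return Reach(frames=start + np.arange(len(xy)), xy=xy)

    def test_after_removal_is_vain(self):
        r = self.reach([(100, 0), (110, 0), (120, 0)], start=500)
        lab = auto_classify_reach(r, (160, 0), pellet_present=(0, 400), slit_x=100)
        assert lab == "vain"

    def test_distance_beyond_radius_is_complete_miss(self):
        r = self.reach([(100, 200), (120, 240), (160, 240)])
        lab = auto_classify_reach(r, (160, 200), (0, 1000), slit_x=100, contact_radius_px=15)
        assert lab == "complete_miss"

    def test_contact_without_retrieval_is_contact_miss(self):
        r = self.reach([(100, 200), (130, 200), (158, 200)])
        lab = auto_classify_reach(r, (160, 200), (0, 1000), slit_x=100, retrieved=False)
        assert lab == "contact_miss"

    def test_contact_with_retrieval_is_success(self):
        r = self.reach([(100, 200), (130, 200), (160, 200)])
        lab = auto_classify_reach(r, (160, 200), (0, 1000), slit_x=100, retrieved=True)
        assert lab == "success"

    def test_missing_pellet_track_raises(self):
        r = self.reach([(100, 200), (130, 200)])
        with pytest.raises(ScoringError, match="pellet"):
            auto_classify_reach(r, None, (0, 1000), slit_x=100)
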