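"""Synthetic cohort generator: determinism, ground truth, imposed effects."""

import hashlib

import numpy as np
import pytest

from reachlearn import (
    filter_track,
    reach_delta_y,
    simulate_cohort,
    simulate_reach_trajectory,
    simulate_subject_day,
    simulate_trial,
    write_cohort,
)
from reachlearn.config import DecayCurve, GroupParams, SimulationConfig
from reachlearn.detect import Reach
from reachlearn.simulate import UnknownOutcomeError, draw_trial_labels, simulate_outcome_cohort


def noiseless_group(label="WT", **kw):
    return GroupParams(
        label=label,
        trajectory_noise_sigma_curve=DecayCurve(0.0, 0.0),
        vertical_spread_curve=DecayCurve(0.0, 0.0),
        **kw,
    )


@pytest.fixture
def cfg():
    return SimulationConfig(
        groups=[noiseless_group(), noiseless_group("KO", genotype="KO")],
        trials_per_day=5,
        dropout_prob=0.0,
    )


class TestReachTrajectory:
    def test_noiseless_success_touches_pellet_at_apex(self, cfg):
        rng = np.random.default_rng(1)
        xy, lik, apex = simulate_reach_trajectory(cfg, 1, cfg.groups[0], "success", rng)
        d = np.hypot(xy[:, 0] - cfg.pellet_xy[0], xy[:, 1] - cfg.pellet_xy[1])
        assert d[apex] == pytest.approx(0.0, abs=1e-9)
        assert d.min() == pytest.approx(0.0, abs=1e-9)
        assert len(xy) >= 6
        assert np.all(lik >= 0.85)  # dropout disabled

    def test_same_seed_byte_identical(self, cfg):
        a = simulate_reach_trajectory(cfg, 3, cfg.groups[0], "contact_miss",
                                      np.random.default_rng(7))
        b = simulate_reach_trajectory(cfg, 3, cfg.groups[0], "contact_miss",
                                      np.random.default_rng(7))
        assert a[0].tobytes() == b[0].tobytes()
        assert a[1].tobytes() == b[1].tobytes()

    def test_unknown_outcome_rejected(self, cfg):
        with pytest.raises(UnknownOutcomeError):
            simulate_reach_trajectory(cfg, 1, cfg.groups[0], "slip", np.random.default_rng(0))

    def test_miss_overshoots_pellet_x(self, cfg):
        rng = np.random.default_rng(2)
        xy, _, apex = simulate_reach_trajectory(cfg, 1, cfg.groups[0], "complete_miss", rng)
        overshoot = cfg.groups[0].overshoot_curve(1)
        assert xy[apex, 0] == pytest.approx(cfg.pellet_xy[0] + overshoot)

    def test_delta_y_decreases_with_day(self):
        """Monte-Carlo mean ΔY over 1,000 reaches per day is strictly smaller
        on day 8 than day 1 when the vertical-spread curve decreases."""
        g = GroupParams(label="WT", vertical_spread_curve=DecayCurve(18.0, 6.0))
        cfg = SimulationConfig(groups=[g])
        assert g.vertical_spread_curve(8) < g.vertical_spread_curve(1)
        rng = np.random.default_rng(42)
        means = {}
        for day in (1, 8):
            vals = []
            for _ in range(1000):
                xy, _, apex = simulate_reach_trajectory(cfg, day, g, "success", rng)
                vals.append(reach_delta_y(Reach(frames=np.arange(apex + 1), xy=xy[: apex + 1])))
            means[day] = np.mean(vals)
        assert means[8] < means[1]


class TestTrialLabels:
    def test_no_try_rate_one(self):
        cfg = SimulationConfig(no_try_rate=1.0)
        rng = np.random.default_rng(0)
        assert all(draw_trial_labels(rng, 0.5, cfg) == [] for _ in range(100))

    def test_certain_success_single_attempt(self):
        cfg = SimulationConfig(no_try_rate=0.0, vain_rate=0.0,
                               reaches_per_trial_dist=(1.0,))
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert draw_trial_labels(rng, 1.0, cfg) == ["success"]

    def test_at_most_one_success_and_vain_only_after(self):
        cfg = SimulationConfig(no_try_rate=0.1, vain_rate=0.5)
        rng = np.random.default_rng(3)
        for _ in range(500):
            labels = draw_trial_labels(rng, 0.5, cfg)
            assert labels.count("success") <= 1
            if "vain" in labels:
                assert labels.index("vain") > labels.index("success")

    def test_trial_success_fraction_matches_binomial(self):
        """10,000 single-attempt trials at q=0.4: success fraction within 3
        binomial standard errors of 0.4."""
        cfg = SimulationConfig(no_try_rate=0.0, vain_rate=0.0,
                               reaches_per_trial_dist=(1.0,))
        rng = np.random.default_rng(11)
        n = 10_000
        hits = sum("success" in draw_trial_labels(rng, 0.4, cfg) for _ in range(n))
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(hits / n - 0.4) <= 3 * se


class TestTrialAndSession:
    def test_trial_frame_count(self, cfg):
        t = simulate_trial(cfg, cfg.groups[0], 1, 0, np.random.default_rng(0))
        assert all(arr.shape == (cfg.frames_per_trial, 3) for arr in t.points.values())

    def test_vain_reaches_outside_pellet_interval(self, cfg):
        rng = np.random.default_rng(5)
        seen = 0
        for _ in range(200):
            t = simulate_trial(cfg, cfg.groups[0], 8, 0, rng)
            lo, hi = t.pellet_present
            for s, e, lab in t.ground_truth:
                if lab == "vain":
                    seen += 1
                    assert s >= hi
                else:
                    assert lo <= s < hi
        assert seen > 0

    def test_ground_truth_track_consistency(self, cfg):
        """With dropout 0, every ground-truth reach interval has ≥ 6 frames
        inside the tracking bounds with likelihood ≥ 0.85."""
        sess = simulate_subject_day(cfg, 0, 0, 1)
        ft = filter_track(sess.pose, sess.paw, 0.85, cfg.bounds())
        retained = set(ft.frames.tolist())
        gt = sess.ground_truth[~sess.ground_truth.no_try]
        assert len(gt) > 0
        for _, row in gt.iterrows():
            inside = sum(f in retained for f in range(row.start_frame, row.end_frame + 1))
            assert inside >= 6


class TestCohort:
    def test_file_counts_and_manifest(self, tmp_path):
        cfg = SimulationConfig(
            groups=[noiseless_group(n_subjects=1), noiseless_group("KO", genotype="KO", n_subjects=1)],
            days=2, trials_per_day=3,
        )
        paths = write_cohort(simulate_cohort(cfg), tmp_path / "cohort")
        poses = sorted(paths["poses"].glob("*_day*.csv"))
        assert len(poses) == 4  # 2 subjects x 2 days
        manifest = (paths["manifest"]).read_text().strip().splitlines()
        assert len(manifest) == 3  # header + 2 subjects

    def test_same_seed_identical_checksums(self, tmp_path):
        cfg = SimulationConfig(
            groups=[noiseless_group(n_subjects=1)], days=2, trials_per_day=2, seed=9
        )
        sums = []
        for name in ("a", "b"):
            paths = write_cohort(simulate_cohort(cfg), tmp_path / name)
            digest = {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(paths["poses"].iterdir())
            }
            sums.append(digest)
        assert sums[0] == sums[1]

    def test_ground_truth_reach_count_consistent(self, tmp_path, cfg):
        cohort = simulate_cohort(cfg)
        total = 0
        by_scan = 0
        for sess in cohort.iter_sessions():
            gt = sess.ground_truth
            total += int((~gt.no_try).sum())
            by_scan += sum(
                1 for _, r in gt.iterrows() if not r.no_try and r.start_frame >= 0
            )
        assert total == by_scan > 0

    def test_unwritable_path_raises_named_error(self, cfg):
        with pytest.raises(OSError, match="/proc"):
            write_cohort(simulate_cohort(cfg), "/proc/nope")


class TestOutcomeCohort:
    def test_label_partition_and_success_rate(self):
        cfg = SimulationConfig(trials_per_day=50, days=2, seed=4)
        records = simulate_outcome_cohort(cfg)
        assert len(records) == sum(g.n_subjects for g in cfg.groups) * 2 * 50
        for r in records:
            assert r.labels.count("success") <= 1
            assert r.no_try == (len(r.labels) == 0)
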