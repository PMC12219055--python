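"""SDT computation, engagement windows, and trial-history labeling."""

import numpy as np
import pytest
from scipy.stats import norm

from whiskattn import behavior
from whiskattn.behavior import (GO_CATEGORIES, NOGO_CATEGORIES, compute_sdt,
                                classify_trial_history, engagement_window)
from conftest import category_counts, make_session


class TestComputeSDT:
    def test_equal_rates_give_zero_dprime_and_criterion(self):
        m = compute_sdt(5, 5, 5, 5)
        assert m.d_prime == 0.0
        assert m.criterion == 0.0

    def test_inverse_normal_oracle(self):
        m = compute_sdt(84, 16, 50, 50)
        assert m.d_prime == pytest.approx(norm.ppf(0.84), abs=1e-9)
        assert m.criterion == pytest.approx(-0.5 * norm.ppf(0.84), abs=1e-9)

    def test_log_linear_correction_on_perfect_hit_rate(self):
        m = compute_sdt(100, 0, 25, 75)
        assert m.hit_rate == pytest.approx(100.5 / 101)
        assert m.correction_applied
        expected = norm.ppf(100.5 / 101) - norm.ppf(0.25)
        assert m.d_prime == pytest.approx(expected, abs=1e-9)

    def test_no_correction_raises_on_extreme_rate(self):
        with pytest.raises(ValueError):
            compute_sdt(10, 0, 5, 5, correction="none")

    def test_liberal_responding_gives_negative_criterion(self):
        m = compute_sdt(90, 10, 60, 40)
        assert m.criterion < 0

    def test_agrees_with_independent_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_go, n_nogo = rng.integers(2, 200, size=2)
            n_hit = rng.integers(0, n_go + 1)
            n_fa = rng.integers(0, n_nogo + 1)
            m = compute_sdt(n_hit, n_go - n_hit, n_fa, n_nogo - n_fa)
            # independent inverse-normal computation
            hr = n_hit / n_go
            fa = n_fa / n_nogo
            if hr in (0.0, 1.0):
                hr = (n_hit + 0.5) / (n_go + 1)
            if fa in (0.0, 1.0):
                fa = (n_fa + 0.5) / (n_nogo + 1)
            z_hr = norm.ppf(hr)
            z_fa = norm.ppf(fa)
            assert m.d_prime == pytest.approx(z_hr - z_fa, abs=1e-9)
            assert m.criterion == pytest.approx(-(z_hr + z_fa) / 2, abs=1e-9)


class TestEngagementWindow:
    def _good_block(self, grid, n, start_index=0, t0=0.0):
        rows = []
        for i in range(n):
            if i % 2 == 0:
                rows.append(("Go", "D2", "Hit"))
            else:
                rows.append(("NoGo", None, "CR"))
        return rows

    def test_constant_high_performance_returns_full_range(self, grid3x3):
        rows = self._good_block(grid3x3, 120)
        s = make_session(rows, grid3x3)
        first, last = engagement_window(s, window=50, cutoff=0.5)
        assert first == 0
        assert last == len(s.trials) - 1

    def test_low_performance_start_block_is_trimmed(self, grid3x3):
        bad = [("Go", "D2", "Miss") if i % 2 == 0 else ("NoGo", None, "CR")
               for i in range(80)]
        good = self._good_block(grid3x3, 200)
        s = make_session(bad + good, grid3x3)
        first, last = engagement_window(s, window=50, cutoff=0.5)
        # independent scan: first window fully inside the good block that
        # meets the cutoff cannot start before trial 80's neighborhood
        assert first > 40
        assert last == len(s.trials) - 1

    def test_high_cutoff_on_moderate_session_errors(self, grid3x3):
        # deterministic d' ~ 0.5 session (HR 0.6, FA 0.4): the stricter
        # spike-recording cutoff of 1.2 rejects every window
        pattern = [("Go", "D2", "Hit"), ("Go", "D2", "Hit"),
                   ("Go", "D2", "Hit"), ("Go", "D2", "Miss"),
                   ("Go", "D2", "Miss"),
                   ("NoGo", None, "FA"), ("NoGo", None, "FA"),
                   ("NoGo", None, "CR"), ("NoGo", None, "CR"),
                   ("NoGo", None, "CR")]
        s = make_session(pattern * 20, grid3x3)
        assert engagement_window(s, window=50, cutoff=0.4)
        with pytest.raises(ValueError):
            engagement_window(s, window=50, cutoff=1.2)

    def test_too_few_trials_rejected(self, grid3x3):
        s = make_session(self._good_block(grid3x3, 20), grid3x3)
        with pytest.raises(ValueError):
            engagement_window(s, window=50)


class TestClassifyTrialHistory:
    def test_prior_nogo(self, grid3x3):
        s = make_session([("NoGo", None, "CR"), ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[1].category == "priorNoGo"

    def test_multi_hit_different_whisker(self, grid3x3):
        s = make_session([("Go", "C2", "Hit"), ("Go", "C2", "Hit"),
                          ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[2].category == "priorGT1HitDiff"
        assert labels[2].run_length == 2
        assert labels[2].prior_whisker == "C2"

    def test_streak_broken_by_whisker_change(self, grid3x3):
        s = make_session([("Go", "C2", "Hit"), ("Go", "D1", "Hit"),
                          ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[2].category == "prior1HitSame"
        assert labels[2].run_length == 1

    def test_prior_miss_same_and_diff(self, grid3x3):
        s = make_session([("Go", "D1", "Miss"), ("Go", "D1", "Hit"),
                          ("Go", "C3", "Miss"), ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[1].category == "priorMissSame"
        assert labels[3].category == "priorMissDiff"

    def test_nogo_trial_categories(self, grid3x3):
        s = make_session([("Go", "D1", "Hit"), ("NoGo", None, "CR"),
                          ("Go", "C1", "Hit"), ("Go", "C1", "Hit"),
                          ("NoGo", None, "FA")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[1].category == "prior1Hit"
        assert labels[4].category == "priorGT1Hit"

    def test_first_trial_unclassified(self, grid3x3):
        s = make_session([("Go", "D2", "Hit")], grid3x3)
        assert classify_trial_history(s)[0].category is None

    def test_modes_agree_without_nogo_trials(self, grid3x3):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(60):
            w = grid3x3.whiskers[rng.integers(9)]
            rows.append(("Go", w, "Hit" if rng.random() < 0.7 else "Miss"))
        s = make_session(rows, grid3x3)
        a = classify_trial_history(s, mode="consecutive")
        b = classify_trial_history(s, mode="ignore-nogo")
        assert [x.category for x in a] == [y.category for y in b]

    def test_ignore_nogo_skips_nogo_as_history_source(self, grid3x3):
        s = make_session([("Go", "D1", "Hit"), ("NoGo", None, "CR"),
                          ("Go", "D1", "Hit")], grid3x3)
        cons = classify_trial_history(s, mode="consecutive")
        ign = classify_trial_history(s, mode="ignore-nogo")
        assert cons[2].category == "priorNoGo"
        assert ign[2].category == "prior1HitSame"

    def test_low_reward_hit_treated_as_non_boosting(self, grid3x3):
        s = make_session(
            [("Go", "D1", "Hit", {"reward": 0.05}),
             ("Go", "D1", "Hit", {"reward": 4.0}),
             ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(
            s, reward_threshold_fraction=0.04, low_reward_breaks=True)
        # trial 1's prior hit earned ~1% of max reward: treated like a miss
        assert labels[1].category == "priorMissSame"
        # trial 2's prior is a full-reward hit, streak length 1
        assert labels[2].category == "prior1HitSame"

    def test_aborted_trials_do_not_break_streaks_by_default(self, grid3x3):
        s = make_session(
            [("Go", "D1", "Hit"), ("Go", "D1", "Hit"),
             ("Go", "D2", "Miss", {"aborted": True}),
             ("Go", "D1", "Hit")], grid3x3)
        labels = classify_trial_history(s)
        assert labels[3].category == "priorGT1HitSame"
        labels_b = classify_trial_history(s, abort_breaks=True)
        assert labels_b[3].category is None

    def test_offset_class_and_intervals(self, grid3x3):
        s = make_session([("Go", "D1", "Hit"), ("NoGo", None, "CR"),
                          ("Go", "C1", "Hit")], grid3x3)
        labels = classify_trial_history(s, mode="ignore-nogo")
        assert labels[2].offset_class == "same-arc adjacent"
        assert labels[2].inter_go_interval == pytest.approx(6.0)


class TestHistoryConditionedSDT:
    def test_category_counts_partition_engagement_window(
            self, boosted_session, boosted_labels):
        first, last = engagement_window(boosted_session)
        counts = category_counts(boosted_session, boosted_labels,
                                 (first, last))
        total = sum(counts.values())
        n_window = sum(1 for t in boosted_session.trials
                       if not t.aborted and first <= t.index <= last)
        assert total == n_window
        for (kind, cat), _n in counts.items():
            if cat is None:
                continue
            assert cat in (GO_CATEGORIES if kind == "Go"
                           else NOGO_CATEGORIES)

    def test_boosted_sessions_order_categories(self, boosted_config,
                                               grid3x3):
        from whiskattn import simulate
        counts = []
        for seed in range(8):
            s = simulate.generate_session(boosted_config, grid3x3, seed=seed)
            labels = behavior.classify_trial_history(s)
            counts.append(behavior.history_counts(s, labels))
        pooled = behavior.pooled_history_sdt(counts)
        d_same = pooled["priorGT1HitSame"]["metrics"].d_prime
        d_nogo = pooled["priorNoGo"]["metrics"].d_prime
        d_diff = pooled["priorGT1HitDiff"]["metrics"].d_prime
        assert d_same > d_nogo > d_diff
        assert pooled["prior1HitSame"]["metrics"].d_prime > d_nogo

    def test_shuffle_destroys_same_diff_separation(self, boosted_config,
                                                   grid3x3):
        from dataclasses import replace

        from whiskattn import simulate
        rng = np.random.default_rng(9)
        counts_shuffled, counts_real = [], []
        for seed in range(12):
            s = simulate.generate_session(boosted_config, grid3x3, seed=seed)
            counts_real.append(behavior.history_counts(
                s, behavior.classify_trial_history(s)))
            # shuffle whisker identities across Go trials: history becomes
            # uninformative about somatotopic match
            go_ws = [t.whisker for t in s.trials if t.kind == "Go"]
            rng.shuffle(go_ws)
            it = iter(go_ws)
            shuffled = [replace(t, whisker=next(it)) if t.kind == "Go" else t
                        for t in s.trials]
            s2 = behavior.Session(trials=shuffled, grid=grid3x3)
            counts_shuffled.append(behavior.history_counts(
                s2, behavior.classify_trial_history(s2)))
        real = behavior.pooled_history_sdt(counts_real)
        shuf = behavior.pooled_history_sdt(counts_shuffled)
        gap_real = (real["priorGT1HitSame"]["metrics"].d_prime
                    - real["priorGT1HitDiff"]["metrics"].d_prime)
        gap_shuf = (shuf["priorGT1HitSame"]["metrics"].d_prime
                    - shuf["priorGT1HitDiff"]["metrics"].d_prime)
        assert gap_real > 1.0
        assert gap_shuf < gap_real / 2


class TestSpatialGradientAndTemporalProfile:
    def test_spatial_gradient_recovers_kernel_ordering(self, boosted_config,
                                                       grid3x3):
        from whiskattn import simulate
        acc = {}
        for seed in range(8):
            s = simulate.generate_session(boosted_config, grid3x3, seed=seed)
            labels = behavior.classify_trial_history(s)
            grad = behavior.spatial_gradient(s, labels)
            for cls, entry in grad.items():
                acc.setdefault(cls, []).append(entry["delta_d"])
        means = {cls: np.mean(v) for cls, v in acc.items()}
        assert means["same"] > means["same-row adjacent"]
        assert means["same-row adjacent"] > means["same-arc adjacent"]
        assert means["same-arc adjacent"] > means["diagonal adjacent"]

    def test_flat_profile_without_boost(self, grid3x3):
        from whiskattn import simulate
        cfg = simulate.null_behavior_config(p_same_repeat=0.4)
        hit_cats = {"prior1HitSame", "priorGT1HitSame",
                    "prior1HitDiff", "priorGT1HitDiff"}

        def by_offset(t, lab):
            return lab.offset_class if lab.category in hit_cats else None

        counts = []
        for seed in range(12):
            s = simulate.generate_session(cfg, grid3x3, seed=seed)
            labels = behavior.classify_trial_history(s)
            counts.append(behavior.history_counts(s, labels,
                                                  go_key=by_offset))
        pooled = behavior.pooled_history_sdt(
            counts, key_to_nogo=lambda k: ("prior1Hit", "priorGT1Hit"))
        baseline = cfg.baseline_dprime
        for cls, entry in pooled.items():
            assert abs(entry["metrics"].d_prime - baseline) < 0.2, cls

    def test_empty_interval_bins_absent(self, boosted_session,
                                        boosted_labels):
        profile = behavior.temporal_profile(
            boosted_session, boosted_labels,
            interval_bins=(0, 3, 5, 7, 9, 11, 1000, 2000))
        assert (1000, 2000) not in profile
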