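"""Evoked responses, responsiveness, AMI, detrending, profiles, PSTHs."""

import numpy as np
import pytest

from whiskattn import behavior, neural, simulate, stats


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        tr = neural.dff_from_fluorescence([10.0] * 50)
        assert np.allclose(tr.dff, 0.0)

    def test_f0_is_twentieth_percentile(self):
        raw = [10.0, 10.0, 10.0, 20.0]
        tr = neural.dff_from_fluorescence(raw)
        f0 = np.percentile(raw, 20)   # independent oracle
        assert tr.f0 == pytest.approx(f0)
        assert tr.dff[-1] == pytest.approx((20 - f0) / f0)

    def test_neuropil_scaling(self):
        raw = np.array([10.0, 12.0, 14.0, 20.0])
        neuropil = np.array([2.0, 2.0, 2.0, 2.0])
        tr = neural.dff_from_fluorescence(raw, neuropil, scale=0.3)
        assert np.allclose(tr.frames, raw - 0.6)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError):
            neural.dff_from_fluorescence([-5.0, -5.0, -5.0, 1.0])


class TestEvokedResponse:
    def test_flat_trace_gives_zero(self):
        assert neural.evoked_response(np.ones(20), onset=8) == 0.0

    def test_unit_step(self):
        trace = np.zeros(20)
        trace[8:] = 1.0
        assert neural.evoked_response(trace, onset=8) == pytest.approx(1.0)

    def test_out_of_bounds_window_rejected(self):
        with pytest.raises(ValueError):
            neural.evoked_response(np.ones(5), onset=4, post_window=7)

    def test_zscore_normalization(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(0.0, 2.0, size=(200, 3, 20))
        traces[:, :, 8:15] += 4.0
        ev = neural.evoked_from_table(traces, onset=8,
                                      normalize="zscore-baseline")
        # baseline SD is 2, step is 4 -> z-scored evoked ~ 2
        assert np.nanmean(ev) == pytest.approx(2.0, abs=0.1)

    def test_poisson_spike_rate_difference(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(300):
            post = rng.uniform(0, 0.5, size=rng.poisson(20 * 0.5))
            base = -rng.uniform(0, 0.5, size=rng.poisson(5 * 0.5))
            diffs.append(neural.spike_evoked_rate(
                np.concatenate([base, post])))
        assert np.mean(diffs) == pytest.approx(15.0, abs=1.0)


class TestResponsiveness:
    def test_type_one_control(self):
        rng = np.random.default_rng(2)
        n_false = 0
        n_seeds = 40
        for seed in range(n_seeds):
            go = {w: rng.normal(0, 1, 12) for w in ("D1", "D2", "D3")}
            nogo = rng.normal(0, 1, 30)
            res = neural.responsiveness_test(go, nogo, n_iterations=500,
                                             seed=seed)
            n_false += res.responsive
        assert n_false <= 0.05 * n_seeds + 2

    def test_power_on_strong_response(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            go = {"D2": rng.normal(5, 1, 12), "D1": rng.normal(0, 1, 12)}
            nogo = rng.normal(0, 1, 30)
            res = neural.responsiveness_test(go, nogo, n_iterations=500,
                                             seed=seed)
            hits += res.responsive and res.best_whisker == "D2"
        assert hits >= 0.99 * n_seeds - 1

    def test_negative_going_response_is_non_responsive(self):
        rng = np.random.default_rng(4)
        go = {"D2": rng.normal(-5, 1, 15)}
        nogo = rng.normal(0, 1, 30)
        res = neural.responsiveness_test(go, nogo, n_iterations=500, seed=0)
        assert not res.responsive

    def test_reduces_to_core_permutation_test(self):
        rng = np.random.default_rng(5)
        go = {"D2": rng.normal(1, 1, 10)}
        nogo = rng.normal(0, 1, 20)
        res = neural.responsiveness_test(go, nogo, n_iterations=300, seed=77)
        direct = stats.permutation_test_two_sample(
            go["D2"], nogo, n_iterations=300,
            seed=stats.spawn_seeds(77, 1)[0], sided="greater")
        assert res.p_values["D2"] == direct.p_value


class TestAMI:
    def test_equal_means_give_zero(self):
        rec = neural.compute_ami({"priorGT1HitSame": 0.2,
                                  "priorGT1HitDiff": 0.2,
                                  "priorNoGo": 0.2})
        assert rec.ami_same_vs_nogo == 0.0
        assert rec.ami_same_vs_diff == 0.0

    def test_direct_substitution(self):
        rec = neural.compute_ami({"priorGT1HitSame": 0.3, "priorNoGo": 0.1})
        assert rec.ami_same_vs_nogo == pytest.approx(0.5)

    def test_closed_form_under_multiplicative_gain(self):
        for g in (1.5, 2.0, 3.0, 5.0):
            rec = neural.compute_ami({"priorGT1HitSame": g * 0.2,
                                      "priorNoGo": 0.2})
            assert rec.ami_same_vs_nogo == pytest.approx((g - 1) / (g + 1))

    def test_scale_invariance_and_antisymmetry(self):
        a, b = 0.37, 0.12
        r1 = neural.compute_ami({"priorGT1HitSame": a, "priorNoGo": b})
        r2 = neural.compute_ami({"priorGT1HitSame": 7 * a, "priorNoGo": 7 * b})
        assert r1.ami_same_vs_nogo == pytest.approx(r2.ami_same_vs_nogo)
        r3 = neural.compute_ami({"priorGT1HitSame": b, "priorNoGo": a})
        assert r3.ami_same_vs_nogo == pytest.approx(-r1.ami_same_vs_nogo)

    def test_small_denominator_marked_invalid(self):
        rec = neural.compute_ami({"priorGT1HitSame": 1e-8,
                                  "priorNoGo": -1e-8})
        assert rec.ami_same_vs_nogo is None

    def test_noiseless_generator_gain_recovered_exactly(
            self, boosted_session, boosted_labels):
        # gain 3 on matching trials, zero noise, flat tuning (so the
        # whisker mixture in each condition drops out): AMI = (3-1)/(3+1)
        # for cells whose gain applied on every same-condition trial
        cfg = simulate.NeuralGenConfig(n_cells=40, attentional_gain=3.0,
                                       noise_sd=0.0, gain_min_run=2,
                                       gain_space_halfwidth=10.0,
                                       tuning_width=np.inf)
        data = simulate.generate_neural_population(cfg, boosted_session,
                                                   seed=1)
        recs = neural.ami_per_cell(data.evoked, boosted_session,
                                   boosted_labels)
        same_mask = np.array(
            [t.kind == "Go" and lab.category == "priorGT1HitSame"
             for t, lab in zip(boosted_session.trials, boosted_labels)])
        for c, rec in enumerate(recs):
            if rec.ami_same_vs_nogo is None:
                continue
            if np.all(data.truth_gain[same_mask, c] == 3.0):
                assert rec.ami_same_vs_nogo == pytest.approx(0.5, abs=1e-9)

    def test_null_gain_centers_ami_at_zero(self, boosted_session,
                                           boosted_labels):
        cfg = simulate.NeuralGenConfig(n_cells=60, attentional_gain=1.0,
                                       noise_sd=0.1)
        data = simulate.generate_neural_population(cfg, boosted_session,
                                                   seed=2)
        recs = neural.ami_per_cell(data.evoked, boosted_session,
                                   boosted_labels)
        vals = [r.ami_same_vs_diff for r in recs
                if r.ami_same_vs_diff is not None and r.valid]
        assert len(vals) > 10
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * sem + 0.05


class TestDetrend:
    def test_all_zero_traces_stay_zero(self):
        arr = np.zeros((4, 20))
        out, info = neural.detrend_baseline({"c": arr}, onset=10)
        assert np.allclose(out["c"], 0.0)

    def test_linear_baseline_removed_exactly_step_preserved(self):
        frames = np.arange(24, dtype=float)
        m, b = -0.05, 1.2
        step = np.zeros(24)
        step[10:] = 0.7
        trials = np.stack([m * frames + b + step for _ in range(5)])
        out, info = neural.detrend_baseline({"hit": trials}, onset=10,
                                            baseline_window=8)
        det = out["hit"]
        # residual baseline slope ~ 0
        for row in det:
            slope = np.polyfit(frames[2:10], row[2:10], 1)[0]
            assert abs(slope) < 1e-9
        # step amplitude preserved
        amp = det[:, 10:].mean(axis=1) - det[:, 2:10].mean(axis=1)
        expected = (step[10:].mean() - step[2:10].mean()
                    - m * (frames[10:].mean() - frames[2:10].mean())
                    + m * (frames[10:].mean() - frames[2:10].mean()))
        assert np.allclose(amp, step[10:].mean(), atol=1e-9)

    def test_steeper_generator_decay_gives_steeper_fitted_slope(self):
        frames = np.arange(24, dtype=float)
        rew = np.stack([np.exp(-frames / 4) for _ in range(6)])
        unrew = np.stack([np.exp(-frames / 40) for _ in range(6)])
        _, info = neural.detrend_baseline(
            {"prior_rewarded": rew, "prior_unrewarded": unrew},
            onset=10, baseline_window=8)
        assert (info["slopes"]["prior_rewarded"]
                < info["slopes"]["prior_unrewarded"])

    def test_insufficient_trials_skipped(self):
        arr = np.ones((1, 20))
        out, info = neural.detrend_baseline({"c": arr}, onset=10)
        assert info["skipped"] == ["c"]
        assert np.array_equal(out["c"], arr)


class TestSomatotopicProfile:
    def test_spotlight_halfwidth_recovered(self, boosted_config, grid3x3):
        est = []
        for seed in range(6):
            s = simulate.generate_session(boosted_config, grid3x3, seed=seed)
            labels = behavior.classify_trial_history(s)
            cfg = simulate.NeuralGenConfig(n_cells=150, attentional_gain=3.0,
                                           noise_sd=0.02,
                                           gain_space_halfwidth=0.75,
                                           gain_min_run=2)
            data = simulate.generate_neural_population(cfg, s, seed=seed)
            prof = neural.somatotopic_profile(data.cells, data.evoked, s,
                                              labels, bin_width=0.25)
            try:
                est.append(neural.profile_half_max_distance(prof))
            except ValueError:
                continue
        assert len(est) >= 3
        assert np.mean(est) == pytest.approx(0.75, rel=0.25)

    def test_nonspecific_gain_gives_flat_difference(self, boosted_config,
                                                    grid3x3):
        s = simulate.generate_session(boosted_config, grid3x3, seed=3)
        labels = behavior.classify_trial_history(s)
        cfg = simulate.NeuralGenConfig(n_cells=200, cell_class="VIP",
                                       gain_whisker_specific=False,
                                       attentional_gain=2.0, noise_sd=0.02)
        data = simulate.generate_neural_population(cfg, s, seed=3)
        prof = neural.somatotopic_profile(data.cells, data.evoked, s, labels,
                                          bin_width=0.5)
        diff = prof["priorGT1HitSame"] - prof["priorNoGo"]
        valid = ~np.isnan(diff)
        # non-specific gain boosts everywhere tuning is non-zero; the
        # *ratio* profile is flat: normalize by the NoGo profile
        ratio = diff[valid] / prof["priorNoGo"][valid]
        assert ratio.max() - ratio.min() < 0.75


class TestPSTH:
    def test_no_spikes_gives_zero_psth(self):
        out = neural.psth([np.array([])] * 5)
        assert np.allclose(out["rate"], 0.0)

    def test_homogeneous_poisson_rate_recovered(self):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(-0.5, 1.0, rng.poisson(15)))
                  for _ in range(400)]
        out = neural.psth(trials)
        assert out["rate"].mean() == pytest.approx(10.0, abs=0.5)

    def test_deflection_train_produces_five_peaks(self, grid3x3):
        bcfg = simulate.BehaviorGenConfig(n_trials=120)
        s = simulate.generate_session(bcfg, grid3x3, seed=5)
        ncfg = simulate.NeuralGenConfig(n_cells=3, cell_class="RS-spike",
                                        peak_response=40.0, noise_sd=0.0,
                                        tuning_width=5.0)
        data = simulate.generate_neural_population(ncfg, s, seed=5)
        go_idx = [i for i, t in enumerate(s.trials) if t.kind == "Go"]
        trains = [data.spike_times[i][0] for i in go_idx]
        out = neural.psth(trains)
        centers, rate = out["bin_centers"], out["rate"]
        base = rate[centers < 0].mean()
        for k in range(5):
            t0 = 0.100 * k
            peak = rate[(centers >= t0) & (centers < t0 + 0.03)].mean()
            assert peak > base + 3.0, f"deflection {k} peak missing"


def test_laminar_specific_attention_effect(boosted_session, boosted_labels):
    """Whisker-specific AMI appears only in layers carrying the gain."""
    cfg = simulate.NeuralGenConfig(
        n_cells=90, attentional_gain=3.0, noise_sd=0.05,
        gain_space_halfwidth=10.0, gain_min_run=2,
        layers=("L2/3", "L4", "L5a/b"),
        layers_with_gain=("L2/3", "L5a/b"))
    data = simulate.generate_neural_population(cfg, boosted_session, seed=8)
    recs = neural.ami_per_cell(data.evoked, boosted_session, boosted_labels)
    by_layer = {}
    for rec, layer in zip(recs, data.cells.layer):
        if rec.ami_same_vs_diff is not None:
            by_layer.setdefault(layer, []).append(rec.ami_same_vs_diff)
    assert np.mean(by_layer["L2/3"]) > 0.2
    assert np.mean(by_layer["L5a/b"]) > 0.2
    assert abs(np.mean(by_layer["L4"])) < 0.1
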