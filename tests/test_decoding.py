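"""Classifiers, cross-validation harness, time-resolved effect sizes."""

import numpy as np
import pytest

from spikepatterns import (
    SomConfig,
    SomMap,
    SplitPlan,
    build_trajectory,
    classify_split,
    cohens_d_timecourse,
    mean_rate_classify,
    model_trajectories,
    one_sample_z,
    prepare,
    run_performance,
    specificity_classify,
    split_half,
    time_resolved_distances,
    trajectory_classify,
)
from spikepatterns.datasets import SpikeDataset, Trial
from spikepatterns.decoding import Prepared, TrajectoryModel, sliding_trajectory
from spikepatterns.som import ModelTrialSet


class TestSplitHalf:
    def test_even_split_disjoint(self, random_dataset):
        plan = split_half(random_dataset, seed=0)
        for j in random_dataset.stimulus_set:
            assert len(plan.train[j]) == 2 and len(plan.test[j]) == 2
            assert not set(plan.train[j]) & set(plan.test[j])

    def test_odd_count_extra_to_train(self):
        trials = [Trial(i, "a", [np.array([1.0 + i])]) for i in range(5)]
        ds = SpikeDataset([0], trials, ["a"], 10.0)
        plan = split_half(ds, seed=1)
        assert len(plan.train["a"]) == 3 and len(plan.test["a"]) == 2

    def test_seeds_give_different_plans(self, random_dataset):
        plans = {
            tuple(sorted(split_half(random_dataset, s).train_ids)) for s in range(30)
        }
        assert len(plans) > 20

    def test_single_trial_stimulus_rejected(self):
        ds = SpikeDataset([0], [Trial(0, "a", [np.array([1.0])])], ["a"], 10.0)
        with pytest.raises(ValueError):
            split_half(ds, 0)


def make_rate_ds(rates_by_stim, n_trials, TD_ms=2000.0, seed=0):
    """Regular-spacing spike trains at given per-(stimulus, unit) rates."""
    trials, tid = [], 0
    for stim, unit_rates in rates_by_stim.items():
        for _ in range(n_trials):
            spikes = []
            for r in unit_rates:
                n = int(round(r * TD_ms / 1000.0))
                spikes.append(np.linspace(1.0, TD_ms - 1.0, n) if n else np.empty(0))
            trials.append(Trial(tid, stim, spikes))
            tid += 1
    return SpikeDataset(
        list(range(len(next(iter(rates_by_stim.values()))))),
        trials, list(rates_by_stim), TD_ms,
    )


class TestMeanRateClassifier:
    def test_model_rate_is_count_over_duration_and_trials(self):
        # 10 spikes/trial over TD=2 s -> 5 Hz model entry
        ds = make_rate_ds({"a": [5.0], "b": [20.0]}, n_trials=10)
        plan = split_half(ds, 0)
        pred = mean_rate_classify(ds, plan)
        assert set(pred) == plan.test_ids

    def test_nearest_model_wins(self):
        ds = make_rate_ds({"a": [5.0], "b": [20.0]}, n_trials=4)
        plan = split_half(ds, 0)
        # test trial at 18 Hz: closer to the 20 Hz model
        probe = ds.trials[0]
        probe_n = int(18 * 2)
        ds.trials[0] = Trial(probe.trial_id, "a",
                             [np.linspace(1, 1999, probe_n)])
        plan2 = SplitPlan(["a", "b"],
                          {"a": [1, 2], "b": [5, 6]},
                          {"a": [probe.trial_id], "b": [7]})
        pred = mean_rate_classify(ds, plan2)
        assert pred[probe.trial_id] == "b"

    def test_identical_to_model_distance_zero(self):
        ds = make_rate_ds({"a": [5.0, 2.0], "b": [20.0, 9.0]}, n_trials=4)
        plan = split_half(ds, 3)
        pred = mean_rate_classify(ds, plan)
        # every trial has exactly its stimulus's rates -> all correct
        truth = {t.trial_id: t.stimulus for t in ds.trials}
        assert all(pred[tid] == truth[tid] for tid in pred)


def mts_from_seqs(seqs, stimuli, mv):
    som = SomMap(np.asarray(mv, float), SomConfig(n_side=2, m_steps=1))
    return ModelTrialSet(list(range(len(seqs))), list(stimuli),
                         [np.asarray(s) for s in seqs], som)


class TestSpecificityClassifier:
    def test_hand_computed_scores(self):
        # train: pattern 0 exclusive to stim a, pattern 1 exclusive to b.
        # test trial has r = (4, 6) -> scores (4, 6) -> stimulus b.
        mv = np.random.default_rng(0).normal(size=(8, 2))
        seqs = [[0, 0, 0], [1, 1, 1], [0] * 4 + [1] * 6]
        mts = mts_from_seqs(seqs, ["a", "b", "a"], mv)
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [1]}, {"a": [2], "b": []})
        pred = specificity_classify(mts, plan)
        assert pred[2] == "b"

    def test_exclusive_pattern_assigns_its_stimulus(self):
        mv = np.random.default_rng(0).normal(size=(8, 2))
        seqs = [[2, 2], [5, 5], [5, 5, 5]]
        mts = mts_from_seqs(seqs, ["a", "b", "a"], mv)
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [1]}, {"a": [2], "b": []})
        assert specificity_classify(mts, plan)[2] == "b"

    def test_uniform_specificity_ties_to_first_stimulus(self):
        mv = np.random.default_rng(0).normal(size=(8, 2))
        seqs = [[3, 3], [3, 3], [3, 3]]
        mts = mts_from_seqs(seqs, ["a", "b", "b"], mv)
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [1]}, {"a": [], "b": [2]})
        assert specificity_classify(mts, plan)[2] == "a"

    def test_unseen_patterns_score_zero(self):
        mv = np.random.default_rng(0).normal(size=(8, 2))
        seqs = [[0, 0], [1, 1], [7, 7, 1]]  # 7 unseen in training
        mts = mts_from_seqs(seqs, ["a", "b", "b"], mv)
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [1]}, {"a": [], "b": [2]})
        assert specificity_classify(mts, plan)[2] == "b"


class TestTrajectories:
    def setup_method(self):
        self.som = SomMap(
            np.array([[0.0, 2.0], [4.0, 0.0]] + [[9.0, 9.0]] * 6),
            SomConfig(n_side=2, m_steps=1),
        )

    def test_constant_sequence(self):
        traj = build_trajectory(np.zeros(10, int), self.som, 5)
        np.testing.assert_allclose(traj, [[0, 2], [0, 2]])

    def test_window_mean(self):
        traj = build_trajectory(np.array([0, 1, 0, 1]), self.som, 4)
        np.testing.assert_allclose(traj, [[2.0, 1.0]])

    def test_window_count_drops_partial(self):
        traj = build_trajectory(np.zeros(1200, int), self.som, 20)
        assert traj.shape[0] == 60
        assert build_trajectory(np.zeros(130, int), self.som, 20).shape[0] == 6

    def test_tau_bins_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            build_trajectory(np.zeros(3, int), self.som, 4)

    def test_model_trajectories_mean(self):
        trajs = {0: np.zeros((3, 2)), 1: np.full((3, 2), 2.0), 2: np.ones((3, 2))}
        labels = {0: "a", 1: "a", 2: "b"}
        model = model_trajectories(trajs, labels, ["a", "b"])
        np.testing.assert_allclose(model.mt["a"], 1.0)
        np.testing.assert_allclose(model.mt["b"], 1.0)

    def test_model_trajectories_window_oracle(self):
        rng = np.random.default_rng(1)
        trajs = {i: rng.normal(size=(4, 3)) for i in range(6)}
        labels = {i: "a" if i < 4 else "b" for i in range(6)}
        model = model_trajectories(trajs, labels, ["a", "b"])
        for w in range(4):
            np.testing.assert_allclose(
                model.mt["a"][w], np.mean([trajs[i][w] for i in range(4)], axis=0)
            )

    def test_mismatched_window_counts_rejected(self):
        trajs = {0: np.zeros((3, 2)), 1: np.zeros((4, 2))}
        with pytest.raises(ValueError):
            model_trajectories(trajs, {0: "a", 1: "a"}, ["a"])

    def test_classify_exact_match_and_1d_case(self):
        model = TrajectoryModel(["s1", "s2"],
                                {"s1": np.array([[1.0]]), "s2": np.array([[4.0]])}, 1)
        pred = trajectory_classify({0: np.array([[3.0]])}, model)
        assert pred[0] == "s2"
        pred = trajectory_classify({0: np.array([[4.0]])}, model)
        assert pred[0] == "s2"

    def test_distance_matches_window_loop_oracle(self):
        rng = np.random.default_rng(2)
        mt = {"a": rng.normal(size=(5, 3)), "b": rng.normal(size=(5, 3))}
        model = TrajectoryModel(["a", "b"], mt, 1)
        traj = rng.normal(size=(5, 3))
        dts = {
            j: sum(np.linalg.norm(traj[w] - mt[j][w]) for w in range(5))
            for j in ("a", "b")
        }
        expected = min(dts, key=dts.get)
        assert trajectory_classify({0: traj}, model)[0] == expected

    def test_sliding_trajectory_matches_blocked_when_step_equals_window(self):
        pids = np.random.default_rng(3).integers(0, 8, size=100)
        blocked = build_trajectory(pids, self.som, 10)
        _, slid = sliding_trajectory(pids, self.som, 10, 10)
        np.testing.assert_allclose(slid, blocked)


class TestRunPerformance:
    def test_degenerate_classifier_scores_chance_on_balanced_sets(self, random_dataset):
        prep = prepare(random_dataset, 20.0, SomConfig(n_side=2, m_steps=50, seed=0))
        always_first = lambda prep_, plan: {
            tid: plan.stimulus_set[0] for tid in plan.test_ids
        }
        res = run_performance(random_dataset, always_first, 20.0, n_splits=5,
                              seed=0, prep=prep)
        assert res.mean == pytest.approx(1 / 3)
        assert res.chance == pytest.approx(1 / 3)

    def test_mean_equals_per_split_mean(self, random_dataset):
        prep = prepare(random_dataset, 20.0, SomConfig(n_side=2, m_steps=50, seed=0))
        res = run_performance(random_dataset, "rate", 20.0, n_splits=8, seed=1,
                              prep=prep)
        assert res.mean == pytest.approx(res.per_split.mean())
        assert np.all((res.per_split >= 0) & (res.per_split <= 1))


class TestTimeResolved:
    def _prep(self, seqs, stimuli, mv, tau_bins=2):
        som = SomMap(np.asarray(mv, float), SomConfig(n_side=2, m_steps=1))
        mts = ModelTrialSet(list(range(len(seqs))), list(stimuli),
                            [np.asarray(s) for s in seqs], som)
        ds = SpikeDataset(
            [0, 1],
            [Trial(i, stim, [np.empty(0), np.empty(0)]) for i, stim in
             enumerate(stimuli)],
            sorted(set(stimuli), key=str), float(len(seqs[0])),
        )
        trajs = {i: build_trajectory(np.asarray(s), som, tau_bins)
                 for i, s in enumerate(seqs)}
        return Prepared(ds, som, mts, tau_bins, trajs,
                        dict(zip(range(len(seqs)), stimuli)))

    def test_identical_trajectories_zero_distances(self):
        mv = np.random.default_rng(0).normal(size=(8, 2))
        seqs = [[0, 0, 0, 0]] * 4
        prep = self._prep(seqs, ["a", "a", "b", "b"], mv)
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [2]}, {"a": [1], "b": [3]})
        # two test trials needed for an SD; duplicate via both stimuli
        plan = SplitPlan(["a", "b"], {"a": [0], "b": [2]}, {"a": [1], "b": [3]})
        t, dT, dO, sT, sO = time_resolved_distances(prep, plan, "a",
                                                    win_bins=2, step_ms=1.0)
        with np.errstate(invalid="ignore"):
            assert np.nanmax(np.abs(dT)) == 0 and np.nanmax(np.abs(dO)) == 0

    def test_matches_per_trial_loop_oracle(self):
        rng = np.random.default_rng(4)
        mv = rng.normal(size=(8, 3))
        seqs = [rng.integers(0, 8, size=12) for _ in range(8)]
        stimuli = ["a", "a", "a", "a", "b", "b", "b", "b"]
        som = SomMap(mv, SomConfig(n_side=2, m_steps=1))
        prep = self._prep(seqs, stimuli, mv, tau_bins=3)
        plan = SplitPlan(["a", "b"], {"a": [0, 1], "b": [4, 5]},
                         {"a": [2, 3], "b": [6, 7]})
        t, dT, dO, sT, sO = time_resolved_distances(prep, plan, "a",
                                                    win_bins=3, step_ms=1.0)
        # oracle: explicit loops over test trials / other stimuli
        slid = {i: sliding_trajectory(np.asarray(s), som, 3, 1)[1]
                for i, s in enumerate(seqs)}
        mt_a = (slid[0] + slid[1]) / 2
        mt_b = (slid[4] + slid[5]) / 2
        d_true = np.array([np.linalg.norm(slid[i] - mt_a, axis=1) for i in (2, 3)])
        d_oth = np.array([np.linalg.norm(slid[i] - mt_b, axis=1) for i in (2, 3)])
        np.testing.assert_allclose(dT, d_true.mean(0))
        np.testing.assert_allclose(dO, d_oth.mean(0))
        np.testing.assert_allclose(sT, d_true.std(0, ddof=1))
        np.testing.assert_allclose(sO, d_oth.std(0, ddof=1))


class TestCohensD:
    def test_equal_means_zero(self):
        d = cohens_d_timecourse([1.0, 2.0], [1.0, 2.0], [0.5, 0.5], [0.5, 0.5])
        np.testing.assert_allclose(d, 0.0)

    def test_unit_effect(self):
        # d_O - d_T equals the pooled SD -> d = 1
        d = cohens_d_timecourse([1.0], [2.0], [1.0], [1.0])
        np.testing.assert_allclose(d, 1.0)

    def test_formula_on_arrays(self):
        rng = np.random.default_rng(5)
        dT, dO = rng.uniform(0, 2, 10), rng.uniform(0, 2, 10)
        sT, sO = rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 10)
        d = cohens_d_timecourse(dT, dO, sT, sO)
        np.testing.assert_allclose(d, (dO - dT) / np.sqrt((sT**2 + sO**2) / 2))

    def test_sign_flips_when_distances_swap(self):
        d1 = cohens_d_timecourse([1.0], [3.0], [0.5], [0.5])
        d2 = cohens_d_timecourse([3.0], [1.0], [0.5], [0.5])
        np.testing.assert_allclose(d1, -d2)

    def test_degenerate_zero_sds_equal_means(self):
        np.testing.assert_allclose(
            cohens_d_timecourse([1.0], [1.0], [0.0], [0.0]), 0.0
        )


class TestOneSampleZ:
    def test_mean_equals_mu0(self):
        z, p = one_sample_z([1.0, 2.0, 3.0], 2.0)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_case(self):
        # mean 1, SD 1, n 100 vs mu0=0 -> z = 10
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1) + 1.0
        z, p = one_sample_z(x, 0.0)
        assert z == pytest.approx(10.0)
        assert p < 1e-20

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            z, p = one_sample_z(rng.normal(size=30), 0.0)
            ps.append(p)
        ps = np.array(ps)
        # under the null ~10% of p-values below 0.1, ~50% below 0.5
        assert 0.04 < (ps < 0.1).mean() < 0.18
        assert 0.4 < (ps < 0.5).mean() < 0.6

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_z([1.0, 1.0, 1.0], 0.0)
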