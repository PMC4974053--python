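"""Ideal-observer auROC, permutation nulls, TDR axes and trajectories."""

import numpy as np
import pytest

from caltask import decoding, synthetic
from caltask.decoding import (
    distance_auroc, fit_task_axes, ideal_observer_auroc, population_tensor,
    project_trajectories, shuffle_null, significance_epochs,
)


def _pop(selectivity_on, seed=5, n_neurons=80, noise=0.15):
    """Population that codes only stimulus or only choice."""
    cfg = synthetic.SessionConfig(n_trials=240, seed=seed,
                                  hit_rate=0.8, fa_rate=0.25)
    table = synthetic.generate_session(cfg)
    mix = {a: 0.0 for a in synthetic.ARCHETYPES}
    mix.update({"StimOnly": 0.5, "Delay": 0.5})
    spec = {name: synthetic.ArchetypeSpec(name, selectivity_dist=lambda r: 0.0)
            for name in ("StimOnly", "Delay")}
    tr, _ = synthetic.generate_traces(
        table, mix, n_neurons=n_neurons, noise_sd=noise, seed=seed + 1,
        selectivity_on=selectivity_on,
        archetypes={**synthetic.default_archetypes(), **spec})
    return population_tensor(tr), tr.time_s


class TestAuroc:
    def test_perfect_separation(self):
        assert distance_auroc([0.3, 0.4], [0.1, 0.2]) == 1.0

    def test_interleaved_three_quarters(self):
        # exhaustive pairs: (0.2,0.1) (0.2,0.3) (0.4,0.1) (0.4,0.3)
        assert distance_auroc([0.2, 0.4], [0.1, 0.3]) == 0.75

    def test_equals_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 9, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert distance_auroc(a, b) == pytest.approx(wins / (n1 * n2))

    def test_ties_count_half(self):
        assert distance_auroc([1.0], [1.0]) == 0.5


class TestIdealObserver:
    def test_stimulus_population_dissociation(self):
        (X, labels), time_s = _pop("stimulus")
        stim = ideal_observer_auroc(X, labels, "stimulus", 50,
                                    time_s=time_s, n_iter=30, seed=1)
        _, hi_s = shuffle_null(X, labels, "stimulus", 50, n_perm=200, seed=2)
        assert significance_epochs(stim.auroc, hi_s, time_s)
        assert stim.auroc.max() > 0.9
        choice = ideal_observer_auroc(X, labels, "choice", 50,
                                      time_s=time_s, n_iter=30, seed=1)
        _, hi_c = shuffle_null(X, labels, "choice", 50, n_perm=200, seed=2)
        assert not significance_epochs(choice.auroc, hi_c, time_s)

    def test_choice_population_dissociation(self):
        (X, labels), time_s = _pop("choice")
        choice = ideal_observer_auroc(X, labels, "choice", 50,
                                      time_s=time_s, n_iter=30, seed=3)
        _, hi_c = shuffle_null(X, labels, "choice", 50, n_perm=200, seed=4)
        assert significance_epochs(choice.auroc, hi_c, time_s)
        stim = ideal_observer_auroc(X, labels, "stimulus", 50,
                                    time_s=time_s, n_iter=30, seed=3)
        _, hi_s = shuffle_null(X, labels, "stimulus", 50, n_perm=200, seed=4)
        assert not significance_epochs(stim.auroc, hi_s, time_s)

    def test_oversized_population_rejected(self):
        (X, labels), _ = _pop("stimulus", n_neurons=20)
        with pytest.raises(ValueError):
            ideal_observer_auroc(X, labels, "stimulus", 500, n_iter=2)

    def test_deterministic_under_seed(self):
        (X, labels), _ = _pop("stimulus", n_neurons=30)
        a = ideal_observer_auroc(X, labels, "stimulus", 10, n_iter=5, seed=9)
        b = ideal_observer_auroc(X, labels, "stimulus", 10, n_iter=5, seed=9)
        np.testing.assert_array_equal(a.auroc, b.auroc)


class TestShuffleNull:
    def test_null_centered_at_half(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 20, 8))
        labels = np.array(["miss"] * 10 + ["CR"] * 30)
        lo, hi = shuffle_null(X, labels, "stimulus", 10, n_perm=300,
                              seed=1, fold=False)
        assert np.all(lo < 0.5) and np.all(hi > 0.5)

    def test_interval_narrows_with_trial_count(self):
        rng = np.random.default_rng(11)
        widths = []
        for n_tr in (20, 80):
            X = rng.standard_normal((n_tr, 20, 4))
            labels = np.array(["miss"] * (n_tr // 4) + ["CR"] * (3 * n_tr // 4))
            lo, hi = shuffle_null(X, labels, "stimulus", 10, n_perm=300,
                                  seed=2, fold=False)
            widths.append(np.mean(hi - lo))
        assert widths[1] < widths[0]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((24, 10, 5))
        labels = np.array(["miss"] * 6 + ["CR"] * 18)
        a = shuffle_null(X, labels, "stimulus", 5, n_perm=50, seed=7)
        b = shuffle_null(X, labels, "stimulus", 5, n_perm=50, seed=7)
        np.testing.assert_array_equal(a[1], b[1])


class TestSignificanceEpochs:
    def test_below_ci_everywhere_empty(self):
        assert significance_epochs(np.full(10, 0.5), np.full(10, 0.6)) == []

    def test_two_point_run_rejected(self):
        curve = np.full(10, 0.5); curve[4:6] = 0.9
        assert significance_epochs(curve, np.full(10, 0.6)) == []

    def test_run_reported_in_seconds(self):
        curve = np.full(12, 0.5); curve[5:10] = 0.9
        t = np.arange(12) * 0.2
        assert significance_epochs(curve, np.full(12, 0.6), t) == \
            [(1.0, 1.8)]

    def test_type_one_error_of_run_rule(self):
        # fully shuffled data should produce significant intervals rarely
        rng = np.random.default_rng(13)
        n_sig = 0
        n_rep = 40
        for rep in range(n_rep):
            X = rng.standard_normal((32, 15, 20))
            labels = np.array(["miss"] * 8 + ["CR"] * 24)
            c = ideal_observer_auroc(X, labels, "stimulus", 10,
                                     n_iter=10, seed=rep)
            _, hi = shuffle_null(X, labels, "stimulus", 10, n_perm=100,
                                 seed=rep + 1000)
            n_sig += bool(significance_epochs(c.auroc, hi))
        assert n_sig <= 0.15 * n_rep


class TestTaskAxes:
    @staticmethod
    def _planted(seed=0, noise=0.2, n=150, trials=160, T=20):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n); a /= np.linalg.norm(a)
        stim = rng.choice([1.0, -1.0], trials)
        lick = np.where(stim > 0, rng.random(trials) < 0.8,
                        rng.random(trials) < 0.2)
        labels = np.where(stim > 0, np.where(lick, "hit", "miss"),
                          np.where(lick, "FA", "CR"))
        ramp = np.linspace(0, 1, T)
        X = stim[:, None, None] * a[None, :, None] * ramp[None, None, :]
        X = X + noise * rng.standard_normal(X.shape)
        return X, labels, a

    def test_axes_unit_and_orthogonal(self):
        X, labels, _ = self._planted()
        axes = fit_task_axes(X, labels)
        assert np.linalg.norm(axes.stimulus_axis) == pytest.approx(1.0)
        assert np.linalg.norm(axes.choice_axis) == pytest.approx(1.0)
        assert abs(axes.stimulus_axis @ axes.choice_axis) < 1e-10

    def test_recovers_planted_stimulus_axis(self):
        X, labels, a = self._planted(noise=0.15)
        axes = fit_task_axes(X, labels)
        assert abs(axes.stimulus_axis @ a) >= 0.95

    def test_code_swap_flips_sign_only(self):
        X, labels, _ = self._planted()
        axes = fit_task_axes(X, labels)
        swapped = np.array(
            [{"hit": "CR", "CR": "hit", "miss": "FA", "FA": "miss"}[l]
             for l in labels])
        axes2 = fit_task_axes(X, swapped)
        assert abs(axes.stimulus_axis @ axes2.stimulus_axis) > 0.99

    def test_no_error_trials_rejected(self):
        X, labels, _ = self._planted()
        pure = np.where(np.isin(labels, ["hit", "miss"]), "hit", "CR")
        with pytest.raises(ValueError):
            fit_task_axes(X, pure)


class TestTrajectories:
    def test_identical_conditions_zero_separation(self):
        rng = np.random.default_rng(20)
        base = rng.standard_normal((1, 30, 10))
        X = np.repeat(base, 12, axis=0)
        labels = np.array((["hit"] * 3 + ["CR"] * 3 + ["miss"] * 3
                           + ["FA"] * 3))
        axes = decoding.TaskAxes(
            stimulus_axis=np.eye(30)[0], choice_axis=np.eye(30)[1],
            pc_basis=np.eye(30)[:, :5])
        traj = project_trajectories(X, labels, axes, n_perm=0)
        np.testing.assert_allclose(traj.delta_stim, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.delta_choice, 0.0, atol=1e-12)

    def test_stimulus_population_separates_on_stimulus_axis_only(self):
        X, labels, a = TestTaskAxes._planted(noise=0.15)
        axes = fit_task_axes(X, labels)
        traj = project_trajectories(X, labels, axes, n_perm=200, seed=3)
        assert np.abs(traj.delta_stim).max() > traj.null_stim[1].max()
        # the choice axis carries only axis-estimation leak of the stimulus
        # signal: an order of magnitude below the stimulus separation
        assert np.abs(traj.delta_choice).max() \
            < 0.15 * np.abs(traj.delta_stim).max()

    def test_orthonormal_basis_preserves_norms(self):
        X, labels, _ = TestTaskAxes._planted()
        axes = fit_task_axes(X, labels)
        traj = project_trajectories(X, labels, axes, n_perm=0)
        # rotating the two axes by 90 degrees preserves trajectory norms
        rot = decoding.TaskAxes(stimulus_axis=-axes.choice_axis,
                                choice_axis=axes.stimulus_axis,
                                pc_basis=axes.pc_basis)
        traj2 = project_trajectories(X, labels, rot, n_perm=0)
        for c in ("hit", "CR"):
            np.testing.assert_allclose(
                np.linalg.norm(traj.conditions[c], axis=0),
                np.linalg.norm(traj2.conditions[c], axis=0), atol=1e-9)

    def test_absent_condition_rejected(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((6, 5, 4))
        labels = np.array(["hit"] * 6)
        axes = decoding.TaskAxes(stimulus_axis=np.eye(5)[0],
                                 choice_axis=np.eye(5)[1],
                                 pc_basis=np.eye(5)[:, :2])
        with pytest.raises(ValueError):
            project_trajectories(X, labels, axes, n_perm=0)
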