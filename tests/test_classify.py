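"""Per-subject decoding scheme: selection, balancing, splitting, tuning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from confmvpa import (
    ClassifierSpec,
    DataError,
    SimulationConfig,
    SubjectDecoder,
    TuningError,
    classify_subject,
    downsample_balance,
    select_trials,
    simulate_subject,
    split_train_test,
    tune_c,
)
from confmvpa.simulate import simulate_trial_table


def _table(conditions, correct=None, runs=None, rt=None):
    n = len(conditions)
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "condition": conditions,
        "response_time_ms": rt if rt is not None else np.full(n, 1200.0),
        "run_id": runs if runs is not None else np.ones(n, dtype=int),
        "correct": correct if correct is not None else np.ones(n, dtype=bool),
    })


class TestSelectTrials:
    def test_design_counts(self):
        cfg = SimulationConfig(incorrect_rate=0.0)
        trials = simulate_trial_table(cfg, 0)
        idx, y = select_trials(trials, "spatial")
        assert y.sum() == 80 and (~y).sum() == 160

    def test_all_incorrect_raises(self):
        t = _table(["spatial", "pair"] * 4, correct=np.zeros(8, dtype=bool))
        with pytest.raises(DataError, match="no correct"):
            select_trials(t, "spatial")

    def test_only_correct_trials_counted(self):
        correct = np.array([True, False, True, True, False, True])
        t = _table(["spatial", "spatial", "pair", "temporal", "pair", "pair"],
                   correct=correct)
        idx, y = select_trials(t, "pair")
        assert len(idx) == int(correct.sum())
        assert y.sum() == 2  # two correct pair trials

    def test_empty_class_raises(self):
        t = _table(["spatial"] * 6)
        with pytest.raises(DataError, match="empty"):
            select_trials(t, "pair")


class TestBalanceAndSplit:
    def test_downsample_80_160(self, rng):
        y = np.r_[np.ones(80, bool), np.zeros(160, bool)]
        keep = downsample_balance(y, rng)
        assert y[keep].sum() == 80 and (~y[keep]).sum() == 80

    def test_already_balanced_unchanged(self, rng):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert np.array_equal(downsample_balance(y, rng), np.arange(20))

    def test_degenerate_one_vs_many(self, rng):
        y = np.r_[np.ones(1, bool), np.zeros(100, bool)]
        keep = downsample_balance(y, rng)
        assert y[keep].sum() == 1 and (~y[keep]).sum() == 1

    def test_downsample_deterministic(self):
        y = np.r_[np.ones(30, bool), np.zeros(90, bool)]
        a = downsample_balance(y, np.random.default_rng(5))
        b = downsample_balance(y, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_split_80_20_arithmetic(self, rng):
        y = np.r_[np.ones(80, bool), np.zeros(80, bool)]
        tr, te = split_train_test(y, 0.8, rng)
        assert y[tr].sum() == 64 and (~y[tr]).sum() == 64
        assert y[te].sum() == 16 and (~y[te]).sum() == 16
        assert np.array_equal(np.sort(np.r_[tr, te]), np.arange(160))

    def test_split_leaving_empty_test_raises(self, rng):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        with pytest.raises(DataError, match="without"):
            split_train_test(y, 0.99, rng)

    def test_split_deterministic(self):
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        a = split_train_test(y, 0.8, np.random.default_rng(9))
        b = split_train_test(y, 0.8, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestTuneC:
    def test_tie_breaks_to_smallest_c(self, rng):
        # constant features: every C yields the same CV accuracy
        X = np.zeros((40, 6))
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        runs = np.tile(np.arange(1, 5), 10)
        chosen, acc = tune_c(X, y, runs, n_folds=4)
        assert chosen == 1e-10

    def test_separable_data_reaches_perfect_cv(self, rng):
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        X = rng.normal(size=(80, 5))
        X[:40, 0] += 20.0  # huge separation on one feature
        runs = np.tile(np.arange(1, 6), 16)
        chosen, acc = tune_c(X, y, runs, n_folds=5)
        means = np.nanmean(acc, axis=1)
        assert np.nanmax(means) == 1.0

    def test_singleton_grid_returned(self, rng):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        X = rng.normal(size=(20, 3))
        runs = np.tile([1, 2], 10)
        chosen, _ = tune_c(X, y, runs, c_grid=[0.5], n_folds=2)
        assert chosen == 0.5

    def test_single_run_cannot_cv(self, rng):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.raises(TuningError):
            tune_c(rng.normal(size=(20, 3)), y, np.ones(20, int))


class TestClassifySubject:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(pattern_effect=0.5, n_voxels=15)
        trials, D, _ = simulate_subject(cfg, 3)
        r1 = classify_subject(D, trials, seed=7)
        r2 = classify_subject(D, trials, seed=7)
        assert r1.accuracy == r2.accuracy and r1.chosen_c == r2.chosen_c
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies,
                              equal_nan=True)

    def test_strong_pattern_low_noise_decodes(self):
        cfg = SimulationConfig(pattern_effect=3.0, noise_sd=0.3, n_voxels=30)
        trials, D, _ = simulate_subject(cfg, 1)
        res = classify_subject(D, trials, seed=1)
        assert res.accuracy > 0.9

    def test_class_counts(self):
        cfg = SimulationConfig(incorrect_rate=0.0)
        trials, D, _ = simulate_subject(cfg, 2)
        res = classify_subject(D, trials, seed=2, tune="fixed")
        assert res.n_train_per_class == 64
        assert res.n_test_per_class == 16

    def test_monotone_in_pattern_effect(self):
        # matched subject seeds, three effect levels
        means = []
        for effect in (0.0, 0.8, 2.0):
            cfg = SimulationConfig(pattern_effect=effect, n_voxels=20)
            accs = []
            for s in range(15):
                trials, D, _ = simulate_subject(cfg, s)
                accs.append(
                    classify_subject(D, trials, seed=s, tune="fixed").accuracy
                )
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.02 <= means[2] + 0.04

    def test_shuffled_labels_center_on_chance(self):
        cfg = SimulationConfig(pattern_effect=2.0, n_voxels=15)
        trials, D, _ = simulate_subject(cfg, 11)
        rng = np.random.default_rng(0)
        accs = []
        for i in range(30):
            shuffled = trials.copy()
            shuffled["condition"] = rng.permutation(
                trials["condition"].to_numpy())
            try:
                accs.append(classify_subject(D, shuffled, seed=i,
                                             tune="fixed").accuracy)
            except DataError:
                pass
        assert abs(np.mean(accs) - 0.5) < 0.06


class TestSubjectDecoder:
    def _fit(self, correction=None, seed=0, **kw):
        cfg = SimulationConfig(pattern_effect=1.0, n_voxels=15)
        trials, D, _ = simulate_subject(cfg, 8)
        dec = SubjectDecoder(target_condition="pair", correction=correction,
                             random_state=seed, **kw)
        dec.fit(
            D.values.T, trials["condition"].to_numpy(),
            rt=trials["response_time_ms"].to_numpy(),
            runs=trials["run_id"].to_numpy(),
            correct=trials["correct"].to_numpy(),
        )
        return dec, trials, D

    def test_fitted_attributes_and_predict(self):
        dec, trials, D = self._fit()
        assert 0.0 <= dec.accuracy_ <= 1.0
        assert dec.chosen_c_ in dec.c_grid
        assert dec.coef_.shape == (1, 15)
        preds = dec.predict(D.values.T[dec.test_trials_])
        assert preds.dtype == bool

    def test_sklearn_clone_compatible(self):
        dec = SubjectDecoder(correction="mean_signal", random_state=3)
        c = clone(dec)
        assert c.get_params() == dec.get_params()

    def test_no_leakage_test_trials_do_not_affect_tuning(self):
        # corrupting held-out trial features must not change the chosen C
        # or the learned weights (standardization is train-estimated)
        dec, trials, D = self._fit(seed=4)
        X = D.values.T.copy()
        X[dec.test_trials_] += 1e3
        dec2 = SubjectDecoder(target_condition="pair", random_state=4)
        dec2.fit(X, trials["condition"].to_numpy(),
                 rt=trials["response_time_ms"].to_numpy(),
                 runs=trials["run_id"].to_numpy(),
                 correct=trials["correct"].to_numpy())
        assert dec2.chosen_c_ == dec.chosen_c_
        assert np.allclose(dec2.coef_, dec.coef_)

    def test_rt_correction_requires_rt(self):
        cfg = SimulationConfig(n_voxels=8)
        trials, D, _ = simulate_subject(cfg, 0)
        dec = SubjectDecoder(correction="response_time")
        with pytest.raises(DataError, match="rt"):
            dec.fit(D.values.T, trials["condition"].to_numpy())

    def test_train_scope_correction_runs(self):
        cfg = SimulationConfig(mean_effect=0.5, n_voxels=10)
        trials, D, _ = simulate_subject(cfg, 5)
        res = classify_subject(D, trials, correction="mean_signal", seed=5,
                               correction_scope="train", tune="fixed")
        assert 0.0 <= res.accuracy <= 1.0
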