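"""Elastic-net clock calibration, prediction and site selection."""

import warnings

import numpy as np
import pytest

from clocktol import (
    ClockModel,
    DatasetProfile,
    MethylationDataset,
    SignalSpec,
    SplitSpec,
    count_selected_sites,
    fit_clock,
    generate_dataset,
    predict_ages,
    prune_outliers_and_refit,
    selection_overlap,
    split_train_test,
)


class TestSplit:
    def test_seventy_thirty_split_is_disjoint_and_exhaustive(self):
        ds = generate_dataset(
            DatasetProfile("x", 100, 10, 50),
            SignalSpec(n_informative=5, n_noise=5),
            seed=0,
        )
        train, test = split_train_test(ds, SplitSpec(0.7, seed=1))
        assert train.n_samples == 70 and test.n_samples == 30
        assert set(train.samples) | set(test.samples) == set(ds.samples)
        assert set(train.samples) & set(test.samples) == set()

    def test_same_seed_gives_identical_partition(self, small_dataset):
        a = split_train_test(small_dataset, SplitSpec(0.7, seed=5))
        b = split_train_test(small_dataset, SplitSpec(0.7, seed=5))
        assert a[0].samples == b[0].samples and a[1].samples == b[1].samples

    def test_round_half_up_on_train_size(self):
        # n=63 at 0.7 -> 44.1 -> 44 train, 19 test
        ds = generate_dataset(
            DatasetProfile("turtleish", 63, 1, 43),
            SignalSpec(n_informative=5, n_noise=5),
            seed=0,
        )
        train, test = split_train_test(ds, SplitSpec(0.7, seed=0))
        assert (train.n_samples, test.n_samples) == (44, 19)

    def test_too_few_samples_for_folds_rejected(self):
        ds = generate_dataset(
            DatasetProfile("tiny", 20, 10, 40),
            SignalSpec(n_informative=2, n_noise=2),
            seed=0,
        )
        with pytest.raises(ValueError, match="too small"):
            split_train_test(ds, SplitSpec(0.7, seed=0), cv_folds=10)


class TestFitClock:
    def test_all_constant_features_give_intercept_only_model(self):
        betas = np.full((5, 30), 0.5)
        ages = np.linspace(10, 40, 30)
        ds = MethylationDataset(
            [f"cg{i}" for i in range(5)], [f"s{i}" for i in range(30)], betas, ages
        )
        with pytest.warns(UserWarning, match="intercept-only"):
            model = fit_clock(ds, seed=0)
        assert count_selected_sites(model) == 0
        assert model.intercept == pytest.approx(ages.mean())
        assert np.allclose(predict_ages(model, ds), ages.mean())

    def test_constant_ages_rejected(self):
        betas = np.random.default_rng(0).random((5, 30))
        ds = MethylationDataset(
            [f"cg{i}" for i in range(5)],
            [f"s{i}" for i in range(30)],
            betas,
            np.full(30, 12.0),
        )
        with pytest.raises(ValueError, match="constant"):
            fit_clock(ds, seed=0)

    def test_noiseless_signal_is_recovered(self, noiseless_dataset):
        train, test = split_train_test(noiseless_dataset, SplitSpec(0.7, seed=2))
        model = fit_clock(train, seed=2)
        pred = predict_ages(model, test)
        r = np.corrcoef(pred, test.ages)[0, 1]
        assert r >= 0.99

    def test_seeded_determinism(self, small_dataset):
        train, _ = split_train_test(small_dataset, SplitSpec(0.7, seed=4))
        a = fit_clock(train, seed=9)
        b = fit_clock(train, seed=9)
        assert a.intercept == b.intercept
        assert a.weights == b.weights
        assert a.penalty_strength == b.penalty_strength

    def test_selection_sparsity_increases_with_penalty(self, small_dataset):
        # refit the same standardized problem at increasing penalty
        # strength: the selected-site count must not grow
        from sklearn.linear_model import ElasticNet

        train, _ = split_train_test(small_dataset, SplitSpec(0.7, seed=4))
        X = train.betas.T
        Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        counts = []
        for strength in (0.01, 0.1, 1.0, 10.0):
            en = ElasticNet(alpha=strength, l1_ratio=0.5, max_iter=5000)
            en.fit(Xs, train.ages)
            counts.append(int(np.sum(en.coef_ != 0)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPredict:
    def test_intercept_only_prediction_is_constant(self, small_dataset):
        model = ClockModel(intercept=33.0, weights={})
        assert np.allclose(predict_ages(model, small_dataset), 33.0)

    def test_single_site_hand_arithmetic(self):
        ds = MethylationDataset(
            ["cgA"], [f"s{i}" for i in range(3)],
            np.array([[0.5, 0.0, 1.0]]), np.array([1.0, 1.0, 1.0]),
        )
        model = ClockModel(intercept=1.0, weights={"cgA": 2.0})
        assert np.allclose(predict_ages(model, ds), [2.0, 1.0, 3.0])

    def test_agreement_with_dot_product_oracle(self, rng):
        n_sites, n_samples = 30, 15
        sites = [f"cg{i}" for i in range(n_sites)]
        betas = rng.random((n_sites, n_samples))
        ds = MethylationDataset(
            sites, [f"s{i}" for i in range(n_samples)], betas,
            rng.uniform(1, 50, n_samples),
        )
        for _ in range(50):
            support = rng.choice(n_sites, size=rng.integers(1, 10), replace=False)
            w = {sites[j]: float(rng.normal()) for j in support}
            b0 = float(rng.normal() * 10)
            model = ClockModel(intercept=b0, weights=w)
            expected = np.array([
                b0 + sum(w[s] * betas[sites.index(s), i] for s in w)
                for i in range(n_samples)
            ])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # negative predictions possible
                got = predict_ages(model, ds)
            assert np.allclose(got, expected)

    def test_missing_site_raises(self, small_dataset):
        model = ClockModel(intercept=0.0, weights={"cg_not_there": 1.0})
        with pytest.raises(KeyError, match="cg_not_there"):
            predict_ages(model, small_dataset)


class TestSelection:
    def test_count_ignores_zero_weights(self):
        model = ClockModel(0.0, {"a": 0.0, "b": 1.2, "c": -0.3})
        assert count_selected_sites(model) == 2
        assert count_selected_sites(ClockModel(5.0, {})) == 0

    def test_overlap_identical_and_disjoint(self):
        a = ClockModel(0.0, {"a": 1.0, "b": 2.0})
        b = ClockModel(0.0, {"c": 1.0, "d": 2.0})
        assert selection_overlap(a, a) == 2
        assert selection_overlap(a, b) == 0

    def test_overlap_matches_set_oracle(self, rng):
        universe = [f"cg{i}" for i in range(40)]
        for _ in range(100):
            sa = rng.choice(universe, size=rng.integers(0, 20), replace=False)
            sb = rng.choice(universe, size=rng.integers(0, 20), replace=False)
            a = ClockModel(0.0, {s: 1.0 for s in sa})
            b = ClockModel(0.0, {s: 1.0 for s in sb})
            assert selection_overlap(a, b) == len(set(sa) & set(sb))


class TestSerialization:
    def test_json_round_trip(self, small_dataset, tmp_path):
        train, _ = split_train_test(small_dataset, SplitSpec(0.7, seed=0))
        model = fit_clock(train, seed=0)
        model.to_json(tmp_path / "clock.json")
        back = ClockModel.from_json(tmp_path / "clock.json")
        assert back.intercept == model.intercept
        assert back.weights == model.weights
        assert back.penalty_strength == model.penalty_strength


class TestPruning:
    def test_clean_data_is_a_fixed_point(self, noiseless_dataset):
        spec = SplitSpec(0.7, seed=1)
        model, removed = prune_outliers_and_refit(
            noiseless_dataset, spec, k_sd=50.0, max_iter=3, seed=1
        )
        baseline = fit_clock(split_train_test(noiseless_dataset, spec)[0], seed=1)
        assert removed == []
        assert model.weights == baseline.weights

    def test_max_iter_zero_returns_baseline(self, small_dataset):
        spec = SplitSpec(0.7, seed=2)
        model, removed = prune_outliers_and_refit(
            small_dataset, spec, k_sd=2.0, max_iter=0, seed=2
        )
        baseline = fit_clock(split_train_test(small_dataset, spec)[0], seed=2)
        assert removed == []
        assert model.weights == baseline.weights

    def test_planted_age_outliers_are_enriched_among_removals(self):
        # corrupt 10 of 100 sample ages by +/-80%; flagged removals should
        # hit corrupted samples far above their base rate
        profile = DatasetProfile("x", 100, 16, 88)
        signal = SignalSpec(n_informative=40, n_noise=160, noise_sd=0.02)
        ds = generate_dataset(profile, signal, seed=21)
        rng = np.random.default_rng(21)
        corrupt = rng.choice(ds.n_samples, size=10, replace=False)
        ages = ds.ages.copy()
        ages[corrupt] *= 1 + rng.choice([-0.8, 0.8], size=10)
        corrupted_ids = {ds.samples[i] for i in corrupt}
        noisy = ds.with_ages(ages)

        _, removed = prune_outliers_and_refit(
            noisy, SplitSpec(0.7, seed=21), k_sd=2.0, max_iter=4, seed=21
        )
        assert removed, "expected at least one removal"
        hit_rate = np.mean([s in corrupted_ids for s in removed])
        assert hit_rate > 0.1  # base rate of corrupted samples

    def test_invalid_k_sd(self, small_dataset):
        with pytest.raises(ValueError, match="k_sd"):
            prune_outliers_and_refit(small_dataset, SplitSpec(0.7, seed=0), k_sd=0.0)
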