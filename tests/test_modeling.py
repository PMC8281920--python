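"""Fitting, correlation, GBT/consensus and the leave-one-protein-out driver."""

import numpy as np
import pandas as pd
import pytest

from aspholib.modeling import (DegenerateSeriesError, GBTConfig, consensus,
                               leave_one_protein_out, pearson_cc,
                               per_protein_least_squares, standardize_images,
                               train_gbt)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([3.0, 7.0, 11.0, 2.0])
        assert pearson_cc(x, x) == pytest.approx(1.0)
        assert pearson_cc(-x, x) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert pearson_cc(np.array([1.0, 2.0, 3.0]),
                          np.array([1.0, 2.0, 4.0])) == pytest.approx(
            0.981981, abs=1e-6)

    def test_symmetric_in_the_two_series(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert pearson_cc(a, b) == pytest.approx(pearson_cc(b, a), abs=1e-15)

    def test_agrees_with_two_pass_covariance(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=30), rng.normal(size=30)
            expected = np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
            assert pearson_cc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_series_is_an_explicit_error(self):
        with pytest.raises(DegenerateSeriesError):
            pearson_cc(np.ones(5), np.arange(5.0))


class TestLeastSquares:
    def test_exactly_linear_targets_are_recovered(self, rng):
        x = rng.normal(size=(100, 10))
        w = rng.normal(size=10)
        y = x @ w + 3.0
        fit = per_protein_least_squares(x, y)
        assert fit.pcc == pytest.approx(1.0)
        assert not fit.underdetermined
        np.testing.assert_allclose(fit.coefficients, w, atol=1e-9)
        np.testing.assert_allclose(fit.predict(x), y, atol=1e-9)

    def test_underdetermined_fit_interpolates_and_is_flagged(self, rng):
        x = rng.normal(size=(20, 60))   # fewer rows than parameters
        y = rng.normal(size=20)
        fit = per_protein_least_squares(x, y)
        assert fit.underdetermined
        assert fit.pcc == pytest.approx(1.0)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_pcc_invariant_under_affine_target_rescaling(self, rng):
        x = rng.normal(size=(80, 5))
        y = x @ rng.normal(size=5) + rng.normal(size=80)
        a = per_protein_least_squares(x, y).pcc
        b = per_protein_least_squares(x, 4.2 * y + 11.0).pcc
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            per_protein_least_squares(np.ones((1, 3)), np.ones(1))


class TestGBT:
    def test_constant_target_predicts_that_constant(self, rng):
        x = rng.normal(size=(40, 4))
        model = train_gbt(x, np.full(40, 7.5), seed=0)
        np.testing.assert_allclose(model.predict(x), 7.5, atol=1e-9)

    def test_deterministic_given_data_config_seed(self, rng):
        x = rng.normal(size=(60, 6))
        y = x[:, 0] * 2 + rng.normal(size=60) * 0.1
        p1 = train_gbt(x, y, seed=3).predict(x)
        p2 = train_gbt(x, y, seed=3).predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_learns_a_strong_signal(self, rng):
        x = rng.normal(size=(300, 5))
        y = 3 * x[:, 0] - 2 * x[:, 1] + 0.1 * rng.normal(size=300)
        model = train_gbt(x, y, seed=0)
        assert pearson_cc(model.predict(x), y) >= 0.8

    def test_config_defaults_match_the_quantile_objective(self):
        config = GBTConfig()
        assert (config.loss, config.alpha) == ("quantile", 0.975)
        assert (config.n_estimators, config.learning_rate) == (500, 0.25)
        assert (config.max_depth, config.min_samples_leaf,
                config.min_samples_split) == (4, 9, 9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_gbt(np.empty((0, 3)), np.empty(0))


class TestImageStandardization:
    def test_training_channels_become_standard(self, rng):
        imgs = rng.normal(3.0, 2.0, size=(50, 8, 10, 3))
        out, scaler = standardize_images(imgs)
        np.testing.assert_allclose(out.mean(axis=(0, 1, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=(0, 1, 2)), 1.0, atol=1e-10)

    def test_held_out_images_use_training_parameters(self, rng):
        train = rng.normal(5.0, 1.0, size=(40, 8, 10, 3))
        held = rng.normal(0.0, 3.0, size=(10, 8, 10, 3))
        _, held_std, scaler = standardize_images(train, held)
        np.testing.assert_allclose(held_std, (held - scaler.mean)
                                   / scaler.std, atol=1e-12)
        # held-out statistics are NOT standard: no leakage of their stats
        assert abs(held_std.mean()) > 0.5 or abs(held_std.std() - 1) > 0.5

    def test_reapplying_is_idempotent_on_training_statistics(self, rng):
        imgs = rng.normal(size=(30, 8, 10, 3))
        out, scaler = standardize_images(imgs)
        again = scaler.apply(imgs)
        np.testing.assert_allclose(out, again, atol=1e-12)

    def test_zero_variance_channel_floored_with_warning(self, rng):
        imgs = rng.normal(size=(10, 8, 10, 3))
        imgs[..., 1] = 4.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = standardize_images(imgs)
        assert np.all(np.isfinite(out))


class TestConsensus:
    def test_elementwise_average(self):
        np.testing.assert_array_equal(consensus([2.0, 4.0], [4.0, 6.0]),
                                      [3.0, 5.0])

    def test_idempotent_and_symmetric(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        np.testing.assert_array_equal(consensus(x, x), x)
        np.testing.assert_array_equal(consensus(x, y), consensus(y, x))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus([1.0], [1.0, 2.0])


def toy_table(rng, n_proteins=3, n_rows=25):
    frames = []
    w = np.array([2.0, -1.0, 0.5])
    for k in range(n_proteins):
        x = rng.normal(size=(n_rows, 3))
        frames.append(pd.DataFrame({
            "pdb_id": f"p{k}",
            "chain": "A",
            "residue_number": np.arange(1, n_rows + 1),
            "f0": x[:, 0], "f1": x[:, 1], "f2": x[:, 2],
            "bfactor": x @ w + 10 + 0.1 * rng.normal(size=n_rows),
        }))
    return pd.concat(frames, ignore_index=True)


class TestLeaveOneProteinOut:
    def test_partition_and_no_leakage(self, rng):
        table = toy_table(rng)
        seen = []

        class Recorder:
            def __init__(self, n_train):
                self.n_train = n_train

            def predict(self, x):
                return np.zeros(len(x)) + np.arange(len(x))

        def trainer(x, y, seed):
            seen.append(len(x))
            return Recorder(len(x))

        result = leave_one_protein_out(table, ["f0", "f1", "f2"], trainer)
        assert len(seen) == 3
        assert all(n == 50 for n in seen)  # each model excludes one protein
        assert len(result.predictions) == len(table)

    def test_blind_recovery_of_a_shared_law(self, rng):
        table = toy_table(rng, n_proteins=4, n_rows=40)
        result = leave_one_protein_out(table, ["f0", "f1", "f2"], seed=0)
        assert (result.per_protein_pcc > 0.5).all()

    def test_size_class_reporting(self, rng):
        table = toy_table(rng, n_proteins=4, n_rows=30)
        result = leave_one_protein_out(table, ["f0", "f1", "f2"], seed=0,
                                       size_boundaries=(10, 35))
        assert set(result.size_class_means.index) >= {"medium"}

    def test_single_protein_rejected(self, rng):
        table = toy_table(rng, n_proteins=1)
        with pytest.raises(ValueError):
            leave_one_protein_out(table, ["f0"])
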