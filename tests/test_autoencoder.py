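"""Objectives, corruption, network construction and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xae._net import DenseAutoencoderNet, kl_gaussian
from xae.autoencoder import (
    PathwayAutoencoder,
    corrupt,
    delta_filter,
    delta_inverse,
    load_checkpoint,
    objective,
    reconstruction_loss,
    save_checkpoint,
    vae_objective,
)
from xae.errors import ValidationError

matrices = arrays(
    float, (3, 4), elements=st.floats(0, 1, allow_nan=False, width=32)
)


class TestDeltas:
    def test_filter_zero_branch(self):
        x = np.array([[0.5, 1.0], [0.0, 0.25]])
        np.testing.assert_array_equal(delta_filter(x, 0), np.zeros_like(x))

    def test_positive_branch_is_identity(self, rng):
        x = rng.random((4, 5))
        np.testing.assert_array_equal(delta_filter(x, 1), x)
        np.testing.assert_array_equal(delta_inverse(x, 1), x)

    def test_inverse_complements_negatives(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(delta_inverse(x, 0), 1.0 - x)

    @given(matrices)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_filter_branches_partition_input(self, x):
        np.testing.assert_allclose(delta_filter(x, 0) + delta_filter(x, 1), x)

    @given(matrices)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_inverse_is_involution_on_negatives(self, x):
        np.testing.assert_allclose(
            delta_inverse(delta_inverse(x, 0), 0), x, atol=1e-12
        )

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            delta_filter(np.zeros((2, 2)), 2)


class TestReconstructionLoss:
    def test_uniform_half_closed_form(self):
        target = np.full((6, 4), 0.5)
        assert reconstruction_loss(target, target) == pytest.approx(24 * np.log(2))

    def test_confident_correct_output_near_zero(self):
        ones = np.ones((3, 3))
        assert reconstruction_loss(ones, ones * (1 - 1e-7)) == pytest.approx(0, abs=1e-5)

    def test_matches_cell_loop_oracle(self, rng):
        t = rng.random((5, 7))
        o = np.clip(rng.random((5, 7)), 0.05, 0.95)
        oracle = -sum(
            t[i, j] * np.log(o[i, j]) + (1 - t[i, j]) * np.log(1 - o[i, j])
            for i in range(5)
            for j in range(7)
        )
        assert reconstruction_loss(t, o) == pytest.approx(oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestObjective:
    def test_single_positive_equals_plain_loss(self, rng):
        x = rng.random((3, 4))
        out = np.clip(rng.random((3, 4)), 0.1, 0.9)
        assert objective([x], [1], [out], "F") == pytest.approx(
            reconstruction_loss(x, out)
        )

    def test_filter_on_all_positive_batch_is_plain_autoencoder_objective(self, rng):
        batch = [rng.random((3, 4)) for _ in range(4)]
        outs = [np.clip(rng.random((3, 4)), 0.1, 0.9) for _ in range(4)]
        plain = sum(reconstruction_loss(x, o) for x, o in zip(batch, outs))
        assert objective(batch, [1] * 4, outs, "F") == pytest.approx(plain)

    def test_filter_negative_batch_near_zero_for_zero_output(self):
        batch = [np.random.default_rng(0).random((3, 4))]
        outs = [np.full((3, 4), 1e-7)]
        assert objective(batch, [0], outs, "F") < 1e-4

    def test_matches_per_element_oracle(self, rng):
        batch = [rng.random((2, 3)) for _ in range(5)]
        classes = [0, 1, 0, 1, 1]
        outs = [np.clip(rng.random((2, 3)), 0.1, 0.9) for _ in range(5)]
        for alpha, delta in (("F", delta_filter), ("I", delta_inverse)):
            oracle = sum(
                reconstruction_loss(delta(x, c), o)
                for x, c, o in zip(batch, classes, outs)
            )
            assert objective(batch, classes, outs, alpha) == pytest.approx(oracle)

    def test_inverse_loss_minimised_by_complement_output(self, rng):
        # for binary x with class 0, the target is 1-x: outputting (almost) 1-x
        # must beat any perturbed output (cross-entropy calibration)
        x = (rng.random((4, 5)) > 0.5).astype(float)
        best = np.clip(1.0 - x, 1e-6, 1 - 1e-6)
        loss_best = objective([x], [0], [best], "I")
        for _ in range(10):
            other = np.clip(best + rng.normal(0, 0.2, best.shape), 1e-6, 1 - 1e-6)
            assert loss_best <= objective([x], [0], [other], "I") + 1e-9


class TestVAEObjective:
    def test_prior_posterior_gives_zero_kl(self, rng):
        x = rng.random((2, 3))
        out = np.clip(rng.random((2, 3)), 0.1, 0.9)
        mus = np.zeros((1, 4))
        logvars = np.zeros((1, 4))
        assert vae_objective([x], [1], [out], mus, logvars, "F") == pytest.approx(
            objective([x], [1], [out], "F")
        )

    def test_unit_mean_unit_variance_dimension_is_half(self):
        assert kl_gaussian(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo_oracle(self, rng):
        mu = rng.normal(0, 1, 3)
        logvar = rng.normal(0, 0.5, 3)
        analytic = kl_gaussian(mu, logvar)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * rng.standard_normal((100_000, 3))
        log_q = (-0.5 * ((z - mu) / sigma) ** 2 - 0.5 * np.log(2 * np.pi) - 0.5 * logvar).sum(1)
        log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(1)
        mc = float(np.mean(log_q - log_p))
        assert analytic == pytest.approx(mc, rel=0.05, abs=0.02)

    def test_kl_nonnegative_so_vae_objective_dominates_plain(self, rng):
        x = rng.random((2, 3))
        out = np.clip(rng.random((2, 3)), 0.1, 0.9)
        mus = rng.normal(0, 1, (1, 4))
        logvars = rng.normal(0, 1, (1, 4))
        assert vae_objective([x], [1], [out], mus, logvars, "F") >= objective(
            [x], [1], [out], "F"
        )


class TestCorrupt:
    def test_zero_ratio_is_identity(self, rng):
        x = rng.random((5, 5))
        np.testing.assert_array_equal(corrupt(x, 0.0, 1), x)

    def test_flips_exactly_rounded_fraction_of_cells(self, rng):
        x = (rng.random((962, 24)) > 0.5).astype(float)
        out = corrupt(x, 0.001, seed=3)
        assert int((out != x).sum()) == 23  # round(0.001 * 23088)
        changed = out != x
        np.testing.assert_array_equal(out[changed], 1.0 - x[changed])

    def test_original_untouched_and_deterministic(self, rng):
        x = rng.random((10, 10))
        copy = x.copy()
        a = corrupt(x, 0.2, seed=7)
        b = corrupt(x, 0.2, seed=7)
        np.testing.assert_array_equal(x, copy)
        np.testing.assert_array_equal(a, b)

    def test_near_total_corruption_approaches_complement(self, rng):
        x = (rng.random((10, 10)) > 0.5).astype(float)
        out = corrupt(x, 0.99, seed=1)
        assert int((out == 1.0 - x).sum()) == 99


class TestNetwork:
    def test_latent_head_sizes(self, rng):
        g = np.random.default_rng(0)
        ae = DenseAutoencoderNet(20, 32, 8, variational=False, rng=g)
        vae = DenseAutoencoderNet(20, 32, 8, variational=True, rng=g)
        x = rng.random((3, 20))
        assert ae.encode(x).shape == (3, 8)
        assert vae.encode(x).shape == (3, 16)

    def test_decoded_entries_strictly_inside_unit_interval(self, rng):
        net = DenseAutoencoderNet(12, 16, 4, False, np.random.default_rng(1))
        out = net.decode(rng.normal(0, 5, (4, 4)))
        assert np.all(out > 0) and np.all(out < 1)


def _tiny_data(rng, n=40, l=4, w=6):
    X = (rng.random((n, l, w)) < 0.15).astype(float)
    y = rng.integers(0, 2, n)
    # make positives denser so the task is learnable
    X[y == 1, 0, :] = 1.0
    return X, y


class TestTraining:
    @pytest.mark.parametrize("architecture", ["AE", "DAE", "VAE"])
    def test_loss_decreases_over_training(self, rng, architecture):
        X, y = _tiny_data(rng)
        model = PathwayAutoencoder(
            alpha="F", architecture=architecture, max_epochs=50,
            patience=50, learning_rate=1e-3, random_state=0,
        ).fit(X, y)
        assert model.history_[-1][0] <= model.history_[0][0]

    def test_same_seed_reproduces_identical_history(self, rng):
        X, y = _tiny_data(rng)
        kw = dict(alpha="I", architecture="VAE", max_epochs=10, random_state=5)
        a = PathwayAutoencoder(**kw).fit(X, y)
        b = PathwayAutoencoder(**kw).fit(X, y)
        assert a.history_ == b.history_
        np.testing.assert_array_equal(a.decision_function(X), b.decision_function(X))

    def test_early_stopping_respects_patience(self, rng):
        X, y = _tiny_data(rng)
        model = PathwayAutoencoder(
            alpha="F", architecture="AE", max_epochs=500, patience=3,
            learning_rate=0.0, random_state=0,   # frozen weights: no improvement
        ).fit(X, y)
        # first epoch sets the best; the next `patience` epochs stop the run
        assert len(model.history_) == 4

    def test_single_class_training_rejected(self, rng):
        X, _ = _tiny_data(rng)
        with pytest.raises(ValidationError):
            PathwayAutoencoder(max_epochs=2).fit(X, np.ones(len(X), dtype=int))

    def test_out_of_range_input_rejected(self, rng):
        X, y = _tiny_data(rng)
        with pytest.raises(ValidationError):
            PathwayAutoencoder(max_epochs=2).fit(X * 3.0, y)

    def test_reconstruction_shape_and_range(self, rng):
        X, y = _tiny_data(rng)
        model = PathwayAutoencoder(
            alpha="F", architecture="AE", max_epochs=5, random_state=0
        ).fit(X, y)
        out = model.reconstruct(X)
        assert out.shape == X.shape
        assert np.all(out > 0) and np.all(out < 1)

    def test_checkpoint_round_trip_preserves_scores(self, rng, tmp_path):
        X, y = _tiny_data(rng)
        model = PathwayAutoencoder(
            alpha="I", architecture="VAE", max_epochs=5, random_state=0
        ).fit(X, y)
        save_checkpoint(tmp_path / "m.npz", model, row_labels=["a"] * 4, rescale_factor=2.0)
        loaded, meta = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            loaded.decision_function(X), model.decision_function(X)
        )
        assert meta["rescale_factor"] == 2.0
        assert loaded.threshold_ == model.threshold_
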