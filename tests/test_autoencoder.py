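"""Autoencoder: forward algebra, loss oracle, gradients, training behavior."""

import numpy as np
import pytest

from aesurv.autoencoder import (
    Autoencoder,
    encode,
    layer_forward,
    reconstruction_logloss,
)
from aesurv.exceptions import ContractError, DivergenceError


def tiny_model(d=2, hidden=(2, 1, 2), seed=0, **kw):
    """Initialized (single pass, zero learning rate) model on random data."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.05, 0.95, size=(8, d))
    model = Autoencoder(
        hidden_sizes=hidden, learning_rate=0.0, epochs=1, batch_size=8,
        dropout=0.0, random_state=seed, **kw,
    ).fit(X)
    return model, X


def loop_loss_oracle(model, X):
    """Independent evaluation of the training objective with explicit loops."""
    total = 0.0
    for x in X:
        a = list(x)
        activity = 0.0
        for i, (W, b) in enumerate(zip(model.coefs_, model.intercepts_)):
            z = [sum(W[r][c] * a[c] for c in range(len(a))) + b[r]
                 for r in range(W.shape[0])]
            if i == len(model.coefs_) - 1:
                a = [1.0 / (1.0 + np.exp(-v)) for v in z]
            else:
                a = [np.tanh(v) for v in z]
            activity += sum(v * v for v in a)
        recon = -sum(
            x[j] * np.log(a[j]) + (1 - x[j]) * np.log(1 - a[j])
            for j in range(len(x))
        )
        total += recon + model.l2_activity * activity
    total /= len(X)
    total += model.l1_weight * sum(np.abs(W).sum() for W in model.coefs_)
    return total


class TestLayerForward:
    def test_zero_weights_give_zero_tanh_output(self):
        out = layer_forward([1.0, -2.0], np.zeros((3, 2)), np.zeros(3), "tanh")
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_identity_weights_linearize_for_small_inputs(self):
        x = np.array([1e-4, -2e-4])
        out = layer_forward(x, np.eye(2), np.zeros(2), "tanh")
        np.testing.assert_allclose(out, x, rtol=1e-6)

    def test_shape_mismatch_is_a_contract_error(self):
        with pytest.raises(ContractError, match="shape"):
            layer_forward([1.0, 2.0], np.zeros((2, 3)), np.zeros(2), "tanh")


class TestReconstructionLogloss:
    @pytest.mark.parametrize(
        "x,xp,expected",
        [
            ([1.0], [0.5], 0.6931),       # -log 1/2
            ([1.0, 0.0], [0.9, 0.1], 0.21072),  # -2 log 0.9
            ([0.5], [0.5], 0.6931),
        ],
    )
    def test_closed_form_values(self, x, xp, expected):
        assert reconstruction_logloss(x, xp) == pytest.approx(expected, abs=1e-4)

    def test_symmetric_under_complement(self, rng):
        x = rng.uniform(0, 1, 12)
        xp = rng.uniform(0.01, 0.99, 12)
        assert reconstruction_logloss(x, xp) == pytest.approx(
            reconstruction_logloss(1 - x, 1 - xp)
        )

    def test_reconstruction_at_boundary_is_a_domain_error(self):
        with pytest.raises(ContractError):
            reconstruction_logloss([0.5], [1.0])


class TestTotalLoss:
    def test_no_penalty_equals_mean_reconstruction(self, rng):
        model, X = tiny_model(l1_weight=0.0, l2_activity=0.0)
        expected = np.mean(
            [reconstruction_logloss(x, model.reconstruct(x)[0]) for x in X]
        )
        assert model.total_loss(X) == pytest.approx(expected)

    def test_zero_weights_contribute_no_l1(self):
        model, X = tiny_model()
        model.coefs_ = [np.zeros_like(W) for W in model.coefs_]
        loss_on = model.total_loss(X)
        model.l1_weight = 0.0
        assert model.total_loss(X) == pytest.approx(loss_on)

    def test_matches_explicit_loop_oracle(self):
        model, X = tiny_model()
        assert model.total_loss(X) == pytest.approx(loop_loss_oracle(model, X))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Analytic gradients of the full objective vs central differences
        on a d=2 toy network, relative error < 1e-4."""
        model, X = tiny_model()
        _, gW, gb = model._loss_and_grads(X, rng=None)
        h = 1e-6
        for li in range(len(model.coefs_)):
            for arr, grad in ((model.coefs_[li], gW[li]),
                              (model.intercepts_[li], gb[li])):
                flat = arr.ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    up = model.total_loss(X)
                    flat[idx] = orig - h
                    down = model.total_loss(X)
                    flat[idx] = orig
                    fd = (up - down) / (2 * h)
                    g = grad.ravel()[idx]
                    assert g == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_fixed_seed_gives_identical_loss_trajectories(self, rng):
        X = rng.uniform(0.1, 0.9, size=(40, 10))
        runs = [
            Autoencoder(hidden_sizes=(6, 3, 6), learning_rate=1e-3, epochs=3,
                        batch_size=8, random_state=42).fit(X).loss_curve_
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_zero_learning_rate_is_a_no_op(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 6))
        model = Autoencoder(hidden_sizes=(4, 2, 4), learning_rate=0.0, epochs=3,
                            batch_size=20, dropout=0.0, random_state=1).fit(X)
        fresh = Autoencoder(hidden_sizes=(4, 2, 4), random_state=1)
        fresh._init_params([6, 4, 2, 4, 6], np.random.default_rng(1))
        for W, W0 in zip(model.coefs_, fresh.coefs_):
            np.testing.assert_array_equal(W, W0)
        assert np.ptp(model.loss_curve_) == pytest.approx(0.0, abs=1e-12)

    def test_training_reduces_loss_on_reference_cohort(self, reference_pipeline):
        """SGD makes steady progress on the reducible part of the loss.

        The summed logistic reconstruction loss has a large irreducible
        entropy floor (outputting 0.5 everywhere already costs ~log 2 per
        input dimension), so progress is judged on the smoothed trend and
        an absolute reduction, not a fixed fraction of the total.
        """
        curve = np.asarray(reference_pipeline["model"].loss_curve_)
        assert curve[-1] < curve[0] - 10.0
        smoothed = np.convolve(curve, np.ones(5) / 5, mode="valid")
        assert (np.diff(smoothed) <= 1e-3 * smoothed[:-1]).all()

    def test_divergent_learning_rate_raises_with_epoch(self, rng):
        X = rng.uniform(0.1, 0.9, size=(30, 8))
        with pytest.raises(DivergenceError):
            Autoencoder(hidden_sizes=(6, 3, 6), learning_rate=1e6, epochs=5,
                        batch_size=10, random_state=0).fit(X)

    def test_too_few_samples_for_a_batch_is_an_error(self, rng):
        X = rng.uniform(0.1, 0.9, size=(5, 4))
        with pytest.raises(ContractError, match="batch_size"):
            Autoencoder(hidden_sizes=(3, 1, 3), batch_size=32).fit(X)


class TestEncode:
    def test_inference_is_deterministic_despite_dropout_config(self, rng):
        X = rng.uniform(0.1, 0.9, size=(33, 10))
        model = Autoencoder(hidden_sizes=(6, 3, 6), learning_rate=1e-3, epochs=2,
                            batch_size=8, dropout=0.5, random_state=3).fit(X)
        np.testing.assert_array_equal(model.transform(X), model.transform(X))

    def test_bottleneck_width_and_names(self, reference_pipeline):
        latent = reference_pipeline["latent"]
        assert latent.shape[1] == 100
        assert latent.columns[0] == "AE_001" and latent.columns[-1] == "AE_100"
        assert np.isfinite(latent.to_numpy()).all()

    def test_sample_permutation_permutes_rows_identically(self, rng):
        X = rng.uniform(0.1, 0.9, size=(21, 10))
        model = Autoencoder(hidden_sizes=(6, 3, 6), learning_rate=1e-3, epochs=2,
                            batch_size=7, random_state=3).fit(X)
        perm = rng.permutation(len(X))
        np.testing.assert_allclose(
            model.transform(X[perm]), model.transform(X)[perm], atol=1e-12
        )

    def test_single_sample_and_width_mismatch(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 6))
        model = Autoencoder(hidden_sizes=(4, 2, 4), learning_rate=1e-3, epochs=1,
                            batch_size=5, random_state=0).fit(X)
        assert model.transform(X[0]).shape == (2,)
        with pytest.raises(ContractError, match="width"):
            model.transform(np.ones((3, 7)))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 6))
        model = Autoencoder(hidden_sizes=(4, 2, 4), learning_rate=1e-3, epochs=2,
                            batch_size=5, random_state=0).fit(X)
        model.save(tmp_path / "ckpt")
        back = Autoencoder.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(back.transform(X), model.transform(X))
        assert back.loss_curve_ == model.loss_curve_
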