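"""Feature extraction and linear discriminant direction/amplitude models."""

import numpy as np
import pytest

from turndetect.turn_classification import (
    DiscriminantModel,
    FeatureTriple,
    classify_amplitude,
    classify_direction,
    extract_features,
    train_discriminant,
)

from .conftest import make_signals, make_trial


def two_gaussian_sample(rng, n_per_class, mean, cov=None):
    """Symmetric two-class Gaussian mixture at +-mean."""
    cov = np.eye(3) if cov is None else cov
    mean = np.asarray(mean, float)
    Xp = rng.multivariate_normal(mean, cov, n_per_class)
    Xn = rng.multivariate_normal(-mean, cov, n_per_class)
    X = np.vstack([Xp, Xn])
    y = np.array(["left"] * n_per_class + ["right"] * n_per_class)
    return X, y


class TestExtractFeatures:
    def test_signed_identity_read(self):
        sig = make_signals(
            omega=np.full(200, 10.0), theta=np.full(200, 12.0),
            mag=np.full(200, 5.0), n=200,
        )
        feat = extract_features(sig, 500.0, absolute=False)
        assert (feat.angular_velocity_at_T, feat.mag_at_T, feat.angle_at_T) == (
            10.0, 5.0, 12.0,
        )

    def test_absolute_rectifies_negative_channels(self):
        sig = make_signals(
            omega=np.full(200, -10.0), theta=np.full(200, -12.0),
            mag=np.full(200, -5.0), n=200,
        )
        feat = extract_features(sig, 500.0, absolute=True)
        assert (feat.angular_velocity_at_T, feat.mag_at_T, feat.angle_at_T) == (
            10.0, 5.0, 12.0,
        )
        signed = extract_features(sig, 500.0, absolute=False)
        assert signed.angular_velocity_at_T == -10.0

    def test_time_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            extract_features(make_signals(n=100), 2000.0, absolute=False)

    def test_absolute_triple_rejects_negative_fields(self):
        with pytest.raises(ValueError):
            FeatureTriple(-1.0, 0.0, 0.0, absolute=True)


class TestDiscriminant:
    def test_point_at_class_mean_is_classified_to_it(self):
        rng = np.random.default_rng(0)
        X, y = two_gaussian_sample(rng, 200, [50.0, 20.0, 30.0])
        model = train_discriminant(X, y)
        assert model.predict(np.array([[50.0, 20.0, 30.0]])) == ["left"]
        assert model.predict(np.array([[-50.0, -20.0, -30.0]])) == ["right"]

    def test_exact_tie_breaks_to_first_label(self):
        # constructed model: equal priors, identity covariance, means +-m;
        # the midpoint (origin) scores both classes identically
        model = DiscriminantModel(
            class_labels=("a", "b"),
            class_means=np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
            pooled_covariance=np.eye(3),
            priors=np.array([0.5, 0.5]),
        )
        # closed form: delta_a(0) = -0.5 + log 0.5 = delta_b(0)
        assert model.predict(np.zeros((1, 3))) == ["a"]

    def test_accuracy_close_to_bayes_rate(self):
        """Held-out accuracy within 3 points of the Monte-Carlo Bayes rate."""
        rng = np.random.default_rng(1)
        mean = np.array([0.8, 0.4, 0.6])
        X, y = two_gaussian_sample(rng, 400, mean)
        model = train_discriminant(X, y)
        Xt, yt = two_gaussian_sample(rng, 50_000, mean)
        accuracy = np.mean(np.array(model.predict(Xt)) == yt)
        # Bayes oracle from the known parameters: sign of m' x
        bayes = np.where(Xt @ mean > 0, "left", "right")
        bayes_rate = np.mean(bayes == yt)
        assert abs(accuracy - bayes_rate) < 0.03

    def test_matches_reference_lda_implementation(self):
        """Independent cross-check against scikit-learn's LDA."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(2)
        X, y = two_gaussian_sample(rng, 300, [2.0, 1.0, -1.5])
        model = train_discriminant(X, y)
        ref = sklearn.LinearDiscriminantAnalysis().fit(X, y)
        Xt, _ = two_gaussian_sample(rng, 500, [2.0, 1.0, -1.5])
        agreement = np.mean(np.array(model.predict(Xt)) == ref.predict(Xt))
        assert agreement > 0.995

    def test_training_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        X, y = two_gaussian_sample(rng, 50, [1.0, 2.0, 3.0])
        perm = rng.permutation(len(y))
        a = train_discriminant(X, y)
        b = train_discriminant(X[perm], y[perm])
        assert np.allclose(a.class_means, b.class_means)
        assert np.allclose(a.pooled_covariance, b.pooled_covariance)
        assert np.allclose(a.priors, b.priors)

    def test_singular_covariance_is_regularized(self):
        X = np.array([[1.0, 1.0, 0.0], [1.1, 1.1, 0.0],
                      [-1.0, -1.0, 0.0], [-0.9, -0.9, 0.0]])
        y = np.array(["p", "p", "n", "n"])
        model = train_discriminant(X, y)  # rank-deficient within-class scatter
        assert model.predict(np.array([[1.0, 1.0, 0.0]])) == ["p"]

    def test_class_with_one_sample_rejected(self):
        X = np.zeros((3, 3))
        with pytest.raises(ValueError):
            train_discriminant(X, np.array(["a", "a", "b"]))

    def test_linear_boundary_along_segment(self):
        """On a fixed 3-class model, predictions along a segment change at
        most C-1 = 2 times (linear decision boundaries)."""
        rng = np.random.default_rng(4)
        X = np.vstack([
            rng.normal([0, 0, 0], 1.0, (100, 3)),
            rng.normal([6, 0, 0], 1.0, (100, 3)),
            rng.normal([3, 5, 0], 1.0, (100, 3)),
        ])
        y = np.repeat([0, 1, 2], 100)
        model = train_discriminant(X, y)
        a, b = np.array([-3.0, -2.0, 0.0]), np.array([9.0, 7.0, 0.0])
        ts = np.linspace(0, 1, 400)
        labels = model.predict(a[None, :] + ts[:, None] * (b - a)[None, :])
        changes = sum(l1 != l2 for l1, l2 in zip(labels, labels[1:]))
        assert changes <= 2

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        X, y = two_gaussian_sample(rng, 30, [1.0, 0.5, 0.2])
        model = train_discriminant(X, y)
        path = tmp_path / "model.json"
        model.save(path, location="upper_back", offset_ms=100.0, absolute=False)
        back = DiscriminantModel.load(path)
        assert back.class_labels == model.class_labels
        assert np.allclose(back.class_means, model.class_means)
        assert np.allclose(back.pooled_covariance, model.pooled_covariance)


class TestTrialClassification:
    def _trial(self, sign, amp=45.0):
        n = 1200
        omega = np.zeros(n)
        theta = np.zeros(n)
        mag = np.zeros(n)
        omega[500:] = sign * amp
        theta[500:] = sign * amp / 2.0
        mag[500:] = sign * amp / 3.0
        return make_trial(
            make_signals(omega=omega, theta=theta, mag=mag, n=n),
            path_label="left_45" if sign > 0 else "right_45",
        )

    def _direction_model(self):
        rng = np.random.default_rng(6)
        X, y = two_gaussian_sample(rng, 100, [45.0, 15.0, 22.5])
        return train_discriminant(X, y)

    def test_positive_signals_classify_left(self):
        model = self._direction_model()
        trial = self._trial(+1)
        from .conftest import UB

        assert classify_direction(model, trial, UB, 5000.0, 100.0) == "left"

    def test_mirrored_trial_flips_direction_keeps_amplitude(self):
        from .conftest import UB

        model = self._direction_model()
        rng = np.random.default_rng(7)
        Xa = np.vstack([
            rng.normal([a, a / 3.0, a / 2.0], 2.0, (50, 3)) for a in (22, 45, 90)
        ])
        ya = np.repeat([22, 45, 90], 50)
        amp_model = train_discriminant(np.abs(Xa), ya)
        left, right = self._trial(+1), self._trial(-1)
        assert classify_direction(model, left, UB, 5000.0, 100.0) == "left"
        assert classify_direction(model, right, UB, 5000.0, 100.0) == "right"
        assert classify_amplitude(amp_model, left, UB, 5000.0, 100.0) == classify_amplitude(
            amp_model, right, UB, 5000.0, 100.0
        )
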