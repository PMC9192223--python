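import numpy as np
import pytest
from scipy.stats import norm

from mimodes import (
    ConfigurationError,
    DegenerateInputError,
    classify,
    decision_density,
    decision_score,
    decision_values,
    fit_discriminant,
    overlap_area,
    select_threshold,
)
from mimodes.classifier import DecisionThreshold, DiscriminantModel


def two_cloud_data(rng, n=500, sep=4.0, cov=None):
    cov = np.eye(2) if cov is None else cov
    a = rng.multivariate_normal([0.0, 0.0], cov, n)
    b = rng.multivariate_normal([sep, 0.0], cov, n)
    x = np.vstack([a, b])
    labels = ["relaxed"] * n + ["imagery"] * n
    return x, labels


class TestFitDiscriminant:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        x, labels = two_cloud_data(rng, n=500, sep=4.0, cov=cov)
        model = fit_discriminant(x, labels)
        se = np.sqrt(np.diag(cov) / 500)
        assert np.all(np.abs(model.class_means["relaxed"] - [0, 0]) < 3 * se)
        assert np.all(np.abs(model.class_means["imagery"] - [4, 0]) < 3 * se)
        rel = np.linalg.norm(model.gamma - cov) / np.linalg.norm(cov)
        assert rel < 0.2

    def test_duplicated_samples_near_identical_model(self):
        rng = np.random.default_rng(1)
        x, labels = two_cloud_data(rng, n=500)
        m1 = fit_discriminant(x, labels)
        m2 = fit_discriminant(np.vstack([x, x]), labels + labels)
        for k in m1.class_means:
            assert np.allclose(m1.class_means[k], m2.class_means[k])
        assert np.linalg.norm(m2.gamma - m1.gamma) / np.linalg.norm(m1.gamma) < 0.01

    def test_small_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_discriminant(np.zeros((3, 2)), ["relaxed", "relaxed", "imagery"])

    def test_projection_rank(self):
        rng = np.random.default_rng(2)
        x, labels = two_cloud_data(rng, n=50)
        model = fit_discriminant(x, labels, projection_rank=1)
        assert model.projection.shape == (2, 1)
        assert model.gamma.shape == (1, 1)

    def test_per_class_gamma_mode(self):
        rng = np.random.default_rng(3)
        x, labels = two_cloud_data(rng, n=100)
        model = fit_discriminant(x, labels, per_class_gamma=True)
        assert set(model.gamma_by_class) == {"relaxed", "imagery"}


class TestDecisionValue:
    def unit_model(self):
        return DiscriminantModel(
            classes=["relaxed", "imagery"],
            class_means={
                "relaxed": np.array([0.0, 0.0]),
                "imagery": np.array([2.0, 0.0]),
            },
            projection=np.eye(2),
            gamma=np.eye(2),
            class_counts={"relaxed": 10, "imagery": 10},
        )

    def test_value_at_class_mean(self):
        model = self.unit_model()
        g = decision_values(model, np.array([0.0, 0.0]))
        # at the mean only ln K - 1/2 ln det Gamma survives; det I = 1
        assert g["relaxed"] == pytest.approx(np.log(2))

    def test_identity_gamma_closed_form(self):
        model = self.unit_model()
        x = np.array([1.0, 2.0])
        g = decision_values(model, x)
        for lab in model.classes:
            expected = -0.5 * np.sum((x - model.class_means[lab]) ** 2) + np.log(2)
            assert g[lab] == pytest.approx(expected)

    def test_midpoint_scores_zero(self):
        model = self.unit_model()
        assert decision_score(model, np.array([1.0, 5.0])) == pytest.approx(0.0)

    def test_nearest_mean_equivalence(self):
        # shared identity covariance, equal priors -> nearest-mean rule
        model = self.unit_model()
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.uniform(-3, 5, 2)
            score = decision_score(model, x)
            nearer_imagery = np.linalg.norm(x - [2, 0]) < np.linalg.norm(x)
            assert (score > 0) == nearer_imagery

    def test_shared_covariance_qda_oracle(self):
        """Label-for-label match with a hand-rolled pooled-covariance
        Mahalanobis classifier on a 50-point 2-D fixture."""
        rng = np.random.default_rng(5)
        cov = np.array([[1.5, 0.4], [0.4, 0.8]])
        x, labels = two_cloud_data(rng, n=25, sep=3.0, cov=cov)
        model = fit_discriminant(x, labels)

        # independent oracle: pooled covariance from np.cov, nearest
        # Mahalanobis mean with equal priors
        xa = x[np.array(labels) == "relaxed"]
        xb = x[np.array(labels) == "imagery"]
        pooled = (
            (len(xa) - 1) * np.cov(xa.T) + (len(xb) - 1) * np.cov(xb.T)
        ) / (len(xa) + len(xb) - 2)
        pinv = np.linalg.inv(pooled)

        test = rng.multivariate_normal([1.5, 0.0], cov, 50)
        for p in test:
            da = (p - xa.mean(0)) @ pinv @ (p - xa.mean(0))
            db = (p - xb.mean(0)) @ pinv @ (p - xb.mean(0))
            oracle = "imagery" if db < da else "relaxed"
            ours = "imagery" if decision_score(model, p) > 0 else "relaxed"
            assert ours == oracle


class TestDecisionDensity:
    def test_standard_normal_kde_value(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal(1000)
        curve = decision_density(v)
        at_zero = np.interp(0.0, curve.grid, curve.density)
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.15)

    def test_nonnegative_and_integrates_to_one(self):
        rng = np.random.default_rng(7)
        curve = decision_density(rng.standard_normal(200))
        assert np.all(curve.density >= 0)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(100)
        c0 = decision_density(v)
        c1 = decision_density(v + 5.0)
        assert np.allclose(c1.grid, c0.grid + 5.0)
        assert np.allclose(c1.density, c0.density)

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            decision_density([1.0, 2.0])

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            curve = decision_density(np.ones(20))
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)


class TestOverlapArea:
    def test_identical_curves(self):
        rng = np.random.default_rng(9)
        c = decision_density(rng.standard_normal(500))
        assert overlap_area(c, c) == pytest.approx(1.0, abs=1e-3)

    def test_distant_normals_disjoint(self):
        rng = np.random.default_rng(10)
        a = decision_density(rng.standard_normal(2000))
        b = decision_density(rng.standard_normal(2000) + 10.0)
        assert overlap_area(a, b) < 0.01

    def test_closed_form_normal_overlap(self):
        # equal-variance normals d apart overlap in 2*Phi(-d/2); d=2 -> 0.3173
        rng = np.random.default_rng(11)
        a = decision_density(rng.standard_normal(5000))
        b = decision_density(rng.standard_normal(5000) + 2.0)
        assert overlap_area(a, b) == pytest.approx(2 * norm.cdf(-1.0), abs=0.03)


class TestSelectThreshold:
    def test_order_statistics_by_hand(self):
        scores = np.arange(1.0, 101.0)
        thr = select_threshold(scores, fpr_max=0.10)
        assert 90.0 < thr.value <= 91.0
        assert thr.achieved_fpr == pytest.approx(0.10)

    def test_half_fpr_is_median(self):
        rng = np.random.default_rng(12)
        scores = rng.standard_normal(1001)
        thr = select_threshold(scores, fpr_max=0.5)
        assert thr.value == pytest.approx(np.median(scores), abs=0.05)

    def test_tied_scores_conservative(self):
        thr = select_threshold(np.full(20, 3.0), fpr_max=0.10)
        assert thr.value > 3.0
        assert thr.achieved_fpr == 0.0

    def test_invalid_fpr(self):
        with pytest.raises(ConfigurationError):
            select_threshold(np.arange(20.0), fpr_max=1.5)

    def test_too_few_scores(self):
        with pytest.raises(DegenerateInputError):
            select_threshold(np.arange(5.0), fpr_max=0.1)

    def test_monotonicity_in_fpr_max(self):
        rng = np.random.default_rng(13)
        scores = rng.standard_normal(200)
        grid = [0.05, 0.1, 0.2, 0.3, 0.5]
        thresholds = [select_threshold(scores, f) for f in grid]
        values = [t.value for t in thresholds]
        fprs = [t.achieved_fpr for t in thresholds]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))
        for t, f in zip(thresholds, grid):
            assert t.achieved_fpr <= f


class TestClassify:
    def model_and_threshold(self):
        model = DiscriminantModel(
            classes=["relaxed", "imagery"],
            class_means={
                "relaxed": np.array([0.0]),
                "imagery": np.array([2.0]),
            },
            projection=np.eye(1),
            gamma=np.eye(1),
            class_counts={"relaxed": 10, "imagery": 10},
        )
        thr = DecisionThreshold(value=0.0, fpr_max=0.1, achieved_fpr=0.1)
        return model, thr

    def test_extreme_scores(self):
        model, thr = self.model_and_threshold()
        assert classify(model, thr, np.array([10.0])) == "imagery"
        assert classify(model, thr, np.array([-10.0])) == "relaxed"

    def test_held_out_fpr_binomial_bound(self):
        rng = np.random.default_rng(14)
        fpr_max = 0.10
        train_neg = rng.standard_normal(500)
        thr = select_threshold(train_neg, fpr_max=fpr_max)
        held_out = rng.standard_normal(200)
        fpr = float(np.mean(held_out >= thr.value))
        slack = 2 * np.sqrt(fpr_max * (1 - fpr_max) / 200)
        assert fpr <= fpr_max + slack
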