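"""Shapley attribution: axioms, oracles and the additivity convention."""

import itertools
import math

import numpy as np
import pytest

from oncosurv.explain import (
    ShapleyReport,
    coalition_value,
    exact_shapley,
    overall_score,
    permutation_shapley,
)

# printed per-feature attributions (tumor size, EGFR mutation, age) and totals
SHAP_ROWS = [
    ([0.35, 0.28, 0.17], 0.80),
    ([0.31, 0.26, 0.18], 0.75),
    ([0.37, 0.31, 0.21], 0.89),
    ([0.28, 0.22, 0.15], 0.65),
    ([0.42, 0.33, 0.20], 0.95),
]


def all_orders_shapley(model, x, background):
    """Independent oracle: average marginal contribution over all n! orders."""
    x = np.asarray(x, float)
    n = x.size
    bg = np.atleast_2d(np.asarray(background, float)).mean(axis=0)
    phi = np.zeros(n)
    for order in itertools.permutations(range(n)):
        row = bg.copy()
        prev = float(model(row[None])[0])
        for i in order:
            row[i] = x[i]
            cur = float(model(row[None])[0])
            phi[i] += cur - prev
            prev = cur
    return phi / math.factorial(n)


class TestCoalitionValue:
    def test_full_and_empty_coalitions(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)
        model = lambda rows: rows @ w
        x = rng.normal(size=4)
        bg = rng.normal(size=(10, 4))
        assert coalition_value(model, x, set(range(4)), bg) == pytest.approx(x @ w)
        assert coalition_value(model, x, set(), bg) == pytest.approx(bg.mean(0) @ w)

    def test_linear_model_mean_zero_background(self):
        w = np.array([2.0, -1.0, 0.5])
        model = lambda rows: rows @ w
        x = np.array([1.0, 2.0, -1.0])
        bg = np.zeros((3, 3))
        assert coalition_value(model, x, {0, 2}, bg) == pytest.approx(
            w[0] * x[0] + w[2] * x[2]
        )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            coalition_value(lambda r: r.sum(1), [1.0], {0}, np.empty((0, 1)))


class TestExactShapley:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=6)
        x = rng.normal(size=6)
        rep = exact_shapley(lambda rows: rows @ w, x, np.zeros((4, 6)))
        assert np.allclose(rep.phi, w * x, atol=1e-12)
        assert rep.phi.sum() == pytest.approx(rep.full_value - rep.baseline_value, abs=1e-8)

    def test_dummy_feature_zero_attribution(self):
        model = lambda rows: rows[:, 0] * 2 + rows[:, 1] ** 2
        rep = exact_shapley(model, [1.0, 2.0, 5.0], np.zeros((3, 3)))
        assert rep.phi[2] == 0.0

    def test_symmetric_features_equal_attribution(self):
        model = lambda rows: np.tanh(rows[:, 0] + rows[:, 1])
        rep = exact_shapley(model, [0.7, 0.7], np.zeros((2, 2)))
        assert rep.phi[0] == pytest.approx(rep.phi[1], abs=1e-12)

    def test_matches_all_orders_enumeration(self):
        rng = np.random.default_rng(2)
        w1 = rng.normal(size=(4, 5))
        w2 = rng.normal(size=4)
        model = lambda rows: np.tanh(rows @ w1.T) @ w2
        x = rng.normal(size=5)
        bg = rng.normal(size=(6, 5))
        rep = exact_shapley(model, x, bg)
        oracle = all_orders_shapley(model, x, bg)
        assert np.abs(rep.phi - oracle).max() < 1e-10

    def test_axioms_on_randomized_small_models(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            w = rng.normal(size=n)
            b = rng.normal()
            model = lambda rows, w=w, b=b: np.sin(rows @ w) + b
            x = rng.normal(size=n)
            bg = rng.normal(size=(5, n))
            rep = exact_shapley(model, x, bg)
            # efficiency
            assert rep.phi.sum() == pytest.approx(
                rep.full_value - rep.baseline_value, abs=1e-8
            )

    def test_too_many_features_directs_to_permutation(self):
        with pytest.raises(ValueError, match="permutation"):
            exact_shapley(lambda r: r.sum(1), np.zeros(16), np.zeros((2, 16)))


class TestPermutationShapley:
    MODEL_W1 = np.random.default_rng(4).normal(size=(4, 6))
    MODEL_W2 = np.random.default_rng(5).normal(size=4)

    @classmethod
    def model(cls, rows):
        return np.tanh(rows @ cls.MODEL_W1.T) @ cls.MODEL_W2

    def test_agrees_with_exact_within_three_standard_errors(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=6)
        bg = rng.normal(size=(8, 6))
        exact = exact_shapley(self.model, x, bg)
        est = permutation_shapley(self.model, x, bg, n_samples=2000, seed=0)
        assert (np.abs(est.phi - exact.phi) <= 3 * est.std_errors + 1e-12).all()

    def test_standard_error_shrinks_with_sqrt_samples(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        bg = rng.normal(size=(8, 6))
        ses = []
        for n in (500, 2000):  # 4x samples -> about half the SE
            reps = [
                permutation_shapley(self.model, x, bg, n_samples=n, seed=s).std_errors
                for s in range(3)
            ]
            ses.append(np.mean(reps))
        assert ses[1] == pytest.approx(ses[0] / 2, rel=0.25)

    def test_same_seed_identical_estimates(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=6)
        bg = rng.normal(size=(4, 6))
        a = permutation_shapley(self.model, x, bg, n_samples=50, seed=9)
        b = permutation_shapley(self.model, x, bg, n_samples=50, seed=9)
        assert np.array_equal(a.phi, b.phi)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            permutation_shapley(self.model, np.zeros(6), np.zeros((2, 6)), n_samples=5)


class TestOverallScore:
    @pytest.mark.parametrize("phi,total", SHAP_ROWS)
    def test_reference_additivity_rows(self, phi, total):
        rep = ShapleyReport(
            feature_names=["tumor_size", "egfr", "age"],
            phi=np.array(phi),
            baseline_value=0.0,
            full_value=sum(phi),
            method="exact",
        )
        assert overall_score(rep) == pytest.approx(total, abs=1e-12)

    def test_zero_attributions(self):
        rep = ShapleyReport(["a"], np.zeros(1), 0.0, 0.0, "exact")
        assert overall_score(rep) == 0.0

    def test_alternative_conventions(self):
        rep = ShapleyReport(["a", "b"], np.array([0.5, -0.25]), 0.0, 0.25, "exact")
        assert overall_score(rep, "abs_sum") == pytest.approx(0.75)
        assert overall_score(rep, "normalized") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            overall_score(rep, "bogus")
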