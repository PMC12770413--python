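"""Cox partial likelihood, Breslow baseline, concordance and stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncosurv import simulate, survival
from oncosurv._nn import Tensor
from oncosurv.survival import (
    RiskCutpoints,
    breslow_baseline,
    concordance_index,
    cox_loss_tensor,
    cumulative_hazard,
    neg_log_partial_likelihood,
    stratify_risk,
)
from tests.conftest import brute_force_cindex

# printed per-patient hazard ratios and their risk-group assignments
HAZARD_GROUPS = [(1.43, "high"), (1.08, "medium"), (1.55, "high"), (0.92, "low"), (1.67, "high")]


class TestPartialLikelihood:
    def test_two_subject_closed_form(self):
        # times (1,2), both events, equal scores 0 -> log 2
        assert neg_log_partial_likelihood([0.0, 0.0], [1, 2], [1, 1]) == pytest.approx(
            np.log(2), abs=1e-12
        )
        a, b = 0.7, -0.4
        expect = -(a - np.logaddexp(a, b) + b - b)
        assert neg_log_partial_likelihood([a, b], [1, 2], [1, 1]) == pytest.approx(
            expect, abs=1e-12
        )

    @given(st.integers(0, 10_000), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        n = 12
        s = rng.normal(size=n)
        t = rng.exponential(1, n)
        d = (rng.uniform(size=n) < 0.7).astype(int)
        if d.sum() == 0:
            d[0] = 1
        base = neg_log_partial_likelihood(s, t, d)
        assert neg_log_partial_likelihood(s + shift, t, d) == pytest.approx(base, abs=1e-8)

    def test_equal_scores_sum_of_log_risk_set_sizes(self):
        n = 6
        t = np.arange(1, n + 1)
        d = np.ones(n, int)
        expect = sum(np.log(k) for k in range(1, n + 1))
        assert neg_log_partial_likelihood(np.zeros(n), t, d) == pytest.approx(expect)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            neg_log_partial_likelihood([1.0, 2.0], [1, 2], [0, 0])

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(3)
        n = 20
        s0 = rng.normal(size=(n, 1))
        t = rng.exponential(1, n)
        d = (rng.uniform(size=n) < 0.6).astype(int)
        d[0] = 1
        s = Tensor(s0.copy(), requires_grad=True)
        cox_loss_tensor(s, t, d).backward()
        eps = 1e-6
        for i in range(n):
            up, dn = s0.copy(), s0.copy()
            up[i] += eps
            dn[i] -= eps
            num = (
                neg_log_partial_likelihood(up.ravel(), t, d)
                - neg_log_partial_likelihood(dn.ravel(), t, d)
            ) / (2 * eps)
            assert abs(s.grad[i, 0] - num) <= 1e-4 * max(1.0, abs(num))


class TestBreslow:
    def test_hand_evaluated_increments(self):
        times, h0 = breslow_baseline([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(h0, np.cumsum([1 / 3, 1 / 2, 1 / 1]))
        assert np.allclose(times, [1.0, 2.0, 3.0])

    def test_non_decreasing_and_scaling_identity(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=30)
        t = rng.exponential(1, 30)
        d = (rng.uniform(size=30) < 0.6).astype(int)
        d[0] = 1
        _, h0 = breslow_baseline(s, t, d)
        assert (np.diff(h0) >= 0).all() and (h0 >= 0).all()
        _, h0_double = breslow_baseline(s + np.log(2), t, d)
        assert np.allclose(h0_double, h0 / 2)


class TestCumulativeHazard:
    @pytest.fixture()
    def toy_state(self):
        from oncosurv._layers import MLP

        net = MLP((1, 1), seed=0)
        net.weights[0].value[:] = 1.0
        net.biases[0].value[:] = 0.0
        state = survival.SurvivalModelState(
            net=net,
            feature_names=["x1"],
            feature_means=np.zeros(1),
            feature_sds=np.ones(1),
            baseline_times=np.array([1.0, 2.0, 3.0]),
            baseline_h0=np.cumsum([1 / 3, 1 / 2, 1 / 1]),
        )
        return state

    def test_zero_time_and_unit_hazard_identity(self, toy_state):
        assert cumulative_hazard(toy_state, [0.0], 0.0) == 0.0
        # exp(f(x)) = 1 at x = 0 -> H equals H0
        assert cumulative_hazard(toy_state, [0.0], 2.5) == pytest.approx(1 / 3 + 1 / 2)

    def test_hand_product_after_second_event(self, toy_state):
        x = [np.log(2.0)]  # exp(f) = 2
        assert cumulative_hazard(toy_state, x, 2.5) == pytest.approx(2 * (1 / 3 + 1 / 2))

    def test_monotone_in_time_and_survival_in_unit_interval(self, toy_state):
        ts = np.linspace(0, 5, 30)
        h = [cumulative_hazard(toy_state, [0.3], t) for t in ts]
        assert (np.diff(h) >= 0).all()
        s = [survival.survival_function(toy_state, [0.3], t) for t in ts]
        assert all(0.0 <= v <= 1.0 for v in s)

    def test_negative_time_rejected(self, toy_state):
        with pytest.raises(ValueError):
            cumulative_hazard(toy_state, [0.0], -1.0)


class TestConcordance:
    def test_perfectly_anti_ordered_predictions(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index([4, 3, 2, 1], t, [1, 1, 1, 1]) == 1.0

    def test_all_tied_predictions_give_half(self):
        assert concordance_index([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.5

    def test_hand_enumerated_censored_example(self):
        # comparable pairs (earlier subject must have an observed event):
        # (1,2) 4>1, (1,3) 4>3, (1,4) 4>2 concordant; (2,3) 1<3 and
        # (2,4) 1<2 discordant -> 3/5; confirmed by brute force and lifelines
        c = concordance_index([4, 1, 3, 2], [1, 2, 3, 4], [1, 1, 0, 1])
        assert c == pytest.approx(3 / 5)
        assert c == brute_force_cindex([4, 1, 3, 2], [1, 2, 3, 4], [1, 1, 0, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 31)
            p = rng.choice(rng.normal(size=max(2, n // 2)), size=n)  # forces ties
            t = np.round(rng.exponential(1, n), 2)
            d = (rng.uniform(size=n) < 0.7).astype(int)
            try:
                expect = brute_force_cindex(p, t, d)
            except ValueError:
                with pytest.raises(ValueError):
                    concordance_index(p, t, d)
                continue
            assert concordance_index(p, t, d) == expect

    def test_agrees_with_lifelines_on_continuous_data(self):
        from lifelines.utils import concordance_index as lifelines_cindex

        rng = np.random.default_rng(1)
        n = 300
        p = rng.normal(size=n)
        t = rng.exponential(1, n)
        d = (rng.uniform(size=n) < 0.7).astype(int)
        ours = concordance_index(p, t, d)
        # lifelines scores low-risk-lives-longer, so feed negated hazards
        assert ours == pytest.approx(lifelines_cindex(t, -p, d), abs=1e-12)


class TestStratification:
    @pytest.mark.parametrize("hr,group", HAZARD_GROUPS)
    def test_default_cutpoints_reproduce_reference_groups(self, hr, group):
        assert stratify_risk(hr) == group

    def test_boundary_is_half_open(self):
        cp = RiskCutpoints(low_upper=1.0, high_lower=1.2)
        assert stratify_risk(1.0, cp) == "medium"
        assert stratify_risk(1.2, cp) == "high"

    def test_invalid_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            RiskCutpoints(low_upper=1.5, high_lower=1.2)


class TestFitting:
    def test_linear_fit_recovers_generating_coefficients(self, fitted_linear_cox):
        state, _, _ = fitted_linear_cox
        beta_hat = state.coefficients()
        truth = np.array([1.0, -0.8, 0.5])
        assert np.all(np.sign(beta_hat) == np.sign(truth))
        assert np.abs(beta_hat - truth).max() <= 0.25

    def test_training_loss_decreases(self, cox_table_600):
        df = cox_table_600.iloc[:200]
        _, hist = survival.fit_deepsurv(
            df[["x1", "x2", "x3"]].to_numpy(),
            df["time"],
            df["event"],
            hidden=(8,),
            lr=0.02,
            epochs=60,
            seed=0,
            return_history=True,
        )
        smooth = np.convolve(hist, np.ones(5) / 5, mode="valid")
        assert (np.diff(smooth[:10]) < 0).all()

    def test_patient_order_permutation_invariance(self, cox_table_600):
        df = cox_table_600.iloc[:100]
        x = df[["x1", "x2", "x3"]].to_numpy()
        t, d = df["time"].to_numpy(), df["event"].to_numpy()
        perm = np.random.default_rng(0).permutation(len(df))
        a = neg_log_partial_likelihood(x @ [1, -1, 0.5], t, d)
        b = neg_log_partial_likelihood((x @ [1, -1, 0.5])[perm], t[perm], d[perm])
        assert a == pytest.approx(b, abs=1e-6)

    def test_all_censored_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 2))
        with pytest.raises(ValueError):
            survival.fit_deepsurv(x, rng.exponential(1, 30), np.zeros(30, int))
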