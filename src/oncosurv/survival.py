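"""Deep Cox proportional-hazards survival modelling.

The hazard for covariates x is h(t|x) = h0(t) exp(f(x)) with f a small
neural risk network (a plain linear model when no hidden layers are
configured).  Training minimises the negative log partial likelihood with
Breslow's convention for tied event times; the cumulative baseline hazard
H0 is then estimated by the Breslow step estimator, giving per-patient
cumulative-hazard curves H(t|x) = H0(t) exp(f(x)).  Ranking quality is
measured by Harrell's concordance index, and hazard ratios exp(f(x)) are
mapped to low/medium/high risk groups by fixed cutpoints (default 1.0 and
1.2) or cohort tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._layers import MLP
from ._nn import Adam, Tensor

__all__ = [
    "RiskCutpoints",
    "SurvivalModelState",
    "RiskPrediction",
    "neg_log_partial_likelihood",
    "cox_loss_tensor",
    "fit_deepsurv",
    "breslow_baseline",
    "cumulative_hazard",
    "survival_function",
    "concordance_index",
    "stratify_risk",
    "tertile_cutpoints",
]


@dataclass
class RiskCutpoints:
    """Hazard-ratio thresholds separating low / medium / high risk."""

    low_upper: float = 1.0
    high_lower: float = 1.2

    def __post_init__(self):
        if not self.low_upper < self.high_lower:
            raise ValueError("low_upper must be < high_lower")


@dataclass
class SurvivalModelState:
    """Fitted risk network plus the Breslow baseline hazard table."""

    net: MLP
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_h0: np.ndarray = field(default_factory=lambda: np.empty(0))

    def risk_scores(self, x) -> np.ndarray:
        """f(x): the log hazard ratio for each row of x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        z = (x - self.feature_means) / self.feature_sds
        return self.net.forward(z).value.ravel()

    def hazard_ratios(self, x) -> np.ndarray:
        return np.exp(self.risk_scores(x))

    def coefficients(self) -> np.ndarray:
        """Original-scale coefficients; only defined for a linear net."""
        if len(self.net.weights) != 1:
            raise ValueError("coefficients are defined only for a linear risk net")
        return self.net.weights[0].value.ravel() / self.feature_sds


@dataclass
class RiskPrediction:
    hazard_ratio: float
    risk_group: str
    cumulative_hazard: object  # callable t -> H(t|x)


def _validate_survival_arrays(risk_scores, times, events):
    s = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=int).ravel()
    if not (len(s) == len(t) == len(d)):
        raise ValueError("risk_scores, times and events must have equal length")
    return s, t, d


def neg_log_partial_likelihood(risk_scores, times, events) -> float:
    """Negative log Cox partial likelihood (Breslow ties).

    -sum over observed events i of [ f(x_i) - log sum_{j: t_j >= t_i}
    exp(f(x_j)) ].  Tied event times share the same risk set.
    """
    s, t, d = _validate_survival_arrays(risk_scores, times, events)
    if d.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    m = s.max()
    e = np.exp(s - m)
    # risk set of i: subjects with t_j >= t_i
    log_denom = np.array(
        [np.log(e[t >= ti].sum()) + m for ti in t]
    )
    return float(-(d * (s - log_denom)).sum())


def cox_loss_tensor(scores: Tensor, times, events, normalize: bool = False) -> Tensor:
    """Autodiff Cox partial-likelihood loss; `scores` is an (n, 1) Tensor."""
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=float).ravel()
    n = t.size
    if d.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    risk_mat = (t[None, :] >= t[:, None]).astype(float)  # row i: risk set of i
    m = float(scores.value.max())
    e = (scores - m).exp()                      # (n, 1)
    log_denom = (Tensor(risk_mat) @ e).log() + m  # (n, 1)
    terms = (scores - log_denom).reshape(n) * Tensor(d)
    loss = -terms.sum()
    if normalize:
        loss = loss * (1.0 / d.sum())
    return loss


def breslow_baseline(risk_scores, times, events) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the cumulative baseline hazard H0.

    At each distinct event time the increment is (number of events) /
    (sum of exp(f) over the risk set); H0 is the running sum.
    """
    s, t, d = _validate_survival_arrays(risk_scores, times, events)
    if d.sum() == 0:
        raise ValueError("Breslow baseline requires at least one event")
    exp_s = np.exp(s)
    event_times = np.unique(t[d == 1])
    increments = np.array(
        [
            (d[t == et].sum()) / exp_s[t >= et].sum()
            for et in event_times
        ]
    )
    return event_times, np.cumsum(increments)


def cumulative_hazard(state: SurvivalModelState, x, t: float) -> float:
    """H(t|x) = H0(t) exp(f(x)), with H0 right-continuous step interpolation."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if state.baseline_times.size == 0:
        raise ValueError("model has no fitted baseline hazard")
    idx = np.searchsorted(state.baseline_times, t, side="right") - 1
    h0 = 0.0 if idx < 0 else float(state.baseline_h0[idx])
    return h0 * float(state.hazard_ratios(x)[0])


def survival_function(state: SurvivalModelState, x, t: float) -> float:
    """S(t|x) = exp(-H(t|x))."""
    return float(np.exp(-cumulative_hazard(state, x, t)))


def concordance_index(pred_hazard, times, events) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly.

    Pair (i, j) is comparable when subject i has an observed event and
    t_i < t_j; it is concordant when pred_hazard_i > pred_hazard_j.
    Prediction ties count one half.
    """
    p, t, d = _validate_survival_arrays(pred_hazard, times, events)
    comparable = (d[:, None] == 1) & (t[:, None] < t[None, :])
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    conc = (p[:, None] > p[None, :]) & comparable
    ties = (p[:, None] == p[None, :]) & comparable
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)


def stratify_risk(hazard_ratio: float, cutpoints: RiskCutpoints | None = None) -> str:
    """Map a hazard ratio to 'low' / 'medium' / 'high' (half-open bins)."""
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    cp = cutpoints or RiskCutpoints()
    if hazard_ratio < cp.low_upper:
        return "low"
    if hazard_ratio < cp.high_lower:
        return "medium"
    return "high"


def tertile_cutpoints(hazard_ratios) -> RiskCutpoints:
    """Cohort-tertile alternative to the fixed default cutpoints."""
    q1, q2 = np.quantile(np.asarray(hazard_ratios, dtype=float), [1 / 3, 2 / 3])
    return RiskCutpoints(low_upper=float(q1), high_lower=float(q2))


def fit_deepsurv(
    x,
    times,
    events,
    feature_names: list[str] | None = None,
    hidden: tuple[int, ...] = (32, 16),
    dropout: float = 0.0,
    lr: float = 0.05,
    epochs: int = 500,
    seed: int = 0,
    standardize: bool = True,
    return_history: bool = False,
):
    """Fit the deep Cox model by full-batch Adam on the partial likelihood.

    `hidden=()` gives a plain linear Cox-type risk model.  Features are
    z-scored internally (stored in the state) unless `standardize=False`.
    Deterministic for a fixed seed.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=int).ravel()
    if len(x) < 20:
        raise ValueError("need at least 20 samples")
    if d.sum() < 5:
        raise ValueError("need at least 5 observed events")
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(x.shape[1])]

    if standardize:
        means, sds = x.mean(axis=0), x.std(axis=0) + 1e-12
    else:
        means, sds = np.zeros(x.shape[1]), np.ones(x.shape[1])
    z = (x - means) / sds

    net = MLP(
        (x.shape[1], *hidden, 1),
        hidden_activation="relu",
        dropout=dropout,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    opt = Adam(net.params, lr=lr)
    history = []
    for _ in range(epochs):
        opt.zero_grad()
        scores = net.forward(z, train=dropout > 0, rng=rng)
        loss = cox_loss_tensor(scores, t, d, normalize=True)
        loss.backward()
        opt.step()
        history.append(float(loss.value))

    state = SurvivalModelState(
        net=net,
        feature_names=list(feature_names),
        feature_means=means,
        feature_sds=sds,
    )
    bt, bh = breslow_baseline(state.risk_scores(x), t, d)
    state.baseline_times, state.baseline_h0 = bt, bh
    if return_history:
        return state, history
    return state


def predict_risk_table(
    state: SurvivalModelState,
    x,
    patient_ids=None,
    cutpoints: RiskCutpoints | None = None,
) -> pd.DataFrame:
    """Per-patient hazard ratios and risk groups as a DataFrame."""
    hr = state.hazard_ratios(x)
    ids = patient_ids if patient_ids is not None else list(range(len(hr)))
    return pd.DataFrame(
        {
            "patient_id": ids,
            "hazard_ratio": hr,
            "risk_group": [stratify_risk(h, cutpoints) for h in hr],
        }
    )
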