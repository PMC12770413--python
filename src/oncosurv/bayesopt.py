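"""Gaussian-process Bayesian optimisation with the UCB acquisition.

A squared-exponential GP surrogate (per-dimension lengthscales, inputs
mapped to the unit cube, log-scaled where requested) models the objective
from previously evaluated configurations; the next configuration
maximises the upper confidence bound mu + kappa * sigma over a seeded
random candidate set.  Integer dimensions are relaxed to continuous
values and rounded after proposal.  Used to tune the hyperparameters of
the other modules (learning rate, dropout, layer counts, EWC strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import qmc

__all__ = [
    "SearchSpace",
    "TrialLog",
    "gp_posterior",
    "fit_gp_hyperparams",
    "ucb_acquisition",
    "optimize",
]

_KINDS = ("continuous", "log_continuous", "integer")


@dataclass
class SearchSpace:
    """Box search space: list of (name, kind, lower, upper)."""

    dimensions: list[tuple[str, str, float, float]]

    def __post_init__(self):
        for name, kind, lo, hi in self.dimensions:
            if kind not in _KINDS:
                raise ValueError(f"{name}: unknown kind {kind}")
            if not lo < hi:
                raise ValueError(f"{name}: lower must be < upper")
            if kind == "integer" and (lo != int(lo) or hi != int(hi)):
                raise ValueError(f"{name}: integer bounds must be integral")
            if kind == "log_continuous" and lo <= 0:
                raise ValueError(f"{name}: log-scale bounds must be positive")

    @property
    def names(self) -> list[str]:
        return [d[0] for d in self.dimensions]

    def from_unit(self, u: np.ndarray) -> dict:
        """Map a unit-cube point to a configuration dict."""
        cfg = {}
        for uj, (name, kind, lo, hi) in zip(u, self.dimensions):
            if kind == "log_continuous":
                val = float(np.exp(np.log(lo) + uj * (np.log(hi) - np.log(lo))))
            else:
                val = float(lo + uj * (hi - lo))
                if kind == "integer":
                    val = int(np.clip(round(val), lo, hi))
            cfg[name] = val
        return cfg

    def to_unit(self, cfg: dict) -> np.ndarray:
        u = []
        for name, kind, lo, hi in self.dimensions:
            v = cfg[name]
            if kind == "log_continuous":
                u.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                u.append((v - lo) / (hi - lo))
        return np.asarray(u)


@dataclass
class TrialLog:
    configs: list[dict] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)  # nan marks a failed trial
    gp_hyperparams: dict = field(default_factory=dict)
    best_config: dict | None = None
    best_score: float = float("-inf")


def _se_kernel(xa, xb, lengthscales, signal_var) -> np.ndarray:
    ell = np.asarray(lengthscales, dtype=float)
    d2 = (((xa[:, None, :] - xb[None, :, :]) / ell) ** 2).sum(axis=-1)
    return signal_var * np.exp(-0.5 * d2)


def gp_posterior(
    x_obs,
    y_obs,
    x_query,
    lengthscales,
    signal_var: float = 1.0,
    noise_var: float = 1e-6,
    jitter: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean GP regression posterior with a squared-exponential kernel.

    Returns (mu, sigma^2) at each query point; sigma^2 is clipped at 0.
    """
    x_obs = np.atleast_2d(np.asarray(x_obs, dtype=float))
    x_query = np.atleast_2d(np.asarray(x_query, dtype=float))
    y = np.asarray(y_obs, dtype=float).ravel()
    if len(x_obs) == 0:
        raise ValueError("need at least one observation")
    k = _se_kernel(x_obs, x_obs, lengthscales, signal_var)
    k[np.diag_indices_from(k)] += noise_var + jitter
    try:
        cf = cho_factor(k)
    except np.linalg.LinAlgError as e:
        raise ValueError("kernel matrix is singular even after jitter") from e
    ks = _se_kernel(x_query, x_obs, lengthscales, signal_var)
    mu = ks @ cho_solve(cf, y)
    var = signal_var - (ks * cho_solve(cf, ks.T).T).sum(axis=1)
    return mu, np.maximum(var, 0.0)


def _log_marginal(x, y, ell, sv, nv) -> float:
    k = _se_kernel(x, x, np.full(x.shape[1], ell), sv)
    k[np.diag_indices_from(k)] += nv + 1e-8
    try:
        cf = cho_factor(k)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = cho_solve(cf, y)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi))


def fit_gp_hyperparams(x_obs, y_obs) -> dict:
    """Marginal-likelihood grid search for (lengthscale, signal, noise)."""
    x = np.atleast_2d(np.asarray(x_obs, dtype=float))
    y = np.asarray(y_obs, dtype=float).ravel()
    sv = max(float(y.var()), 1e-6)
    best, best_ll = None, -np.inf
    for ell in (0.1, 0.2, 0.3, 0.5, 1.0, 2.0):
        for nv_rel in (1e-6, 1e-4, 1e-2, 1e-1):
            ll = _log_marginal(x, y, ell, sv, nv_rel * sv)
            if ll > best_ll:
                best_ll, best = ll, {
                    "lengthscales": np.full(x.shape[1], ell),
                    "signal_var": sv,
                    "noise_var": nv_rel * sv,
                }
    return best


def ucb_acquisition(mu, sigma, kappa: float = 2.0):
    """Upper confidence bound mu + kappa * sigma (sigma >= 0)."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be >= 0")
    return mu + kappa * np.asarray(sigma)


def optimize(
    objective,
    space: SearchSpace,
    budget: int = 50,
    kappa: float = 2.0,
    seed: int = 0,
    n_init: int = 5,
    n_candidates: int = 1000,
) -> TrialLog:
    """Run GP-UCB optimisation with exactly `budget` objective evaluations.

    The initial design is `n_init` scrambled-Sobol points; afterwards each
    proposal maximises the UCB over a fresh seeded uniform candidate set.
    Trials whose objective raises are logged with a NaN score and excluded
    from the surrogate; the budget is still consumed.
    """
    if budget < n_init:
        raise ValueError(f"budget must be >= {n_init}")
    rng = np.random.default_rng(seed)
    d = len(space.dimensions)
    sobol = qmc.Sobol(d, scramble=True, seed=seed)
    log = TrialLog()
    units: list[np.ndarray] = []

    def evaluate(u: np.ndarray) -> None:
        cfg = space.from_unit(u)
        try:
            score = float(objective(cfg))
        except Exception:
            score = float("nan")
        units.append(space.to_unit(cfg))  # rounded integers: actual point used
        log.configs.append(cfg)
        log.scores.append(score)
        if not np.isnan(score) and score > log.best_score:
            log.best_score = score
            log.best_config = cfg

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # n_init need not be 2^k
        init = sobol.random(n_init)
    for u in init:
        evaluate(u)

    for _ in range(budget - n_init):
        x = np.array([u for u, s in zip(units, log.scores) if not np.isnan(s)])
        y = np.array([s for s in log.scores if not np.isnan(s)])
        if len(x) == 0:
            evaluate(rng.uniform(size=d))
            continue
        hp = fit_gp_hyperparams(x, y)
        log.gp_hyperparams = {
            "lengthscales": hp["lengthscales"].tolist(),
            "signal_var": hp["signal_var"],
            "noise_var": hp["noise_var"],
        }
        cand = rng.uniform(size=(n_candidates, d))
        mu, var = gp_posterior(
            x, y - y.mean(), cand,
            hp["lengthscales"], hp["signal_var"], hp["noise_var"],
        )
        acq = ucb_acquisition(mu + y.mean(), np.sqrt(var), kappa)
        evaluate(cand[int(np.argmax(acq))])

    return log
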