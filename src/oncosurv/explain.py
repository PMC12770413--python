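"""Shapley-value feature attribution for the classifier and survival model.

The attribution of feature i is its average marginal contribution over
feature coalitions,

    phi_i = sum_{S subset of N\\{i}} |S|! (|N|-|S|-1)! / |N|!
            * ( f(S u {i}) - f(S) ),

where f(S) evaluates the model with the features outside S replaced by
their background means (the interventional convention).  Exact coalition
enumeration is used for up to 15 features; a uniform-permutation Monte
Carlo estimator with per-feature standard errors covers larger sets.
Explained scalars: the predicted-class probability for the classifier and
the log hazard ratio f(x) for the survival model.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "ShapleyReport",
    "coalition_value",
    "exact_shapley",
    "permutation_shapley",
    "overall_score",
]

_MAX_EXACT = 15


@dataclass
class ShapleyReport:
    feature_names: list[str]
    phi: np.ndarray
    baseline_value: float        # f(empty set)
    full_value: float            # f(all features)
    method: str                  # "exact" | "permutation"
    n_samples: int | None = None
    seed: int | None = None
    std_errors: np.ndarray | None = None

    @property
    def overall_score(self) -> float:
        return overall_score(self)


def _as_model(model):
    """Accept either f(2-D array) -> 1-D or f(1-D row) -> scalar."""
    def call(rows: np.ndarray) -> np.ndarray:
        out = np.asarray(model(rows))
        if out.ndim == 0:  # scalar-only model: evaluate row by row
            return np.array([float(model(r)) for r in rows])
        return out.ravel()
    return call


def coalition_value(model, x, subset, background) -> float:
    """f(S): model output with features outside `subset` set to background means."""
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    x = np.asarray(x, dtype=float).ravel()
    row = bg.mean(axis=0).copy()
    idx = list(subset)
    row[idx] = x[idx]
    return float(_as_model(model)(row[None])[0])


def exact_shapley(
    model, x, background, feature_names: list[str] | None = None
) -> ShapleyReport:
    """Exact Shapley values by full 2^n coalition enumeration (n <= 15)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n > _MAX_EXACT:
        raise ValueError(
            f"{n} features exceeds the exact-enumeration limit of {_MAX_EXACT}; "
            "use permutation_shapley"
        )
    bg_mean = np.atleast_2d(np.asarray(background, dtype=float)).mean(axis=0)
    if bg_mean.size == 0:
        raise ValueError("background must be non-empty")
    f = _as_model(model)

    # evaluate every coalition once: row for bitmask m keeps x where bit set
    masks = np.arange(2**n)
    bits = (masks[:, None] >> np.arange(n)) & 1  # (2^n, n)
    rows = np.where(bits.astype(bool), x, bg_mean)
    values = f(rows)

    size = bits.sum(axis=1)
    # weight by coalition size: |S|! (n-|S|-1)! / n!
    w = np.array(
        [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    )
    phi = np.zeros(n)
    for i in range(n):
        without = (masks & (1 << i)) == 0
        s_masks = masks[without]
        phi[i] = (
            w[size[s_masks]] * (values[s_masks | (1 << i)] - values[s_masks])
        ).sum()

    names = feature_names or [f"f{j + 1}" for j in range(n)]
    return ShapleyReport(
        feature_names=list(names),
        phi=phi,
        baseline_value=float(values[0]),
        full_value=float(values[-1]),
        method="exact",
    )


def permutation_shapley(
    model,
    x,
    background,
    n_samples: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ShapleyReport:
    """Monte Carlo Shapley: marginal contributions over random feature orders.

    Unbiased for the exact values; per-feature standard errors of the mean
    are reported.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    bg_mean = np.atleast_2d(np.asarray(background, dtype=float)).mean(axis=0)
    if bg_mean.size == 0:
        raise ValueError("background must be non-empty")
    f = _as_model(model)
    rng = np.random.default_rng(seed)

    contribs = np.zeros((n_samples, n))
    for s in range(n_samples):
        order = rng.permutation(n)
        row = bg_mean.copy()
        prev = f(row[None])[0]
        for i in order:
            row[i] = x[i]
            cur = f(row[None])[0]
            contribs[s, i] = cur - prev
            prev = cur
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_samples)

    names = feature_names or [f"f{j + 1}" for j in range(n)]
    return ShapleyReport(
        feature_names=list(names),
        phi=phi,
        baseline_value=float(f(bg_mean[None])[0]),
        full_value=float(f(x[None])[0]),
        method="permutation",
        n_samples=n_samples,
        seed=seed,
        std_errors=se,
    )


def overall_score(report: ShapleyReport, convention: str = "sum") -> float:
    """Aggregate per-feature attributions into one score.

    Default is the plain sum of the listed values; "abs_sum" and
    "normalized" (abs values rescaled to sum to 1, then summed - i.e. 1.0)
    are provided as alternatives.
    """
    phi = np.asarray(report.phi, dtype=float)
    if convention == "sum":
        return float(phi.sum())
    if convention == "abs_sum":
        return float(np.abs(phi).sum())
    if convention == "normalized":
        a = np.abs(phi)
        return float((a / a.sum()).sum()) if a.sum() > 0 else 0.0
    raise ValueError(f"unknown convention: {convention}")
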