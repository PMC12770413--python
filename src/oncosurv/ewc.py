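"""Elastic Weight Consolidation for incremental survival-model updates.

When a new batch of patients arrives, the risk network is updated by
minimising the Cox loss on the new batch plus the quadratic EWC penalty
(lambda/2) * sum_i F_i (theta_i - theta_i*)^2, where theta* is the
parameter snapshot after the previous task and F is the diagonal
empirical Fisher information (mean over mini-batches of squared gradients
of the Cox loss at theta*).  Parameters important to earlier cohorts are
thereby anchored, preventing catastrophic forgetting.

Optimisation uses a proximal step that treats the quadratic penalty
exactly: theta_{k+1} = (theta_k / lr - g_data + lambda F theta*) /
(1/lr + lambda F).  This reduces to plain gradient descent at lambda = 0
and freezes parameters at the anchor as lambda -> infinity, for any
learning rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .survival import (
    SurvivalModelState,
    concordance_index,
    cox_loss_tensor,
    neg_log_partial_likelihood,
)

__all__ = [
    "EWCState",
    "estimate_fisher",
    "ewc_penalty",
    "ewc_loss",
    "incremental_update",
]


@dataclass
class EWCState:
    anchor_params: list[np.ndarray]
    fisher_diag: list[np.ndarray]
    lambda_ewc: float = 100.0
    batch_size_new: int = 50

    def __post_init__(self):
        if self.lambda_ewc < 0:
            raise ValueError("lambda_ewc must be >= 0")
        for a, f in zip(self.anchor_params, self.fisher_diag):
            if a.shape != f.shape:
                raise ValueError("fisher_diag shape does not match anchor_params")
            if (f < 0).any():
                raise ValueError("fisher_diag entries must be >= 0")


def _grads(state: SurvivalModelState, x, times, events) -> list[np.ndarray]:
    """Gradients of the (normalized) Cox loss w.r.t. the net parameters."""
    z = (np.atleast_2d(np.asarray(x, float)) - state.feature_means) / state.feature_sds
    for p in state.net.params:
        p.grad = None
    loss = cox_loss_tensor(state.net.forward(z), times, events, normalize=True)
    loss.backward()
    return [
        p.grad.copy() if p.grad is not None else np.zeros_like(p.value)
        for p in state.net.params
    ]


def estimate_fisher(
    state: SurvivalModelState, x, times, events, batch_size: int = 50
) -> list[np.ndarray]:
    """Diagonal empirical Fisher: mean over mini-batches of squared gradients.

    Batches are taken in data order; batches without any observed event are
    skipped (the partial likelihood is undefined on them).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t = np.asarray(times, dtype=float).ravel()
    d = np.asarray(events, dtype=int).ravel()
    if d.sum() == 0:
        raise ValueError("Fisher estimation requires at least one event")
    sums = [np.zeros_like(p.value) for p in state.net.params]
    n_batches = 0
    for start in range(0, len(t), batch_size):
        sl = slice(start, start + batch_size)
        if d[sl].sum() == 0:
            continue
        g = _grads(state, x[sl], t[sl], d[sl])
        for s, gi in zip(sums, g):
            s += gi**2
        n_batches += 1
    return [s / n_batches for s in sums]


def ewc_penalty(current_params: list[np.ndarray], ewc_state: EWCState) -> float:
    """(lambda/2) * sum_i F_i (theta_i - theta_i*)^2."""
    total = 0.0
    for p, a, f in zip(current_params, ewc_state.anchor_params, ewc_state.fisher_diag):
        p = np.asarray(p, dtype=float)
        if p.shape != a.shape:
            raise ValueError("parameter shapes do not match the anchor")
        total += float((f * (p - a) ** 2).sum())
    return 0.5 * ewc_state.lambda_ewc * total


def ewc_loss(
    state: SurvivalModelState,
    x,
    times,
    events,
    ewc_state: EWCState,
    current_params: list[np.ndarray] | None = None,
) -> float:
    """Cox loss on the new batch plus the EWC penalty at `current_params`.

    When `current_params` is None the network's present parameters are used.
    """
    if current_params is not None:
        saved = state.net.get_params()
        state.net.set_params(current_params)
    try:
        data_loss = neg_log_partial_likelihood(state.risk_scores(x), times, events)
        params = state.net.get_params()
    finally:
        if current_params is not None:
            state.net.set_params(saved)
    return data_loss + ewc_penalty(params, ewc_state)


def incremental_update(
    state: SurvivalModelState,
    ewc_state: EWCState,
    new_x,
    new_times,
    new_events,
    old_task: tuple | None = None,
    epochs: int = 200,
    lr: float = 0.05,
    seed: int = 0,
) -> tuple[SurvivalModelState, dict]:
    """Update the model on a new patient batch under the EWC penalty.

    Returns (updated_state, retention_report); the report holds the
    old-task C-index before/after the update and the new-task C-index.
    The anchor inside `ewc_state` is refreshed to the updated parameters.
    """
    new_x = np.atleast_2d(np.asarray(new_x, dtype=float))
    if len(new_x) == 0:
        raise ValueError("empty update batch")
    new_t = np.asarray(new_times, dtype=float).ravel()
    new_d = np.asarray(new_events, dtype=int).ravel()

    updated = copy.deepcopy(state)
    lam = ewc_state.lambda_ewc

    report: dict = {}
    if old_task is not None:
        ox, ot, od = old_task
        report["old_cindex_before"] = concordance_index(
            state.hazard_ratios(ox), ot, od
        )

    for _ in range(epochs):
        g = _grads(updated, new_x, new_t, new_d)
        for p, gi, a, f in zip(
            updated.net.params, g, ewc_state.anchor_params, ewc_state.fisher_diag
        ):
            # proximal step: exact in the quadratic EWC penalty
            p.value = (p.value / lr - gi + lam * f * a) / (1.0 / lr + lam * f)

    if old_task is not None:
        ox, ot, od = old_task
        report["old_cindex_after"] = concordance_index(
            updated.hazard_ratios(ox), ot, od
        )
    report["new_cindex"] = concordance_index(
        updated.hazard_ratios(new_x), new_t, new_d
    )
    ewc_state.anchor_params = updated.net.get_params()
    return updated, report
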