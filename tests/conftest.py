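"""Shared fixtures: small seeded cohorts and trained model states.

Expensive artifacts (trained segmenter, classifier cohort, survival
tables) are session-scoped so the whole suite trains each model once.
"""

from __future__ import annotations

import numpy as np
import pytest

from oncosurv import fuse, segment, simulate, survival


@pytest.fixture(scope="session")
def seg_cohort():
    """40 patients, 32-px images: the segmenter's training fixture."""
    return simulate.generate_cohort(
        simulate.CohortConfig(n_patients=40, image_size=32, seed=0, noise_sd=0.05)
    )


@pytest.fixture(scope="session")
def trained_segmenter(seg_cohort):
    return segment.train_segmenter(
        seg_cohort, segment.SegmenterConfig(seed=0, epochs=20)
    )


@pytest.fixture(scope="session")
def clf_cohort():
    """300 patients with subtype signal in both modalities."""
    return simulate.generate_cohort(
        simulate.CohortConfig(n_patients=300, image_size=32, seed=0)
    )


@pytest.fixture(scope="session")
def trained_classifier(clf_cohort):
    return fuse.train_classifier(
        clf_cohort,
        fuse.FusionConfig(mode="attention", seed=0),
        fuse.ClassifierTrainConfig(epochs=20, seed=0),
    )


@pytest.fixture(scope="session")
def cox_table_600():
    """n=600 proportional-hazards cohort, beta=(1, -0.8, 0.5), 30% censoring."""
    return simulate.generate_survival_table(
        600, (1.0, -0.8, 0.5), baseline_rate=0.1, censor_fraction=0.3, seed=42
    )


@pytest.fixture(scope="session")
def fitted_linear_cox(cox_table_600):
    df = cox_table_600
    x = df[["x1", "x2", "x3"]].to_numpy()
    state = survival.fit_deepsurv(
        x, df["time"], df["event"], hidden=(), lr=0.05, epochs=500, seed=42
    )
    return state, x, df


def brute_force_cindex(pred, times, events) -> float:
    """O(n^2) reference enumeration of Harrell's concordance index."""
    pred = np.asarray(pred, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[i] < times[j]:
                den += 1
                if pred[i] > pred[j]:
                    num += 1
                elif pred[i] == pred[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
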