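"""Evaluation harness: splits, cross-validation and the full pipeline.

The harness mirrors a standard protocol: a stratified 70/15/15
train/validation/test split, five-fold stratified cross-validation, and
an end-to-end run chaining simulation, segmenter training, subtype
classification, survival modelling and Shapley attribution, emitting a
single metrics report.  One global seed determines every stage seed via
a fixed documented derivation (numpy SeedSequence spawning, one child
per stage in pipeline order).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import explain, fuse, segment, simulate, survival

__all__ = [
    "RunConfig",
    "stratified_split",
    "cross_validate",
    "survival_features",
    "run_pipeline",
]

_STAGES = ("simulate", "segment", "classify", "survival", "explain")


@dataclass
class RunConfig:
    n_patients: int = 300
    image_size: int = 64
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    cv_folds: int = 5
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"
    segmenter: dict = field(default_factory=dict)   # SegmenterConfig overrides
    classifier: dict = field(default_factory=dict)  # FusionConfig/train overrides
    surv: dict = field(default_factory=dict)        # fit_deepsurv overrides
    simulate: dict = field(default_factory=dict)    # CohortConfig overrides

    def validate(self) -> None:
        if len(self.split) != 3 or any(f <= 0 for f in self.split):
            raise ValueError("split must be three positive fractions")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STAGES, children)
        }

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stratified_split(cohort, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Disjoint, exhaustive stratified train/val/test split by subtype."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.array([s.subtype for s in cohort])
    counts = np.bincount(labels, minlength=3)
    if (counts[counts > 0] < 3).any():
        raise ValueError("every present subtype needs at least 3 members")
    idx = np.arange(len(cohort))
    tr, rest = train_test_split(
        idx, test_size=fractions[1] + fractions[2], stratify=labels, random_state=seed
    )
    val, te = train_test_split(
        rest,
        test_size=fractions[2] / (fractions[1] + fractions[2]),
        stratify=labels[rest],
        random_state=seed,
    )
    pick = lambda ii: [cohort[i] for i in sorted(ii)]
    return pick(tr), pick(val), pick(te)


def cross_validate(cohort, k: int, evaluate, seed: int = 0) -> dict:
    """Stratified k-fold CV; `evaluate(train, val) -> {metric: value}`.

    Returns per-fold metrics plus their mean and standard deviation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([s.subtype for s in cohort])
    if k > np.bincount(labels).min():
        raise ValueError("k exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(np.zeros(len(cohort)), labels):
        folds.append(evaluate([cohort[i] for i in tr], [cohort[i] for i in va]))
    keys = folds[0].keys()
    summary = {
        key: {
            "per_fold": [f[key] for f in folds],
            "mean": float(np.mean([f[key] for f in folds])),
            "std": float(np.std([f[key] for f in folds])),
        }
        for key in keys
    }
    return summary


def survival_features(samples, masks=None) -> dict[str, np.ndarray]:
    """Covariate blocks mirroring clinical / imaging / genomic feature sets.

    clinical: age, comorbidity; imaging: tumor area and mean intensity from
    the (predicted or reference) mask; genomic: the full genomic vector.
    """
    msks = (
        [np.asarray(m, float) for m in masks]
        if masks is not None
        else [np.asarray(s.mask, float) for s in samples]
    )
    clinical = np.array(
        [[s.clinical["age"], s.clinical["comorbidity"]] for s in samples]
    )
    imaging = np.array(
        [
            [m.sum(), (np.asarray(s.image) * m).sum() / max(m.sum(), 1.0)]
            for s, m in zip(samples, msks)
        ]
    )
    genomic = np.stack([np.asarray(s.genomic, float) for s in samples])
    return {"clinical": clinical, "imaging": imaging, "genomic": genomic}


def _cindex_by_feature_set(train, test, cfg: RunConfig, seed: int) -> dict[str, float]:
    """Held-out C-index for the nested covariate sets."""
    feats_tr, feats_te = survival_features(train), survival_features(test)
    t_tr = np.array([s.time for s in train])
    d_tr = np.array([s.event for s in train])
    t_te = np.array([s.time for s in test])
    d_te = np.array([s.event for s in test])
    combos = {
        "clinical": ["clinical"],
        "clinical+imaging": ["clinical", "imaging"],
        "clinical+genomic": ["clinical", "genomic"],
        "all": ["clinical", "imaging", "genomic"],
    }
    out = {}
    fit_kw = dict(hidden=(), lr=0.05, epochs=400)
    fit_kw.update(cfg.surv)
    for name, blocks in combos.items():
        x_tr = np.hstack([feats_tr[b] for b in blocks])
        x_te = np.hstack([feats_te[b] for b in blocks])
        state = survival.fit_deepsurv(x_tr, t_tr, d_tr, seed=seed, **fit_kw)
        out[name] = survival.concordance_index(
            state.hazard_ratios(x_te), t_te, d_te
        )
    return out, state, np.hstack([feats_te[b] for b in combos["all"]])


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, train every stage and evaluate on the held-out test split.

    Returns the metrics report (also written to ``out_dir`` when set).
    """
    config.validate()
    seeds = config.stage_seeds()
    t_start = time.time()

    sim_kw = dict(
        n_patients=config.n_patients,
        image_size=config.image_size,
        seed=seeds["simulate"],
    )
    sim_kw.update(config.simulate)
    cohort = simulate.generate_cohort(simulate.CohortConfig(**sim_kw))
    train, val, test = stratified_split(cohort, config.split, seed=config.seed)

    # --- segmentation ---
    seg_cfg = segment.SegmenterConfig(seed=seeds["segment"], **config.segmenter)
    seg_state = segment.train_segmenter(train, seg_cfg)
    seg_outputs = [segment.refine_segment(seg_state, s.image, s.mask) for s in test]
    mean_dice = float(np.mean([o.dice_trace[-1] for o in seg_outputs]))
    pred_masks = [o.final_mask for o in seg_outputs]

    # --- subtype classification (train+val pool; heldout fraction = val) ---
    clf_pool = train + val
    fusion_kw = {
        k: v for k, v in config.classifier.items()
        if k in ("mode", "n_heads", "d_k", "feature_dim")
    }
    train_kw = {
        k: v for k, v in config.classifier.items()
        if k in ("epochs", "lr", "batch_size", "holdout", "mlp_hidden")
    }
    clf_state, clf_metrics = fuse.train_classifier(
        clf_pool,
        fuse.FusionConfig(seed=seeds["classify"], **fusion_kw),
        fuse.ClassifierTrainConfig(seed=seeds["classify"], **train_kw),
    )
    test_probs = clf_state.predict_proba(
        [s.image for s in test], pred_masks, [s.genomic for s in test]
    )
    test_acc = float(
        (test_probs.argmax(axis=1) == np.array([s.subtype for s in test])).mean()
    )

    # --- survival ---
    surv_metrics, surv_state, x_te_all = _cindex_by_feature_set(
        train + val, test, config, seeds["survival"]
    )
    hr = surv_state.hazard_ratios(x_te_all)
    pred_groups = [survival.stratify_risk(h) for h in hr]
    true_hr = np.exp([s.true_risk for s in test])
    true_groups = [survival.stratify_risk(h) for h in true_hr]
    group_names = ["low", "medium", "high"]
    confusion = np.zeros((3, 3), dtype=int)
    for tg, pg in zip(true_groups, pred_groups):
        confusion[group_names.index(tg), group_names.index(pg)] += 1

    # --- attribution for the first test patient (survival risk) ---
    feature_block = survival_features(test)
    x_all = np.hstack([feature_block[b] for b in ("clinical", "imaging", "genomic")])
    shap = explain.exact_shapley(
        lambda rows: surv_state.risk_scores(rows),
        x_all[0],
        x_all,
        feature_names=["age", "comorbidity", "area", "intensity"]
        + [f"g{j + 1}" for j in range(feature_block["genomic"].shape[1])],
    )

    report = {
        "config_hash": config.config_hash(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runtime_s": round(time.time() - t_start, 2),
        "n_train": len(train),
        "n_val": len(val),
        "n_test": len(test),
        "segmentation": {
            "mean_dice": mean_dice,
            "mean_iterations": float(np.mean([o.iterations_run for o in seg_outputs])),
        },
        "classification": {
            "holdout_accuracy": clf_metrics["accuracy"],
            "auc_ovr": {str(k): v for k, v in clf_metrics["auc_ovr"].items()},
            "test_accuracy": test_acc,
        },
        "survival": {
            "cindex": surv_metrics,
            "risk_confusion_vs_truth": confusion.tolist(),
        },
        "explain": {
            "feature_names": shap.feature_names,
            "phi": shap.phi.tolist(),
            "overall_score": shap.overall_score,
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
    return report
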