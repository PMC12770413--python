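"""On-disk cohort layout and model checkpoints.

A cohort directory holds ``images/{patient_id}.png`` (8-bit grayscale),
``masks/{patient_id}.png`` (0/255), ``genomic.csv``, ``clinical.csv``,
``outcomes.csv`` (subtype, time, event) and, for simulated cohorts,
``truth.csv`` with the generating linear predictor.  ``patient_id`` is
the join key everywhere; every patient must appear in every table.
Masks are stored 0/255 and read back as {0, 1}.  Model checkpoints are
NPZ archives of parameter arrays plus a JSON metadata entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .simulate import CohortSample

__all__ = ["write_cohort", "read_cohort", "save_checkpoint", "load_checkpoint"]


def write_cohort(cohort: list[CohortSample], path) -> None:
    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)
    (path / "masks").mkdir(parents=True, exist_ok=True)
    for s in cohort:
        img = np.clip(np.round(np.asarray(s.image) * 255), 0, 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path / "images" / f"{s.patient_id}.png")
        msk = (np.asarray(s.mask) > 0.5).astype(np.uint8) * 255
        Image.fromarray(msk, mode="L").save(path / "masks" / f"{s.patient_id}.png")

    ids = [s.patient_id for s in cohort]
    n_g = len(cohort[0].genomic)
    pd.DataFrame(
        np.stack([s.genomic for s in cohort]),
        columns=[f"g{j + 1}" for j in range(n_g)],
    ).assign(patient_id=ids)[["patient_id"] + [f"g{j + 1}" for j in range(n_g)]].to_csv(
        path / "genomic.csv", index=False
    )
    pd.DataFrame(
        {
            "patient_id": ids,
            "age": [s.clinical["age"] for s in cohort],
            "comorbidity": [s.clinical["comorbidity"] for s in cohort],
        }
    ).to_csv(path / "clinical.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": ids,
            "subtype": [s.subtype for s in cohort],
            "time": [s.time for s in cohort],
            "event": [s.event for s in cohort],
        }
    ).to_csv(path / "outcomes.csv", index=False)
    pd.DataFrame({"patient_id": ids, "true_risk": [s.true_risk for s in cohort]}).to_csv(
        path / "truth.csv", index=False
    )


def _read_table(path: Path, name: str, required: list[str]) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise FileNotFoundError(f"cohort table missing: {f}")
    df = pd.read_csv(f)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: malformed header, missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{name}: duplicate patient_id {dup}")
    return df.set_index("patient_id")


def read_cohort(path) -> list[CohortSample]:
    path = Path(path)
    genomic = _read_table(path, "genomic.csv", ["patient_id"])
    clinical = _read_table(path, "clinical.csv", ["patient_id", "age", "comorbidity"])
    outcomes = _read_table(
        path, "outcomes.csv", ["patient_id", "subtype", "time", "event"]
    )
    truth = None
    if (path / "truth.csv").exists():
        truth = _read_table(path, "truth.csv", ["patient_id", "true_risk"])

    image_ids = sorted(p.stem for p in (path / "images").glob("*.png"))
    for pid in image_ids:
        for name, table in (
            ("genomic.csv", genomic),
            ("clinical.csv", clinical),
            ("outcomes.csv", outcomes),
        ):
            if pid not in table.index:
                raise ValueError(f"patient {pid} missing from {name}")

    cohort = []
    for pid in image_ids:
        image = np.asarray(Image.open(path / "images" / f"{pid}.png"), float) / 255.0
        mask_file = path / "masks" / f"{pid}.png"
        if not mask_file.exists():
            raise ValueError(f"patient {pid} missing from masks/")
        mask = (np.asarray(Image.open(mask_file), float) > 127).astype(np.float64)
        if image.shape != mask.shape:
            raise ValueError(f"patient {pid}: image/mask shape mismatch")
        cohort.append(
            CohortSample(
                patient_id=pid,
                image=image,
                mask=mask,
                genomic=genomic.loc[pid].to_numpy(dtype=float),
                clinical={
                    "age": float(clinical.loc[pid, "age"]),
                    "comorbidity": int(clinical.loc[pid, "comorbidity"]),
                },
                subtype=int(outcomes.loc[pid, "subtype"]),
                time=float(outcomes.loc[pid, "time"]),
                event=int(outcomes.loc[pid, "event"]),
                true_risk=float(truth.loc[pid, "true_risk"]) if truth is not None else 0.0,
            )
        )
    return cohort


def save_checkpoint(path, params: list[np.ndarray], meta: dict) -> None:
    arrays = {f"param_{i}": p for i, p in enumerate(params)}
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[list[np.ndarray], dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        n = sum(1 for k in z.files if k.startswith("param_"))
        params = [z[f"param_{i}"] for i in range(n)]
    return params, meta


# -- model checkpoints ---------------------------------------------------


def save_segmenter(path, state) -> None:
    from dataclasses import asdict

    save_checkpoint(
        path,
        state.net.get_params(),
        {"kind": "segmenter", "config": asdict(state.config)},
    )


def load_segmenter(path):
    from .segment import SegmenterConfig, SegmenterState, UNet

    params, meta = load_checkpoint(path)
    if meta.get("kind") != "segmenter":
        raise ValueError("not a segmenter checkpoint")
    cfg = SegmenterConfig(**meta["config"])
    net = UNet(cfg.base_channels, seed=cfg.seed)
    net.set_params(params)
    return SegmenterState(net=net, config=cfg, trained=True)


def save_survival(path, state) -> None:
    save_checkpoint(
        path,
        state.net.get_params()
        + [state.feature_means, state.feature_sds, state.baseline_times, state.baseline_h0],
        {
            "kind": "survival",
            "sizes": list(state.net.sizes),
            "dropout": state.net.dropout,
            "feature_names": state.feature_names,
        },
    )


def load_survival(path):
    from ._layers import MLP
    from .survival import SurvivalModelState

    params, meta = load_checkpoint(path)
    if meta.get("kind") != "survival":
        raise ValueError("not a survival checkpoint")
    net = MLP(tuple(meta["sizes"]), dropout=meta["dropout"])
    net.set_params(params[:-4])
    means, sds, bt, bh = params[-4:]
    return SurvivalModelState(
        net=net,
        feature_names=list(meta["feature_names"]),
        feature_means=means,
        feature_sds=sds,
        baseline_times=bt,
        baseline_h0=bh,
    )


def save_classifier(path, state) -> None:
    from dataclasses import asdict

    params = (
        state.cnn.get_params()
        + state.mlp.get_params()
        + [state.head_w.value, state.head_b.value]
    )
    n_attn = 0
    if state.attn is not None:
        attn_vals = [p.value for p in state.attn.params]
        params += attn_vals
        n_attn = len(attn_vals)
    save_checkpoint(
        path,
        params,
        {
            "kind": "classifier",
            "fusion": asdict(state.fusion_config),
            "cnn_channels": list(state.cnn.channels),
            "mlp_sizes": list(state.mlp.sizes),
            "n_attn": n_attn,
        },
    )


def load_classifier(path):
    from ._layers import MLP
    from ._nn import Tensor
    from .fuse import ClassifierState, CrossAttentionParams, FusionConfig, ImageCNN

    params, meta = load_checkpoint(path)
    if meta.get("kind") != "classifier":
        raise ValueError("not a classifier checkpoint")
    cfg = FusionConfig(**meta["fusion"])
    cnn = ImageCNN(cfg.feature_dim, tuple(meta["cnn_channels"]), seed=cfg.seed)
    mlp = MLP(
        tuple(meta["mlp_sizes"]),
        hidden_activation="relu",
        output_activation="sigmoid",
    )
    n_cnn, n_mlp = len(cnn.params), len(mlp.params)
    cnn.set_params(params[:n_cnn])
    mlp.set_params(params[n_cnn : n_cnn + n_mlp])
    head_w = Tensor(params[n_cnn + n_mlp], requires_grad=True)
    head_b = Tensor(params[n_cnn + n_mlp + 1], requires_grad=True)
    attn = None
    if meta["n_attn"]:
        attn = CrossAttentionParams(cfg.feature_dim, cfg.n_heads, cfg.d_k, seed=cfg.seed + 2)
        for p, v in zip(attn.params, params[n_cnn + n_mlp + 2 :]):
            p.value = v.copy()
    return ClassifierState(cnn, mlp, head_w, head_b, cfg, attn)
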