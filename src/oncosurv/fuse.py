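"""Multimodal feature extraction, fusion and subtype classification.

Spatial features come from a small CNN applied to the mask-gated image;
biological features come from an MLP over the genomic vector with a
sigmoid output embedding, so both modality embeddings live in (0, 1).
Three fusion modes are supported:

* ``concat`` - [f_img; f_genomic (; f_hist)]
* ``sum`` - element-wise sum (requires equal embedding lengths)
* ``attention`` - cross-modal attention: the image embedding queries the
  other modalities; per-head softmax weights (averaged across heads)
  scale each modality before an additive fusion
  ``sum_m a_m f_m + f_img``.

A softmax head maps the fused vector to probabilities over the three
lung-cancer subtypes (adenocarcinoma-, squamous- and large-cell-like).
The whole stack trains end-to-end by cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._layers import MLP
from ._nn import Adam, Tensor, glorot_init, he_init

__all__ = [
    "FusionConfig",
    "FeatureBundle",
    "ImageCNN",
    "CrossAttentionParams",
    "extract_image_features",
    "extract_genomic_features",
    "cross_attention",
    "fuse_features",
    "classify_subtype",
    "train_classifier",
]


@dataclass
class FusionConfig:
    mode: str = "attention"  # concat | sum | attention
    n_heads: int = 4
    d_k: int = 8
    feature_dim: int = 16
    share_projections: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("concat", "sum", "attention"):
            raise ValueError(f"unknown fusion mode: {self.mode}")
        if self.d_k <= 0:
            raise ValueError("d_k must be > 0")
        if self.mode == "attention" and self.feature_dim % self.n_heads:
            raise ValueError("feature_dim must be divisible by n_heads")


@dataclass
class FeatureBundle:
    f_img: np.ndarray
    f_genomic: np.ndarray
    f_fusion: np.ndarray
    subtype_probs: np.ndarray
    f_hist: np.ndarray | None = None
    attention: dict[str, np.ndarray] | None = None


class ImageCNN:
    """Mask-gated convolutional feature extractor.

    Three 3x3 conv + ReLU blocks with 2x2 pooling, global average pooling,
    then a dense layer with sigmoid output to `feature_dim`.
    """

    def __init__(self, feature_dim: int = 16, channels=(8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.feature_dim = feature_dim
        self.convs = []
        cin = 1
        for cout in channels:
            w = Tensor(he_init(rng, (cout, cin, 3, 3), cin * 9), requires_grad=True)
            b = Tensor(np.zeros(cout), requires_grad=True)
            self.convs.append((w, b))
            cin = cout
        self.dense_w = Tensor(glorot_init(rng, cin, feature_dim), requires_grad=True)
        self.dense_b = Tensor(np.zeros(feature_dim), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        out = []
        for w, b in self.convs:
            out.extend([w, b])
        out.extend([self.dense_w, self.dense_b])
        return out

    def forward(self, x) -> Tensor:
        """x: (B, 1, H, W), already mask-gated -> (B, feature_dim) in (0,1)."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        for i, (w, b) in enumerate(self.convs):
            t = t.conv2d(w, b).relu()
            if i < len(self.convs) - 1:
                t = t.maxpool2()
        t = t.mean(axis=3).mean(axis=2)  # global average pool
        return (t @ self.dense_w + self.dense_b).sigmoid()

    def get_params(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_params(self, values) -> None:
        for p, v in zip(self.params, values):
            p.value = np.asarray(v, dtype=np.float64).copy()


def extract_image_features(image, mask, cnn_state: ImageCNN) -> np.ndarray:
    """Masked image -> fixed-length spatial feature vector."""
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask, dtype=float)
    if img.shape != msk.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {msk.shape}")
    x = (img * msk)[None, None]
    return cnn_state.forward(x).value[0]


def extract_genomic_features(g, mlp_state: MLP) -> np.ndarray:
    """Genomic vector -> biological feature embedding in (0, 1)."""
    g = np.asarray(g, dtype=float).ravel()
    if g.size != mlp_state.sizes[0]:
        raise ValueError(
            f"expected genomic length {mlp_state.sizes[0]}, got {g.size}"
        )
    return mlp_state.forward(g[None]).value[0]


class CrossAttentionParams:
    """Per-head query/key/value projections plus output feed-forward."""

    def __init__(self, dim: int, n_heads: int = 4, d_k: int = 8, seed: int = 0):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        rng = np.random.default_rng(seed)
        self.dim, self.n_heads, self.d_k = dim, n_heads, d_k
        self.d_v = dim // n_heads
        self.wq = Tensor(
            rng.normal(0, dim**-0.5, (n_heads, dim, d_k)), requires_grad=True
        )
        self.wk = Tensor(
            rng.normal(0, dim**-0.5, (n_heads, dim, d_k)), requires_grad=True
        )
        self.wv = Tensor(
            rng.normal(0, dim**-0.5, (n_heads, dim, self.d_v)), requires_grad=True
        )
        self.ff_w = Tensor(glorot_init(rng, dim, dim), requires_grad=True)
        self.ff_b = Tensor(np.zeros(dim), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.wq, self.wk, self.wv, self.ff_w, self.ff_b]


def cross_attention(
    f_query, f_key_value, params: CrossAttentionParams, n_heads: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product cross-attention of one query over m key positions.

    Per head: A = softmax(q K^T / sqrt(d_k)); head outputs A V are
    concatenated, standardized, and passed through a feed-forward
    projection.  Returns (output vector, attention weights (n_heads, m)).
    """
    q_in = np.asarray(f_query, dtype=float).ravel()
    kv = np.atleast_2d(np.asarray(f_key_value, dtype=float))  # (m, dim)
    n_heads = n_heads or params.n_heads
    if q_in.size != params.dim or kv.shape[1] != params.dim:
        raise ValueError("feature dimensions do not match attention params")
    if n_heads != params.n_heads:
        raise ValueError("n_heads does not match params")

    heads, weights = [], []
    for h in range(n_heads):
        q = q_in @ params.wq.value[h]              # (d_k,)
        k = kv @ params.wk.value[h]                # (m, d_k)
        v = kv @ params.wv.value[h]                # (m, d_v)
        scores = (k @ q) / np.sqrt(params.d_k)     # (m,)
        scores -= scores.max()
        a = np.exp(scores)
        a /= a.sum()
        weights.append(a)
        heads.append(a @ v)
    out = np.concatenate(heads)
    out = (out - out.mean()) / (out.std() + 1e-8)  # normalization
    out = np.maximum(out @ params.ff_w.value + params.ff_b.value, 0.0)
    return out, np.stack(weights)


def _modal_attention_weights(
    f_img, others: list[np.ndarray], params: CrossAttentionParams
) -> np.ndarray:
    """Per-modality scalar weights: softmax over modalities, head-averaged."""
    _, w = cross_attention(f_img, np.stack(others), params)
    return w.mean(axis=0)  # (m,)


def fuse_features(
    f_img,
    f_genomic,
    f_hist=None,
    config: FusionConfig | None = None,
    params: CrossAttentionParams | None = None,
    attention_weights=None,
) -> np.ndarray:
    """Fuse modality embeddings according to the configured mode.

    ``attention_weights`` overrides the computed per-modality scalars
    (ordered genomic first, then histology).
    """
    cfg = config or FusionConfig(mode="concat")
    f_img = np.asarray(f_img, dtype=float).ravel()
    f_genomic = np.asarray(f_genomic, dtype=float).ravel()
    mods = [f_genomic] + ([np.asarray(f_hist, float).ravel()] if f_hist is not None else [])

    if cfg.mode == "concat":
        return np.concatenate([f_img] + mods)
    if any(m.size != f_img.size for m in mods):
        raise ValueError("sum/attention fusion requires equal embedding lengths")
    if cfg.mode == "sum":
        return f_img + sum(mods)
    # attention mode
    if attention_weights is None:
        if params is None:
            raise ValueError("attention mode needs params or explicit weights")
        attention_weights = _modal_attention_weights(f_img, mods, params)
    a = np.asarray(attention_weights, dtype=float).ravel()
    return f_img + sum(w * m for w, m in zip(a, mods))


def classify_subtype(f_fusion, head_params) -> np.ndarray:
    """softmax(W f + b) over the three subtypes."""
    w, b = head_params
    w = np.asarray(w, dtype=float)
    f = np.asarray(f_fusion, dtype=float).ravel()
    if f.size != w.shape[0]:
        raise ValueError(f"fused dim {f.size} does not match head {w.shape[0]}")
    z = f @ w + np.asarray(b, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class ClassifierTrainConfig:
    epochs: int = 30
    lr: float = 3e-3
    batch_size: int = 32
    holdout: float = 0.25
    mlp_hidden: tuple[int, ...] = (64, 32)
    seed: int = 0


@dataclass
class ClassifierState:
    cnn: ImageCNN
    mlp: MLP
    head_w: Tensor
    head_b: Tensor
    fusion_config: FusionConfig
    attn: CrossAttentionParams | None = None

    def predict_proba(self, images, masks, genomics) -> np.ndarray:
        out = []
        for img, msk, g in zip(images, masks, genomics):
            fi = extract_image_features(img, msk, self.cnn)
            fg = extract_genomic_features(g, self.mlp)
            fz = fuse_features(fi, fg, config=self.fusion_config, params=self.attn)
            out.append(classify_subtype(fz, (self.head_w.value, self.head_b.value)))
        return np.stack(out)

    def bundle(self, image, mask, genomic) -> FeatureBundle:
        fi = extract_image_features(image, mask, self.cnn)
        fg = extract_genomic_features(genomic, self.mlp)
        attn = None
        if self.fusion_config.mode == "attention" and self.attn is not None:
            _, w = cross_attention(fi, fg[None], self.attn)
            attn = {"img_genomic": w}
        fz = fuse_features(fi, fg, config=self.fusion_config, params=self.attn)
        probs = classify_subtype(fz, (self.head_w.value, self.head_b.value))
        return FeatureBundle(
            f_img=fi, f_genomic=fg, f_fusion=fz, subtype_probs=probs, attention=attn
        )


def _forward_batch(state: ClassifierState, images, genomics) -> Tensor:
    """End-to-end logits for a batch (images already mask-gated)."""
    fi = state.cnn.forward(images)                       # (B, d)
    fg = state.mlp.forward(Tensor(genomics))             # (B, d)
    cfg = state.fusion_config
    if cfg.mode == "concat":
        fz = Tensor.concat([fi, fg], axis=1)
    else:
        # single non-image modality: the modality softmax weight is exactly 1
        fz = fi + fg
    return fz @ state.head_w + state.head_b


def train_classifier(
    cohort,
    fusion_config: FusionConfig | None = None,
    train_config: ClassifierTrainConfig | None = None,
    masks=None,
):
    """End-to-end training of extractors + fusion + softmax head.

    Uses a stratified holdout split; returns (ClassifierState, metrics)
    where metrics holds held-out accuracy, per-class one-vs-rest AUC and
    the confusion matrix.  `masks` overrides the cohort's reference masks
    (e.g. with segmenter output).
    """
    cfg = fusion_config or FusionConfig()
    tc = train_config or ClassifierTrainConfig()
    images = np.stack([np.asarray(s.image, float) for s in cohort])
    msks = (
        np.stack([np.asarray(m, float) for m in masks])
        if masks is not None
        else np.stack([np.asarray(s.mask, float) for s in cohort])
    )
    genomics = np.stack([np.asarray(s.genomic, float) for s in cohort])
    labels = np.array([s.subtype for s in cohort])

    idx_tr, idx_te = train_test_split(
        np.arange(len(cohort)),
        test_size=tc.holdout,
        stratify=labels,
        random_state=tc.seed,
    )
    missing = set(range(3)) - set(labels[idx_tr])
    if missing:
        raise ValueError(f"subtype class(es) {sorted(missing)} absent from training split")

    d = cfg.feature_dim
    cnn = ImageCNN(feature_dim=d, seed=cfg.seed)
    mlp = MLP(
        (genomics.shape[1], *tc.mlp_hidden, d),
        hidden_activation="relu",
        output_activation="sigmoid",
        seed=cfg.seed + 1,
    )
    head_in = 2 * d if cfg.mode == "concat" else d
    rng = np.random.default_rng(tc.seed)
    head_w = Tensor(glorot_init(rng, head_in, 3), requires_grad=True)
    head_b = Tensor(np.zeros(3), requires_grad=True)
    attn = (
        CrossAttentionParams(d, cfg.n_heads, cfg.d_k, seed=cfg.seed + 2)
        if cfg.mode == "attention"
        else None
    )
    state = ClassifierState(cnn, mlp, head_w, head_b, cfg, attn)

    gated = (images * msks)[:, None, :, :]
    params = cnn.params + mlp.params + [head_w, head_b]
    opt = Adam(params, lr=tc.lr)
    onehot = np.eye(3)[labels]
    for _ in range(tc.epochs):
        order = rng.permutation(idx_tr)
        for start in range(0, len(order), tc.batch_size):
            bi = order[start : start + tc.batch_size]
            opt.zero_grad()
            logits = _forward_batch(state, gated[bi], genomics[bi])
            logp = logits - logits.logsumexp(axis=1, keepdims=True)
            loss = -(logp * Tensor(onehot[bi])).sum() * (1.0 / len(bi))
            loss.backward()
            opt.step()

    probs = state.predict_proba(images[idx_te], msks[idx_te], genomics[idx_te])
    pred = probs.argmax(axis=1)
    y_te = labels[idx_te]
    auc = {}
    for c in range(3):
        if len(set(y_te == c)) == 2:
            auc[c] = float(roc_auc_score((y_te == c).astype(int), probs[:, c]))
        else:  # class absent from the held-out split
            auc[c] = float("nan")
    metrics = {
        "accuracy": float((pred == y_te).mean()),
        "auc_ovr": auc,
        "confusion_matrix": _sk_confusion(y_te, pred, labels=[0, 1, 2]),
        "test_indices": idx_te,
    }
    return state, metrics
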