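"""Iteratively refined encoder-decoder tumor segmentation.

A small U-Net-style network (depth-3 encoder/decoder with skip
connections, base 16 channels) is trained with a combined cross-entropy +
Dice loss.  At inference the first iteration is a plain forward pass;
each further iteration feeds the image together with the previous soft
mask back through the network and adds a lambda-scaled correction to the
previous logits.  The loop halts when the relative Dice improvement or
the absolute loss change stays below its threshold for `patience`
consecutive iterations, or at `max_iterations`.

The refinement is a learned recurrent residual: the previous soft mask
enters as a second input channel and the network output is treated as a
logit correction.  Without a reference mask both the Dice trace and the
loss trace fall back to self-consistency between consecutive soft masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Tensor, he_init

__all__ = [
    "SegmenterConfig",
    "SegmentationOutput",
    "UNet",
    "dice_coefficient",
    "combined_loss",
    "train_segmenter",
    "refine_segment",
]


@dataclass
class SegmenterConfig:
    depth: int = 3
    base_channels: int = 16
    lambda_refine: float = 0.5
    alpha_loss: float = 1.0
    max_iterations: int = 6
    dice_improve_tol: float = 0.005   # stop once relative Dice gain < 0.5%
    loss_delta_tol: float = 0.001
    patience: int = 2
    epochs: int = 20
    lr: float = 3e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.dice_improve_tol <= 0:
            raise ValueError("dice_improve_tol must be > 0")
        if self.alpha_loss < 0:
            raise ValueError("alpha_loss must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class SegmentationOutput:
    soft_masks: list[np.ndarray]
    final_mask: np.ndarray
    dice_trace: list[float]
    loss_trace: list[float]
    iterations_run: int
    stop_reason: str  # converged_dice | converged_loss | max_iterations


def dice_coefficient(pred_mask, ref_mask, smooth: float = 1e-6) -> float:
    """(2 sum(p*r) + s) / (sum p + sum r + s); accepts soft or hard masks."""
    p = np.asarray(pred_mask, dtype=float)
    r = np.asarray(ref_mask, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    return float((2.0 * (p * r).sum() + smooth) / (p.sum() + r.sum() + smooth))


def combined_loss(probs, ref_mask, alpha: float = 1.0) -> float:
    """Pixel-mean binary cross-entropy plus alpha * (1 - soft Dice)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = np.clip(np.asarray(probs, dtype=float), 1e-7, 1 - 1e-7)
    r = np.asarray(ref_mask, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    bce = float(-(r * np.log(p) + (1 - r) * np.log(1 - p)).mean())
    return bce + alpha * (1.0 - dice_coefficient(p, r))


class UNet:
    """Depth-3 encoder/decoder with skip connections, 2 input channels."""

    def __init__(self, base_channels: int = 16, seed: int = 0, in_channels: int = 2):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.base_channels = c
        self.in_channels = in_channels

        def conv(cin, cout, k=3):
            w = Tensor(he_init(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
            b = Tensor(np.zeros(cout), requires_grad=True)
            return w, b

        self.enc1 = conv(in_channels, c)
        self.enc2 = conv(c, 2 * c)
        self.bott = conv(2 * c, 4 * c)
        self.dec2 = conv(6 * c, 2 * c)   # upsampled bottleneck + skip
        self.dec1 = conv(3 * c, c)
        self.out = conv(c, 1, k=1)
        self.out[0].value *= 0.1  # start near-uniform logits

    @property
    def params(self) -> list[Tensor]:
        out = []
        for w, b in (self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.out):
            out.extend([w, b])
        return out

    def forward(self, x) -> Tensor:
        """x: (N, 2, H, W) with H, W divisible by 4 -> logits (N, 1, H, W)."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        e1 = t.conv2d(*self.enc1).relu()
        e2 = e1.maxpool2().conv2d(*self.enc2).relu()
        b = e2.maxpool2().conv2d(*self.bott).relu()
        d2 = Tensor.concat([b.upsample2(), e2], axis=1).conv2d(*self.dec2).relu()
        d1 = Tensor.concat([d2.upsample2(), e1], axis=1).conv2d(*self.dec1).relu()
        return d1.conv2d(*self.out)

    def get_params(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_params(self, values) -> None:
        for p, v in zip(self.params, values):
            p.value = np.asarray(v, dtype=np.float64).copy()


@dataclass
class SegmenterState:
    net: UNet
    config: SegmenterConfig
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)


def _loss_tensor(logits: Tensor, ref: np.ndarray, alpha: float) -> Tensor:
    probs = logits.sigmoid()
    eps = 1e-7
    bce = -(
        Tensor(ref) * (probs + eps).log()
        + Tensor(1.0 - ref) * (1.0 - probs + eps).log()
    ).mean()
    inter = (probs * Tensor(ref)).sum()
    dice = (2.0 * inter + 1e-6) / (probs.sum() + ref.sum() + 1e-6)
    return bce + alpha * (1.0 - dice)


def train_segmenter(cohort, config: SegmenterConfig | None = None) -> SegmenterState:
    """Train the segmenter on (image, mask) pairs from cohort samples.

    Each step unrolls the first refinement cycle exactly as it runs at
    inference: a plain pass with a zero mask channel giving logits L1,
    then a refinement pass fed sigmoid(L1) whose output corrects L1 by a
    lambda-scaled residual.  A third, teacher-forced pass feeds the
    reference mask itself, anchoring the refinement fixed point at the
    ground truth so iterating on an already-good mask does not drift.
    The loss averages the combined loss of all three passes.
    """
    config = config or SegmenterConfig()
    images = np.stack([np.asarray(s.image, dtype=float) for s in cohort])
    masks = np.stack([np.asarray(s.mask, dtype=float) for s in cohort])
    if len(images) < 1:
        raise ValueError("empty training cohort")
    if images.shape[1] != images.shape[2]:
        raise ValueError("images must be square")

    rng = np.random.default_rng(config.seed)
    net = UNet(config.base_channels, seed=config.seed)
    opt = Adam(net.params, lr=config.lr)
    n = len(images)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            img = images[idx]
            y = masks[idx][:, None, :, :]
            zeros = np.zeros_like(img)
            opt.zero_grad()
            logits1 = net.forward(np.stack([img, zeros], axis=1))
            prev_soft = 1.0 / (1.0 + np.exp(-logits1.value[:, 0]))  # detached
            repass = net.forward(np.stack([img, prev_soft], axis=1))
            logits2 = logits1 + config.lambda_refine * (repass - logits1)
            teacher = net.forward(np.stack([img, masks[idx]], axis=1))
            loss = (
                _loss_tensor(logits1, y, config.alpha_loss)
                + _loss_tensor(logits2, y, config.alpha_loss)
                + _loss_tensor(teacher, y, config.alpha_loss)
            ) * (1.0 / 3.0)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * len(idx)
        history.append(epoch_loss / n)
    return SegmenterState(net=net, config=config, trained=True, loss_history=history)


def refine_segment(
    state: SegmenterState,
    image: np.ndarray,
    ref_mask: np.ndarray | None = None,
    config: SegmenterConfig | None = None,
) -> SegmentationOutput:
    """Run the iterative refinement loop on one image."""
    if not getattr(state, "trained", False):
        raise ValueError("segmenter state is untrained")
    cfg = config or state.config
    img = np.asarray(image, dtype=float)
    alpha = cfg.alpha_loss

    def fwd(prev_soft: np.ndarray) -> np.ndarray:
        x = np.stack([img, prev_soft])[None]  # (1, 2, H, W)
        return state.net.forward(x).value[0, 0]

    logits = fwd(np.zeros_like(img))
    probs = 1.0 / (1.0 + np.exp(-logits))
    soft_masks = [probs]
    if ref_mask is not None:
        dice_trace = [dice_coefficient(probs > 0.5, ref_mask)]
        loss_trace = [combined_loss(probs, ref_mask, alpha)]
    else:
        dice_trace = [1.0]
        loss_trace = [combined_loss(probs, probs > 0.5, alpha)]

    stop_reason = "max_iterations"
    below = 0
    last_was_dice = True
    it = 1
    while it < cfg.max_iterations:
        repass = fwd(soft_masks[-1])
        logits = logits + cfg.lambda_refine * (repass - logits)
        probs = 1.0 / (1.0 + np.exp(-logits))
        soft_masks.append(probs)
        it += 1
        if ref_mask is not None:
            dice_trace.append(dice_coefficient(probs > 0.5, ref_mask))
            loss_trace.append(combined_loss(probs, ref_mask, alpha))
        else:
            dice_trace.append(
                dice_coefficient(probs > 0.5, soft_masks[-2] > 0.5)
            )
            loss_trace.append(combined_loss(probs, soft_masks[-2] > 0.5, alpha))

        rel_gain = (dice_trace[-1] - dice_trace[-2]) / max(abs(dice_trace[-2]), 1e-12)
        dice_ok = rel_gain < cfg.dice_improve_tol
        loss_ok = abs(loss_trace[-1] - loss_trace[-2]) < cfg.loss_delta_tol
        if dice_ok or loss_ok:
            below += 1
            last_was_dice = dice_ok
        else:
            below = 0
        if below >= cfg.patience:
            stop_reason = "converged_dice" if last_was_dice else "converged_loss"
            break

    return SegmentationOutput(
        soft_masks=soft_masks,
        final_mask=(soft_masks[-1] > 0.5).astype(np.uint8),
        dice_trace=dice_trace,
        loss_trace=loss_trace,
        iterations_run=it,
        stop_reason=stop_reason,
    )
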