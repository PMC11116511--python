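"""2D frontal-sinus segmentation stage (FSNet).

A U-shaped encoder-decoder trained per axial slice with the Dice loss.  Each
convolution block is a 3x3 convolution + batch normalization + ReLU; the
decoder upsamples with 2x2 stride-2 transposed convolutions and the output
layer is a 1x1 convolution with a sigmoid, giving a per-pixel probability of
sinus membership.  Named backbones select channel/depth profiles of the
same plain block design (no pretrained weights are bundled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .core import BinaryMask, Volume

#: backbone name -> (encoder/decoder levels, base channels)
BACKBONES = {
    "tiny": (3, 8),
    "vgg16-like": (5, 16),
    "resnet101-like": (5, 16),
    "inceptionv3-like": (5, 16),
    "efficientnetb5-like": (5, 12),
    "densenet201-like": (5, 16),
}


@dataclass
class SegModelConfig:
    backbone: str = "tiny"
    decoder_levels: int | None = None
    base_channels: int | None = None
    use_pretrained: bool = False
    input_size: tuple[int, int] = (64, 64)
    #: prior foreground probability used to initialize the output bias
    #: (sinus voxels are a rare class; starting near the background prior
    #: avoids an early flood of false positives on sinus-free slices)
    foreground_prior: float = 0.02

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; "
                             f"choose from {sorted(BACKBONES)}")
        levels, base = BACKBONES[self.backbone]
        if self.decoder_levels is None:
            self.decoder_levels = levels
        if self.base_channels is None:
            self.base_channels = base
        if self.decoder_levels < 1:
            raise ValueError("decoder_levels must be >= 1")
        for d in self.input_size:
            if d % (2 ** self.decoder_levels) != 0:
                raise ValueError(
                    f"input size {self.input_size} not divisible by "
                    f"2^{self.decoder_levels}")
        if self.use_pretrained:
            raise ValueError("pretrained encoder weights are not bundled; "
                             "set use_pretrained=False")


@dataclass
class SegTrainConfig:
    epochs: int = 200
    batch_size: int = 16
    initial_lr: float = 1e-3
    lr_floor: float = 1e-6
    plateau_patience: int = 20
    rotation_deg: float = 10.0
    blur_strength: float = 0.1
    max_blur_sigma: float = 2.0
    brightness_frac: float = 0.1
    augment: bool = True
    #: "batch" pools the Dice sums over the whole minibatch (the common
    #: framework idiom, and the only variant that gives sinus-free slices a
    #: usable gradient); "per_slice" averages the printed per-image loss
    dice_aggregation: str = "batch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor > self.initial_lr:
            raise ValueError("lr_floor must be <= initial_lr")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.dice_aggregation not in ("batch", "per_slice"):
            raise ValueError("dice_aggregation must be 'batch' or 'per_slice'")


@dataclass
class SliceBatch:
    """Paired 2D slices and {0,1} masks with (subject, slice index) provenance."""

    images: np.ndarray  # (N, H, W)
    masks: np.ndarray   # (N, H, W) in {0,1}
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.images.shape != self.masks.shape:
            raise ValueError("images and masks must have matching shapes")
        if self.images.ndim != 3:
            raise ValueError("SliceBatch holds stacks of 2D slices")

    def __len__(self) -> int:
        return self.images.shape[0]


def dice_loss(y: np.ndarray, y_hat: np.ndarray, epsilon: float = 1e-3,
              mode: str = "train") -> float:
    """Dice loss 1 - 2(Σyŷ + ε) / ((Σy + Σŷ) + ε).

    The stabilizer ε makes the loss slightly negative at perfect overlap and
    exactly -1 in the empty/empty degenerate case.  With ``mode="metric"``
    the empty/empty case instead returns 0 (vacuously perfect agreement)
    with a warning, avoiding a pathological reward for all-empty slices.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y_hat.min() < 0 or y_hat.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
        raise ValueError("ground truth must be binary")
    s = float((y * y_hat).sum())
    t = float(y.sum() + y_hat.sum())
    if mode == "metric" and t == 0.0:
        warnings.warn("empty ground truth and empty prediction: "
                      "Dice treated as perfect (loss 0)")
        return 0.0
    return 1.0 - 2.0 * (s + epsilon) / (t + epsilon)


def _batched_dice_loss_grad(y: np.ndarray, p: np.ndarray, epsilon: float = 1e-3,
                            aggregation: str = "batch",
                            ) -> tuple[float, np.ndarray]:
    """Dice loss over a (N,1,H,W) batch and its gradient w.r.t. ``p``.

    ``batch``: one Dice over the pooled sums of the whole minibatch.
    ``per_slice``: mean of the per-image losses.
    """
    yf = y.astype(np.float64)
    pf = p.astype(np.float64)
    if aggregation == "batch":
        s = float((yf * pf).sum()) + epsilon
        t = float(yf.sum() + pf.sum()) + epsilon
        loss = 1.0 - 2.0 * s / t
        grad = -2.0 * (yf * t - s) / t ** 2
        return loss, grad.astype(np.float32)
    n = y.shape[0]
    yr = yf.reshape(n, -1)
    pr = pf.reshape(n, -1)
    s = (yr * pr).sum(axis=1) + epsilon
    t = yr.sum(axis=1) + pr.sum(axis=1) + epsilon
    loss = float(np.mean(1.0 - 2.0 * s / t))
    grad = (-2.0 * (yr * t[:, None] - s[:, None]) / (t ** 2)[:, None]) / n
    return loss, grad.reshape(p.shape).astype(np.float32)


class FSNet:
    """U-shaped per-slice segmentation model on the numpy layer core."""

    def __init__(self, config: SegModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2027]))
        L, B = config.decoder_levels, config.base_channels
        ch = [B * 2 ** i for i in range(L + 1)]  # encoder channels per level

        def block(cin, cout):
            return (nn.Conv2d(cin, cout, 3, rng=rng), nn.BatchNorm(cout), nn.ReLU())

        self.enc_blocks = []
        cin = 1
        for i in range(L):
            self.enc_blocks.append(block(cin, ch[i]))
            cin = ch[i]
        self.pools = [nn.MaxPool2d() for _ in range(L)]
        self.bottleneck = block(ch[L - 1], ch[L])
        self.ups = []
        self.dec_blocks = []
        for i in reversed(range(L)):
            self.ups.append(nn.ConvTranspose2d(ch[i + 1], ch[i], rng=rng))
            self.dec_blocks.append(block(2 * ch[i], ch[i]))
        self.out_conv = nn.Conv2d(ch[0], 1, 1, rng=rng)
        p0 = float(np.clip(config.foreground_prior, 1e-4, 0.5))
        self.out_conv.params["b"][...] = np.log(p0 / (1.0 - p0))
        self.out_act = nn.Sigmoid()

    @property
    def n_upsample_stages(self) -> int:
        return len(self.ups)

    def layers(self) -> list[nn.Layer]:
        out = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for up, blk in zip(self.ups, self.dec_blocks):
            out.append(up)
            out.extend(blk)
        out.extend([self.out_conv, self.out_act])
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N,1,H,W) slices to (N,1,H,W) probabilities."""
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        for layer in self.bottleneck:
            h = layer.forward(h, training)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([h, skip], axis=1)
            for layer in blk:
                h = layer.forward(h, training)
        h = self.out_conv.forward(h, training)
        return self.out_act.forward(h, training)

    def backward(self, gy: np.ndarray) -> None:
        g = self.out_act.backward(gy)
        g = self.out_conv.backward(g)
        gskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
            for layer in reversed(blk):
                g = layer.backward(g)
            c = up.params["W"].shape[1]  # upsampled channels before concat
            gskips.append(g[:, c:])
            g = up.backward(np.ascontiguousarray(g[:, :c]))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # gskips[0] belongs to encoder level 0; the encoder is walked
        # deep-to-shallow here, so take them from the end
        for blk, pool, gskip in zip(reversed(self.enc_blocks),
                                    reversed(self.pools), reversed(gskips)):
            g = pool.backward(g) + gskip
            for layer in reversed(blk):
                g = layer.backward(g)

    def state_dict(self) -> dict:
        return {f"L{i}.{k}": v for i, l in enumerate(self.layers())
                for k, v in l.state_dict().items()}

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            sub = {k.split(".", 1)[1]: v for k, v in state.items()
                   if k.startswith(f"L{i}.")}
            layer.load_state_dict(sub)


def build_fsnet(config: SegModelConfig, seed: int = 0) -> FSNet:
    return FSNet(config, seed=seed)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator, cfg: SegTrainConfig
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Jointly rotate image+mask; blur and rescale the image only."""
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    img = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
    msk = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant")
    sigma = rng.uniform(0.0, cfg.blur_strength * cfg.max_blur_sigma)
    if sigma > 1e-3:
        img = ndimage.gaussian_filter(img, sigma)
    img = img * rng.uniform(1.0 - cfg.brightness_frac, 1.0 + cfg.brightness_frac)
    return img.astype(np.float32), msk.astype(np.float32)


def _eval_loss(model: FSNet, batch: SliceBatch, aggregation: str = "batch",
               chunk: int = 64) -> float:
    losses = []
    for i in range(0, len(batch), chunk):
        x = batch.images[i:i + chunk, None].astype(np.float32)
        y = batch.masks[i:i + chunk, None].astype(np.float32)
        p = model.forward(x, training=False)
        loss, _ = _batched_dice_loss_grad(y, p, aggregation=aggregation)
        losses.append((loss, x.shape[0]))
    return float(sum(l * n for l, n in losses) / sum(n for _, n in losses))


def train_fsnet(model: FSNet, train: SliceBatch, val: SliceBatch,
                config: SegTrainConfig) -> tuple[FSNet, dict]:
    """Adam + Dice-loss training with plateau-halving learning rate.

    Returns the model and a history dict with per-epoch train/val loss and
    the learning rate in effect.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    opt = nn.Adam(model.layers(), lr=config.initial_lr)
    sched = nn.ReduceLROnPlateau(opt, config.plateau_patience, config.lr_floor)
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        lr_in_effect = opt.lr
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, msks = [], []
            for j in idx:
                im, mk = train.images[j], train.masks[j]
                if config.augment:
                    im, mk = augment_pair(im, mk, rng, config)
                imgs.append(im)
                msks.append(mk)
            x = np.stack(imgs)[:, None].astype(np.float32)
            y = np.stack(msks)[:, None].astype(np.float32)
            p = model.forward(x, training=True)
            loss, grad = _batched_dice_loss_grad(
                y, p, aggregation=config.dice_aggregation)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {start}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        val_loss = _eval_loss(model, val, config.dice_aggregation)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr_in_effect)
        sched.step(val_loss)
    return model, history


def predict_slices(model: FSNet, volume: Volume, threshold: float = 0.5,
                   chunk: int = 64, resample: bool = False
                   ) -> tuple[np.ndarray, BinaryMask]:
    """Segment every axial slice; returns probabilities and the >=0.5 mask."""
    h, w = volume.data.shape[1:]
    if (h, w) != tuple(model.config.input_size):
        if not resample:
            raise ValueError(
                f"slice size {(h, w)} != model input {model.config.input_size} "
                "and resampling is not enabled")
        from skimage.transform import resize
        probs_small = []
        for i in range(0, volume.data.shape[0], chunk):
            sl = np.stack([
                resize(s, model.config.input_size, order=1, anti_aliasing=False)
                for s in volume.data[i:i + chunk]])
            probs_small.append(model.forward(sl[:, None].astype(np.float32))[:, 0])
        ps = np.concatenate(probs_small)
        probs = np.stack([resize(p, (h, w), order=1, anti_aliasing=False)
                          for p in ps]).astype(np.float32)
    else:
        out = []
        for i in range(0, volume.data.shape[0], chunk):
            x = volume.data[i:i + chunk, None].astype(np.float32)
            out.append(model.forward(x, training=False)[:, 0])
        probs = np.concatenate(out)
    mask = BinaryMask((probs >= threshold).astype(np.uint8), volume.spacing)
    return probs, mask
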