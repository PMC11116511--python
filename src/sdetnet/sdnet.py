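"""3D sex classifier (SDNet) with anatomy-guided attention (AGAM).

Per level: ConvBlock (3x3x3 conv + BN + ReLU) -> optional AGAM -> 2x max
pooling; a global average pool and a sigmoid output head give P(male).
The attention module receives the ROI's sinus mask, resampled by trilinear
interpolation onto the level's feature grid, and gates the level's features:

    A = Conv1(S),  B = Conv1(F)
    F_dis = psi(ReLU(A + B))          # psi: 1x1x1 conv to one channel
    F_att = GR(sigmoid(F_dis))        # GR: grid resampling to F's grid
    F_n   = F_att * F                 # elementwise, broadcast over channels

Because sigmoid output lies in (0,1), gating only ever attenuates features,
steering the classifier toward the sinus and away from background anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .core import ROISample


@dataclass
class SDNetConfig:
    channels: tuple[int, ...] = (16, 32, 64, 128)
    use_agam: bool = True
    input_channels: int = 2
    attention_bias: bool = True

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("need at least one level")
        if any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must be strictly increasing")
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")

    @property
    def levels(self) -> int:
        return len(self.channels)


@dataclass
class SDTrainConfig:
    epochs: int = 100
    batch_size: int = 1
    initial_lr: float = 1e-4
    lr_floor: float = 1e-7
    plateau_patience: int = 25
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor > self.initial_lr:
            raise ValueError("lr_floor must be <= initial_lr")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


def bce_loss(p: np.ndarray, p_hat: np.ndarray, clip: float = 1e-7) -> float:
    """Mean binary cross-entropy with probability clipping at ``clip``."""
    p = np.asarray(p, dtype=np.float64).ravel()
    p_hat = np.asarray(p_hat, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != p_hat.shape:
        raise ValueError("label/probability length mismatch")
    if not np.all(np.isin(np.unique(p), (0.0, 1.0))):
        raise ValueError("labels must be binary")
    q = np.clip(p_hat, clip, 1.0 - clip)
    return float(-np.mean(p * np.log(q) + (1.0 - p) * np.log(1.0 - q)))


def resample_trilinear(vol: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Resample a 3D array onto a new grid by trilinear interpolation.

    Endpoint-aligned: source and target corner voxels coincide.  When the
    grids already match the input is returned unchanged (exact identity).
    """
    if tuple(vol.shape) == tuple(shape):
        return vol
    coords = np.meshgrid(*[
        np.linspace(0.0, s - 1.0, t) for s, t in zip(vol.shape, shape)
    ], indexing="ij")
    return ndimage.map_coordinates(vol.astype(np.float64), coords, order=1
                                   ).astype(np.float32)


class AGAM:
    """Anatomy-guided attention for one level (explicit forward/backward)."""

    def __init__(self, channels: int, *, rng: np.random.Generator,
                 bias: bool = True) -> None:
        self.conv_s = nn.PointwiseConv3d(1, channels, rng=rng, bias=bias)
        self.conv_f = nn.PointwiseConv3d(channels, channels, rng=rng, bias=bias)
        self.psi = nn.PointwiseConv3d(channels, 1, rng=rng, bias=bias)
        self.relu = nn.ReLU()
        self.sig = nn.Sigmoid()

    def layers(self) -> list[nn.Layer]:
        return [self.conv_s, self.conv_f, self.psi, self.relu, self.sig]

    def forward(self, f_m: np.ndarray, s_m: np.ndarray,
                training: bool = False) -> np.ndarray:
        """Gate features ``f_m`` (N,C,D,H,W) by the mask map ``s_m`` (N,1,D,H,W)."""
        if f_m.shape[1] != self.conv_f.params["W"].shape[1]:
            raise ValueError(
                f"feature channels {f_m.shape[1]} do not match the module's "
                f"{self.conv_f.params['W'].shape[1]}")
        s_r = np.stack([
            resample_trilinear(s_m[i, 0], f_m.shape[2:]) for i in range(s_m.shape[0])
        ])[:, None]
        a = self.conv_s.forward(s_r.astype(np.float32), training)
        b = self.conv_f.forward(f_m, training)
        h = self.relu.forward(a + b, training)
        f_dis = self.psi.forward(h, training)
        f_att = self.sig.forward(f_dis, training)
        # F_dis already lives on f_m's grid (the mask was resampled before
        # Conv1), so grid resampling of F_att is the identity here
        self._f_m, self._f_att = f_m, f_att
        return f_att * f_m

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g_att = (gy * self._f_m).sum(axis=1, keepdims=True)
        g_fm = gy * self._f_att
        g = self.sig.backward(g_att)
        g = self.psi.backward(g)
        g = self.relu.backward(g)
        self.conv_s.backward(g)  # gradient w.r.t. the mask is discarded
        g_fm = g_fm + self.conv_f.backward(g)
        self._f_m = self._f_att = None
        return g_fm.astype(np.float32, copy=False)


def agam_forward(f_m: np.ndarray, s_m: np.ndarray, module: AGAM) -> np.ndarray:
    """Functional wrapper: gate level features by the ROI mask map."""
    return module.forward(f_m, s_m, training=False)


class SDNet:
    """Mask-aware 3D CNN mapping an ROI input to P(male)."""

    def __init__(self, config: SDNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4099]))
        self.blocks = []
        cin = config.input_channels
        for ch in config.channels:
            self.blocks.append((nn.Conv3d(cin, ch, 3, rng=rng),
                                nn.BatchNorm(ch), nn.ReLU()))
            cin = ch
        self.agams = ([AGAM(ch, rng=rng, bias=config.attention_bias)
                       for ch in config.channels] if config.use_agam else None)
        self.pools = [nn.MaxPool3d() for _ in config.channels]
        self.gap = nn.GlobalAvgPool3d()
        self.head = nn.Dense(config.channels[-1], 1, rng=rng)
        self.out = nn.Sigmoid()

    def layers(self) -> list[nn.Layer]:
        out = []
        for blk in self.blocks:
            out.extend(blk)
        if self.agams is not None:
            for ag in self.agams:
                out.extend(ag.layers())
        out.extend(self.pools)
        out.extend([self.gap, self.head, self.out])
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def forward(self, x: np.ndarray, s_m: np.ndarray | None = None,
                training: bool = False) -> np.ndarray:
        """Classify (N,C,D,H,W) inputs; ``s_m`` is the (N,1,D,H,W) ROI mask.

        The mask map is required when the attention modules are enabled.
        """
        if x.shape[1] != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels} input "
                             f"channels, got {x.shape[1]}")
        if min(x.shape[2:]) < 2 ** self.config.levels:
            raise ValueError("input spatially too small for the configured depth")
        if self.agams is not None and s_m is None:
            raise ValueError("AGAM is enabled but no mask map was supplied")
        h = x
        for i, (blk, pool) in enumerate(zip(self.blocks, self.pools)):
            for layer in blk:
                h = layer.forward(h, training)
            if self.agams is not None:
                h = self.agams[i].forward(h, s_m, training)
            h = pool.forward(h, training)
        h = self.gap.forward(h, training)
        h = self.head.forward(h, training)
        return self.out.forward(h, training)[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        g = self.out.backward(gy[:, None])
        g = self.head.backward(g)
        g = self.gap.backward(g)
        for i in reversed(range(len(self.blocks))):
            g = self.pools[i].backward(g)
            if self.agams is not None:
                g = self.agams[i].backward(g)
            for layer in reversed(self.blocks[i]):
                g = layer.backward(g)

    def state_dict(self) -> dict:
        return {f"L{i}.{k}": v for i, l in enumerate(self.layers())
                for k, v in l.state_dict().items()}

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers()):
            sub = {k.split(".", 1)[1]: v for k, v in state.items()
                   if k.startswith(f"L{i}.")}
            layer.load_state_dict(sub)


def build_sdnet(config: SDNetConfig, seed: int = 0) -> SDNet:
    return SDNet(config, seed=seed)


def _mci_and_mask(roi: ROISample, channels: tuple[str, ...]
                  ) -> tuple[np.ndarray, np.ndarray]:
    from .roi import assemble_mci
    x = assemble_mci(roi, channels)
    s = roi.mask_channel[None].astype(np.float32)
    return x, s


def train_sdnet(model: SDNet, train: list[ROISample], val: list[ROISample],
                config: SDTrainConfig,
                channels: tuple[str, ...] = ("image", "mask"),
                ) -> tuple[SDNet, dict]:
    """BCE training of the classifier on labeled ROI samples."""
    if not train or not val:
        raise ValueError("train and validation sets must be nonempty")
    if any(r.label is None for r in train + val):
        raise ValueError("all ROI samples must carry a sex label")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    opt = nn.Adam(model.layers(), lr=config.initial_lr,
                  beta1=config.beta1, beta2=config.beta2)
    sched = nn.ReduceLROnPlateau(opt, config.plateau_patience, config.lr_floor)
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "lr": []}
    clip = 1e-7

    data = [(_mci_and_mask(r, channels), float(r.label)) for r in train]
    vdata = [(_mci_and_mask(r, channels), float(r.label)) for r in val]

    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        losses = []
        lr_in_effect = opt.lr
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = np.stack([data[j][0][0] for j in idx])
            s = np.stack([data[j][0][1] for j in idx])
            y = np.array([data[j][1] for j in idx], dtype=np.float64)
            p = model.forward(x, s, training=True).astype(np.float64)
            loss = bce_loss(y, p, clip)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            q = np.clip(p, clip, 1 - clip)
            grad = ((q - y) / (q * (1 - q)) / len(idx)).astype(np.float32)
            grad[(p <= clip) | (p >= 1 - clip)] = 0.0  # clipped region is flat
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        vp = predict_batch(model, [d[0] for d in vdata])
        vy = np.array([d[1] for d in vdata])
        val_loss = bce_loss(vy, vp, clip)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr_in_effect)
        sched.step(val_loss)
    return model, history


def predict_batch(model: SDNet, items: list[tuple[np.ndarray, np.ndarray]]
                  ) -> np.ndarray:
    return np.array([
        float(model.forward(x[None], s[None], training=False)[0])
        for x, s in items
    ])


def predict_sex(model: SDNet, roi: ROISample,
                channels: tuple[str, ...] = ("image", "mask")) -> float:
    """P(male) for one ROI; the hard label is probability >= 0.5 -> male."""
    x, s = _mci_and_mask(roi, channels)
    return float(model.forward(x[None], s[None], training=False)[0])
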