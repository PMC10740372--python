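"""3D encoder-decoder segmentation: compound Dice + cross-entropy loss,
a configurable U-Net, and a training loop with plateau-driven learning-rate
decay and windowed convergence stopping.

Loss conventions (K classes over N voxels, u predicted probabilities,
v one-hot ground truth):

    L_ce   = -1/N sum_i sum_k v_ik log u_ik
    L_dice = -2/K sum_k (sum_i u_ik v_ik) / (sum_i u_ik + sum_i v_ik)
    L_total = L_dice + L_ce

The soft Dice term runs over *all* classes including background and lies in
[-1, 0]; absent classes are stabilized by additive smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import ImageVolume, LabelMask

__all__ = [
    "SegNetConfig",
    "TrainSchedule",
    "PlateauScheduler",
    "TrainResult",
    "ce_loss",
    "dice_loss",
    "total_loss",
    "one_hot",
    "build_segnet",
    "UNet3D",
    "train_segmenter",
]

CE_EPS = 1e-7
DICE_EPS = 1e-5


def _canon(u, v, class_axis: int):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs v {v.shape}")
    u = np.moveaxis(u, class_axis, 0).reshape(u.shape[class_axis], -1)
    v = np.moveaxis(v, class_axis, 0).reshape(v.shape[class_axis], -1)
    return u, v


def ce_loss(u, v, class_axis: int = 0) -> float:
    """Mean voxelwise cross-entropy; probabilities clipped at 1e-7."""
    u, v = _canon(u, v, class_axis)
    n = u.shape[1]
    return float(-(v * np.log(np.clip(u, CE_EPS, 1.0))).sum() / n)


def dice_loss(u, v, class_axis: int = 0) -> float:
    """Soft Dice over all K classes, in [-1, 0]."""
    u, v = _canon(u, v, class_axis)
    k = u.shape[0]
    num = (u * v).sum(axis=1) + DICE_EPS
    den = u.sum(axis=1) + v.sum(axis=1) + DICE_EPS
    return float(-(2.0 / k) * (num / den).sum())


def total_loss(u, v, class_axis: int = 0) -> float:
    return dice_loss(u, v, class_axis) + ce_loss(u, v, class_axis)


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """(...,) integer labels -> (K, ...) one-hot indicators."""
    return np.stack([(mask == k).astype(float) for k in range(num_classes)], axis=0)


def _loss_tensors(probs: nn.Tensor, v: np.ndarray) -> nn.Tensor:
    """L_total = L_dice + L_ce on an autodiff probability tensor (K, ...)."""
    k = v.shape[0]
    n = v[0].size
    vt = nn.Tensor(v)
    ce = (vt * probs.clamp_min(CE_EPS).log()).sum() * (-1.0 / n)
    axes = tuple(range(1, probs.data.ndim))
    num = (probs * vt).sum(axis=axes) + DICE_EPS
    den = probs.sum(axis=axes) + vt.sum(axis=axes) + DICE_EPS
    dice = (num / den).sum() * (-2.0 / k)
    return ce + dice


@dataclass
class SegNetConfig:
    depth: int = 3
    base_channels: int = 8
    patch_size: int = 16
    num_classes: int = 2
    max_channels: int = 64

    def __post_init__(self) -> None:
        if self.patch_size % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )


@dataclass
class TrainSchedule:
    lr0: float = 3e-4
    max_epochs: int = 1000
    decay_factor: float = 5.0
    plateau_window: int = 30
    plateau_eps: float = 5e-3
    converge_window: int = 60
    converge_eps: float = 5e-3
    lr_floor: float = 1e-6


class PlateauScheduler:
    """Plateau-decay / windowed-convergence schedule.

    After each epoch's mean loss is recorded: if the mean loss of the last
    ``plateau_window`` epochs improved on the mean of the preceding window
    by less than ``plateau_eps``, the learning rate is divided by
    ``decay_factor`` and the plateau rule is re-armed (it needs two fresh
    windows after a decay). Training stops once the improvement over
    ``converge_window``-epoch windows falls below ``converge_eps``, or the
    learning rate drops below ``lr_floor``, or ``max_epochs`` is reached.
    """

    def __init__(self, schedule: TrainSchedule):
        self.schedule = schedule
        self.lr = schedule.lr0
        self.losses: list[float] = []
        self._epochs_since_decay = 0

    @staticmethod
    def _window_drop(losses: list[float], w: int) -> float | None:
        if len(losses) < 2 * w:
            return None
        last = float(np.mean(losses[-w:]))
        prev = float(np.mean(losses[-2 * w : -w]))
        return prev - last

    def update(self, epoch_loss: float) -> None:
        """Record one epoch's mean loss and apply the decay rule."""
        s = self.schedule
        self.losses.append(float(epoch_loss))
        self._epochs_since_decay += 1
        if self._epochs_since_decay >= 2 * s.plateau_window:
            drop = self._window_drop(self.losses, s.plateau_window)
            if drop is not None and drop < s.plateau_eps:
                self.lr /= s.decay_factor
                self._epochs_since_decay = 0

    def should_stop(self) -> str | None:
        """Return the stop reason, or None to continue."""
        s = self.schedule
        if self.lr < s.lr_floor:
            return "lr_below_floor"
        drop = self._window_drop(self.losses, s.converge_window)
        if drop is not None and drop < s.converge_eps:
            return "converged"
        if len(self.losses) >= s.max_epochs:
            return "max_epochs"
        return None


class _ConvBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = nn.Conv3d(c_in, c_out, 3, rng)
        self.norm = nn.InstanceNorm3d(c_out)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.norm(self.conv(x)).leaky_relu()


class UNet3D(nn.Module):
    """Encoder-decoder with skip connections, instance norm, leaky ReLU,
    2x average-pool downsampling and nearest-neighbor upsampling; per-voxel
    K-class softmax head."""

    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [min(config.base_channels * 2**lv, config.max_channels) for lv in range(config.depth)]
        self.enc = []
        c_prev = 1
        for c in ch:
            self.enc.append([_ConvBlock(c_prev, c, rng), _ConvBlock(c, c, rng)])
            c_prev = c
        self.dec = []
        for lv in range(config.depth - 2, -1, -1):
            c_skip, c_up = ch[lv], ch[lv + 1]
            self.dec.append([_ConvBlock(c_up + c_skip, c_skip, rng), _ConvBlock(c_skip, c_skip, rng)])
        self.head = nn.Conv3d(ch[0], config.num_classes, 1, rng)

    def parameters(self):
        params = []
        for blocks in self.enc + self.dec:
            for b in blocks:
                params.extend(b.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(self, patch: np.ndarray | nn.Tensor) -> nn.Tensor:
        """(D, H, W) or (1, D, H, W) input -> (K, D, H, W) softmax tensor."""
        if not isinstance(patch, nn.Tensor):
            patch = np.asarray(patch, dtype=float)
            if patch.ndim == 3:
                patch = patch[None]
            patch = nn.Tensor(patch)
        x = patch
        skips = []
        for lv, blocks in enumerate(self.enc):
            for b in blocks:
                x = b(x)
            if lv < len(self.enc) - 1:
                skips.append(x)
                x = nn.avg_pool2(x)
        for blocks, skip in zip(self.dec, reversed(skips)):
            x = nn.concat([nn.upsample_nearest2(x), skip], axis=0)
            for b in blocks:
                x = b(x)
        return self.head(x).softmax(axis=0)

    def predict_proba(self, patch: np.ndarray) -> np.ndarray:
        return self.forward(patch).data


def build_segnet(config: SegNetConfig, seed: int = 0) -> UNet3D:
    return UNet3D(config, seed=seed)


def save_segnet(model: UNet3D, path) -> None:
    """Persist config and weights as a .npz archive."""
    cfg = model.config
    np.savez(
        path,
        _config=np.array(
            [cfg.depth, cfg.base_channels, cfg.patch_size, cfg.num_classes, cfg.max_channels]
        ),
        **{f"p{i}": p.data for i, p in enumerate(model.parameters())},
    )


def load_segnet(path) -> UNet3D:
    with np.load(path) as z:
        d, b, ps, k, mc = (int(x) for x in z["_config"])
        model = UNet3D(SegNetConfig(depth=d, base_channels=b, patch_size=ps, num_classes=k, max_channels=mc))
        model.load_state_dict([z[f"p{i}"] for i in range(len(model.parameters()))])
    return model


@dataclass
class TrainResult:
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    stop_reason: str = ""


def _sample_patch(
    rng: np.random.Generator, img: np.ndarray, lab: np.ndarray, ps: int, fg_prob: float
):
    shape = img.shape
    if any(s < ps for s in shape):
        raise ValueError(f"volume {shape} smaller than patch size {ps}")
    fg = np.argwhere(lab > 0)
    if len(fg) > 0 and rng.random() < fg_prob:
        c = fg[rng.integers(len(fg))]
        org = [int(np.clip(ci - ps // 2, 0, s - ps)) for ci, s in zip(c, shape)]
    else:
        org = [int(rng.integers(0, s - ps + 1)) for s in shape]
    sl = tuple(slice(o, o + ps) for o in org)
    return img[sl], lab[sl]


def train_segmenter(
    model: UNet3D,
    dataset,
    schedule: TrainSchedule,
    seed: int = 0,
    steps_per_epoch: int | None = None,
    fg_oversample: float = 0.5,
    batch_size: int = 2,
) -> TrainResult:
    """Train on random patches with foreground oversampling.

    ``dataset`` is a nonempty sequence of (ImageVolume, LabelMask) pairs,
    already preprocessed (resampled / z-scored). Gradients are averaged
    over ``batch_size`` patches per optimizer step. Per-epoch mean L_total
    is recorded; the learning rate follows :class:`PlateauScheduler`.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    arrays = [
        (
            (p[0].data if isinstance(p[0], ImageVolume) else np.asarray(p[0])).astype(float),
            (p[1].data if isinstance(p[1], LabelMask) else np.asarray(p[1])).astype(np.int64),
        )
        for p in dataset
    ]
    rng = np.random.default_rng(seed)
    sched = PlateauScheduler(schedule)
    result = TrainResult()
    if sched.should_stop() == "lr_below_floor":
        result.stop_reason = "lr_below_floor"
        return result
    opt = nn.Adam(model.parameters(), lr=sched.lr)
    ps = model.config.patch_size
    k = model.config.num_classes
    n_steps = steps_per_epoch or len(arrays)
    while True:
        opt.lr = sched.lr
        epoch_losses = []
        order = rng.permutation(len(arrays))
        for step in range(n_steps):
            opt.zero_grad()
            batch_loss = 0.0
            for bi in range(batch_size):
                img, lab = arrays[order[(step * batch_size + bi) % len(arrays)]]
                patch, labp = _sample_patch(rng, img, lab, ps, fg_oversample)
                probs = model.forward(patch)
                loss = _loss_tensors(probs, one_hot(labp, k)) * (1.0 / batch_size)
                loss.backward()
                batch_loss += float(loss.data)
            opt.step()
            epoch_losses.append(batch_loss)
        sched.update(float(np.mean(epoch_losses)))
        result.losses.append(float(np.mean(epoch_losses)))
        result.lrs.append(opt.lr)
        reason = sched.should_stop()
        if reason:
            result.stop_reason = reason
            return result
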