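"""Multi-modal pCR prediction: a staged 3D convolutional image branch
multiplicatively gated, stage by stage, by a fully-connected branch over
the molecular markers (HER2, ER, PR, Ki-67).

After image stage s produces feature maps with C_s channels, the s-th FC
layer emits a length-C_s vector g; channel c of the feature maps is scaled
by g_c (broadcast over space). Forcing all gates to one recovers the
ungated image-only network; forcing the first gate to zero makes the
output independent of image content. The head is global average pooling
followed by a 2-class softmax, trained with cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .io import ImageVolume, LabelMask, PatientRecord
from .preprocess import zscore_normalize

__all__ = [
    "MarkerVector",
    "FusionNetConfig",
    "PredictionResult",
    "encode_markers",
    "dilate_lesion",
    "crop_resample_lesion",
    "build_fusion_net",
    "FusionNet",
    "train_fusion",
    "predict_pcr",
]

MARKER_ORDER = ("her2", "er", "pr", "ki67")


class EncodingError(ValueError):
    """A marker field is missing or malformed."""


@dataclass
class MarkerVector:
    values: np.ndarray  # (her2, er, pr, ki67)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError("marker vector must have exactly 4 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker values must be finite")


def encode_markers(record: PatientRecord | dict) -> MarkerVector:
    """(her2, er, pr, ki67): binary statuses as 0/1, Ki-67 as a fraction."""
    get = record.get if isinstance(record, dict) else lambda k, d=None: getattr(record, k, d)
    vals = []
    for name in MARKER_ORDER:
        v = get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise EncodingError(f"marker {name!r} is missing")
        vals.append(float(v))
    return MarkerVector(values=np.array(vals))


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(r, r, r, indexing="ij")
    return x**2 + y**2 + z**2 <= radius**2


def dilate_lesion(mask: LabelMask, radius_vox: int) -> LabelMask:
    """Morphological dilation with a spherical structuring element."""
    if radius_vox < 0:
        raise ValueError(f"dilation radius must be >= 0, got {radius_vox}")
    if radius_vox == 0:
        return mask.with_data(mask.data.copy())
    out = ndimage.binary_dilation(mask.data > 0, structure=_ball(radius_vox))
    return mask.with_data(out.astype(mask.data.dtype))


def crop_resample_lesion(vol: ImageVolume, lesion_mask: LabelMask, cube: int = 32) -> ImageVolume:
    """Bounding-box crop of the lesion, trilinearly resampled to cube^3 and
    z-scored."""
    fg = np.argwhere(lesion_mask.data > 0)
    if len(fg) == 0:
        raise ValueError("cannot crop an empty lesion mask")
    lo, hi = fg.min(axis=0), fg.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    crop = vol.data[sl].astype(float)
    zoom = [cube / s for s in crop.shape]
    data = ndimage.zoom(crop, zoom, order=1, mode="nearest", grid_mode=True)
    data = data[:cube, :cube, :cube]
    out = ImageVolume(data=data, spacing=vol.spacing)
    return zscore_normalize(out)


@dataclass
class FusionNetConfig:
    num_stages: int = 5
    image_channels: tuple[int, ...] = (8, 16, 32, 32, 32)
    fc_widths: tuple[int, ...] | None = None  # defaults to image_channels
    input_cube: int = 32
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.image_channels) != self.num_stages:
            raise ValueError("image_channels must list one width per stage")
        if self.fc_widths is None:
            self.fc_widths = tuple(self.image_channels)
        if tuple(self.fc_widths) != tuple(self.image_channels):
            raise ValueError(
                "fc_widths must equal image_channels stage-for-stage "
                "(multiplicative gating requires matching dimensions)"
            )
        if self.input_cube % 2 ** (self.num_stages - 1) != 0:
            raise ValueError(
                f"input_cube {self.input_cube} must be divisible by "
                f"2^{self.num_stages - 1}"
            )


@dataclass
class PredictionResult:
    patient_id: str
    p_pcr: float
    predicted_label: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_pcr <= 1.0:
            raise ValueError("p_pcr must lie in [0, 1]")


class _ResStage(nn.Module):
    """Residual conv stage followed by 2x downsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = nn.Conv3d(c_in, c_out, 3, rng)
        self.norm1 = nn.InstanceNorm3d(c_out)
        self.conv2 = nn.Conv3d(c_out, c_out, 3, rng)
        self.norm2 = nn.InstanceNorm3d(c_out)
        self.proj = nn.Conv3d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        y = self.norm1(self.conv1(x)).leaky_relu()
        y = self.norm2(self.conv2(y))
        skip = self.proj(x) if self.proj is not None else x
        out = (y + skip).leaky_relu()
        if min(out.shape[1:]) >= 2:
            out = nn.avg_pool2(out)  # deepest stages may already be 1 voxel
        return out


class FusionNet(nn.Module):
    def __init__(self, config: FusionNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stages = []
        c_prev = 1
        for c in config.image_channels:
            self.stages.append(_ResStage(c_prev, c, rng))
            c_prev = c
        self.fcs = []
        f_prev = 4
        for c in config.fc_widths:
            self.fcs.append(nn.Linear(f_prev, c, rng))
            f_prev = c
        self.head = nn.Linear(config.image_channels[-1], 2, rng)

    def parameters(self):
        params = []
        for m in self.stages + self.fcs:
            params.extend(m.parameters())
        params.extend(self.head.parameters())
        return params

    def forward(
        self,
        image: np.ndarray,
        markers: MarkerVector | np.ndarray,
        gate_mode: str = "normal",
        dropout_rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        """Return the 2-class softmax output.

        ``gate_mode``: "normal" uses the FC branch; "ones" forces every
        gate to 1 (ungated image-only network); "zeros" forces the stage-1
        gate to 0 (output independent of image content).
        """
        if gate_mode not in ("normal", "ones", "zeros"):
            raise ValueError(f"unknown gate_mode {gate_mode!r}")
        image = np.asarray(image, dtype=float)
        if image.shape != (self.config.input_cube,) * 3:
            raise ValueError(
                f"expected a {self.config.input_cube}^3 crop, got {image.shape}"
            )
        mv = markers.values if isinstance(markers, MarkerVector) else np.asarray(markers, float)
        x = nn.Tensor(image[None])
        h = nn.Tensor(mv)
        for s, (stage, fc) in enumerate(zip(self.stages, self.fcs)):
            x = stage(x)
            h = fc(h).leaky_relu()
            if gate_mode == "normal":
                gate = h.reshape(-1, 1, 1, 1)
                x = x * gate
            elif gate_mode == "zeros" and s == 0:
                x = x * 0.0
        feat = nn.global_mean(x)
        if self.config.dropout > 0 and dropout_rng is not None:
            keep = (dropout_rng.random(feat.shape) >= self.config.dropout) / (
                1 - self.config.dropout
            )
            feat = feat * nn.Tensor(keep)
        return self.head(feat).softmax(axis=0)

    def predict_proba(self, image, markers, gate_mode: str = "normal") -> np.ndarray:
        return self.forward(image, markers, gate_mode=gate_mode).data


def build_fusion_net(config: FusionNetConfig, seed: int = 0) -> FusionNet:
    return FusionNet(config, seed=seed)


def save_fusion_net(model: FusionNet, path) -> None:
    cfg = model.config
    np.savez(
        path,
        _channels=np.array(cfg.image_channels),
        _misc=np.array([cfg.input_cube, cfg.dropout]),
        **{f"p{i}": p.data for i, p in enumerate(model.parameters())},
    )


def load_fusion_net(path) -> FusionNet:
    with np.load(path) as z:
        channels = tuple(int(c) for c in z["_channels"])
        cube, dropout = z["_misc"]
        model = FusionNet(
            FusionNetConfig(
                num_stages=len(channels),
                image_channels=channels,
                input_cube=int(cube),
                dropout=float(dropout),
            )
        )
        model.load_state_dict([z[f"p{i}"] for i in range(len(model.parameters()))])
    return model


@dataclass
class FusionTrainResult:
    losses: list[float] = field(default_factory=list)


def train_fusion(
    model: FusionNet,
    samples,
    lr: float = 1e-4,
    epochs: int = 50,
    seed: int = 0,
    gate_mode: str = "normal",
) -> FusionTrainResult:
    """Cross-entropy training of the fusion classifier.

    ``samples`` is a sequence of (crop, MarkerVector-or-array, label)
    triples; crops must already be cube-sized and z-scored. ``gate_mode``
    "ones" trains the image-only ablation.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("training set is empty")
    labels = {int(s[2]) for s in samples}
    if len(labels) < 2:
        raise ValueError("training labels are single-class; cannot train a classifier")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    result = FusionTrainResult()
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        epoch = []
        for i in order:
            crop, markers, label = samples[i]
            probs = model.forward(crop, markers, gate_mode=gate_mode, dropout_rng=rng)
            loss = probs.clamp_min(1e-9).log().__mul__(-1.0)
            loss = (loss * nn.Tensor(np.eye(2)[int(label)])).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch.append(float(loss.data))
        result.losses.append(float(np.mean(epoch)))
    return result


def predict_pcr(
    model: FusionNet,
    crop: ImageVolume | np.ndarray,
    markers: MarkerVector,
    patient_id: str = "",
    gate_mode: str = "normal",
) -> PredictionResult:
    data = crop.data if isinstance(crop, ImageVolume) else np.asarray(crop)
    p = float(model.predict_proba(data, markers, gate_mode=gate_mode)[1])
    return PredictionResult(patient_id=patient_id, p_pcr=p, predicted_label=int(p >= 0.5))
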