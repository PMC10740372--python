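"""Gray-level histogram equalization and matching for cross-center
intensity harmonization.

The equalized level of gray level k is the scaled cumulative histogram

    s_k = (L - 1) / M * sum_{j<=k} n_j,    k = 0 .. L-1,

with M the total voxel count (the 2D "width x height" generalized to 3D).
Matching composes the source equalization with the inverse of the
reference's: each source level maps to the reference level whose equalized
value is nearest (ties to the lower level). Used to augment a training
cohort with copies matched to randomly selected test-center histograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import ImageVolume

__all__ = [
    "GrayHistogram",
    "EqualizationMap",
    "compute_histogram",
    "equalization_map",
    "match_histogram",
    "augment_cohort_by_matching",
    "ks_distance_to_histogram",
]


@dataclass
class GrayHistogram:
    """L-bin histogram of a volume's intensities.

    ``vmin``/``vmax`` record the linear quantization range so matched
    output can be expressed back on the reference intensity scale.
    """

    counts: np.ndarray
    L: int
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != self.L:
            raise ValueError("counts must be a length-L vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_centers(self) -> np.ndarray:
        width = (self.vmax - self.vmin) / self.L if self.vmax > self.vmin else 0.0
        return self.vmin + (np.arange(self.L) + 0.5) * width

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"counts": self.counts.tolist(), "L": self.L, "vmin": self.vmin, "vmax": self.vmax}
            )
        )

    @classmethod
    def from_json(cls, path) -> "GrayHistogram":
        d = json.loads(Path(path).read_text())
        return cls(counts=np.array(d["counts"]), L=d["L"], vmin=d["vmin"], vmax=d["vmax"])


@dataclass
class EqualizationMap:
    s: np.ndarray  # level k -> equalized value s_k

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(np.diff(self.s) < -1e-9):
            raise ValueError("equalization map must be nondecreasing")


def _quantize(data: np.ndarray, L: int, vmin: float, vmax: float) -> np.ndarray:
    if vmax <= vmin:
        return np.zeros(data.shape, dtype=np.int64)
    levels = np.floor((data - vmin) / (vmax - vmin) * L).astype(np.int64)
    return np.clip(levels, 0, L - 1)


def compute_histogram(vol: ImageVolume, L: int = 256) -> GrayHistogram:
    """Linearly quantize the volume's [min, max] range into L gray levels."""
    if L < 2:
        raise ValueError(f"need at least 2 gray levels, got {L}")
    data = np.asarray(vol.data, dtype=float)
    vmin, vmax = float(data.min()), float(data.max())
    levels = _quantize(data, L, vmin, vmax)
    counts = np.bincount(levels.ravel(), minlength=L)
    return GrayHistogram(counts=counts, L=L, vmin=vmin, vmax=vmax)


def equalization_map(hist: GrayHistogram) -> EqualizationMap:
    """Scaled cumulative map s_k = (L-1)/total * sum_{j<=k} n_j."""
    if hist.total == 0:
        raise ValueError("cannot equalize an empty histogram")
    s = (hist.L - 1) / hist.total * np.cumsum(hist.counts)
    return EqualizationMap(s=s)


def _match_levels(src_map: EqualizationMap, ref_map: EqualizationMap) -> np.ndarray:
    """For each source level, the reference level with nearest equalized
    value; ties broken toward the lower level."""
    ref = ref_map.s
    idx = np.searchsorted(ref, src_map.s, side="left")
    idx = np.clip(idx, 0, len(ref) - 1)
    lower = np.maximum(idx - 1, 0)
    # prefer the lower level when it is at least as close
    d_lower = np.abs(src_map.s - ref[lower])
    d_idx = np.abs(ref[idx] - src_map.s)
    return np.where(d_lower <= d_idx, lower, idx)


def match_histogram(source: ImageVolume, reference: GrayHistogram) -> ImageVolume:
    """Map the source volume's gray-level distribution onto the reference's.

    Output intensities live on the reference scale (bin centers of the
    reference histogram); geometry is untouched.
    """
    L = reference.L
    src_hist = compute_histogram(source, L=L)
    lut = _match_levels(equalization_map(src_hist), equalization_map(reference))
    src_levels = _quantize(np.asarray(source.data, dtype=float), L, src_hist.vmin, src_hist.vmax)
    matched_levels = lut[src_levels]
    out = reference.bin_centers()[matched_levels]
    return source.with_data(out)


def ks_distance_to_histogram(values: np.ndarray, hist: GrayHistogram) -> float:
    """One-sample Kolmogorov-Smirnov distance between an empirical sample
    and the step CDF defined by a gray-level histogram."""
    values = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(values)
    cdf_ref = np.cumsum(hist.counts) / hist.total
    edges = hist.vmin + (np.arange(1, hist.L + 1)) * (hist.vmax - hist.vmin) / hist.L
    # reference CDF evaluated at each sample point
    ref_at = cdf_ref[np.clip(np.searchsorted(edges, values, side="left"), 0, hist.L - 1)]
    ref_at = np.where(values >= edges[-1], 1.0, ref_at)
    ref_at = np.where(values < hist.vmin, 0.0, ref_at)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(emp_hi - ref_at), np.abs(emp_lo - ref_at))))


def augment_cohort_by_matching(train, test_histograms, seed: int):
    """Augment a training cohort: each sample is kept and additionally
    emitted once matched against a uniformly random test-center histogram.

    ``train`` is a sequence of (ImageVolume, payload) pairs; payload (masks,
    record, ...) is passed through unchanged. Returns a list of
    (ImageVolume, payload, matched: bool) triples of length 2n.
    """
    test_histograms = list(test_histograms)
    if not test_histograms:
        raise ValueError("need at least one test-center histogram")
    rng = np.random.default_rng(seed)
    out = []
    for vol, payload in train:
        out.append((vol, payload, False))
        ref = test_histograms[int(rng.integers(len(test_histograms)))]
        out.append((match_histogram(vol, ref), payload, True))
    return out
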