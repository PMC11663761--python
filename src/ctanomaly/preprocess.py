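"""Organ-wise preprocessing: mask, crop, window, resize, slice bags.

The model consumes one organ at a time. From a CT volume and multi-organ
label mask, the organ is cut out with a small bounding-box margin, voxels
outside the organ are filled with the air value (-1000 HU), intensities
are windowed (level 100, width 300) and scaled to [-1, 1], the crop is
resized to a fixed grid, and finally groups of five adjacent axial slices
are stacked as channels and taken in two-slice steps to form the bag
sequence for multiple-instance learning. The order is fixed:
crop -> window -> resize -> bag, so interpolation happens on bounded
values and the background fill cannot bleed mid-range intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skimage_resize
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import MASK_LABELS

__all__ = [
    "OrganVolume",
    "SliceBagSequence",
    "filter_exam_by_slices",
    "crop_organ",
    "window_normalize",
    "resize_volume",
    "build_slice_bags",
    "preprocess_organ",
    "OrganPreprocessor",
]

BACKGROUND_HU = -1000.0
MIN_SLICES, MAX_SLICES = 40, 300
DEFAULT_TARGET = (256, 256, 64)


class EmptyOrganError(ValueError):
    """Requested organ has no voxels in the mask."""


class TooFewSlicesError(ValueError):
    """Volume depth smaller than the slice-bag window."""


@dataclass
class OrganVolume:
    """Masked, windowed, resized single-organ array, values in [-1, 1]."""

    array: np.ndarray  # W x H x D float
    organ: str
    exam_id: str

    def __post_init__(self) -> None:
        if self.array.min() < -1.0 - 1e-6 or self.array.max() > 1.0 + 1e-6:
            raise ValueError("organ volume values must lie in [-1, 1]")


@dataclass
class SliceBagSequence:
    """Ordered bags of five adjacent axial slices stacked as channels."""

    bags: np.ndarray  # n_bags x W x H x window
    starts: np.ndarray  # slice start index of each bag


def filter_exam_by_slices(n_slices: int) -> bool:
    """Inclusion rule: keep exams with 40 to 300 axial slices inclusive."""
    if n_slices < 0:
        raise ValueError("slice count must be >= 0")
    return MIN_SLICES <= n_slices <= MAX_SLICES


def crop_organ(
    volume: np.ndarray,
    mask: np.ndarray,
    organ_id: int | str,
    margin_vox: int = 4,
) -> np.ndarray:
    """Bounding-box crop of one organ with non-organ voxels set to -1000 HU."""
    if isinstance(organ_id, str):
        organ_id = MASK_LABELS[organ_id]
    organ = mask == organ_id
    if not organ.any():
        raise EmptyOrganError(f"organ label {organ_id} absent from mask")
    out = np.where(organ, volume, BACKGROUND_HU)
    slices = []
    for ax, idx in enumerate(np.nonzero(organ)):
        lo = max(int(idx.min()) - margin_vox, 0)
        hi = min(int(idx.max()) + margin_vox + 1, volume.shape[ax])
        slices.append(slice(lo, hi))
    return out[tuple(slices)]


def window_normalize(
    hu_array: np.ndarray, level: float = 100.0, width: float = 300.0
) -> np.ndarray:
    """Clip HU to the window [level-width/2, level+width/2], scale to [-1, 1]."""
    if width <= 0:
        raise ValueError("window width must be positive")
    arr = np.asarray(hu_array, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("HU values must be finite")
    lo, hi = level - width / 2.0, level + width / 2.0
    return (np.clip(arr, lo, hi) - level) / (width / 2.0)


def resize_volume(
    array: np.ndarray, target: tuple[int, int, int] = DEFAULT_TARGET
) -> np.ndarray:
    """Trilinear resize to the target grid; output bounded by input extremes."""
    array = np.asarray(array, dtype=float)
    if array.size == 0 or min(array.shape) == 0:
        raise ValueError("cannot resize a degenerate (zero-sized) axis")
    out = _skimage_resize(
        array, target, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, array.min(), array.max())


def build_slice_bags(
    organ_volume: np.ndarray | OrganVolume, window: int = 5, step: int = 2
) -> SliceBagSequence:
    """Stack ``window`` adjacent axial slices as channels, every ``step`` slices.

    Bags start at 0, step, 2*step, ... while start + window <= depth, giving
    floor((D - window)/step) + 1 bags; trailing slices that do not fill a
    window are not padded.
    """
    arr = organ_volume.array if isinstance(organ_volume, OrganVolume) else organ_volume
    depth = arr.shape[2]
    if depth < window:
        raise TooFewSlicesError(f"depth {depth} < window {window}")
    starts = np.arange(0, depth - window + 1, step)
    bags = np.stack([arr[:, :, s : s + window] for s in starts])
    return SliceBagSequence(bags=bags, starts=starts)


def preprocess_organ(
    volume: np.ndarray,
    mask: np.ndarray,
    organ: str,
    exam_id: str = "",
    target: tuple[int, int, int] = DEFAULT_TARGET,
    margin_vox: int = 4,
    level: float = 100.0,
    width: float = 300.0,
) -> OrganVolume:
    """Full fixed-order pipeline: crop -> window -> resize for one organ."""
    crop = crop_organ(volume, mask, organ, margin_vox)
    normed = window_normalize(crop, level, width)
    resized = resize_volume(normed, target)
    return OrganVolume(array=resized, organ=organ, exam_id=exam_id)


class OrganPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer mapping (volume, mask) pairs to model-ready organ volumes.

    Parameters mirror :func:`preprocess_organ`; ``transform`` accepts an
    iterable of ``(volume, mask)`` or ``(volume, mask, exam_id)`` tuples and
    returns a list of :class:`OrganVolume`.
    """

    def __init__(
        self,
        organ: str = "liver",
        target: tuple[int, int, int] = DEFAULT_TARGET,
        margin_vox: int = 4,
        level: float = 100.0,
        width: float = 300.0,
    ):
        self.organ = organ
        self.target = target
        self.margin_vox = margin_vox
        self.level = level
        self.width = width

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0  # stateless
        return self

    def transform(self, X) -> list[OrganVolume]:
        out = []
        for item in X:
            volume, mask = item[0], item[1]
            exam_id = item[2] if len(item) > 2 else ""
            out.append(
                preprocess_organ(
                    volume,
                    mask,
                    self.organ,
                    exam_id=exam_id,
                    target=self.target,
                    margin_vox=self.margin_vox,
                    level=self.level,
                    width=self.width,
                )
            )
        return out
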