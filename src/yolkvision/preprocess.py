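"""Candling-image preprocessing.

Turns a raw RGB transmittance image of a duck egg into a 32x32
background-free grayscale region of interest (ROI) plus a co-registered
binary egg mask:

1. split the RGB channels (red carries the egg outline, blue the yolk
   shadow),
2. 3x3 median de-noising of the red and blue channels,
3. Otsu threshold on the red channel to segment the egg from the dark
   background,
4. square bounding box of the egg, padded by 30 px,
5. crop the blue channel and the binary mask, multiply them so the
   background is exactly zero,
6. bicubic resize of both to 32x32 (mask re-binarized at 0.5).

All coordinates are row-major, 0-based, top-left origin; crop rectangles
are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

from . import config

log = logging.getLogger(__name__)

__all__ = [
    "CandledImage",
    "RoiPair",
    "NoEggFoundError",
    "split_channels",
    "median3",
    "otsu_level",
    "binarize",
    "egg_bbox",
    "apply_mask",
    "resize32",
    "preprocess",
    "CandlingPreprocessor",
]


class NoEggFoundError(ValueError):
    """Raised when no sufficiently large bright region exists in the frame."""


@dataclass
class CandledImage:
    """An RGB candling image stored as three uint8 channel grids."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channel shapes differ")
        if self.red.ndim != 2:
            raise ValueError("channels must be 2-D grids")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @classmethod
    def from_array(cls, rgb: np.ndarray, label: Optional[str] = None) -> "CandledImage":
        rgb = np.asarray(rgb)
        if rgb.ndim != 3 or rgb.shape[2] < 3:
            raise ValueError("expected an H x W x 3 RGB array")
        return cls(
            red=rgb[:, :, 0].astype(np.uint8),
            green=rgb[:, :, 1].astype(np.uint8),
            blue=rgb[:, :, 2].astype(np.uint8),
            label=label,
        )

    @classmethod
    def from_file(cls, path, label: Optional[str] = None) -> "CandledImage":
        arr = iio.imread(path)
        if arr.ndim == 2:
            raise ValueError(f"{path}: grayscale image, expected RGB")
        return cls.from_array(arr[:, :, :3], label=label)

    def to_array(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue], axis=-1)

    def to_file(self, path) -> None:
        iio.imwrite(path, self.to_array())


@dataclass
class RoiPair:
    """Normalized 32x32 grayscale ROI with its co-registered binary mask."""

    roi: np.ndarray            # float, 0..255, zero outside the mask
    mask: np.ndarray           # uint8, {0, 1}
    crop_rectangle: tuple      # (top, left, side) in source coordinates

    def __post_init__(self) -> None:
        if self.roi.shape != (config.ROI_SIDE, config.ROI_SIDE):
            raise ValueError(f"roi must be {config.ROI_SIDE}x{config.ROI_SIDE}")
        if self.mask.shape != self.roi.shape:
            raise ValueError("mask shape differs from roi")

    @property
    def roi01(self) -> np.ndarray:
        """ROI rescaled to [0, 1] (division by 255) for the CNN input."""
        return self.roi / 255.0


def split_channels(img: CandledImage):
    """Return the (red, green, blue) channel grids of an RGB image."""
    return img.red, img.green, img.blue


def median3(grid: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication at the borders."""
    grid = np.asarray(grid)
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    k = config.MEDIAN_KERNEL
    return ndimage.median_filter(grid, size=k, mode="nearest")


def otsu_level(grid: np.ndarray) -> int:
    """Otsu threshold over the 256-bin integer histogram.

    Returns the integer t in [0, 255] maximizing the between-class variance
    of the split ``pixel <= t`` vs ``pixel > t`` (foreground is the brighter
    class).  Ties break toward the smallest t.  A constant grid has no
    split; its value is returned (so binarization yields all-background)
    and a warning is logged.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("empty grid")
    vals = np.clip(np.round(grid), 0, 255).astype(np.int64).ravel()
    if vals.min() == vals.max():
        log.warning("otsu_level: constant grid (value %d); no foreground", vals[0])
        return int(vals[0])
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)                  # weight of class <= t
    mu = np.cumsum(p * np.arange(256))    # first moment of class <= t
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))


def binarize(grid: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground rule ``pixel > threshold`` as a uint8 {0,1} grid."""
    return (np.asarray(grid) > threshold).astype(np.uint8)


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component of a binary grid."""
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoEggFoundError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = 1 + int(np.argmax(sizes))
    return (labels == best).astype(np.uint8)


def egg_bbox(binary: np.ndarray, pad: int = config.CROP_PAD) -> tuple:
    """Square crop rectangle (top, left, side) around the largest component.

    The component's bounding rectangle is expanded symmetrically along its
    shorter side to a square, padded by ``pad`` on all four sides, then
    fitted inside the image: if the padded square overruns the frame its
    side shrinks to the frame and it is shifted inward, so the result is
    always a square fully inside the image.
    """
    comp = largest_component(binary)
    rows = np.any(comp, axis=1).nonzero()[0]
    cols = np.any(comp, axis=0).nonzero()[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    side = max(r1 - r0, c1 - c0) + 2 * pad
    cy = (r0 + r1) / 2.0
    cx = (c0 + c1) / 2.0
    h, w = binary.shape
    side = min(side, h, w)
    top = int(round(cy - side / 2.0))
    left = int(round(cx - side / 2.0))
    top = max(0, min(top, h - side))
    left = max(0, min(left, w - side))
    return (top, left, side)


def apply_mask(roi_grid: np.ndarray, mask_grid: np.ndarray) -> np.ndarray:
    """Zero the background: elementwise product of ROI and binary mask."""
    roi_grid = np.asarray(roi_grid)
    mask_grid = np.asarray(mask_grid)
    if roi_grid.shape != mask_grid.shape:
        raise ValueError("roi and mask shapes differ")
    return roi_grid * mask_grid


def resize32(grid: np.ndarray, side: int = config.ROI_SIDE,
             is_mask: bool = False) -> np.ndarray:
    """Bicubic resize to ``side`` x ``side``.

    Grayscale output is clipped to [0, 255]; masks are re-binarized at 0.5
    after interpolation.  Resizing a grid already at the target size is the
    identity.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.shape[0] <= 1 or grid.shape[1] <= 1:
        raise ValueError("degenerate grid")
    if grid.shape == (side, side):
        out = grid.copy()
    else:
        out = _sk_resize(grid, (side, side), order=3, mode="edge",
                         anti_aliasing=max(grid.shape) > side,
                         preserve_range=True)
    if is_mask:
        return (out > 0.5).astype(np.uint8)
    return np.clip(out, 0.0, 255.0)


def preprocess(img: CandledImage, pad: int = config.CROP_PAD,
               min_egg_area: int = config.MIN_EGG_AREA) -> RoiPair:
    """Full preprocessing chain: RGB image -> 32x32 masked ROI pair."""
    red, _green, blue = split_channels(img)
    red_dn = median3(red)
    blue_dn = median3(blue)
    t = otsu_level(red_dn)
    egg_bin = binarize(red_dn, t)
    if egg_bin.sum() == 0:
        raise NoEggFoundError("threshold segmentation found no foreground")
    comp = largest_component(egg_bin)
    if int(comp.sum()) < min_egg_area:
        raise NoEggFoundError(
            f"largest bright region ({int(comp.sum())} px) below "
            f"minimum egg area {min_egg_area}")
    top, left, side = egg_bbox(comp, pad=pad)
    roi = blue_dn[top:top + side, left:left + side].astype(np.float64)
    mask = comp[top:top + side, left:left + side]
    roi = apply_mask(roi, mask)
    roi32 = resize32(roi)
    mask32 = resize32(mask, is_mask=True)
    roi32 = roi32 * mask32          # keep zero background after interpolation
    return RoiPair(roi=roi32, mask=mask32, crop_rectangle=(top, left, side))


class CandlingPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`preprocess`.

    ``transform`` maps a sequence of :class:`CandledImage` (or H x W x 3
    arrays) to the stacked (n, 32, 32) array of [0, 1]-scaled ROIs; use
    :meth:`transform_pairs` when the masks and crop rectangles are needed.
    """

    def __init__(self, pad: int = config.CROP_PAD,
                 min_egg_area: int = config.MIN_EGG_AREA):
        self.pad = pad
        self.min_egg_area = min_egg_area

    def fit(self, X, y=None):
        return self

    def transform_pairs(self, X) -> list:
        pairs = []
        for item in X:
            img = item if isinstance(item, CandledImage) else CandledImage.from_array(item)
            pairs.append(preprocess(img, pad=self.pad, min_egg_area=self.min_egg_area))
        return pairs

    def transform(self, X) -> np.ndarray:
        return np.stack([rp.roi01 for rp in self.transform_pairs(X)])
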