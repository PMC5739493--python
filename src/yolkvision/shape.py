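"""Yolk segmentation and Fourier-descriptor shape features.

The yolk shadow is segmented out of the 32x32 ROI (Otsu split of albumen
vs yolk+background, mask subtraction, median removal of the shell rim),
its boundary is traced as a closed pixel contour, and the contour is
encoded as complex Fourier coefficients of s(k) = x_k + i*y_k.  The
coefficient magnitudes, divided by the fundamental |a(1)| and with the DC
term zeroed, form normalized Fourier descriptors (NFDs) that are invariant
to translation, scale, rotation and the starting point of the trace:

    d(0) = 0,   d(u) = |a(u)| / |a(1)|   (so d(1) = 1).

The 14-dimensional feature vector [d(2), ..., d(15)] feeds the Fisher
discriminant.  Truncated inverse transforms reconstruct approximate
boundaries; the reconstruction error eps_n is the mean distance from each
original boundary point to its nearest reconstructed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from . import config
from .preprocess import RoiPair, binarize, median3, otsu_level

__all__ = [
    "Contour",
    "DescriptorSet",
    "NoYolkError",
    "segment_yolk",
    "trace_boundary",
    "fourier_descriptors",
    "normalize_fds",
    "feature_vector",
    "reconstruct_boundary",
    "reconstruction_error",
    "contour_features",
    "YolkShapeFeaturizer",
]


class NoYolkError(ValueError):
    """Raised when the segmentation leaves no yolk pixels."""


@dataclass
class Contour:
    """Ordered closed boundary: points[k] = (x_k, y_k), k = 0..N-1.

    Orientation is normalized to counter-clockwise in the (x, y) plane
    (positive shoelace area with y pointing up).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an N x 2 array")
        if len(self.points) < 4:
            raise ValueError("a closed contour needs at least 4 points")
        diffs = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        if np.any(np.all(diffs == 0, axis=1)):
            raise ValueError("consecutive duplicate points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise traversal."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def as_complex(self) -> np.ndarray:
        return self.points[:, 0] + 1j * self.points[:, 1]


@dataclass
class DescriptorSet:
    """Fourier coefficients of a contour and the derived NFDs."""

    coeffs: np.ndarray                 # complex a(u), u = 0..N-1
    nfd: Optional[np.ndarray] = None   # real d(u), u = 0..m-1

    @property
    def n_points(self) -> int:
        return len(self.coeffs)


def segment_yolk(rp: RoiPair, restrict_to_mask: bool = True) -> np.ndarray:
    """Extract the binary yolk region from a preprocessed ROI pair.

    Otsu on the ROI makes the bright albumen foreground; subtracting it
    from the egg mask leaves the yolk shadow plus the thin shell rim; a
    3x3 median filter removes the rim.  Separated double yolks survive as
    two components — downstream, only the largest is traced.

    By default the Otsu threshold is estimated from egg pixels only
    (``restrict_to_mask``): the zeroed background otherwise dominates the
    histogram and, for large yolk shadows, drags the split down to
    background-vs-egg instead of yolk-vs-albumen.  The binarization is
    still applied to the full ROI, and the background (value 0) always
    falls in the dark class.
    """
    if restrict_to_mask:
        t = otsu_level(rp.roi[rp.mask > 0])
    else:
        t = otsu_level(rp.roi)
    albumen = binarize(rp.roi, t)
    yolk_and_rim = np.clip(rp.mask.astype(np.int16) - albumen, 0, 1).astype(np.uint8)
    yolk = median3(yolk_and_rim)
    if yolk.sum() == 0:
        raise NoYolkError("no yolk region after shell-rim removal")
    return yolk


# Moore neighborhood in clockwise image order starting east:
# (drow, dcol); clockwise on screen = counter-clockwise in y-up coords.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(binary: np.ndarray) -> Contour:
    """Moore boundary trace of the largest 8-connected component.

    Starts at the topmost-then-leftmost boundary pixel and returns the
    closed ordered pixel sequence as (x, y) = (col, row) pairs, with
    orientation normalized so the shoelace area in (x, y) is positive.
    """
    binary = np.asarray(binary)
    if binary.sum() == 0:
        raise ValueError("empty grid")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    padded = np.zeros((comp.shape[0] + 2, comp.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = comp

    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(np.min(cols[rows == rows[0]])))
    # enter the start pixel from its western neighbour (background, since the
    # start pixel is leftmost in the top row)
    boundary = [start]
    prev_dir = 4            # direction pointing back where we came from: west
    cur = start
    while True:
        # scan the Moore neighbourhood clockwise, starting just after the
        # backtrack direction
        found = False
        for i in range(8):
            d = (prev_dir + 1 + i) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if padded[nxt]:
                # new backtrack direction: where cur lies relative to nxt
                prev_dir = (d + 4) % 8
                cur = nxt
                found = True
                break
        if not found:       # isolated pixel
            break
        if cur == start and len(boundary) > 1:
            break
        boundary.append(cur)

    pts = np.array([(c - 1, r - 1) for r, c in boundary], dtype=np.float64)
    if len(pts) < 4:
        raise ValueError("component too small to form a closed contour")
    contour = Contour(pts)
    if contour.signed_area < 0:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
        contour = Contour(pts)
    return contour


def fourier_descriptors(c: Contour) -> DescriptorSet:
    """Discrete Fourier transform of the complex boundary signal.

    a(u) = sum_k s(k) exp(-2*pi*i*u*k/N) with s(k) = x_k + i*y_k.
    """
    return DescriptorSet(coeffs=np.fft.fft(c.as_complex()))


def normalize_fds(ds: DescriptorSet, m: int = config.NFD_TRUNCATION) -> DescriptorSet:
    """Fill the first ``m`` normalized Fourier descriptors.

    Magnitudes remove rotation and start-point dependence, division by
    |a(1)| removes scale, and forcing d(0) = 0 removes translation.
    """
    mags = np.abs(ds.coeffs)
    if len(mags) < m:
        raise ValueError(f"contour has {len(mags)} points, need >= {m}")
    a1 = mags[1]
    if a1 <= 1e-9 * mags.max():
        raise ValueError("degenerate contour: vanishing fundamental |a(1)|")
    nfd = mags[:m] / a1
    nfd[0] = 0.0
    nfd[1] = 1.0
    return DescriptorSet(coeffs=ds.coeffs, nfd=nfd)


def feature_vector(ds: DescriptorSet) -> np.ndarray:
    """The retained descriptor vector [d(2), ..., d(15)], length 14."""
    lo, hi = config.FEATURE_RANGE
    if ds.nfd is None or len(ds.nfd) < hi:
        raise ValueError(f"need at least {hi} normalized descriptors")
    return np.asarray(ds.nfd[lo:hi], dtype=np.float64)


def _band_order(n_points: int) -> np.ndarray:
    """Coefficient indices sorted by |frequency|: 0, +1, -1, +2, -2, ..."""
    order = [0]
    f = 1
    while len(order) < n_points:
        order.append(f)
        if len(order) < n_points and n_points - f != f:
            order.append(n_points - f)
        f += 1
    return np.array(order[:n_points])


def reconstruct_boundary(ds: DescriptorSet, n: int) -> Contour:
    """Inverse transform keeping only the n lowest-|frequency| harmonics."""
    N = ds.n_points
    if not 2 <= n <= N:
        raise ValueError(f"n must be in [2, {N}]")
    keep = _band_order(N)[:n]
    coeffs = np.zeros(N, dtype=complex)
    coeffs[keep] = ds.coeffs[keep]
    s = np.fft.ifft(coeffs)
    return Contour(np.column_stack([s.real, s.imag]))


def reconstruction_error(original: Contour, recon: Contour) -> float:
    """Mean nearest-point distance from original to reconstructed boundary.

    eps = (1/N) * sum_k min_j ||(x_k, y_k) - (x_nj, y_nj)||.
    """
    tree = cKDTree(recon.points)
    dists, _ = tree.query(original.points)
    return float(np.mean(dists))


def contour_features(rp: RoiPair, m: int = config.NFD_TRUNCATION) -> np.ndarray:
    """ROI pair -> 14-dim NFD feature vector (largest yolk component)."""
    yolk = segment_yolk(rp)
    contour = trace_boundary(yolk)
    ds = normalize_fds(fourier_descriptors(contour), m=m)
    return feature_vector(ds)


class YolkShapeFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: ROI pairs -> (n, 14) NFD feature matrix.

    Parameters
    ----------
    m : number of normalized descriptors computed per contour.
    on_error : "raise" propagates segmentation failures; "nan" emits a row
        of NaNs so callers can flag rather than drop failed images.
    """

    def __init__(self, m: int = config.NFD_TRUNCATION, on_error: str = "raise"):
        self.m = m
        self.on_error = on_error

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        lo, hi = config.FEATURE_RANGE
        out = np.empty((len(X), hi - lo), dtype=np.float64)
        for i, rp in enumerate(X):
            try:
                out[i] = contour_features(rp, m=self.m)
            except (NoYolkError, ValueError):
                if self.on_error == "raise":
                    raise
                out[i] = np.nan
        return out
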