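"""Synthetic candled-egg images with ground truth, and analytic contours.

No public dataset of duck-egg transmittance images exists, so this module
renders the scenes the rest of the pipeline expects: a bright elliptical
egg on a near-black background, glowing brightest in the red channel,
with one roughly circular yolk shadow (single-yolked, SY) or an 8-shaped
pair of overlapping shadows (double-yolked, DY) darkest in the blue
channel.  A configurable fraction of DY scenes carries two *separated*
yolk shadows, the known failure mode of single-contour shape analysis.

The candler optics are abstracted to per-channel mean intensity levels
plus a quadratic radial brightness falloff inside the egg; only the
ordering of channel contrasts matters to the downstream algorithms.
Rendering is a pure function of the scene description, so every image is
reproducible from its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np

from .config import DEFAULT_RANGES, SceneRanges
from .preprocess import CandledImage
from .shape import Contour

__all__ = [
    "EggScene",
    "LabeledDataset",
    "make_egg_image",
    "make_truth_mask",
    "make_dataset",
    "analytic_contour",
]


@dataclass
class EggScene:
    """Complete description of one synthetic candled-egg frame."""

    image_width: int
    image_height: int
    egg_center: Tuple[float, float]            # (x, y), px
    egg_semi_axes: Tuple[float, float]         # (a, b), px
    yolk_centers: List[Tuple[float, float]]    # 1 (SY) or 2 (DY) entries
    yolk_radius: float
    yolk_overlap_fraction: float               # <0 encodes separated yolks
    background_level: Tuple[float, float, float]
    albumen_level: Tuple[float, float, float]
    yolk_level: Tuple[float, float, float]
    noise_sigma: float
    label: str                                 # "SY" | "DY"
    seed: int
    falloff: float = 0.15

    def validate(self) -> None:
        if self.label not in ("SY", "DY"):
            raise ValueError(f"label must be SY or DY, got {self.label!r}")
        expected = 1 if self.label == "SY" else 2
        if len(self.yolk_centers) != expected:
            raise ValueError(
                f"{self.label} scene needs {expected} yolk center(s), "
                f"got {len(self.yolk_centers)}")
        for levels in (self.background_level, self.albumen_level, self.yolk_level):
            if not all(0 <= v <= 255 for v in levels):
                raise ValueError("intensity levels must lie in [0, 255]")
        cx, cy = self.egg_center
        a, b = self.egg_semi_axes
        r = self.yolk_radius
        if r >= min(a, b):
            raise ValueError("yolk radius exceeds egg semi-axis")
        for x, y in self.yolk_centers:
            # disc inside the ellipse shrunk by r: conservative containment
            if ((x - cx) / (a - r)) ** 2 + ((y - cy) / (b - r)) ** 2 > 1.0:
                raise ValueError(
                    f"yolk at ({x:.1f}, {y:.1f}) protrudes outside the egg")

    @staticmethod
    def double_yolk_centers(egg_center: Tuple[float, float], radius: float,
                            overlap_fraction: float,
                            angle: float) -> List[Tuple[float, float]]:
        """Two disc centers about the egg center.

        Center distance is 2*r*(1 - f): f in (0, 1] overlaps the discs into
        an 8 shape, f < 0 pulls them apart (the separated failure mode).
        """
        d = 2.0 * radius * (1.0 - overlap_fraction)
        dx, dy = 0.5 * d * np.cos(angle), 0.5 * d * np.sin(angle)
        cx, cy = egg_center
        return [(cx - dx, cy - dy), (cx + dx, cy + dy)]


@dataclass
class LabeledDataset:
    """A rendered image collection with labels and ground-truth masks."""

    images: List[CandledImage]
    labels: List[str]
    truth_masks: List[np.ndarray]
    scenes: List[EggScene] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.truth_masks)):
            raise ValueError("images, labels and truth_masks lengths differ")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def separated_flags(self) -> np.ndarray:
        """True where a DY scene has non-overlapping yolk discs."""
        return np.array([s.label == "DY" and s.yolk_overlap_fraction < 0
                         for s in self.scenes])

    def write(self, outdir) -> Path:
        """Write PNGs, single-channel truth masks and a CSV manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(exist_ok=True)
        manifest = outdir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "label", "seed", "egg_center_x",
                             "egg_center_y", "semi_a", "semi_b", "yolk_radius",
                             "overlap_fraction", "noise_sigma"])
            for i, (img, lab, mask, scene) in enumerate(
                    zip(self.images, self.labels, self.truth_masks, self.scenes)):
                name = f"egg_{i:04d}_{lab}.png"
                img.to_file(outdir / name)
                iio.imwrite(outdir / "masks" / name,
                            (mask * 255).astype(np.uint8))
                writer.writerow([name, lab, scene.seed,
                                 f"{scene.egg_center[0]:.2f}",
                                 f"{scene.egg_center[1]:.2f}",
                                 f"{scene.egg_semi_axes[0]:.2f}",
                                 f"{scene.egg_semi_axes[1]:.2f}",
                                 f"{scene.yolk_radius:.2f}",
                                 f"{scene.yolk_overlap_fraction:.3f}",
                                 f"{scene.noise_sigma:.2f}"])
        return manifest


def _grids(scene: EggScene):
    yy, xx = np.mgrid[0:scene.image_height, 0:scene.image_width]
    cx, cy = scene.egg_center
    a, b = scene.egg_semi_axes
    rho2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    egg = rho2 <= 1.0
    yolk = np.zeros_like(egg)
    for x, y in scene.yolk_centers:
        yolk |= (xx - x) ** 2 + (yy - y) ** 2 <= scene.yolk_radius ** 2
    return egg, yolk, rho2


def make_egg_image(scene: EggScene) -> CandledImage:
    """Render a scene to an RGB candling image (deterministic per seed)."""
    scene.validate()
    egg, yolk, rho2 = _grids(scene)
    shade = 1.0 - scene.falloff * np.clip(rho2, 0.0, 1.0)
    rng = np.random.default_rng(scene.seed)
    channels = []
    for c in range(3):
        grid = np.full(egg.shape, scene.background_level[c], dtype=np.float64)
        grid[egg] = scene.albumen_level[c] * shade[egg]
        grid[yolk] = scene.yolk_level[c] * shade[yolk]
        if scene.noise_sigma > 0:
            grid = grid + rng.normal(0.0, scene.noise_sigma, size=grid.shape)
        channels.append(np.clip(np.round(grid), 0, 255).astype(np.uint8))
    return CandledImage(red=channels[0], green=channels[1], blue=channels[2],
                        label=scene.label)


def make_truth_mask(scene: EggScene) -> np.ndarray:
    """Binary ground-truth yolk mask (union of the yolk discs)."""
    _egg, yolk, _rho2 = _grids(scene)
    return yolk.astype(np.uint8)


def _draw_scene(rng: np.random.Generator, label: str, ranges: SceneRanges,
                separated: bool) -> EggScene:
    u = rng.uniform
    cx = ranges.image_width / 2 + u(-ranges.center_jitter, ranges.center_jitter)
    cy = ranges.image_height / 2 + u(-ranges.center_jitter, ranges.center_jitter)
    a = u(*ranges.semi_axis_a)
    b = u(*ranges.semi_axis_b)
    r = u(*ranges.yolk_radius)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    if label == "SY":
        centers = [(cx + u(-6, 6), cy + u(-6, 6))]
        overlap = 1.0
    else:
        if separated:
            overlap = -u(*ranges.separated_gap)
        else:
            overlap = u(*ranges.overlap_fraction)
        # separation along a near-horizontal axis keeps both discs inside
        # the (wider-than-tall) egg ellipse
        angle = u(-np.pi / 12, np.pi / 12)
        centers = EggScene.double_yolk_centers((cx, cy), r, overlap, angle)
    return EggScene(
        image_width=ranges.image_width, image_height=ranges.image_height,
        egg_center=(cx, cy), egg_semi_axes=(a, b), yolk_centers=centers,
        yolk_radius=r, yolk_overlap_fraction=overlap,
        background_level=ranges.background_level,
        albumen_level=ranges.albumen_level,
        yolk_level=ranges.yolk_level,
        noise_sigma=u(*ranges.noise_sigma), label=label, seed=seed,
        falloff=ranges.falloff)


def make_dataset(n_sy: int, n_dy: int, ranges: SceneRanges = DEFAULT_RANGES,
                 seed: int = 0,
                 separated_fraction: Optional[float] = None) -> LabeledDataset:
    """Draw scene parameters uniformly from ``ranges`` and render them.

    ``separated_fraction`` of the DY scenes (rounded; default from
    ``ranges``) get non-overlapping yolk discs.  Reproducible by seed.
    """
    if n_sy < 0 or n_dy < 0:
        raise ValueError("sample counts must be non-negative")
    frac = ranges.separated_fraction if separated_fraction is None else separated_fraction
    rng = np.random.default_rng(seed)
    n_sep = int(round(frac * n_dy))
    sep_flags = np.zeros(n_dy, dtype=bool)
    sep_flags[rng.permutation(n_dy)[:n_sep]] = True

    scenes = [_draw_scene(rng, "SY", ranges, False) for _ in range(n_sy)]
    scenes += [_draw_scene(rng, "DY", ranges, bool(f)) for f in sep_flags]
    images = [make_egg_image(s) for s in scenes]
    masks = [make_truth_mask(s) for s in scenes]
    return LabeledDataset(images=images, labels=[s.label for s in scenes],
                          truth_masks=masks, scenes=scenes, seed=seed)


def analytic_contour(shape_name: str, n_points: int, *, radius: float = 1.0,
                     center: Tuple[float, float] = (0.0, 0.0),
                     extent: float = 1.0, waist: float = 0.6) -> Contour:
    """Closed analytic test contours with uniform parameterization.

    ``circle``: radius ``radius`` about ``center``.  ``figure_eight``: the
    two-lobed simple closed polar curve r(t) = extent*(1 + waist*cos 2t)
    / (1 + waist) — an 8-shaped outline like two overlapping discs (a true
    lemniscate self-intersects, which a traced yolk boundary never does).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points for a closed contour")
    t = 2.0 * np.pi * np.arange(n_points) / n_points
    if shape_name == "circle":
        x = center[0] + radius * np.cos(t)
        y = center[1] + radius * np.sin(t)
    elif shape_name == "figure_eight":
        if not 0 < waist < 1:
            raise ValueError("waist must be in (0, 1)")
        r = extent * (1.0 + waist * np.cos(2.0 * t)) / (1.0 + waist)
        x = center[0] + r * np.cos(t)
        y = center[1] + r * np.sin(t)
    else:
        raise ValueError(f"unknown shape {shape_name!r}")
    return Contour(np.column_stack([x, y]))
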