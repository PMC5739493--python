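"""Frozen default parameters for the whole pipeline.

Every constant the classification chain depends on lives here: the scene
ranges the synthetic candler draws from, the preprocessing geometry and the
classifier hyperparameters.  The intensity levels were calibrated once so
that the channel-contrast contracts hold (egg vs background in the red
channel, albumen vs yolk shadow in the blue channel) and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: side of the normalized region of interest, pixels
ROI_SIDE = 32

#: padding added around the egg bounding square before cropping, pixels
CROP_PAD = 30

#: median-filter kernel side
MEDIAN_KERNEL = 3

#: number of normalized Fourier descriptors kept (harmonics 0..M-1)
NFD_TRUNCATION = 16

#: harmonic orders retained in the feature vector: d(2)..d(15), 14 values
FEATURE_RANGE = (2, 16)

#: smallest egg-candidate pixel area accepted by the preprocessor
MIN_EGG_AREA = 256


@dataclass(frozen=True)
class SceneRanges:
    """Uniform sampling ranges for synthetic candled-egg scenes.

    Intensity levels are per-channel (R, G, B) means on the 0-255 scale.
    The egg glows brightest in the red channel; the yolk shadow is darkest
    relative to the albumen in the blue channel, mirroring how a warm LED
    candler renders a duck egg on a CCD camera.
    """

    image_width: int = 400
    image_height: int = 300
    center_jitter: float = 12.0          # px, uniform in +-jitter around frame center
    semi_axis_a: tuple[float, float] = (95.0, 110.0)    # egg half-length, px
    semi_axis_b: tuple[float, float] = (70.0, 80.0)     # egg half-width, px
    yolk_radius: tuple[float, float] = (34.0, 40.0)     # px
    overlap_fraction: tuple[float, float] = (0.25, 0.55)   # DY disc overlap
    separated_gap: tuple[float, float] = (0.08, 0.20)   # extra gap, in radii
    separated_fraction: float = 0.05     # share of DY scenes with split yolks
    background_level: tuple[float, float, float] = (12.0, 10.0, 8.0)
    albumen_level: tuple[float, float, float] = (178.0, 132.0, 186.0)
    yolk_level: tuple[float, float, float] = (150.0, 100.0, 70.0)
    falloff: float = 0.15                # radial brightness falloff inside egg
    noise_sigma: tuple[float, float] = (3.0, 7.0)       # additive Gaussian, DN


#: the frozen ranges used by the default synthetic benchmark
DEFAULT_RANGES = SceneRanges()


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol of the convolutional classifier."""

    learning_rate: float = 0.2
    batch_size: int = 50
    epochs: int = 100
    split_ratio: float = 0.95   # training share of the repeated random split
    repeats: int = 10
    seed: int = 0


DEFAULT_TRAIN = TrainConfig()
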