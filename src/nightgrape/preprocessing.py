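"""Image standardization and R-component preparation.

Night-time grape images taken under warm-white LED illumination have a red
channel in which fruit pixels sit in a high, narrow intensity band
(roughly 160-215) while foliage and ground stay mostly below 150.  The
pipeline therefore works on the R component alone: images are first resized
to a fixed working resolution, the R plane is extracted, and its values are
cyclically rotated upward by a fixed offset so the fruit band occupies the
top of the 8-bit range and over-bright highlights wrap to the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from skimage.transform import resize


class InvalidInputError(ValueError):
    """Raised when an input image or parameter set violates a precondition."""


@dataclass(frozen=True)
class PipelineConfig:
    """Geometry and rotation constants of the pipeline.

    Attributes
    ----------
    standard_size : (width, height)
        Working resolution every input is resampled to.
    coarse_size : (width, height)
        Resolution of the coarse pyramid stage; must divide the standard
        size by the same integer factor on both axes.
    rotation_offset : int
        Cyclic shift applied to the R component (intensity units).
    wrap_modulus : int
        Top of the intensity scale; values exceeding it wrap by subtracting
        it (note: NOT a mod-256 wrap — 220 maps to 255 and 221 maps to 1).
    """

    standard_size: tuple[int, int] = (300, 450)
    coarse_size: tuple[int, int] = (50, 75)
    rotation_offset: int = 35
    wrap_modulus: int = 255

    def __post_init__(self) -> None:
        sw, sh = self.standard_size
        cw, ch = self.coarse_size
        if cw <= 0 or ch <= 0 or sw % cw or sh % ch or sw // cw != sh // ch:
            raise InvalidInputError(
                "coarse_size must divide standard_size by the same integer "
                f"factor on both axes, got {self.standard_size} vs "
                f"{self.coarse_size}"
            )

    @property
    def pyramid_factor(self) -> int:
        return self.standard_size[0] // self.coarse_size[0]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("standard_size", "coarse_size"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("rotation_offset", "wrap_modulus"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)


@dataclass
class RgbImage:
    """8-bit RGB raster, row-major, origin at the top-left corner."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidInputError(
                f"expected a nonempty HxWx3 array, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise InvalidInputError("channel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ChannelImage:
    """Single 8-bit intensity plane tagged with its provenance.

    ``channel_tag`` is ``"R"`` for the raw red plane and ``"R_rotated"``
    after the cyclic value rotation.
    """

    values: np.ndarray
    channel_tag: str = "R"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidInputError(f"expected a nonempty HxW array, got {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise InvalidInputError("channel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        if self.channel_tag not in ("R", "R_rotated"):
            raise InvalidInputError(f"unknown channel_tag {self.channel_tag!r}")
        self.values = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def standardize(image: RgbImage, config: PipelineConfig | None = None) -> RgbImage:
    """Resample an image to the working resolution.

    Bilinear interpolation with a Gaussian anti-aliasing prefilter on
    downsampling.  An image already at the target size is returned
    unchanged, pixel for pixel.
    """
    config = config or PipelineConfig()
    w, h = config.standard_size
    if image.height == h and image.width == w:
        return RgbImage(image.pixels.copy())
    out = resize(
        image.pixels.astype(np.float64),
        (h, w, 3),
        order=1,
        anti_aliasing=(image.height > h or image.width > w),
        preserve_range=True,
    )
    return RgbImage(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def extract_red(image: RgbImage) -> ChannelImage:
    """Return the first color plane as an R-tagged channel image."""
    return ChannelImage(image.pixels[:, :, 0].copy(), channel_tag="R")


def rotation_lut(config: PipelineConfig | None = None) -> np.ndarray:
    """256-entry lookup table of the channel-value rotation.

    v -> v + offset when v + offset <= wrap_modulus, else
    v + offset - wrap_modulus.  With the defaults (offset 35, top 255) this
    sends 220 to 255 and 221 to 1: the wrap subtracts 255, not 256.
    """
    config = config or PipelineConfig()
    v = np.arange(256, dtype=np.int32) + config.rotation_offset
    lut = np.where(v <= config.wrap_modulus, v, v - config.wrap_modulus)
    return lut.astype(np.uint8)


def rotate_channel(
    channel: ChannelImage, config: PipelineConfig | None = None
) -> ChannelImage:
    """Cyclically rotate R-component values so fruit occupies the top band."""
    if channel.channel_tag != "R":
        raise InvalidInputError("rotate_channel expects the un-rotated R channel")
    lut = rotation_lut(config)
    return ChannelImage(lut[channel.values], channel_tag="R_rotated")


def channel_histogram(channel: ChannelImage) -> np.ndarray:
    """256-bin histogram; bin k counts pixels of value exactly k."""
    return np.bincount(channel.values.ravel(), minlength=256).astype(np.int64)


def downsample_channel(
    channel: ChannelImage, size: tuple[int, int]
) -> ChannelImage:
    """Resample a channel to ``size`` = (width, height), bilinear."""
    w, h = size
    if channel.shape == (h, w):
        return ChannelImage(channel.values.copy(), channel.channel_tag)
    out = resize(
        channel.values.astype(np.float64),
        (h, w),
        order=1,
        anti_aliasing=(channel.shape[0] > h or channel.shape[1] > w),
        preserve_range=True,
    )
    return ChannelImage(
        np.clip(np.rint(out), 0, 255).astype(np.uint8), channel.channel_tag
    )


def read_rgb(path) -> RgbImage:
    """Read an 8-bit PNG/JPEG/TIFF file as an RGB image."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / corrupt file
        raise InvalidInputError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise InvalidInputError(f"{path!r} is not a 3-channel image")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RgbImage(arr)


def write_rgb(path, image: RgbImage) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, image.pixels)
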