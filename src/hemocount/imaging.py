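"""Image I/O and green/blue background masking.

HE-stained tissue is distinguished from empty slide regions by color:
eosin-pink tissue strongly absorbs in the green channel, hematoxylin-blue
structures absorb red/green, while bare slide (and hemolymph lumina) is
near-white, i.e. bright in *every* channel.  A pixel is therefore classified
as background iff it is simultaneously bright in the green AND the blue
channel; everything else is retained as tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "RGBImage",
    "BackgroundConfig",
    "read_image",
    "write_image",
    "background_mask",
]


@dataclass
class RGBImage:
    """8-bit RGB raster with optional physical pixel size.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    pixel_size_um : micrometers per pixel, or None if unknown
    id : source identifier (file stem or synthetic id)
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise FormatError(
                    f"expected 8-bit intensities in [0, 255], got dtype {px.dtype}"
                )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def field_area_mm2(self) -> float | None:
        """Physical field area in mm^2, if pixel size is known."""
        if self.pixel_size_um is None:
            return None
        h, w = self.shape
        return h * w * (self.pixel_size_um / 1000.0) ** 2


@dataclass
class BackgroundConfig:
    """Brightness thresholds above which a pixel counts as empty slide.

    Both default to 200/255: keeps eosin pink (suppressed green) while
    removing near-white lumina under standard HE illumination.
    """

    green_threshold: int = 200
    blue_threshold: int = 200

    def __post_init__(self) -> None:
        for name in ("green_threshold", "blue_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValidationError(f"{name}={v} outside [0, 255]")


def read_image(path: str | Path, pixel_size_um: float | None = None) -> RGBImage:
    """Read an 8-bit RGB PNG or TIFF.

    Grayscale, >8-bit, or non-3-channel files are rejected with a
    :class:`FormatError` naming the offending property.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except OSError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path}: bit depth {arr.dtype} not supported; 8-bit required"
        )
    if arr.ndim == 2:
        raise FormatError(f"{path}: grayscale image; 3-channel RGB required")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(
            f"{path}: expected 3 color channels, got shape {arr.shape}"
        )
    if arr.shape[2] == 4:  # tolerate opaque alpha, reject real transparency
        if not np.all(arr[:, :, 3] == 255):
            raise FormatError(f"{path}: transparent RGBA not supported")
        arr = arr[:, :, :3]
    return RGBImage(pixels=arr, pixel_size_um=pixel_size_um, id=path.stem)


def write_image(img: RGBImage, path: str | Path) -> None:
    """Write an RGBImage as PNG or TIFF (by extension), losslessly."""
    path = Path(path)
    iio.imwrite(path, img.pixels)


def background_mask(img: RGBImage, cfg: BackgroundConfig | None = None) -> np.ndarray:
    """Boolean mask, True on retained tissue pixels.

    A pixel is background (False) iff green >= green_threshold AND
    blue >= blue_threshold.
    """
    if cfg is None:
        cfg = BackgroundConfig()
    g = img.pixels[:, :, 1]
    b = img.pixels[:, :, 2]
    bg = (g >= cfg.green_threshold) & (b >= cfg.blue_threshold)
    return ~bg
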