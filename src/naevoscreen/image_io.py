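"""Raster I/O, scale-bar detection and physical calibration.

Photomicrographs carry a printed scale bar (typically 500 µm). Counting the
bar's pixel length gives the µm/pixel resolution, from which every area
quantification downstream is derived. Images are plain RGB uint8 arrays of
shape ``(height, width, 3)``; annotation masks are uint8 arrays of shape
``(height, width)`` with values ``0`` (unlabeled), ``1`` (C1, regular) and
``2`` (C2, anomalous).

Coordinate convention: row-major, origin top-left, 0-based, half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "CalibrationInfo",
    "ImageIOError",
    "MissingImageError",
    "UnsupportedImageError",
    "ScaleBarNotFoundError",
    "LABEL_UNLABELED",
    "LABEL_REGULAR",
    "LABEL_ANOMALOUS",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "detect_scale_bar",
    "calibrate",
]

LABEL_UNLABELED = 0
LABEL_REGULAR = 1
LABEL_ANOMALOUS = 2


class ImageIOError(Exception):
    """Base class for raster I/O and calibration failures."""


class MissingImageError(ImageIOError, FileNotFoundError):
    """The requested image file does not exist."""


class UnsupportedImageError(ImageIOError):
    """The file exists but is not a readable PNG/TIFF raster."""


class ScaleBarNotFoundError(ImageIOError):
    """No qualifying scale-bar run was found; manual calibration is required."""


@dataclass(frozen=True)
class CalibrationInfo:
    """Physical calibration of one image, derived from its scale bar.

    Attributes
    ----------
    scale_bar_length_px : float
        Length of the scale bar in pixels (>= 1). Detected bars are integer;
        a float is allowed so a calibration can be reconstructed from a known
        total area.
    scale_bar_microns : float
        Physical length the bar represents, in µm (500 by default).
    microns_per_pixel : float
        ``scale_bar_microns / scale_bar_length_px``.
    total_area_mm2 : float
        Physical area of the full image:
        ``width * height * microns_per_pixel**2 * 1e-6``.

    Calibration is stored per image, never globally: images scanned at
    different magnifications have different µm/pixel at identical pixel
    dimensions.
    """

    scale_bar_length_px: float
    scale_bar_microns: float
    microns_per_pixel: float
    total_area_mm2: float

    def __post_init__(self) -> None:
        for name in ("scale_bar_length_px", "scale_bar_microns",
                     "microns_per_pixel", "total_area_mm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.scale_bar_length_px < 1:
            raise ValueError("scale_bar_length_px must be >= 1")

    @classmethod
    def from_scale_bar(
        cls,
        width: int,
        height: int,
        scale_bar_length_px: float,
        scale_bar_microns: float = 500.0,
    ) -> "CalibrationInfo":
        if scale_bar_length_px < 1:
            raise ValueError("scale_bar_length_px must be >= 1")
        if scale_bar_microns <= 0:
            raise ValueError("scale_bar_microns must be > 0")
        mpp = scale_bar_microns / scale_bar_length_px
        return cls(
            scale_bar_length_px=float(scale_bar_length_px),
            scale_bar_microns=float(scale_bar_microns),
            microns_per_pixel=mpp,
            total_area_mm2=width * height * mpp**2 * 1e-6,
        )

    @classmethod
    def from_microns_per_pixel(
        cls,
        width: int,
        height: int,
        microns_per_pixel: float,
        scale_bar_microns: float = 500.0,
    ) -> "CalibrationInfo":
        """Manual calibration when no bar is detectable."""
        if microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        return cls.from_scale_bar(
            width, height, scale_bar_microns / microns_per_pixel, scale_bar_microns
        )

    @classmethod
    def from_total_area(
        cls,
        width: int,
        height: int,
        total_area_mm2: float,
        scale_bar_microns: float = 500.0,
    ) -> "CalibrationInfo":
        """Reconstruct a calibration from a known physical image area."""
        if total_area_mm2 <= 0:
            raise ValueError("total_area_mm2 must be > 0")
        mpp = float(np.sqrt(total_area_mm2 * 1e6 / (width * height)))
        return cls.from_microns_per_pixel(width, height, mpp, scale_bar_microns)

    def to_dict(self) -> dict:
        return {
            "scale_bar_length_px": self.scale_bar_length_px,
            "scale_bar_microns": self.scale_bar_microns,
            "microns_per_pixel": self.microns_per_pixel,
            "total_area_mm2": self.total_area_mm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationInfo":
        return cls(**{k: float(d[k]) for k in (
            "scale_bar_length_px", "scale_bar_microns",
            "microns_per_pixel", "total_area_mm2")})


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    return image


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF photomicrograph as an ``(H, W, 3)`` uint8 RGB array.

    Grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.

    Raises
    ------
    MissingImageError
        If *path* does not exist.
    UnsupportedImageError
        If the file cannot be decoded as a raster image.
    """
    path = Path(path)
    if not path.exists():
        raise MissingImageError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise UnsupportedImageError(f"cannot decode {path}: {exc}") from exc
    return _validate_rgb(arr)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an RGB uint8 array as PNG or TIFF (by extension)."""
    image = _validate_rgb(image)
    Image.fromarray(np.ascontiguousarray(image, dtype=np.uint8)).save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel annotation mask PNG with values {0, 1, 2}."""
    path = Path(path)
    if not path.exists():
        raise MissingImageError(f"mask file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise UnsupportedImageError(f"cannot decode {path}: {exc}") from exc
    bad = set(np.unique(arr)) - {LABEL_UNLABELED, LABEL_REGULAR, LABEL_ANOMALOUS}
    if bad:
        raise UnsupportedImageError(
            f"mask {path} contains values outside {{0,1,2}}: {sorted(bad)}"
        )
    return arr


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    Image.fromarray(mask, mode="L").save(Path(path))


def detect_scale_bar(
    image: np.ndarray,
    bar_color: tuple[int, int, int] = (0, 0, 0),
    tolerance: float = 40.0,
    min_run: int = 50,
) -> int:
    """Length in pixels of the longest horizontal run of bar-colored pixels.

    A pixel matches when each of its channels lies within *tolerance* of the
    corresponding *bar_color* channel. Bars thicker than one pixel count
    length only (the longest single-row run), not area. The detector is
    insensitive to the bar's vertical position.

    Raises
    ------
    ScaleBarNotFoundError
        If no run of at least *min_run* matching pixels exists.
    """
    image = _validate_rgb(image)
    color = np.asarray(bar_color, dtype=np.int16)
    match = np.all(
        np.abs(image.astype(np.int16) - color[None, None, :]) <= tolerance, axis=2
    )
    # Longest run per row via cumulative reset trick on the padded difference.
    padded = np.zeros((match.shape[0], match.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = match
    diff = np.diff(padded, axis=1)
    starts_r, starts_c = np.nonzero(diff == 1)
    ends_r, ends_c = np.nonzero(diff == -1)
    if starts_c.size == 0:
        raise ScaleBarNotFoundError(
            "no scale-bar run found; supply microns_per_pixel manually"
        )
    best = int((ends_c - starts_c).max())
    if best < min_run:
        raise ScaleBarNotFoundError(
            f"longest candidate run is {best} px (< min_run={min_run}); "
            "supply microns_per_pixel manually"
        )
    return best


def calibrate(
    image: np.ndarray,
    scale_bar_length_px: float,
    scale_bar_microns: float = 500.0,
) -> CalibrationInfo:
    """Derive the physical calibration of *image* from its scale-bar length."""
    image = _validate_rgb(image)
    height, width = image.shape[:2]
    return CalibrationInfo.from_scale_bar(
        width, height, scale_bar_length_px, scale_bar_microns
    )
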