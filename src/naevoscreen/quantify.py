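"""Quantitative indicators derived from a probability map.

The pre-screening indicator is the *equivalent area*: pixels whose C2
(anomalous) probability strictly exceeds the red threshold (default 0.38)
are counted as "red"; under scale-bar calibration the count converts to a
physical area in mm² and then to a percentage of the image's total area.
That percentage is what the triage rule compares against its 12% threshold.

Tie-break: the threshold inequality is strict (``p_c2 > threshold``) and the
red count is taken from the probability map itself, never re-counted from
the rendered red-on-black overlay (which is a presentation artifact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ProbabilityMap
from .image_io import CalibrationInfo, _validate_rgb

__all__ = [
    "RedPixelQuantification",
    "RGBHistogram",
    "red_filter",
    "equivalent_area",
    "percentage_indicator",
    "quantify_case",
    "rgb_histogram",
    "render_red_overlay",
]

DEFAULT_RED_THRESHOLD = 0.38


@dataclass(frozen=True)
class RedPixelQuantification:
    """One image's quantification: red-pixel count, equivalent area (mm²)
    and equivalent-area percentage of the total calibrated image area."""

    red_threshold: float
    red_pixel_count: int
    equivalent_area_mm2: float
    equivalent_area_pct: float
    total_area_mm2: float

    def to_dict(self) -> dict:
        return {
            "red_threshold": self.red_threshold,
            "red_pixel_count": self.red_pixel_count,
            "equivalent_area_mm2": self.equivalent_area_mm2,
            "equivalent_area_pct": self.equivalent_area_pct,
            "total_area_mm2": self.total_area_mm2,
        }


@dataclass
class RGBHistogram:
    """3-D RGB color histogram: counts of pixels per (R, G, B) bin."""

    bins: dict[tuple[int, int, int], int]
    bin_width: int

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"r_bin": r, "g_bin": g, "b_bin": b, "count": c}
            for (r, g, b), c in sorted(self.bins.items())
        ]
        return pd.DataFrame(rows, columns=["r_bin", "g_bin", "b_bin", "count"])


def _threshold(prob: ProbabilityMap | np.ndarray, red_threshold: float) -> np.ndarray:
    if not 0 < red_threshold < 1:
        raise ValueError("red_threshold must lie in (0, 1)")
    p_c2 = prob.p_c2 if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    return p_c2 > red_threshold


def red_filter(
    prob: ProbabilityMap | np.ndarray,
    red_threshold: float = DEFAULT_RED_THRESHOLD,
) -> tuple[np.ndarray, int]:
    """Red mask (``p_c2`` strictly above threshold) and red-pixel count."""
    mask = _threshold(prob, red_threshold)
    return mask, int(mask.sum())


def equivalent_area(
    red_pixel_count: int,
    calibration: CalibrationInfo,
    width: int,
    height: int,
) -> float:
    """Physical area (mm²) of ``red_pixel_count`` pixels:
    ``count * total_area_mm2 / (width * height)``."""
    n_pixels = width * height
    if red_pixel_count < 0 or red_pixel_count > n_pixels:
        raise ValueError(
            f"red_pixel_count {red_pixel_count} outside [0, {n_pixels}]"
        )
    return red_pixel_count * calibration.total_area_mm2 / n_pixels


def percentage_indicator(equivalent_area_mm2: float, total_area_mm2: float) -> float:
    """Equivalent area as a percentage of the total image area."""
    if total_area_mm2 <= 0:
        raise ValueError("total_area_mm2 must be > 0")
    if not 0 <= equivalent_area_mm2 <= total_area_mm2 * (1 + 1e-12):
        raise ValueError("equivalent area must lie in [0, total_area_mm2]")
    return 100.0 * equivalent_area_mm2 / total_area_mm2


def quantify_case(
    prob: ProbabilityMap,
    calibration: CalibrationInfo,
    red_threshold: float = DEFAULT_RED_THRESHOLD,
) -> RedPixelQuantification:
    """Full quantification of one probability map under a calibration."""
    _, count = red_filter(prob, red_threshold)
    area = equivalent_area(count, calibration, prob.width, prob.height)
    pct = percentage_indicator(area, calibration.total_area_mm2)
    return RedPixelQuantification(
        red_threshold=red_threshold,
        red_pixel_count=count,
        equivalent_area_mm2=area,
        equivalent_area_pct=pct,
        total_area_mm2=calibration.total_area_mm2,
    )


def rgb_histogram(image: np.ndarray, bin_width: int = 32) -> RGBHistogram:
    """Count pixels per 3-D RGB color bin; total count equals pixel count."""
    image = _validate_rgb(image)
    if bin_width < 1 or 256 % bin_width != 0:
        raise ValueError("bin_width must divide 256 evenly")
    binned = image.astype(np.int64) // bin_width
    flat = binned.reshape(-1, 3)
    keys, counts = np.unique(flat, axis=0, return_counts=True)
    return RGBHistogram(
        bins={tuple(int(v) for v in k): int(c) for k, c in zip(keys, counts)},
        bin_width=bin_width,
    )


def render_red_overlay(red_mask: np.ndarray) -> np.ndarray:
    """Red pixels as pure red on a black background (presentation artifact)."""
    red_mask = np.asarray(red_mask, dtype=bool)
    overlay = np.zeros(red_mask.shape + (3,), dtype=np.uint8)
    overlay[red_mask, 0] = 255
    return overlay
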