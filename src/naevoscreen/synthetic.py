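"""Synthetic H&E-like photomicrographs with ground truth.

No real slide images are distributed with this package, so every other
module is exercised on stylized hematoxylin-and-eosin lookalikes: an
eosin-pink textured background, purple elliptical nuclei scattered at a
tissue-like density, and one or more blob-shaped *anomalous* regions where
nuclei are denser, darker and angulated (polygonal) — the nucleus-level
cues a pathologist associates with worrying cellularity. A black scale bar
of known pixel length is drawn bottom-left, and a ground-truth mask marks
the anomalous region (C2) against everything else (C1).

Anomalous regions are carved by thresholding a smoothed Gaussian random
field at the quantile matching the requested area fraction, so the realized
fraction tracks the request up to pixel discreteness. All randomness flows
through one ``numpy.random.Generator`` seeded per case; identical specs and
seeds give byte-identical images.

These fixtures are stylized, not photorealistic: the pipeline's acceptance
surface is calibration arithmetic and parameter recovery, not diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .image_io import LABEL_ANOMALOUS, LABEL_REGULAR, save_image, save_mask

__all__ = ["SyntheticSpec", "SyntheticCase", "generate_case",
           "generate_cohort", "write_case"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic case.

    Defaults mirror the acquisition geometry of the screening study the
    pipeline targets: 1920 × 1088 px at 2.5 µm/pixel with a 500 µm scale
    bar (hence a 200 px bar). ``nucleus_density`` is nuclei per mm² of
    tissue; inside anomalous regions density is multiplied by
    ``anomalous_density_factor`` and nuclei switch to the darker color and
    polygonal outline.
    """

    width: int = 1920
    height: int = 1088
    microns_per_pixel: float = 2.5
    scale_bar_microns: float = 500.0
    background_color: tuple[int, int, int] = (230, 180, 200)
    nucleus_color: tuple[int, int, int] = (95, 65, 145)
    anomalous_nucleus_color: tuple[int, int, int] = (55, 30, 95)
    nucleus_density: float = 1500.0
    anomalous_density_factor: float = 3.0
    anomalous_fraction: float = 0.0
    nucleus_radius_range: tuple[float, float] = (3.0, 7.0)  # microns
    noise_sd: float = 8.0
    texture_sd: float = 10.0
    anomalous_darkening: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.anomalous_fraction <= 0.9:
            raise ValueError("anomalous_fraction must lie in [0, 0.9]")
        if self.microns_per_pixel <= 0 or self.scale_bar_microns <= 0:
            raise ValueError("calibration parameters must be positive")
        lo, hi = self.nucleus_radius_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus_radius_range must be increasing and positive")
        if hi / self.microns_per_pixel * 2 > min(self.width, self.height):
            raise ValueError("nucleus radius exceeds image size")
        for color in (self.background_color, self.nucleus_color,
                      self.anomalous_nucleus_color):
            if len(color) != 3 or any(not 0 <= c <= 255 for c in color):
                raise ValueError(f"invalid RGB color: {color}")

    @property
    def scale_bar_length_px(self) -> int:
        return int(round(self.scale_bar_microns / self.microns_per_pixel))

    @property
    def area_mm2(self) -> float:
        return self.width * self.height * self.microns_per_pixel**2 * 1e-6


@dataclass
class SyntheticCase:
    """A generated fixture: image, truth mask (C2 = anomalous region),
    realized anomalous fraction, anomalous nucleus centroids and the
    drawn scale-bar geometry."""

    image: np.ndarray
    truth_mask: np.ndarray
    true_anomalous_fraction: float
    anomalous_centroids: np.ndarray  # (n, 2) row, col
    scale_bar_length_px: int
    scale_bar_row: int
    spec: SyntheticSpec
    case_id: str = ""


def _anomalous_region(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped boolean mask covering ~anomalous_fraction of the image."""
    if spec.anomalous_fraction <= 0:
        return np.zeros((spec.height, spec.width), dtype=bool)
    field_ = rng.standard_normal((spec.height, spec.width))
    sigma = max(min(spec.height, spec.width) / 8.0, 2.0)
    smooth = ndimage.gaussian_filter(field_, sigma, mode="reflect")
    cut = np.quantile(smooth, 1.0 - spec.anomalous_fraction)
    return smooth > cut


def _draw_nucleus_ellipse(
    image: np.ndarray, r: float, c: float, radius_px: float,
    color: np.ndarray, rng: np.random.Generator,
) -> None:
    ratio = rng.uniform(0.6, 1.0)
    rot = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(
        r, c, radius_px, radius_px * ratio,
        shape=image.shape[:2], rotation=rot,
    )
    jitter = rng.integers(-12, 13, size=3)
    image[rr, cc] = np.clip(color + jitter, 0, 255)


def _draw_nucleus_polygon(
    image: np.ndarray, r: float, c: float, radius_px: float,
    color: np.ndarray, rng: np.random.Generator,
) -> None:
    n_vert = int(rng.integers(5, 8))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
    radii = radius_px * rng.uniform(0.6, 1.25, size=n_vert)
    rr, cc = draw_polygon(
        r + radii * np.sin(angles), c + radii * np.cos(angles),
        shape=image.shape[:2],
    )
    jitter = rng.integers(-12, 13, size=3)
    image[rr, cc] = np.clip(color + jitter, 0, 255)


def generate_case(spec: SyntheticSpec, case_id: str = "") -> SyntheticCase:
    """Render one synthetic case, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # eosin background with low-frequency texture
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = spec.background_color
    texture = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), max(min(h, w) / 32.0, 1.0), mode="reflect"
    )
    if texture.std() > 0:
        texture = texture / texture.std() * spec.texture_sd
    image += texture[..., None]

    region = _anomalous_region(spec, rng)
    # mild regional darkening: the increased-cellularity haze of a dense focus
    image[region] *= 1.0 - spec.anomalous_darkening

    radius_lo, radius_hi = (
        r / spec.microns_per_pixel for r in spec.nucleus_radius_range
    )
    nucleus_color = np.asarray(spec.nucleus_color, dtype=np.int64)
    anomalous_color = np.asarray(spec.anomalous_nucleus_color, dtype=np.int64)

    # regular nuclei everywhere at base density
    n_regular = rng.poisson(spec.nucleus_density * spec.area_mm2)
    for _ in range(n_regular):
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        _draw_nucleus_ellipse(
            image, r, c, rng.uniform(radius_lo, radius_hi), nucleus_color, rng
        )

    # denser, darker, angulated nuclei inside the anomalous region
    centroids: list[tuple[float, float]] = []
    region_area_mm2 = region.sum() * spec.microns_per_pixel**2 * 1e-6
    extra_density = spec.nucleus_density * (spec.anomalous_density_factor - 1.0)
    n_anom = rng.poisson(max(extra_density, 0.0) * region_area_mm2)
    placed = 0
    attempts = 0
    while placed < n_anom and attempts < 50 * max(n_anom, 1):
        attempts += 1
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        if not region[int(r), int(c)]:
            continue
        _draw_nucleus_polygon(
            image, r, c, rng.uniform(radius_lo, radius_hi), anomalous_color, rng
        )
        centroids.append((r, c))
        placed += 1

    image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255)

    # scale bar: black, bottom-left, above a small margin
    bar_len = spec.scale_bar_length_px
    bar_thickness = max(2, h // 250)
    margin = max(8, h // 50)
    bar_row = h - margin - bar_thickness
    bar_col = margin
    if bar_col + bar_len > w:
        raise ValueError("scale bar does not fit in the image width")
    image[bar_row : bar_row + bar_thickness, bar_col : bar_col + bar_len] = 0

    truth = np.where(region, LABEL_ANOMALOUS, LABEL_REGULAR).astype(np.uint8)
    return SyntheticCase(
        image=image.astype(np.uint8),
        truth_mask=truth,
        true_anomalous_fraction=float(region.mean()),
        anomalous_centroids=np.asarray(centroids, dtype=np.float64).reshape(-1, 2),
        scale_bar_length_px=bar_len,
        scale_bar_row=bar_row,
        spec=spec,
        case_id=case_id,
    )


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    benign_fraction_range: tuple[float, float] = (0.01, 0.05),
    malignant_fraction_range: tuple[float, float] = (0.15, 0.30),
) -> list[SyntheticCase]:
    """Generate a cohort of benign and malignant-like cases.

    Benign cases draw their anomalous fraction from
    ``benign_fraction_range`` (well under the 12% triage threshold),
    malignant-like cases from ``malignant_fraction_range`` (well over it).
    Per-case seeds derive deterministically from ``seed``.
    """
    if n_benign < 0 or n_malignant < 0 or n_benign + n_malignant < 1:
        raise ValueError("cohort must contain at least one case")
    base = base_spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_benign + n_malignant):
        benign = i < n_benign
        lo, hi = benign_fraction_range if benign else malignant_fraction_range
        frac = float(rng.uniform(lo, hi))
        case_seed = int(rng.integers(0, 2**31 - 1))
        label = "benign" if benign else "malig"
        idx = i if benign else i - n_benign
        spec = replace(base, anomalous_fraction=frac, seed=case_seed)
        cases.append(generate_case(spec, case_id=f"{label}_{idx:02d}"))
    return cases


def write_case(case: SyntheticCase, out_dir: str | Path) -> dict:
    """Write image + truth mask PNGs; return a manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id or "case"
    image_path = out_dir / f"{cid}.png"
    mask_path = out_dir / f"{cid}_truth.png"
    save_image(image_path, case.image)
    save_mask(mask_path, case.truth_mask)
    return {
        "case_id": cid,
        "image": image_path.name,
        "truth_mask": mask_path.name,
        "true_fraction": case.true_anomalous_fraction,
        "scale_bar_px": case.scale_bar_length_px,
        "seed": case.spec.seed,
    }


def write_cohort(cases: list[SyntheticCase], out_dir: str | Path) -> pd.DataFrame:
    """Write a cohort and its manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    manifest = pd.DataFrame([write_case(c, out_dir) for c in cases])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
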