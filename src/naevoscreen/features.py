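"""Per-pixel feature stack from a multi-scale filter bank.

The pixel classifier sees each pixel as a feature vector built from five
filter families applied to the grayscale projection of the image: Gaussian
blur, Sobel gradient magnitude, Hessian eigenvalues, difference of Gaussians
and membrane projections — plus the raw R/G/B/gray intensities. Scales form
a powers-of-two ladder between a minimum and maximum sigma (defaults 1 and
16), the convention of trainable-segmentation tools this pipeline follows.

With the defaults (5 sigmas) the stack has exactly 40 named channels:
4 raw + 5 Gaussian + 5 Sobel + 10 Hessian + 10 DoG + 6 membrane.

Design choices (documented, not canonical):

* filters operate on the ITU-R 601 luma grayscale; raw RGB is kept as three
  extra channels rather than filtering per channel;
* reflect padding for every convolution;
* DoG sign convention ``blur(sigma_small) - blur(sigma_large)``;
* Hessian channels are the two eigenvalues per scale, larger first, computed
  with Gaussian-derivative kernels (so smoothing and differentiation commute);
* membrane projections rotate a centered-line kernel through 180° in 30
  steps of 6° and reduce the rotation stack with sum/mean/std/median/max/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import _validate_rgb

__all__ = [
    "ALL_FILTER_TYPES",
    "FilterConfig",
    "FeatureStack",
    "MultiscaleFilterBank",
    "sigma_scales",
    "membrane_kernels",
    "membrane_projections",
    "build_feature_stack",
]

ALL_FILTER_TYPES = (
    "gaussian_blur",
    "hessian",
    "membrane_projections",
    "sobel",
    "difference_of_gaussians",
)

#: reductions applied across the membrane-kernel rotation stack, in channel order
MEMBRANE_PROJECTIONS = ("sum", "mean", "std", "median", "max", "min")


def sigma_scales(min_sigma: float, max_sigma: float) -> list[float]:
    """Powers-of-two sigma ladder: ``min_sigma * 2**k`` for all k with the
    product ``<= max_sigma``.

    ``(1, 16) -> [1, 2, 4, 8, 16]``; ``(1, 1) -> [1]``.
    """
    if min_sigma <= 0:
        raise ValueError("min_sigma must be > 0")
    if min_sigma > max_sigma:
        raise ValueError("min_sigma must not exceed max_sigma")
    out = []
    s = float(min_sigma)
    while s <= max_sigma * (1 + 1e-12):
        out.append(s)
        s *= 2.0
    return out


@dataclass(frozen=True)
class FilterConfig:
    """Filter-bank configuration.

    ``membrane_patch_size`` must be odd and at least ``membrane_thickness``;
    sigmas must satisfy ``0 < min_sigma <= max_sigma``.
    """

    filter_types: tuple[str, ...] = ALL_FILTER_TYPES
    membrane_thickness: float = 1.0
    membrane_patch_size: int = 19
    min_sigma: float = 1.0
    max_sigma: float = 16.0
    n_rotations: int = 30
    include_raw_channels: bool = True

    def __post_init__(self) -> None:
        if not self.filter_types:
            raise ValueError("filter_types must be non-empty")
        unknown = set(self.filter_types) - set(ALL_FILTER_TYPES)
        if unknown:
            raise ValueError(f"unknown filter types: {sorted(unknown)}")
        if not 0 < self.min_sigma <= self.max_sigma:
            raise ValueError("require 0 < min_sigma <= max_sigma")
        if self.membrane_patch_size % 2 == 0:
            raise ValueError("membrane_patch_size must be odd")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")
        if self.membrane_patch_size < self.membrane_thickness:
            raise ValueError("membrane_patch_size must be >= membrane_thickness")
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")

    @property
    def sigmas(self) -> list[float]:
        return sigma_scales(self.min_sigma, self.max_sigma)

    def to_dict(self) -> dict:
        return {
            "filter_types": list(self.filter_types),
            "membrane_thickness": self.membrane_thickness,
            "membrane_patch_size": self.membrane_patch_size,
            "min_sigma": self.min_sigma,
            "max_sigma": self.max_sigma,
            "n_rotations": self.n_rotations,
            "include_raw_channels": self.include_raw_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        d["filter_types"] = tuple(d.get("filter_types", ALL_FILTER_TYPES))
        return cls(**d)


@dataclass
class FeatureStack:
    """Per-pixel feature vectors: ``values`` has shape ``(H, W, n_features)``
    (float32) and ``channel_names`` labels the last axis."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be (H, W, C)")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature stack contains non-finite values")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Row-major ``(H*W, n_features)`` view for classifier consumption."""
        return self.values.reshape(-1, self.n_features)


def _sig(s: float) -> str:
    return f"{s:g}"


def grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma projection, float64 in [0, 255]."""
    image = _validate_rgb(image).astype(np.float64)
    return 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]


def membrane_kernels(
    thickness: float = 1.0, patch_size: int = 19, n_rotations: int = 30
) -> np.ndarray:
    """Rotated line kernels, shape ``(n_rotations, patch_size, patch_size)``.

    Each kernel is a line of the given thickness through the patch center,
    at angle ``k * 180° / n_rotations``; a pixel belongs to the line when
    its center lies within ``thickness / 2`` of the line's axis. Kernels
    are normalized to unit sum so rotations of a constant image respond
    identically (and the std projection vanishes on constants).
    """
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    half = patch_size // 2
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = np.empty((n_rotations, patch_size, patch_size))
    for k in range(n_rotations):
        theta = np.pi * k / n_rotations
        # perpendicular distance to a line through the origin at angle theta
        dist = np.abs(dx * np.sin(theta) - dy * np.cos(theta))
        line = (dist <= thickness / 2.0).astype(np.float64)
        kernels[k] = line / line.sum()
    return kernels


def membrane_projections(
    gray: np.ndarray,
    thickness: float = 1.0,
    patch_size: int = 19,
    n_rotations: int = 30,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Six membrane-projection channels of a single-channel image.

    Convolves with each rotated line kernel (reflect padding) and reduces
    the rotation stack pixel-wise with sum, mean, std, median, max and min.
    Returns ``(H, W, 6)`` and the channel names.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("membrane_projections expects a single-channel image")
    kernels = membrane_kernels(thickness, patch_size, n_rotations)
    responses = np.stack(
        [ndimage.convolve(gray, k, mode="reflect") for k in kernels], axis=0
    )
    channels = np.stack(
        [
            responses.sum(axis=0),
            responses.mean(axis=0),
            responses.std(axis=0),
            np.median(responses, axis=0),
            responses.max(axis=0),
            responses.min(axis=0),
        ],
        axis=-1,
    )
    names = tuple(f"membrane_{p}" for p in MEMBRANE_PROJECTIONS)
    return channels, names


def _hessian_eigenvalues(gray: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (larger, smaller) of the Hessian of the Gaussian-smoothed
    image. Central differences of the smoothed surface (rather than sampled
    Gaussian-derivative kernels) reproduce polynomial curvature exactly."""
    smoothed = ndimage.gaussian_filter(gray, sigma, mode="reflect")
    grad_r, grad_c = np.gradient(smoothed)
    hrr, hrc = np.gradient(grad_r)
    hcc = np.gradient(grad_c, axis=1)
    mean = 0.5 * (hrr + hcc)
    radius = np.sqrt((0.5 * (hrr - hcc)) ** 2 + hrc**2)
    return mean + radius, mean - radius


def _sobel_magnitude(smoothed: np.ndarray) -> np.ndarray:
    gr = ndimage.sobel(smoothed, axis=0, mode="reflect")
    gc = ndimage.sobel(smoothed, axis=1, mode="reflect")
    return np.hypot(gr, gc)


def build_feature_stack(
    image: np.ndarray, config: FilterConfig | None = None
) -> FeatureStack:
    """Compute the full feature stack of an RGB image.

    Channel order is fixed: raw R/G/B/gray (if enabled), then per sigma the
    Gaussian blur, then per sigma the Sobel magnitude of the blurred image,
    then per sigma the two Hessian eigenvalues (larger first), then the
    difference of Gaussians for every ordered sigma pair, then the six
    membrane projections. Identical inputs and config give bit-identical
    stacks.
    """
    config = config or FilterConfig()
    image = _validate_rgb(image)
    gray = grayscale(image)
    sigmas = config.sigmas

    channels: list[np.ndarray] = []
    names: list[str] = []

    if config.include_raw_channels:
        channels += [image[..., 0].astype(np.float64),
                     image[..., 1].astype(np.float64),
                     image[..., 2].astype(np.float64),
                     gray]
        names += ["red", "green", "blue", "gray"]

    blurred = {
        s: ndimage.gaussian_filter(gray, s, mode="reflect") for s in sigmas
    }

    if "gaussian_blur" in config.filter_types:
        for s in sigmas:
            channels.append(blurred[s])
            names.append(f"gaussian_s{_sig(s)}")

    if "sobel" in config.filter_types:
        for s in sigmas:
            channels.append(_sobel_magnitude(blurred[s]))
            names.append(f"sobel_s{_sig(s)}")

    if "hessian" in config.filter_types:
        for s in sigmas:
            hi, lo = _hessian_eigenvalues(gray, s)
            channels += [hi, lo]
            names += [f"hessian_eig1_s{_sig(s)}", f"hessian_eig2_s{_sig(s)}"]

    if "difference_of_gaussians" in config.filter_types:
        for i, si in enumerate(sigmas):
            for sj in sigmas[i + 1 :]:
                channels.append(blurred[si] - blurred[sj])
                names.append(f"dog_s{_sig(si)}_s{_sig(sj)}")

    if "membrane_projections" in config.filter_types:
        memb, memb_names = membrane_projections(
            gray,
            thickness=config.membrane_thickness,
            patch_size=config.membrane_patch_size,
            n_rotations=config.n_rotations,
        )
        channels += [memb[..., i] for i in range(memb.shape[-1])]
        names += list(memb_names)

    if not channels:
        raise ValueError("configuration produced no feature channels")

    stack = np.stack(channels, axis=-1).astype(np.float32)
    return FeatureStack(values=stack, channel_names=tuple(names))


class MultiscaleFilterBank(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`build_feature_stack`.

    Stateless apart from its parameters; ``fit`` validates and records the
    channel names, ``transform`` maps an ``(H, W, 3)`` uint8 image to a
    :class:`FeatureStack`.
    """

    def __init__(
        self,
        filter_types: tuple[str, ...] = ALL_FILTER_TYPES,
        membrane_thickness: float = 1.0,
        membrane_patch_size: int = 19,
        min_sigma: float = 1.0,
        max_sigma: float = 16.0,
        n_rotations: int = 30,
        include_raw_channels: bool = True,
    ) -> None:
        self.filter_types = filter_types
        self.membrane_thickness = membrane_thickness
        self.membrane_patch_size = membrane_patch_size
        self.min_sigma = min_sigma
        self.max_sigma = max_sigma
        self.n_rotations = n_rotations
        self.include_raw_channels = include_raw_channels

    def _config(self) -> FilterConfig:
        return FilterConfig(
            filter_types=tuple(self.filter_types),
            membrane_thickness=self.membrane_thickness,
            membrane_patch_size=self.membrane_patch_size,
            min_sigma=self.min_sigma,
            max_sigma=self.max_sigma,
            n_rotations=self.n_rotations,
            include_raw_channels=self.include_raw_channels,
        )

    def fit(self, X=None, y=None) -> "MultiscaleFilterBank":
        config = self._config()  # validates parameters
        probe = build_feature_stack(
            np.zeros((config.membrane_patch_size, config.membrane_patch_size, 3),
                     dtype=np.uint8),
            config,
        )
        self.channel_names_ = probe.channel_names
        self.n_features_out_ = probe.n_features
        return self

    def transform(self, X: np.ndarray) -> FeatureStack:
        return build_feature_stack(X, self._config())
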