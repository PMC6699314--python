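"""On-the-fly paired image/label augmentation.

Each training minibatch item gets an independently sampled random
combination of transforms: an affine map (scaling, rotation, shearing,
translation, composed about the image center), elastic deformation,
Gaussian noise, and Gaussian blur.  Geometry is applied identically to the
image (bilinear interpolation, out-of-bounds fill 0) and its label map
(nearest-neighbor, fill = background).  Intensity corruption applies to
the image only.  Augmented items exist only in memory for the duration of
one minibatch; nothing is ever written to disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import BACKGROUND, GrayImage, LabelMap
from .errors import ContractError


@dataclass
class AugmentConfig:
    """Ranges and per-transform application probabilities.

    Angles in degrees, translations and elastic amplitudes in pixels, noise
    sigma on the unit intensity scale.  Each transform is included
    independently with probability ``p_*``; parameters are drawn uniformly
    from their ranges.
    """

    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    shear_range: tuple[float, float] = (-8.0, 8.0)
    translation_range: tuple[float, float] = (-10.0, 10.0)
    noise_sigma_range: tuple[float, float] = (0.0, 0.03)
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    elastic_alpha_range: tuple[float, float] = (0.0, 10.0)
    elastic_sigma_range: tuple[float, float] = (4.0, 8.0)
    p_affine: float = 0.5
    p_noise: float = 0.5
    p_blur: float = 0.5
    p_elastic: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_affine", "p_noise", "p_blur", "p_elastic"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1], got {p}")
        for name in (
            "scale_range",
            "rotation_range",
            "shear_range",
            "translation_range",
            "noise_sigma_range",
            "blur_sigma_range",
            "elastic_alpha_range",
            "elastic_sigma_range",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ContractError(f"{name} must be a finite interval, got ({lo}, {hi})")

    @classmethod
    def none(cls) -> "AugmentConfig":
        """A configuration that never applies any transform."""
        return cls(p_affine=0.0, p_noise=0.0, p_blur=0.0, p_elastic=0.0)


@dataclass
class TransformSpec:
    """The concrete sampled parameters of one item's transform.

    Neutral values (the defaults) encode the identity; a spec fully
    determines the transform, so storing it reproduces the augmented item.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    shear_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (rows, cols)
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    elastic_alpha: float = 0.0
    elastic_sigma: float = 1.0
    elastic_seed: int = 0
    noise_seed: int = 0

    @property
    def is_identity(self) -> bool:
        return (
            self.scale == 1.0
            and self.rotation_deg == 0.0
            and self.shear_deg == 0.0
            and self.translation == (0.0, 0.0)
            and self.noise_sigma == 0.0
            and self.blur_sigma == 0.0
            and self.elastic_alpha == 0.0
        )

    @property
    def has_affine(self) -> bool:
        return not (
            self.scale == 1.0
            and self.rotation_deg == 0.0
            and self.shear_deg == 0.0
            and self.translation == (0.0, 0.0)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        d = dict(d)
        d["translation"] = tuple(d["translation"])
        return cls(**d)


def sample_transform(config: AugmentConfig, rng: np.random.Generator) -> TransformSpec:
    """Draw one random combination of transforms from the configuration.

    Every random decision consumes draws from ``rng`` in a fixed order, so
    an identical generator state yields an identical spec.
    """
    spec = TransformSpec()
    if rng.random() < config.p_affine:
        spec.scale = float(rng.uniform(*config.scale_range))
        spec.rotation_deg = float(rng.uniform(*config.rotation_range))
        spec.shear_deg = float(rng.uniform(*config.shear_range))
        spec.translation = (
            float(rng.uniform(*config.translation_range)),
            float(rng.uniform(*config.translation_range)),
        )
    if rng.random() < config.p_noise:
        spec.noise_sigma = float(rng.uniform(*config.noise_sigma_range))
        spec.noise_seed = int(rng.integers(0, 2**31 - 1))
    if rng.random() < config.p_blur:
        spec.blur_sigma = float(rng.uniform(*config.blur_sigma_range))
    if rng.random() < config.p_elastic:
        spec.elastic_alpha = float(rng.uniform(*config.elastic_alpha_range))
        spec.elastic_sigma = float(rng.uniform(*config.elastic_sigma_range))
        spec.elastic_seed = int(rng.integers(0, 2**31 - 1))
    return spec


def _forward_affine_matrix(spec: TransformSpec, shape: tuple[int, int]) -> np.ndarray:
    """Homogeneous forward map (input -> output coords) about the center."""
    theta = np.deg2rad(spec.rotation_deg)
    sh = np.tan(np.deg2rad(spec.shear_deg))
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, 0.0], [sh, 1.0]])
    lin = spec.scale * rot @ shear
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    offset = center + np.asarray(spec.translation) - lin @ center
    mat = np.eye(3)
    mat[:2, :2] = lin
    mat[:2, 2] = offset
    return mat


def _elastic_field(
    shape: tuple[int, int], alpha: float, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random displacement field: smoothed white noise rescaled to unit
    standard deviation, then scaled by ``alpha`` pixels."""
    fields = []
    for _ in range(2):
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
        std = smooth.std()
        fields.append(smooth / std * alpha if std > 0 else np.zeros(shape))
    return fields[0], fields[1]


def _resample_pair(
    image: np.ndarray, label: np.ndarray, coords: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    img_out = ndimage.map_coordinates(
        image.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    lab_out = ndimage.map_coordinates(
        label, coords, order=0, mode="constant", cval=BACKGROUND
    )
    return img_out, lab_out


def apply_transform_arrays(
    image: np.ndarray, label: np.ndarray, spec: TransformSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level core of :func:`apply_transform` (unit-float image)."""
    if image.shape != label.shape:
        raise ContractError(f"image shape {image.shape} != label shape {label.shape}")
    if spec.is_identity:
        return image.copy(), label.copy()

    img, lab = np.asarray(image, dtype=np.float64), np.asarray(label)
    shape = img.shape
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    src_r, src_c = rr, cc
    if spec.has_affine:
        inv = np.linalg.inv(_forward_affine_matrix(spec, shape))
        src_r = inv[0, 0] * rr + inv[0, 1] * cc + inv[0, 2]
        src_c = inv[1, 0] * rr + inv[1, 1] * cc + inv[1, 2]
    if spec.elastic_alpha > 0:
        erng = np.random.default_rng(spec.elastic_seed)
        dr, dc = _elastic_field(shape, spec.elastic_alpha, spec.elastic_sigma, erng)
        src_r, src_c = src_r + dr, src_c + dc
    if spec.has_affine or spec.elastic_alpha > 0:
        img, lab = _resample_pair(img, lab, (src_r, src_c))
    else:
        img, lab = img.copy(), lab.copy()

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="reflect")
    if spec.noise_sigma > 0:
        nrng = np.random.default_rng(spec.noise_seed)
        img = img + nrng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), lab


def apply_transform(
    image: GrayImage, label: LabelMap, spec: TransformSpec
) -> tuple[GrayImage, LabelMap]:
    """Apply one sampled transform to a unit-float image and its label map.

    The same geometric map resamples both grids — bilinearly for the image,
    nearest-neighbor for the label — then blur and noise corrupt the image
    only.  Out-of-bounds image pixels fill with 0, labels with background.
    """
    if image.bit_depth != "float":
        raise ContractError("apply_transform expects a unit-float image")
    img, lab = apply_transform_arrays(image.pixels, label.labels, spec)
    return GrayImage(img, "float", image.spacing_mm), LabelMap(lab.astype(np.int64))


def elastic_deform(
    image: GrayImage,
    label: LabelMap,
    alpha: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[GrayImage, LabelMap]:
    """Elastic deformation alone: smoothed-noise displacement of amplitude
    ``alpha`` pixels and smoothness ``sigma``; ``alpha=0`` is the identity."""
    if alpha < 0 or sigma <= 0:
        raise ContractError("alpha must be >= 0 and sigma > 0")
    if image.shape != label.shape:
        raise ContractError("image and label shapes differ")
    if alpha == 0:
        return (
            GrayImage(image.pixels.copy(), image.bit_depth, image.spacing_mm),
            LabelMap(label.labels.copy()),
        )
    shape = image.shape
    dr, dc = _elastic_field(shape, alpha, sigma, rng)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    img, lab = _resample_pair(image.pixels, label.labels, (rr + dr, cc + dc))
    return GrayImage(np.clip(img, 0.0, 1.0), "float", image.spacing_mm), LabelMap(
        lab.astype(np.int64)
    )


def augment_minibatch_arrays(
    images: np.ndarray,
    labels: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[TransformSpec]]:
    """Augment a stacked minibatch (N, H, W).  One independent spec per item;
    inputs are left untouched and outputs are fresh arrays."""
    if images.shape != labels.shape:
        raise ContractError("image and label batches must have matching shapes")
    out_imgs = np.empty_like(images, dtype=np.float32)
    out_labs = np.empty_like(labels)
    specs = [sample_transform(config, rng) for _ in range(images.shape[0])]
    for i, spec in enumerate(specs):
        img, lab = apply_transform_arrays(images[i], labels[i], spec)
        out_imgs[i] = img.astype(np.float32)
        out_labs[i] = lab
    return out_imgs, out_labs, specs


def augment_minibatch(
    images: list[GrayImage],
    labels: list[LabelMap],
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[list[GrayImage], list[LabelMap]]:
    """Augment equal-length lists of unit-float images and label maps."""
    if len(images) != len(labels):
        raise ContractError("batch lengths differ")
    out = [
        apply_transform(img, lab, sample_transform(config, rng))
        for img, lab in zip(images, labels)
    ]
    return [p[0] for p in out], [p[1] for p in out]
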