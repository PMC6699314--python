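"""Data-processing chain for network input.

The chain is: bilinear resize to the working grid (160 x 128 by default,
never cropping or padding), per-image min-max normalization of 16-bit data
to 8-bit, contrast-limited adaptive histogram equalization (CLAHE), and
finally division by 255 to unit floats for the network.  Label maps are
resized with nearest-neighbor interpolation so class values are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .dataio import GrayImage, LabelMap
from .errors import ContractError


@dataclass
class PreprocessConfig:
    target_rows: int = 160
    target_cols: int = 128
    clahe_clip: float = 0.01  # clip limit as a fraction of tile pixel count
    clahe_tiles: tuple[int, int] = (8, 8)  # tile grid (rows x cols of tiles)
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.target_rows < 8 or self.target_cols < 8:
            raise ContractError("target grid must be at least 8 x 8")
        if not 0 < self.clahe_clip <= 1:
            raise ContractError("CLAHE clip limit must lie in (0, 1]")
        if min(self.clahe_tiles) < 1:
            raise ContractError("CLAHE tile counts must be >= 1")
        if self.normalization != "minmax":
            raise ContractError(f"unknown normalization mode {self.normalization!r}")


def resize_bilinear(image: GrayImage, rows: int, cols: int) -> GrayImage:
    """Resize to exactly (rows, cols) by bilinear interpolation; no cropping.

    Uses half-pixel-centered coordinate mapping.  Output pixels are floats
    within the input's intensity range; ``bit_depth`` is carried over.
    """
    if rows < 1 or cols < 1:
        raise ContractError("target size must be positive")
    if image.shape == (rows, cols):
        return GrayImage(image.pixels.astype(np.float64), image.bit_depth, image.spacing_mm)
    out = transform.resize(
        image.pixels.astype(np.float64),
        (rows, cols),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return GrayImage(out, image.bit_depth, image.spacing_mm)


def resize_label(label: LabelMap, rows: int, cols: int) -> LabelMap:
    """Nearest-neighbor resize; output values are a subset of the input's."""
    if rows < 1 or cols < 1:
        raise ContractError("target size must be positive")
    if label.shape == (rows, cols):
        return LabelMap(label.labels.copy())
    out = transform.resize(
        label.labels.astype(np.float64),
        (rows, cols),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return LabelMap(np.rint(out).astype(np.int64))


def normalize_to_8bit(image: GrayImage) -> GrayImage:
    """Per-image min-max scaling of a 16-bit image to integer [0, 255].

    A constant image maps to all zeros (the scale is undefined; zero is the
    declared degenerate rule).
    """
    if image.bit_depth != 16:
        raise ContractError("normalize_to_8bit expects a 16-bit image")
    px = image.pixels.astype(np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        out = np.rint((px - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return GrayImage(out, 8, image.spacing_mm)


def clahe(image: GrayImage, config: PreprocessConfig | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization of an 8-bit image.

    Tile-wise clipped-histogram equalization with bilinear blending between
    tile mappings.  Constant images pass through unchanged (their histogram
    is already flat after clipping).
    """
    config = config or PreprocessConfig()
    if image.bit_depth != 8:
        raise ContractError("clahe expects an 8-bit image")
    rows, cols = image.shape
    tiles_r, tiles_c = config.clahe_tiles
    if tiles_r > rows or tiles_c > cols:
        raise ContractError(f"tile grid {config.clahe_tiles} larger than image {image.shape}")
    px = np.rint(image.pixels).astype(np.uint8)
    if px.min() == px.max():
        return GrayImage(px, 8, image.spacing_mm)
    kernel = (max(1, rows // tiles_r), max(1, cols // tiles_c))
    eq = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=config.clahe_clip)
    return GrayImage(np.rint(eq * 255.0).astype(np.uint8), 8, image.spacing_mm)


def preprocess_pipeline(image: GrayImage, config: PreprocessConfig | None = None) -> GrayImage:
    """Full chain: resize -> (8-bit normalize if 16-bit) -> CLAHE -> /255.

    Returns a unit-float image of the target shape with values in [0, 1].
    """
    config = config or PreprocessConfig()
    out = resize_bilinear(image, config.target_rows, config.target_cols)
    if out.bit_depth == 16:
        out = normalize_to_8bit(out)
    else:
        out = GrayImage(np.rint(out.pixels).astype(np.uint8), 8, out.spacing_mm)
    out = clahe(out, config)
    unit = out.pixels.astype(np.float32) / np.float32(255.0)
    return GrayImage(unit, "float", out.spacing_mm)
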