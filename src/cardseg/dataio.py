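"""Image, label-map, and manifest I/O.

Short-axis cardiac MR frames are handled as plain 2-D grids: 8- or 16-bit
grayscale PNG files, or single slices extracted from NIfTI volumes (the
format used by ACDC-style cine studies).  Label maps use the internal
convention

    1 = background, 2 = RV blood pool, 3 = LV myocardium, 4 = LV blood pool

throughout the package; ACDC-style files (0 = background .. 3 = LV) are
remapped on ingest.  Overlays follow the conventional display colors:
LV red, myocardium green, RV blue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ContractError, FormatError, LabelEncodingError

#: Internal label values.
BACKGROUND, RV, MYOCARDIUM, LV = 1, 2, 3, 4
LABEL_VALUES = (BACKGROUND, RV, MYOCARDIUM, LV)

#: Overlay colors, indexed by label value (Fig-2-style display convention).
OVERLAY_COLORS = {LV: (255, 0, 0), MYOCARDIUM: (0, 255, 0), RV: (0, 0, 255)}

VALID_SPLITS = ("train", "valid", "test")


@dataclass
class GrayImage:
    """A 2-D scalar intensity grid.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity values.  dtype uint8 for 8-bit, uint16 for 16-bit,
        floating for unit-scaled images.
    bit_depth : {8, 16, "float"}
        Storage interpretation.  ``"float"`` means unit-scaled [0, 1].
    spacing_mm : tuple of float, optional
        Pixel spacing (row, col) in mm/pixel when known.
    """

    pixels: np.ndarray
    bit_depth: int | str = 8
    spacing_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ContractError(f"image must be 2-D non-empty, got shape {self.pixels.shape}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if self.bit_depth == 8 and not (0 <= lo and hi <= 255):
            raise ContractError(f"8-bit values must lie in [0,255], got [{lo},{hi}]")
        if self.bit_depth == 16 and not (0 <= lo and hi <= 65535):
            raise ContractError(f"16-bit values must lie in [0,65535], got [{lo},{hi}]")
        if self.bit_depth == "float" and not (0.0 <= lo and hi <= 1.0):
            raise ContractError(f"unit-float values must lie in [0,1], got [{lo},{hi}]")
        if self.bit_depth not in (8, 16, "float"):
            raise ContractError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """A 2-D integer grid of class labels in {1, 2, 3, 4}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ContractError(f"label map must be 2-D, got shape {self.labels.shape}")
        values = np.unique(self.labels)
        if not np.isin(values, LABEL_VALUES).all():
            raise LabelEncodingError(f"label values {values.tolist()} not a subset of {LABEL_VALUES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ManifestRecord:
    image: str
    label: str | None
    split: str
    slice_tag: str = "mid"  # apex | mid | base
    phase: str = "ED"  # ED | ES


@dataclass
class Manifest:
    """An on-disk dataset listing: image/label paths plus split, slice and
    cardiac-phase tags.  Stored as a tab-separated table."""

    records: list[ManifestRecord] = field(default_factory=list)

    def subset(self, split: str) -> "Manifest":
        if split not in VALID_SPLITS:
            raise ContractError(f"unknown split {split!r}")
        return Manifest([r for r in self.records if r.split == split])

    def __len__(self) -> int:
        return len(self.records)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["image", "label", "split", "slice", "phase"])
            for r in self.records:
                writer.writerow([r.image, r.label or "", r.split, r.slice_tag, r.phase])

    @classmethod
    def load(cls, path: str | Path, check_paths: bool = True) -> "Manifest":
        path = Path(path)
        records = []
        with path.open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:5] != ["image", "label", "split", "slice", "phase"]:
                raise FormatError(f"{path}: not a manifest (header {header})")
            for row in reader:
                image, label, split, slice_tag, phase = row[:5]
                if split not in VALID_SPLITS:
                    raise FormatError(f"{path}: bad split tag {split!r}")
                rec = ManifestRecord(image, label or None, split, slice_tag, phase)
                if check_paths:
                    base = path.parent
                    for p in (rec.image, rec.label):
                        if p is not None and not (base / p).exists():
                            raise FormatError(f"{path}: missing referenced file {p}")
                records.append(rec)
        return cls(records)


# ---------------------------------------------------------------------------
# image I/O


def _infer_bit_depth(arr: np.ndarray) -> int:
    return 8 if arr.dtype.itemsize == 1 else 16


def read_image(
    path: str | Path,
    slice_index: int | None = None,
    frame_index: int | None = None,
) -> GrayImage:
    """Read a grayscale image from PNG or a 2-D plane from a NIfTI volume.

    For NIfTI input, ``slice_index`` selects the plane along the third axis
    and ``frame_index`` the time point of a 4-D volume.  Pixel spacing is
    propagated from the NIfTI header when present.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti_slice(path, slice_index or 0, frame_index)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - any reader failure is a format error
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse accidental RGB of equal channels
        if not (arr[..., 0] == arr[..., 1]).all():
            raise FormatError(f"{path}: color PNG is not a grayscale image")
        arr = arr[..., 0]
    return GrayImage(arr, bit_depth=_infer_bit_depth(arr))


def _read_nifti_slice(path: Path, slice_index: int, frame_index: int | None) -> GrayImage:
    import nibabel as nib

    try:
        vol = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(vol.dataobj)
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected a 3-D or 4-D NIfTI volume, got ndim={data.ndim}")
    if not 0 <= slice_index < data.shape[2]:
        raise IndexError(f"{path}: slice index {slice_index} out of range [0,{data.shape[2]})")
    if data.ndim == 4:
        frame = 0 if frame_index is None else frame_index
        if not 0 <= frame < data.shape[3]:
            raise IndexError(f"{path}: frame index {frame} out of range [0,{data.shape[3]})")
        plane = data[:, :, slice_index, frame]
    else:
        plane = data[:, :, slice_index]
    plane = np.asarray(plane)
    if np.issubdtype(plane.dtype, np.floating):
        plane = np.clip(np.rint(plane), 0, 65535).astype(np.uint16)
    else:
        plane = np.clip(plane, 0, 65535).astype(np.uint16)
    zooms = vol.header.get_zooms()[:2]
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) == 2 else None
    return GrayImage(plane, bit_depth=16, spacing_mm=spacing)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8- or 16-bit GrayImage as a grayscale PNG (bit-exact round trip)."""
    if image.bit_depth == "float":
        raise ContractError("unit-float images have no canonical PNG encoding; convert first")
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), image.pixels.astype(dtype))


# ---------------------------------------------------------------------------
# label I/O


def read_label(path: str | Path, encoding: str = "internal") -> LabelMap:
    """Read a label map, remapping to the internal {1..4} convention.

    ``encoding="internal"`` expects stored values in {1..4};
    ``encoding="acdc"`` expects {0..3} (0 = background, 1 = RV, 2 = myocardium,
    3 = LV) and shifts every value up by one.
    """
    if encoding not in ("internal", "acdc"):
        raise ContractError(f"unknown label encoding {encoding!r}")
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read label {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be single-channel")
    values = np.unique(arr)
    allowed = (0, 1, 2, 3) if encoding == "acdc" else LABEL_VALUES
    if not np.isin(values, allowed).all():
        raise LabelEncodingError(
            f"{path}: stored values {values.tolist()} not a subset of {allowed} "
            f"for encoding {encoding!r}"
        )
    arr = arr.astype(np.int64)
    if encoding == "acdc":
        arr = arr + 1
    return LabelMap(arr)


def write_label(label: LabelMap, path: str | Path) -> None:
    iio.imwrite(Path(path), label.labels.astype(np.uint8))


def write_overlay(image: GrayImage, label: LabelMap, path: str | Path) -> None:
    """Write an RGB PNG with LV red, myocardium green, RV blue over the
    grayscale image (background pixels show the image itself)."""
    if image.shape != label.shape:
        raise ContractError(f"image shape {image.shape} != label shape {label.shape}")
    gray = to_display_8bit(image)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for value, color in OVERLAY_COLORS.items():
        rgb[label.labels == value] = color
    iio.imwrite(Path(path), rgb.astype(np.uint8))


def to_display_8bit(image: GrayImage) -> np.ndarray:
    """Render any GrayImage to uint8 for display (min-max for 16-bit, x255 for float)."""
    px = image.pixels
    if image.bit_depth == 8:
        return px.astype(np.uint8)
    if image.bit_depth == "float":
        return np.rint(px * 255).astype(np.uint8)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.zeros(px.shape, dtype=np.uint8)
    return np.rint((px.astype(np.float64) - lo) / (hi - lo) * 255).astype(np.uint8)


def iter_pairs(
    manifest: Manifest, root: str | Path, encoding: str = "internal"
) -> Iterable[tuple[GrayImage, LabelMap | None, ManifestRecord]]:
    """Yield (image, label, record) triples with paths resolved against ``root``."""
    root = Path(root)
    for rec in manifest.records:
        image = read_image(root / rec.image)
        label = read_label(root / rec.label, encoding) if rec.label else None
        yield image, label, rec
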