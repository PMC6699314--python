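"""Synthetic short-axis cardiac phantoms.

Emulates the geometry and contrast of bright-blood (SSFP-like) short-axis
cine frames: a circular LV blood pool inside a concentric myocardial
annulus, with an RV blood-pool crescent attached on one side, over a darker
background.  Intensities are ordered blood > myocardium > background, with
an additive smooth bias field and zero-mean Gaussian noise on a 16-bit
scale.  Three slice modes mimic the along-axis anatomy:

* ``mid``  — full LV / myocardium / RV geometry;
* ``apex`` — radii shrink and the RV vanishes entirely, so the label map
  lacks class 2 (the absent-class case that motivates the improved
  generalized Dice loss);
* ``base`` — an extra bright, unlabeled distractor blob outside the heart
  stands in for out-of-plane structures (pulmonary artery, outflow tracts).

End-systole (ES) frames contract the LV blood pool by a configurable factor
while the outer myocardial radius is retained, so the wall thickens and the
label-4 area strictly shrinks relative to the end-diastole (ED) frame built
from the same seed.  All randomness flows through one seeded generator per
call; identical (config, seed) pairs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dataio import BACKGROUND, LV, MYOCARDIUM, RV, GrayImage, LabelMap, Manifest, ManifestRecord, write_image, write_label
from .errors import ConfigurationError, ContractError

SLICE_MODES = ("apex", "mid", "base")
APEX_SHRINK = 0.55  # radial scale applied to LV/myocardium in apex mode


@dataclass
class PhantomConfig:
    """Geometry, contrast and corruption parameters of one phantom frame.

    Lengths are in pixels on the output grid, intensities on the 16-bit
    scale.  Defaults give a mid-ventricular frame on the 160 x 128 grid
    used throughout the package.
    """

    rows: int = 160
    cols: int = 128
    lv_radius: float = 16.0
    myo_thickness: float = 6.0
    rv_offset: float = 10.0  # leftward shift of the RV disk center
    rv_thickness: float = 7.0  # maximal crescent width beyond the annulus
    contraction: float = 0.65  # ES blood-pool radial scale, in (0, 1]
    phase: str = "ED"  # ED | ES
    intensity_blood: float = 42000.0
    intensity_myo: float = 22000.0
    intensity_background: float = 8000.0
    noise_sigma: float = 1200.0
    bias_amplitude: float = 4000.0
    slice_mode: str = "mid"
    respiratory_shift: tuple[float, float] = (0.0, 0.0)  # (rows, cols) px
    center_jitter: float = 3.0  # uniform per-axis jitter of the heart center

    def __post_init__(self) -> None:
        if self.lv_radius <= 0 or self.myo_thickness <= 0 or self.rv_thickness <= 0:
            raise ConfigurationError("radii and thicknesses must be positive")
        if not 0 < self.contraction <= 1:
            raise ConfigurationError("contraction must lie in (0, 1]")
        if not (self.intensity_blood > self.intensity_myo > self.intensity_background):
            raise ConfigurationError("intensities must be ordered blood > myocardium > background")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ConfigurationError("noise sigma and bias amplitude must be non-negative")
        if self.slice_mode not in SLICE_MODES:
            raise ConfigurationError(f"slice_mode must be one of {SLICE_MODES}")
        if self.phase not in ("ED", "ES"):
            raise ConfigurationError("phase must be 'ED' or 'ES'")

    @classmethod
    def for_grid(cls, rows: int, cols: int, **overrides) -> "PhantomConfig":
        """Defaults with the heart geometry scaled to an arbitrary grid
        (lengths scale with min(rows, cols) relative to the 160x128 default)."""
        s = min(rows, cols) / 128.0
        scaled = dict(
            rows=rows,
            cols=cols,
            lv_radius=16.0 * s,
            myo_thickness=6.0 * s,
            rv_offset=10.0 * s,
            rv_thickness=7.0 * s,
            center_jitter=3.0 * s,
        )
        scaled.update(overrides)
        return cls(**scaled)


def _disk(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float], radius: float) -> np.ndarray:
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(config: PhantomConfig, seed: int) -> tuple[GrayImage, LabelMap]:
    """Render one 16-bit phantom frame and its paired 4-class label map."""
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0 : config.rows, 0 : config.cols].astype(np.float64)

    shrink = APEX_SHRINK if config.slice_mode == "apex" else 1.0
    lv_r = config.lv_radius * shrink
    if config.phase == "ES":
        lv_r *= config.contraction
    outer_r = (config.lv_radius + config.myo_thickness) * shrink

    jitter = rng.uniform(-config.center_jitter, config.center_jitter, size=2)
    center = (
        config.rows / 2 + config.respiratory_shift[0] + jitter[0],
        config.cols / 2 + config.respiratory_shift[1] + jitter[1],
    )
    reach = outer_r + (0.0 if config.slice_mode == "apex" else config.rv_thickness) + 1.0
    if (
        center[0] - reach < 0
        or center[1] - reach < 0
        or center[0] + reach >= config.rows
        or center[1] + reach >= config.cols
    ):
        raise ConfigurationError("phantom heart geometry does not fit inside the grid")

    labels = np.full((config.rows, config.cols), BACKGROUND, dtype=np.int64)
    heart_disk = _disk(rr, cc, center, outer_r)
    lv_disk = _disk(rr, cc, center, lv_r)
    labels[heart_disk] = MYOCARDIUM
    labels[lv_disk] = LV

    if config.slice_mode != "apex":
        # RV crescent: an offset disk minus the LV+myocardium disk.  The disk
        # radius is chosen so its farthest point sits rv_thickness beyond the
        # outer annulus boundary.
        rv_center = (center[0], center[1] - config.rv_offset)
        rv_radius = outer_r + config.rv_thickness - config.rv_offset
        if rv_radius <= 0:
            raise ConfigurationError("rv_offset too large: crescent radius non-positive")
        crescent = _disk(rr, cc, rv_center, rv_radius) & ~heart_disk
        labels[crescent] = RV

    image = np.full(labels.shape, config.intensity_background, dtype=np.float64)
    image[labels == MYOCARDIUM] = config.intensity_myo
    image[(labels == LV) | (labels == RV)] = config.intensity_blood

    if config.slice_mode == "base":
        # unlabeled bright distractor outside the heart (stays background)
        angle = rng.uniform(0, 2 * math.pi)
        dist = reach + rng.uniform(8.0, 16.0)
        blob_center = (center[0] + dist * math.sin(angle), center[1] + dist * math.cos(angle))
        blob = _disk(rr, cc, blob_center, rng.uniform(4.0, 7.0))
        image[blob] = config.intensity_blood * 0.95

    if config.bias_amplitude > 0:
        image += _bias_field(config.rows, config.cols, config.bias_amplitude, rng)
    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=image.shape)

    image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    return GrayImage(image, bit_depth=16), LabelMap(labels)


def _bias_field(rows: int, cols: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order multiplicative-style shading: a random 2-D quadratic
    surface rescaled to [-amplitude, +amplitude]."""
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    a, b, c, d, e = rng.uniform(-1, 1, size=5)
    surface = a * y**2 + b * x**2 + c * x * y + d * y + e * x
    span = surface.max() - surface.min()
    if span == 0:
        return np.zeros((rows, cols))
    surface = (surface - surface.min()) / span * 2 - 1
    return amplitude * surface


def generate_dataset(
    n: int,
    config: PhantomConfig,
    seed: int,
    out_dir: str | Path,
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
    mode_probs: tuple[float, float, float] = (0.25, 0.5, 0.25),
    max_respiratory_shift: float = 5.0,
) -> Manifest:
    """Write ``n`` phantom image/label PNG pairs plus a manifest.

    Frames mix ED and ES phases, slice modes drawn with ``mode_probs``
    (apex, mid, base), and per-frame respiratory shifts.  At least one apex
    frame is forced whenever ``n >= 3`` so any generated training set
    exercises the absent-class loss path.  Fully reproducible for a fixed
    (config, seed).
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ContractError(f"split fractions must sum to 1, got {splits}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    modes = [str(m) for m in rng.choice(SLICE_MODES, size=n, p=mode_probs)]
    if n >= 3 and "apex" not in modes:
        modes[n // 2] = "apex"
    phases = ["ED" if rng.random() < 0.5 else "ES" for _ in range(n)]
    shifts = rng.uniform(-max_respiratory_shift, max_respiratory_shift, size=(n, 2))
    frame_seeds = rng.integers(0, 2**31 - 1, size=n)

    # split boundaries by cumulative rounding so counts are exact for round n
    cuts = np.floor(np.cumsum(splits) * n + 0.5).astype(int)
    cuts[-1] = n

    records: list[ManifestRecord] = []
    width = max(3, len(str(n - 1)))
    for i in range(n):
        cfg = replace(
            config,
            slice_mode=modes[i],
            phase=phases[i],
            respiratory_shift=(float(shifts[i, 0]), float(shifts[i, 1])),
        )
        image, label = generate_phantom(cfg, int(frame_seeds[i]))
        image_name = f"phantom_{i:0{width}d}.png"
        label_name = f"label_{i:0{width}d}.png"
        write_image(image, out_dir / image_name)
        write_label(label, out_dir / label_name)
        split = "train" if i < cuts[0] else ("valid" if i < cuts[1] else "test")
        records.append(ManifestRecord(image_name, label_name, split, modes[i], phases[i]))

    manifest = Manifest(records)
    manifest.save(out_dir / "manifest.tsv")
    return manifest
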