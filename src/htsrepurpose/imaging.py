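"""Quantification of mineralized tissue and stained sections.

Three independent measurements:

* microCT — a Hounsfield-unit volume is segmented by a single global
  threshold (mask = HU >= threshold, no morphology). The mineralized volume
  is V = N * voxel volume (mm^3) for N masked voxels, and the density is the
  summed HU over the mask divided by V (HU/mm^3).
* stained-area fraction — color thresholding in HSV space: a pixel is
  positive when it falls inside a hue/saturation/value window (default tuned
  to an Alizarin-red window with hue wrap-around); the denominator is the
  set of tissue pixels (non-background by a saturation/value rule).
* nuclei counting — intensity threshold, 8-connected components, minimum
  size filter. No declumping: touching nuclei merge into one component
  (documented limitation).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

from .errors import ValidationError


# ---------------------------------------------------------------------------
# microCT


@dataclass
class HUVolume:
    """A 3D array of Hounsfield units with the voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("volume must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


def load_volume(path) -> HUVolume:
    """Load a volume from NIfTI (spacing from the header, mm) or from a
    ``.npy`` array with a ``<stem>.json`` sidecar holding ``spacing_mm``."""
    path = pathlib.Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return HUVolume(data, spacing)
    if name.endswith(".npy"):
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValidationError(f"missing spacing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        return HUVolume(np.load(path), tuple(meta["spacing_mm"]))
    raise ValidationError(f"unsupported volume format: {path}")


def save_volume(vol: HUVolume, path) -> None:
    path = pathlib.Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))
    elif name.endswith(".npy"):
        np.save(path, vol.voxels)
        path.with_suffix(".json").write_text(json.dumps({"spacing_mm": list(vol.spacing)}))
    else:
        raise ValidationError(f"unsupported volume format: {path}")


@dataclass
class SegmentationResult:
    """Threshold segmentation of a HU volume.

    density is sum(HU over mask)/V in HU/mm^3 and is undefined (NaN, with
    ``density_defined=False``) for an empty mask.
    """

    mask: np.ndarray
    n_voxels: int
    volume_mm3: float
    density_hu_per_mm3: float
    hu_threshold: float
    voxel_volume_mm3: float
    density_defined: bool = True


def segment_mineralized(vol: HUVolume, hu_threshold: float,
                        min_component: int = 0) -> SegmentationResult:
    """Global-threshold segmentation: mask = voxels with HU >= hu_threshold.

    ``min_component`` optionally drops 26-connected components smaller than
    that voxel count (off by default). An empty mask yields zero volume and
    an undefined density flag, never an exception.
    """
    if not math.isfinite(hu_threshold):
        raise ValidationError("hu_threshold must be finite")
    mask = vol.voxels >= hu_threshold
    if min_component > 0 and mask.any():
        lbl = skmeasure.label(mask, connectivity=3)
        counts = np.bincount(lbl.ravel())
        keep = np.flatnonzero(counts >= min_component)
        keep = keep[keep != 0]
        mask = np.isin(lbl, keep)
    n = int(mask.sum())
    v = n * vol.voxel_volume_mm3
    if n > 0:
        density = float(vol.voxels[mask].sum() / v)
        defined = True
    else:
        density, defined = math.nan, False
    return SegmentationResult(mask=mask, n_voxels=n, volume_mm3=v,
                              density_hu_per_mm3=density, hu_threshold=float(hu_threshold),
                              voxel_volume_mm3=vol.voxel_volume_mm3,
                              density_defined=defined)


@dataclass
class VolumeChange:
    delta_mm3: float
    percent: float
    percent_defined: bool


def volume_change(early: SegmentationResult, late: SegmentationResult) -> VolumeChange:
    """Absolute and percent change of mineralized volume between two scans.

    Both segmentations must come from the same voxel spacing. A zero early
    volume leaves the percent change undefined (flagged), the absolute
    change is still reported.
    """
    if not math.isclose(early.voxel_volume_mm3, late.voxel_volume_mm3,
                        rel_tol=1e-9):
        raise ValidationError("volumes were reconstructed at different voxel spacings")
    delta = late.volume_mm3 - early.volume_mm3
    if early.volume_mm3 > 0:
        return VolumeChange(delta, 100.0 * delta / early.volume_mm3, True)
    return VolumeChange(delta, math.nan, False)


# ---------------------------------------------------------------------------
# stained-area fraction


@dataclass
class StainConfig:
    """HSV color window for stain-positive pixels and the tissue rule.

    Hue is on [0, 1); the positive window wraps around red: hue >= hue_lo OR
    hue <= hue_hi. Tissue pixels (the denominator) are the non-background
    ones: saturated or dark enough not to be blank slide. Defaults describe
    an Alizarin-red-like window and are artifact choices, not measured
    values.
    """

    hue_lo: float = 0.92
    hue_hi: float = 0.08
    sat_min: float = 0.25
    val_min: float = 0.15
    val_max: float = 1.0
    tissue_sat_min: float = 0.12
    tissue_val_max: float = 0.88


@dataclass
class StainAreaResult:
    positive_pixels: int
    total_tissue_pixels: int
    fraction: float
    config: StainConfig = field(default_factory=StainConfig)
    fraction_defined: bool = True


def stain_positive_area(image: np.ndarray,
                        config: StainConfig | None = None) -> StainAreaResult:
    """Stain-positive area fraction of an 8-bit RGB section image.

    fraction = (pixels inside the HSV window) / (tissue pixels). Zero tissue
    pixels leave the fraction undefined (flagged)."""
    config = config or StainConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError("expected an RGB image (H x W x 3)")
    hsv = skcolor.rgb2hsv(img)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    tissue = (s >= config.tissue_sat_min) | (v <= config.tissue_val_max)
    in_hue = (h >= config.hue_lo) | (h <= config.hue_hi)
    positive = tissue & in_hue & (s >= config.sat_min) \
        & (v >= config.val_min) & (v <= config.val_max)
    n_tissue = int(tissue.sum())
    n_pos = int(positive.sum())
    if n_tissue == 0:
        return StainAreaResult(0, 0, math.nan, config, fraction_defined=False)
    return StainAreaResult(n_pos, n_tissue, n_pos / n_tissue, config)


# ---------------------------------------------------------------------------
# nuclei counting


@dataclass
class NucleiCountResult:
    count: int
    centroids: np.ndarray  # (n, 2) pixel coordinates (row, col)
    intensity_threshold: float
    min_size: int


def count_nuclei(image: np.ndarray, intensity_threshold: float,
                 min_size: int = 1) -> NucleiCountResult:
    """Automated nuclei count on a 2D grayscale image.

    Pixels >= intensity_threshold form the foreground; 8-connected
    components smaller than ``min_size`` pixels are discarded; the count is
    the number of retained components (their centroids are returned).
    Touching nuclei merge into a single component.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValidationError("expected a 2D grayscale image")
    if min_size < 1:
        raise ValidationError("min_size must be >= 1 pixel")
    mask = img >= intensity_threshold
    if not mask.any():
        return NucleiCountResult(0, np.empty((0, 2)), float(intensity_threshold), min_size)
    lbl = skmeasure.label(mask, connectivity=2)
    props = skmeasure.regionprops(lbl)
    kept = [p.centroid for p in props if p.area >= min_size]
    return NucleiCountResult(len(kept), np.asarray(kept, dtype=float).reshape(-1, 2),
                             float(intensity_threshold), min_size)
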