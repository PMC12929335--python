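"""Liver/spleen mean attenuation from labeled volumes or circular ROIs.

Two measurement routes mirror clinical practice: the mean over every voxel
of a 3D organ segmentation (automated route), and the pooled mean over all
pixels of manually placed circular ROIs on axial slices (manual route).
From the liver mean L and spleen mean S the derived steatosis statistics
are the difference L-S and the ratio L/S.

Volumes are assumed to already be in Hounsfield units; any scale/intercept
in the file header is the reader's concern (nibabel applies it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LIVER_LABEL",
    "SPLEEN_LABEL",
    "PhantomVolume",
    "RoiSpec",
    "AttenuationRecord",
    "MaskedMean",
    "masked_mean",
    "roi_mean",
    "derive_record",
    "load_phantom",
    "save_phantom",
    "records_to_frame",
    "read_roi_specs",
]

logger = logging.getLogger(__name__)

LIVER_LABEL = 1
SPLEEN_LABEL = 2

#: Spleen means with |S| at or below this are too close to zero for a
#: meaningful L/S ratio; the ratio is reported as undefined.
RATIO_GUARD_HU = 1.0


@dataclass
class PhantomVolume:
    """A CT-like scalar grid (HU) with an integer organ label mask.

    Labels: 0 background, 1 liver, 2 spleen.  ``spacing`` is mm per axis
    (x, y, z) with z the axial direction.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if self.image.ndim != 3:
            raise ValueError("expected 3-D volumes")
        labels = np.unique(self.mask)
        if not np.all(np.isin(labels, [0, LIVER_LABEL, SPLEEN_LABEL])):
            raise ValueError(f"mask labels must be subset of {{0,1,2}}, found {labels}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI on one axial slice: center (x, y) in voxels, radius in mm."""

    center_x: float
    center_y: float
    slice_index: int
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class AttenuationRecord:
    """One subject-phase measurement with derived liver/spleen statistics."""

    subject_id: str
    phase: str
    liver_hu: float
    spleen_hu: float
    liver_minus_spleen: float
    liver_spleen_ratio: float | None  # None when |S| <= RATIO_GUARD_HU


@dataclass(frozen=True)
class MaskedMean:
    mean_hu: float
    n_voxels: int


def masked_mean(volume: PhantomVolume, label: int) -> MaskedMean:
    """Mean HU over all voxels carrying ``label``, with the voxel count."""
    sel = volume.mask == label
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError(f"label {label} not present in mask")
    return MaskedMean(float(volume.image[sel].mean()), n)


def _roi_pixels(volume: PhantomVolume, roi: RoiSpec, index: int) -> np.ndarray:
    nx, ny, nz = volume.image.shape
    sx, sy, _ = volume.spacing
    rx, ry = roi.radius_mm / sx, roi.radius_mm / sy
    if not (0 <= roi.slice_index < nz):
        raise ValueError(f"ROI {index}: slice {roi.slice_index} outside [0, {nz})")
    if (
        roi.center_x - rx < 0
        or roi.center_x + rx > nx - 1
        or roi.center_y - ry < 0
        or roi.center_y + ry > ny - 1
    ):
        raise ValueError(f"ROI {index}: disc of radius {roi.radius_mm} mm exceeds image bounds")
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dist2 = ((ii - roi.center_x) * sx) ** 2 + ((jj - roi.center_y) * sy) ** 2
    inside = dist2 <= roi.radius_mm**2
    return volume.image[:, :, roi.slice_index][inside]


def roi_mean(volume: PhantomVolume, rois: Sequence[RoiSpec]) -> MaskedMean:
    """Pooled mean over all pixels across all ROIs.

    Pixels are pooled with multiplicity (a pixel inside two overlapping
    discs contributes twice), i.e. the result weights each ROI by its pixel
    count rather than averaging per-ROI means.  Membership is
    pixel-center-within-radius on the ROI's axial slice.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    pools = [_roi_pixels(volume, roi, i) for i, roi in enumerate(rois)]
    pooled = np.concatenate(pools)
    if pooled.size == 0:
        raise ValueError("ROIs contain no pixels")
    return MaskedMean(float(pooled.mean()), int(pooled.size))


def derive_record(subject_id: str, phase: str, liver_hu: float, spleen_hu: float) -> AttenuationRecord:
    """Build a record with L-S and L/S derived from the organ means."""
    liver_hu = float(liver_hu)
    spleen_hu = float(spleen_hu)
    if not (np.isfinite(liver_hu) and np.isfinite(spleen_hu)):
        raise ValueError("liver and spleen attenuation must be finite")
    ratio: float | None
    if abs(spleen_hu) <= RATIO_GUARD_HU:
        logger.warning(
            "spleen mean %.2f HU within %.1f HU of zero for subject %s; L/S undefined",
            spleen_hu,
            RATIO_GUARD_HU,
            subject_id,
        )
        ratio = None
    else:
        ratio = liver_hu / spleen_hu
    return AttenuationRecord(
        subject_id=str(subject_id),
        phase=phase,
        liver_hu=liver_hu,
        spleen_hu=spleen_hu,
        liver_minus_spleen=liver_hu - spleen_hu,
        liver_spleen_ratio=ratio,
    )


def records_to_frame(records: Iterable[AttenuationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "phase": r.phase,
                "liver_hu": r.liver_hu,
                "spleen_hu": r.spleen_hu,
                "liver_minus_spleen": r.liver_minus_spleen,
                "liver_spleen_ratio": r.liver_spleen_ratio,
            }
            for r in records
        ]
    )


def read_roi_specs(path) -> dict:
    """Read ROI specs from CSV (subject, organ, x, y, z, radius_mm).

    Returns {(subject, organ): [RoiSpec, ...]} preserving file order.
    """
    df = pd.read_csv(path)
    required = {"subject", "organ", "x", "y", "z", "radius_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault((str(row.subject), str(row.organ)), []).append(
            RoiSpec(float(row.x), float(row.y), int(row.z), float(row.radius_mm))
        )
    return out


def save_phantom(volume: PhantomVolume, image_path, mask_path, sidecar_path=None) -> None:
    """Write paired NIfTI files sharing one affine, plus a label sidecar."""
    affine = volume.affine
    nib.save(nib.Nifti1Image(volume.image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(volume.mask.astype(np.int16), affine), str(mask_path))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "labels": {"0": "background", "1": "liver", "2": "spleen"},
                    "spacing_mm": list(volume.spacing),
                    "units": "HU",
                },
                fh,
                indent=2,
            )


def load_phantom(image_path, mask_path) -> PhantomVolume:
    """Read a paired NIfTI image/mask into a :class:`PhantomVolume`."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    image = np.asarray(img.get_fdata())
    mask = np.asarray(msk.dataobj).astype(int)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomVolume(image=image, mask=mask, spacing=spacing, affine=img.affine)
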