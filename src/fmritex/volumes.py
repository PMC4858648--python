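"""NIfTI volume / ROI-mask handling and per-slice patch extraction.

Texture analysis operates on 2-D axial slices of the mean EPI volume, so the
central operation here is decomposing a 3-D ROI mask into per-slice patches
(tight bounding boxes plus an in-ROI pixel flag). Control "inactivity" ROIs
with a fixed size and location across subjects are also placed here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from fmritex.errors import (
    DimensionalityError,
    EmptyROIError,
    FormatError,
    GeometryError,
)

E = "E"
NE = "NE"
UNLABELED = "UNLABELED"


@dataclasses.dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with voxel spacing in mm.

    ``axial_axis`` names the slice axis used for 2-D patch extraction
    (default: the third array axis).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D mean EPI volume, got {self.data.ndim}-D data"
            )
        if min(self.data.shape) < 1:
            raise DimensionalityError("all volume dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclasses.dataclass
class ROIMask:
    """Binary mask congruent with its volume, plus identity and class label."""

    mask: np.ndarray
    subject_id: str
    roi_id: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("ROI mask must be 3-D")
        if self.label not in (E, NE, UNLABELED):
            raise ValueError(f"label must be E, NE or UNLABELED, got {self.label!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class ROIPatch:
    """One axial slice of an ROI: intensities plus the in-ROI pixel flags.

    ``values`` is the tight bounding box of the ROI on that slice; only
    pixels with ``inside`` set participate in GLCM pair counting.
    """

    slice_index: int
    values: np.ndarray
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if not self.inside.any():
            raise EmptyROIError("patch has no inside pixel")
        if not np.all(np.isfinite(self.values[self.inside])):
            raise ValueError("non-finite intensity inside ROI patch")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI-1 scalar image; spacing comes from the header."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected the 3-D mean EPI volume, got {data.ndim}-D data "
            "(time series must be averaged first)"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data, affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(roi: ROIMask, volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, subject_id: str, roi_id: str,
              label: str = UNLABELED) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(mask=vol.data > 0, subject_id=subject_id,
                   roi_id=roi_id, label=label)


def extract_patches(volume: ImageVolume, roi: ROIMask) -> list[ROIPatch]:
    """Decompose an ROI into per-axial-slice patches with tight bounding boxes.

    The union of inside pixels over the returned patches equals the ROI's
    voxel set exactly (lossless decomposition).
    """
    if roi.mask.shape != volume.data.shape:
        raise GeometryError(
            f"mask shape {roi.mask.shape} != volume shape {volume.data.shape}"
        )
    if not roi.mask.any():
        raise EmptyROIError(f"ROI {roi.roi_id} has no voxels")

    axis = volume.axial_axis
    mask = np.moveaxis(roi.mask, axis, 0)
    data = np.moveaxis(volume.data, axis, 0)
    patches: list[ROIPatch] = []
    for k in np.flatnonzero(mask.reshape(mask.shape[0], -1).any(axis=1)):
        m2 = mask[k]
        rows = np.flatnonzero(m2.any(axis=1))
        cols = np.flatnonzero(m2.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        patches.append(ROIPatch(
            slice_index=int(k),
            values=np.asarray(data[k, r0:r1, c0:c1], dtype=float),
            inside=m2[r0:r1, c0:c1].copy(),
        ))
    return patches


@dataclasses.dataclass
class ControlROISpec:
    """Fixed geometry for the per-subject 'inactivity' control ROIs.

    Two box-shaped ROIs at fixed grid offsets, identical for every subject;
    the defaults place two 5x5x1 squares well inside a 64x64x30 matrix.
    """

    size: tuple[int, int, int] = (5, 5, 1)
    corners: tuple[tuple[int, int, int], ...] = ((12, 12, 14), (44, 44, 14))

    def __post_init__(self) -> None:
        if len(self.corners) != 2:
            raise ValueError("exactly two control ROIs are placed per subject")
        if any(s < 1 for s in self.size):
            raise ValueError("control ROI size must be >= 1 per axis")


def place_control_rois(volume: ImageVolume, spec: ControlROISpec | None = None,
                       subject_id: str = "subject") -> list[ROIMask]:
    """Place the two fixed control ROIs (labelled NE) inside a volume.

    The coordinates come from ``spec`` alone, so the masks are identical
    across subjects sharing a grid.
    """
    spec = spec or ControlROISpec()
    rois = []
    for idx, corner in enumerate(spec.corners, start=1):
        stop = tuple(c + s for c, s in zip(corner, spec.size))
        if any(c < 0 for c in corner) or any(
                e > d for e, d in zip(stop, volume.shape)):
            raise GeometryError(
                f"control ROI at corner {corner} size {spec.size} exceeds "
                f"volume bounds {volume.shape}"
            )
        mask = np.zeros(volume.shape, dtype=bool)
        mask[corner[0]:stop[0], corner[1]:stop[1], corner[2]:stop[2]] = True
        rois.append(ROIMask(mask=mask, subject_id=subject_id,
                            roi_id=f"{subject_id}_ctrl{idx}", label=NE))
    return rois


MANIFEST_COLUMNS = ["subject_id", "roi_id", "mask_path", "label"]


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"ROI manifest {path} missing columns {sorted(missing)}")
    return df
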