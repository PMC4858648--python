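"""Synthetic stand-ins for the study's (undistributed) human fMRI data.

Two generators, both pure functions of their config (seed included):

* ``generate_volume_dataset`` — mean-EPI-like volumes with textured ROIs.
  Each ROI is a Gaussian random field realized by smoothing white noise
  in-plane with a class-specific correlation length. Expected (E) ROIs are
  the heterogeneous class: short correlation length plus a positive-skew
  transform emulating focal bright activation foci; Non-Expected (NE) ROIs
  are smoother and symmetric, which drives their GLCM autocorrelation and
  sum average upward — the direction observed between the classes in vivo.
  Two fixed-coordinate control ROIs per subject are labelled NE.

* ``generate_feature_table`` — labeled 116x20 feature tables drawn from
  per-class multivariate Gaussians whose marginal means/SDs default to the
  study's printed per-class descriptive statistics, with an equicorrelated
  block (default 0.99) tying together autocorrelation, sum-of-squares
  variance, sum average and sum variance. Joint Gaussianity is an explicit
  modelling simplification; real radiomic features are not jointly normal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from fmritex.errors import GeometryError
from fmritex.texture import FEATURE_NAMES
from fmritex.volumes import (
    E,
    NE,
    ControlROISpec,
    ImageVolume,
    ROIMask,
    place_control_rois,
    write_manifest,
    write_mask,
    write_volume,
)

#: per-class marginal (mean, SD) of each rotation-invariant feature,
#: defaulting to the study population's printed descriptive statistics
#: (43 E / 73 NE ROIs). Keys: feature -> ((mean_E, sd_E), (mean_NE, sd_NE)).
CLASS_FEATURE_STATS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "autocorrelation": ((27.5, 6.9), (33.4, 10.8)),
    "contrast": ((0.3, 0.2), (0.2, 0.4)),
    "correlation": ((0.6, 0.3), (0.6, 0.3)),
    "cluster_prominence": ((8.0, 10.7), (9.1, 20.8)),
    "cluster_shade": ((-1.1, 2.0), (-0.7, 2.3)),
    "dissimilarity": ((0.3, 0.2), (0.2, 0.2)),
    "energy": ((0.5, 0.3), (0.5, 0.3)),
    "entropy": ((0.5, 0.3), (0.4, 0.3)),
    "homogeneity": ((0.9, 0.1), (0.9, 0.1)),
    "maximum_probability": ((0.6, 0.2), (0.6, 0.2)),
    "sum_of_squares_variance": ((27.9, 7.3), (33.4, 10.8)),
    "sum_average": ((10.4, 1.3), (11.4, 1.9)),
    "sum_variance": ((101.5, 25.4), (124.5, 39.8)),
    "sum_entropy": ((0.4, 0.2), (0.4, 0.2)),
    "difference_variance": ((0.3, 0.2), (0.2, 0.4)),
    "difference_entropy": ((0.2, 0.1), (0.2, 0.1)),
    "imc1": ((-0.3, 0.2), (-0.4, 0.2)),
    "imc2": ((0.4, 0.2), (0.4, 0.2)),
    "inverse_difference_normalized": ((1.0, 0.004), (1.0, 0.004)),
    "inverse_difference_moment_normalized": ((1.0, 0.002), (1.0, 0.002)),
}

#: the four strongly intercorrelated brightness/spread features
CORRELATED_BLOCK: tuple[str, ...] = (
    "autocorrelation", "sum_of_squares_variance", "sum_average", "sum_variance",
)


@dataclasses.dataclass
class ClassTexture:
    """Spatial texture parameters of one ROI class."""

    corr_sigma: float   # in-plane Gaussian correlation length (voxels)
    mean: float         # intensity offset of the ROI field (a.u.)
    sd: float           # intensity SD of the ROI field (a.u.)
    skew: float = 0.0   # strength of the positive-skew transform

    def __post_init__(self) -> None:
        if self.corr_sigma <= 0:
            raise ValueError("correlation length must be positive")


@dataclasses.dataclass
class ImageGenConfig:
    """Study-sized synthetic imaging cohort: 15 subjects, 116 ROIs (43 E /
    73 NE including the two fixed control ROIs per subject)."""

    n_subjects: int = 15
    e_rois_per_subject: tuple[int, ...] = (3,) * 13 + (2,) * 2   # 43 E
    ne_rois_per_subject: tuple[int, ...] = (3,) * 13 + (2,) * 2  # +30 ctrl = 73 NE
    volume_shape: tuple[int, int, int] = (64, 64, 30)
    roi_extent: tuple[int, int, int] = (9, 9, 3)
    e_texture: ClassTexture = dataclasses.field(
        default_factory=lambda: ClassTexture(corr_sigma=0.7, mean=600.0,
                                             sd=60.0, skew=1.0))
    ne_texture: ClassTexture = dataclasses.field(
        default_factory=lambda: ClassTexture(corr_sigma=2.0, mean=650.0,
                                             sd=50.0, skew=0.0))
    noise_sd: float = 40.0       # background volume noise SD
    background_mean: float = 500.0
    background_sigma: float = 1.5  # background smoothing
    control_spec: ControlROISpec = dataclasses.field(
        default_factory=ControlROISpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.e_rois_per_subject) != self.n_subjects or \
                len(self.ne_rois_per_subject) != self.n_subjects:
            raise ValueError("per-subject ROI counts must match n_subjects")
        if not self.e_texture.corr_sigma < self.ne_texture.corr_sigma:
            raise ValueError(
                "E is the heterogeneous class: its correlation length must "
                "be shorter than NE's")
        if any(e > v for e, v in zip(self.roi_extent, self.volume_shape)):
            raise GeometryError("ROI extent exceeds volume shape")


def _textured_field(shape: tuple[int, int, int], tex: ClassTexture,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with in-plane correlation + optional skew."""
    pad = int(np.ceil(4 * tex.corr_sigma))
    noise = rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad,
                                 shape[2]))
    g = gaussian_filter(noise, sigma=(tex.corr_sigma, tex.corr_sigma, 0.0))
    g = g[pad:pad + shape[0], pad:pad + shape[1], :]
    g = (g - g.mean()) / (g.std() + 1e-12)
    if tex.skew:
        g = g + tex.skew * (g ** 2 - 1.0) / 2.0  # quadratic skewing, mean ~0
        g = (g - g.mean()) / (g.std() + 1e-12)
    return tex.mean + tex.sd * g


def _place_box(occupied: np.ndarray, extent: tuple[int, int, int],
               rng: np.random.Generator, max_tries: int = 500
               ) -> tuple[slice, slice, slice]:
    shape = occupied.shape
    for _ in range(max_tries):
        corner = tuple(int(rng.integers(1, s - e - 1))
                       for s, e in zip(shape, extent))
        box = tuple(slice(c, c + e) for c, e in zip(corner, extent))
        if not occupied[box].any():
            occupied[box] = True
            return box
    raise GeometryError("could not place a non-overlapping ROI; volume too "
                        "crowded for the configured extents")


@dataclasses.dataclass
class VolumeDataset:
    volumes: dict[str, ImageVolume]      # subject_id -> mean-EPI-like volume
    rois: list[ROIMask]                  # labelled masks, all subjects
    config: ImageGenConfig

    def label_counts(self) -> dict[str, int]:
        return {
            "n_rois": len(self.rois),
            "n_e": sum(r.label == E for r in self.rois),
            "n_ne": sum(r.label == NE for r in self.rois),
        }

    def save(self, out_dir: str | Path) -> Path:
        """Write NIfTI volumes/masks plus the ROI manifest CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for sid, vol in self.volumes.items():
            write_volume(vol, out / f"{sid}_mean_epi.nii")
        for roi in self.rois:
            mask_path = out / f"{roi.roi_id}_mask.nii"
            write_mask(roi, self.volumes[roi.subject_id], mask_path)
            manifest.append({"subject_id": roi.subject_id,
                             "roi_id": roi.roi_id,
                             "mask_path": str(mask_path), "label": roi.label})
        write_manifest(manifest, out / "roi_manifest.csv")
        return out / "roi_manifest.csv"


def generate_volume_dataset(config: ImageGenConfig | None = None
                            ) -> VolumeDataset:
    """Simulate the imaging cohort: textured ROIs embedded in noisy volumes."""
    config = config or ImageGenConfig()
    rng = np.random.default_rng(config.seed)
    volumes: dict[str, ImageVolume] = {}
    rois: list[ROIMask] = []
    spacing = (3.75, 3.75, 4.0)  # 24 cm FOV / 64 matrix, 4 mm slices
    for s in range(config.n_subjects):
        sid = f"sub{s + 1:02d}"
        base = config.background_mean + config.noise_sd * gaussian_filter(
            rng.standard_normal(config.volume_shape),
            sigma=config.background_sigma)
        data = base
        occupied = np.zeros(config.volume_shape, dtype=bool)
        # reserve the fixed control-ROI sites before random placement
        vol_tmp = ImageVolume(data=data.copy(), spacing=spacing)
        controls = place_control_rois(vol_tmp, config.control_spec,
                                      subject_id=sid)
        for ctrl in controls:
            occupied |= ctrl.mask

        subject_rois: list[tuple[str, str]] = []  # (label, roi_id)
        counts = [(E, config.e_rois_per_subject[s], config.e_texture),
                  (NE, config.ne_rois_per_subject[s], config.ne_texture)]
        masks: list[ROIMask] = []
        for label, n_rois, tex in counts:
            for k in range(n_rois):
                box = _place_box(occupied, config.roi_extent, rng)
                data[box] = _textured_field(config.roi_extent, tex, rng)
                mask = np.zeros(config.volume_shape, dtype=bool)
                mask[box] = True
                masks.append(ROIMask(mask=mask, subject_id=sid,
                                     roi_id=f"{sid}_{label.lower()}{k + 1}",
                                     label=label))
        # control ROIs keep background texture ("no functional activity")
        volumes[sid] = ImageVolume(data=data, spacing=spacing)
        rois.extend(masks)
        rois.extend(controls)
    return VolumeDataset(volumes=volumes, rois=rois, config=config)


@dataclasses.dataclass
class TableGenConfig:
    """Feature-table generator matched to the study's printed marginals."""

    n_e: int = 43
    n_ne: int = 73
    n_subjects: int = 15
    class_stats: dict = dataclasses.field(
        default_factory=lambda: dict(CLASS_FEATURE_STATS))
    correlated_features: tuple[str, ...] = CORRELATED_BLOCK
    correlation: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        for feat, ((_, sd_e), (_, sd_ne)) in self.class_stats.items():
            if sd_e < 0 or sd_ne < 0:
                raise ValueError(f"negative SD for feature {feat}")


def _class_cov(sds: np.ndarray, features: list[str],
               block: tuple[str, ...], rho: float) -> np.ndarray:
    corr = np.eye(len(features))
    idx = [features.index(f) for f in block if f in features]
    for a in idx:
        for b in idx:
            if a != b:
                corr[a, b] = rho
    # shrink toward the identity until positive semi-definite
    for _ in range(60):
        if np.linalg.eigvalsh(corr).min() >= -1e-10:
            break
        corr = 0.95 * corr + 0.05 * np.eye(len(features))
    else:
        raise ValueError("correlation matrix infeasible even after shrinkage")
    return corr * np.outer(sds, sds)


def generate_feature_table(config: TableGenConfig | None = None
                           ) -> pd.DataFrame:
    """Draw a labelled feature table from the per-class Gaussian model.

    Subject ids are assigned round-robin over ``n_subjects`` so each subject
    holds a mix of both classes and grouped splitting is exercised.
    """
    config = config or TableGenConfig()
    rng = np.random.default_rng(config.seed)
    features = [f for f in FEATURE_NAMES if f in config.class_stats]
    blocks = []
    for cls_idx, (label, n) in enumerate([(E, config.n_e), (NE, config.n_ne)]):
        means = np.array([config.class_stats[f][cls_idx][0] for f in features])
        sds = np.array([config.class_stats[f][cls_idx][1] for f in features])
        cov = _class_cov(sds, features, config.correlated_features,
                         config.correlation)
        draws = rng.multivariate_normal(means, cov, size=n,
                                        method="svd")
        df = pd.DataFrame(draws, columns=features)
        df.insert(0, "label", label)
        blocks.append(df)
    table = pd.concat(blocks, ignore_index=True)
    table.insert(0, "subject_id",
                 [f"sub{(i % config.n_subjects) + 1:02d}"
                  for i in range(len(table))])
    table.insert(1, "roi_id", [f"roi{i + 1:03d}" for i in range(len(table))])
    return table
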