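"""Gray-level co-occurrence matrices and the 20 rotation-invariant features.

Pipeline per ROI: pool the ROI's intensities over its axial slices and
quantize them into ``n_levels`` equal-width gray bins (default 8); count
co-occurring in-ROI pixel pairs at unit offset along the four directions
0/45/90/135 degrees (symmetric counting, so each GLCM equals its transpose);
accumulate raw counts over the ROI's slices and normalize once per
direction; compute the 20 Haralick/Soh/Clausi features per direction and
average them over directions to obtain a rotation-invariant value.

All entropies use the natural logarithm, with 0*log(0) := 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fmritex.errors import (
    ContractError,
    DegenerateStatisticWarning,
    EmptyROIError,
    FeatureUndefinedError,
)
from fmritex.volumes import ImageVolume, ROIMask, ROIPatch, extract_patches

#: the 20 rotation-invariant texture features, in canonical output order
FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

DIRECTIONS: tuple[int, ...] = (0, 45, 90, 135)

# (row, col) pixel offsets at unit distance; unit grid steps are used for the
# diagonals (no anisotropic-spacing correction).
_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclasses.dataclass
class QuantizedPatch:
    """An ROI slice with intensities mapped to integer gray levels 1..n."""

    slice_index: int
    levels: np.ndarray
    inside: np.ndarray
    n_levels: int
    degenerate: bool = False  # constant ROI collapsed to a single level

    def __post_init__(self) -> None:
        vals = self.levels[self.inside]
        if vals.size and (vals.min() < 1 or vals.max() > self.n_levels):
            raise ContractError("quantized levels out of range 1..n_levels")


@dataclasses.dataclass
class GLCM:
    """Co-occurrence counts or probabilities for one angular direction."""

    matrix: np.ndarray
    direction: int
    distance: int
    normalized: bool = False
    empty: bool = False  # no valid pixel pair contributed

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]


def quantize(patches: Sequence[ROIPatch], n_levels: int = 8) -> list[QuantizedPatch]:
    """Equal-width gray-level quantization over the ROI's pooled range.

    The [min, max] range over all inside pixels of all slices is split into
    ``n_levels`` equal bins; levels are 1-based and the top edge belongs to
    the last bin. A constant ROI maps everything to level 1 and sets the
    degeneracy flag on each patch.
    """
    if n_levels < 2:
        raise ContractError(f"n_levels must be >= 2, got {n_levels}")
    if not patches:
        raise EmptyROIError("no patches to quantize")
    pooled = np.concatenate([p.values[p.inside] for p in patches])
    lo, hi = float(pooled.min()), float(pooled.max())
    degenerate = hi == lo
    out = []
    for p in patches:
        if degenerate:
            levels = np.ones_like(p.values, dtype=np.int64)
        else:
            levels = np.floor((p.values - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
            np.clip(levels, 1, n_levels, out=levels)
        out.append(QuantizedPatch(slice_index=p.slice_index, levels=levels,
                                  inside=p.inside, n_levels=n_levels,
                                  degenerate=degenerate))
    return out


def compute_glcm(patch: QuantizedPatch, direction: int, distance: int = 1) -> GLCM:
    """Raw symmetric co-occurrence counts for one direction.

    Every ordered pair of inside pixels separated by the direction/distance
    offset contributes to both (i, j) and (j, i). Counts are returned
    unnormalized so they can be accumulated across an ROI's slices.
    """
    if direction not in _OFFSETS:
        raise ContractError(f"direction must be one of {DIRECTIONS}, got {direction}")
    if distance < 1:
        raise ContractError("distance must be >= 1")
    n = patch.n_levels
    dr, dc = (d * distance for d in _OFFSETS[direction])
    h, w = patch.levels.shape

    # overlap windows of the grid and its shifted copy
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    mat = np.zeros((n, n), dtype=np.float64)
    if r0 < r1 and c0 < c1:
        a = patch.levels[r0:r1, c0:c1]
        b = patch.levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = patch.inside[r0:r1, c0:c1] & patch.inside[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        i, j = a[ok] - 1, b[ok] - 1
        np.add.at(mat, (i, j), 1.0)
        np.add.at(mat, (j, i), 1.0)
    return GLCM(matrix=mat, direction=direction, distance=distance,
                normalized=False, empty=not mat.any())


def roi_glcms(patches: Sequence[QuantizedPatch], distance: int = 1) -> list[GLCM]:
    """One normalized GLCM per direction, counts accumulated over slices.

    Accumulating raw counts before normalizing weights each slice by its
    number of pixel pairs, so tiny slices do not dominate. Directions with
    no valid pair anywhere stay flagged empty; if all four are empty (e.g. a
    single-pixel ROI) the ROI's features are undefined.
    """
    if not patches:
        raise EmptyROIError("no quantized patches")
    n = patches[0].n_levels
    out = []
    for theta in DIRECTIONS:
        total = np.zeros((n, n))
        for p in patches:
            total += compute_glcm(p, theta, distance).matrix
        s = total.sum()
        if s > 0:
            out.append(GLCM(matrix=total / s, direction=theta,
                            distance=distance, normalized=True))
        else:
            out.append(GLCM(matrix=total, direction=theta, distance=distance,
                            normalized=True, empty=True))
    if all(g.empty for g in out):
        raise FeatureUndefinedError(
            "no co-occurring pixel pair in any direction; texture features "
            "are undefined for this ROI"
        )
    return out


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_derived(p: np.ndarray) -> dict:
    """Marginals, sum/difference distributions and entropies of a GLCM."""
    n = p.shape[0]
    idx = np.arange(1, n + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    i = idx[:, None]
    j = idx[None, :]
    p_sum = np.zeros(2 * n - 1)  # k = 2 .. 2n
    p_diff = np.zeros(n)         # k = 0 .. n-1
    np.add.at(p_sum, (i + j - 2).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    hxy = float(-_xlogx(p).sum())
    pxpy = np.outer(px, py)
    logs = np.zeros_like(pxpy)
    nz = pxpy > 0
    logs[nz] = np.log(pxpy[nz])
    hxy1 = float(-(p * logs).sum())
    hxy2 = float(-_xlogx(pxpy).sum())
    return dict(px=px, py=py, p_sum=p_sum, p_diff=p_diff,
                mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y,
                HX=hx, HY=hy, HXY=hxy, HXY1=hxy1, HXY2=hxy2)


def compute_features(glcm: GLCM) -> dict[str, float]:
    """The 20 texture features of a normalized GLCM (natural-log entropies).

    Degenerate conventions: a diagonal point mass has zero marginal spread,
    so correlation := 1; when max(HX, HY) = 0, imc1 := 0; the imc2 square
    root clamps tiny negative arguments to 0.
    """
    if not glcm.normalized or abs(glcm.matrix.sum() - 1.0) > 1e-9:
        raise ContractError("compute_features requires a normalized GLCM")
    p = glcm.matrix
    n = p.shape[0]
    idx = np.arange(1, n + 1)
    i = idx[:, None].astype(float)
    j = idx[None, :].astype(float)
    d = glcm_derived(p)
    mu_x, mu_y = d["mu_x"], d["mu_y"]
    sigma_x, sigma_y = d["sigma_x"], d["sigma_y"]
    p_sum, p_diff = d["p_sum"], d["p_diff"]
    k_sum = np.arange(2, 2 * n + 1, dtype=float)
    k_diff = np.arange(0, n, dtype=float)

    f: dict[str, float] = {}
    f["autocorrelation"] = float((i * j * p).sum())
    f["contrast"] = float(((i - j) ** 2 * p).sum())
    if sigma_x * sigma_y > 0:
        f["correlation"] = float(
            ((i * j * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    else:
        f["correlation"] = 1.0
    f["cluster_prominence"] = float(((i + j - mu_x - mu_y) ** 4 * p).sum())
    f["cluster_shade"] = float(((i + j - mu_x - mu_y) ** 3 * p).sum())
    f["dissimilarity"] = float((np.abs(i - j) * p).sum())
    f["energy"] = float((p ** 2).sum())
    f["entropy"] = float(-_xlogx(p).sum())
    f["homogeneity"] = float((p / (1.0 + (i - j) ** 2)).sum())
    f["maximum_probability"] = float(p.max())
    mu = float((i * p).sum())  # grand mean of i under p
    f["sum_of_squares_variance"] = float(((i - mu) ** 2 * p).sum())
    sum_avg = float(k_sum @ p_sum)
    f["sum_average"] = sum_avg
    f["sum_variance"] = float(((k_sum - sum_avg) ** 2) @ p_sum)
    f["sum_entropy"] = float(-_xlogx(p_sum).sum())
    diff_mean = float(k_diff @ p_diff)
    f["difference_variance"] = float(((k_diff - diff_mean) ** 2) @ p_diff)
    f["difference_entropy"] = float(-_xlogx(p_diff).sum())
    hx, hy, hxy, hxy1, hxy2 = d["HX"], d["HY"], d["HXY"], d["HXY1"], d["HXY2"]
    denom = max(hx, hy)
    f["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    f["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["inverse_difference_normalized"] = float(
        (p / (1.0 + np.abs(i - j) / n)).sum())
    f["inverse_difference_moment_normalized"] = float(
        (p / (1.0 + (i - j) ** 2 / n ** 2)).sum())
    return {name: f[name] for name in FEATURE_NAMES}


def rotation_invariant_features(glcms: Iterable[GLCM]) -> dict[str, float]:
    """Average the per-direction features into one rotation-invariant vector.

    Directions flagged empty contribute no term to the mean; a warning
    records the exclusion.
    """
    vectors = []
    for g in glcms:
        if g.empty:
            warnings.warn(
                f"direction {g.direction} has no pixel pair; excluded from "
                "the rotation-invariant average", DegenerateStatisticWarning)
            continue
        vectors.append(compute_features(g))
    if not vectors:
        raise FeatureUndefinedError("all directions empty; features undefined")
    return {name: float(np.mean([v[name] for v in vectors]))
            for name in FEATURE_NAMES}


def features_for_roi(volume: ImageVolume, roi: ROIMask, n_levels: int = 8,
                     distance: int = 1) -> dict[str, float]:
    """End-to-end texture vector for one ROI (patches -> quantize -> GLCMs)."""
    patches = extract_patches(volume, roi)
    qpatches = quantize(patches, n_levels=n_levels)
    glcms = roi_glcms(qpatches, distance=distance)
    return rotation_invariant_features(glcms)


def extract_feature_table(volumes: dict[str, ImageVolume],
                          rois: Sequence[ROIMask], n_levels: int = 8,
                          distance: int = 1) -> pd.DataFrame:
    """Texture matrix: one row per ROI with identity, label and provenance.

    ``volumes`` maps subject_id to that subject's mean EPI volume.
    """
    rows = []
    for roi in rois:
        feats = features_for_roi(volumes[roi.subject_id], roi,
                                 n_levels=n_levels, distance=distance)
        rows.append({"subject_id": roi.subject_id, "roi_id": roi.roi_id,
                     "label": roi.label, **feats,
                     "n_levels": n_levels, "distance": distance,
                     "voxel_count": roi.voxel_count})
    return pd.DataFrame(rows)
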