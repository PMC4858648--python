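import numpy as np
import pytest

from fmritex.texture import compute_glcm, quantize
from fmritex.volumes import ImageVolume, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(500.0, 50.0, size=(12, 12, 4))
    return ImageVolume(data=data, spacing=(3.75, 3.75, 4.0))


@pytest.fixture
def box_roi(small_volume):
    mask = np.zeros(small_volume.shape, dtype=bool)
    mask[2:9, 3:10, 1:3] = True
    return ROIMask(mask=mask, subject_id="s1", roi_id="r1", label="E")


def brute_force_glcm(levels: np.ndarray, inside: np.ndarray, n_levels: int,
                     direction: int, distance: int = 1) -> np.ndarray:
    """Independent oracle: O(N^2) loop over all pixel pairs testing the offset."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = (d * distance for d in offsets[direction])
    h, w = levels.shape
    mat = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            for r2 in range(h):
                for c2 in range(w):
                    if (r2 - r, c2 - c) == (dr, dc) and inside[r, c] \
                            and inside[r2, c2]:
                        i, j = levels[r, c] - 1, levels[r2, c2] - 1
                        mat[i, j] += 1
                        mat[j, i] += 1
    return mat


def random_quantized_patch(rng, max_side=12, n_levels=None):
    """A random QuantizedPatch with a random (non-empty) inside mask."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    n = int(n_levels or rng.integers(2, 9))
    values = rng.normal(size=(h, w)) * 10
    inside = rng.random((h, w)) < 0.8
    if not inside.any():
        inside[h // 2, w // 2] = True
    from fmritex.volumes import ROIPatch
    patch = ROIPatch(slice_index=0, values=values, inside=inside)
    return quantize([patch], n_levels=n)[0]


def auc_by_pair_counting(labels, scores) -> float:
    """Independent AUC oracle: normalized Mann-Whitney U with 1/2 for ties."""
    labels = np.asarray(labels, float)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
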