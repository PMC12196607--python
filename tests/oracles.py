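"""Independent brute-force oracles used by the unit and acceptance tests.

These are deliberately naive (explicit neighbour loops, all-pairs
distances, full enumeration) and share no code with the package paths
they check.
"""

from itertools import product

import numpy as np


def brute_force_boundary(values: np.ndarray) -> np.ndarray:
    """Indices of mask voxels with a face-adjacent outside/off-grid neighbour."""
    out = []
    shape = values.shape
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for idx in np.argwhere(values):
        i, j, k = idx
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out.append((i, j, k))
                break
            if not values[ni, nj, nk]:
                out.append((i, j, k))
                break
    return np.asarray(out, dtype=float).reshape(-1, 3)


def brute_force_hausdorff(values_a, values_b, spacing, origin=(0.0, 0.0, 0.0)):
    """All-pairs max-min Euclidean distance between boundary voxel centres."""
    pa = brute_force_boundary(values_a) * np.asarray(spacing) + np.asarray(origin)
    pb = brute_force_boundary(values_b) * np.asarray(spacing) + np.asarray(origin)
    dmat = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(dmat.min(axis=1).max(), dmat.min(axis=0).max())


def brute_force_dice(values_a, values_b) -> float:
    na = int(values_a.sum())
    nb = int(values_b.sum())
    inter = int((values_a & values_b).sum())
    return 2.0 * inter / (na + nb)


def enumerate_wilcoxon_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Mid-ranks of |d|; two-sided p doubles the smaller tail of the
    positive-rank-sum null distribution, capped at 1.
    """
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = np.array(
        [np.sum(ranks[list(signs)]) if any(signs) else 0.0
         for signs in product([False, True], repeat=n)]
    )
    lower = np.mean(w_all <= w_obs + 1e-12)
    upper = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def random_mask_pair(rng, shape, p_range=(0.05, 0.5)):
    """Two random nonempty blob-ish masks on a shared grid."""
    from scipy import ndimage

    def one():
        while True:
            raw = rng.random(shape) < rng.uniform(*p_range)
            smooth = ndimage.binary_opening(raw)
            vals = smooth if smooth.any() else raw
            if vals.any():
                return vals

    return one(), one()
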