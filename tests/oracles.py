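"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the rotation
search enumerates a grid instead of solving Kabsch in closed form, and
the bootstrap resamples blocks instead of propagating block means.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def _batch_rmsd(rotvecs: np.ndarray, mobile_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    mats = Rotation.from_rotvec(rotvecs).as_matrix()  # (B, 3, 3)
    moved = np.einsum("bij,nj->bni", mats, mobile_c)
    d = moved - ref_c[None, :, :]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def brute_force_min_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    final_step_deg: float = 0.1,
) -> float:
    """Minimum RMSD over rotations by grid search in rotation-vector space.

    Coarse global grid over the radius-pi ball (15 deg spacing), then
    repeated local grid refinement around the best point down to a step
    of ``final_step_deg``. Translation is handled exactly by centering,
    which is optimal for any fixed rotation.
    """
    mobile_c = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    ref_c = np.asarray(reference, float) - np.mean(reference, axis=0)

    step = np.radians(15.0)
    axis = np.arange(-np.pi, np.pi + step / 2, step)
    grid = np.array(np.meshgrid(axis, axis, axis)).reshape(3, -1).T
    grid = grid[np.linalg.norm(grid, axis=1) <= np.pi + 1e-9]
    values = _batch_rmsd(grid, mobile_c, ref_c)
    best = grid[np.argmin(values)]
    best_val = float(values.min())

    while step > np.radians(final_step_deg) / 2:
        step /= 3.0
        offsets = np.arange(-3, 4) * step
        local = best[None, :] + np.array(
            np.meshgrid(offsets, offsets, offsets)
        ).reshape(3, -1).T
        values = _batch_rmsd(local, mobile_c, ref_c)
        if values.min() < best_val:
            best_val = float(values.min())
            best = local[np.argmin(values)]
    return best_val


def moving_block_bootstrap_se(
    x: np.ndarray,
    block_len: int,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Moving-block-bootstrap standard error of the mean of a series."""
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, float)
    n = len(x)
    n_blocks = int(np.ceil(n / block_len))
    starts_max = n - block_len
    means = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        sample = np.concatenate([x[s : s + block_len] for s in starts])[:n]
        means[b] = sample.mean()
    return float(means.std(ddof=1))
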