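"""Monte Carlo cluster-extent threshold for voxelwise-thresholded maps.

Null volumes are i.i.d. standard normal fields on the full rectangular grid
(no volume mask), smoothed with a Gaussian kernel of the given FWHM,
re-standardized to unit variance (so the uncorrected voxel p still maps to a
fixed z cut), and thresholded one-tailed.  The largest suprathreshold
cluster per iteration yields an empirical max-cluster-size distribution;
the cluster-extent threshold is the smallest integer k whose exceedance
probability falls below the family-wise alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class MCConfig:
    shape: tuple[int, int, int] = (102, 102, 66)
    voxel_size_mm: float = 2.0
    fwhm_mm: float = 8.0
    voxel_p: float = 0.001
    n_iterations: int = 1000
    fwe_alpha: float = 0.05
    connectivity: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a 3-D grid, got {self.shape}")
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")
        if not 0.0 < self.voxel_p < 0.5:
            raise ValueError("voxel_p must be in (0, 0.5)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if not 0.0 < self.fwe_alpha < 1.0:
            raise ValueError("fwe_alpha must be in (0, 1)")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18, or 26")

    @property
    def sigma_voxels(self) -> float:
        """Gaussian kernel sigma per axis, voxel units: FWHM / (2 sqrt(2 ln 2))."""
        return self.fwhm_mm / self.voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def z_threshold(self) -> float:
        """One-tailed z cut for the uncorrected voxel p."""
        return float(sps.norm.isf(self.voxel_p))


@dataclass(frozen=True)
class MCThresholdResult:
    extent_threshold: int
    max_cluster_sizes: np.ndarray
    achieved_fwe: float
    config: MCConfig

    def exceedance(self, k: int) -> float:
        """Empirical P(max cluster size >= k)."""
        return float(np.mean(self.max_cluster_sizes >= k))


def connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def simulate_null_volume(config: MCConfig, rng: np.random.Generator) -> np.ndarray:
    """One binary suprathreshold mask from smoothed, re-standardized noise."""
    vol = rng.standard_normal(config.shape)
    if config.fwhm_mm > 0:
        vol = ndimage.gaussian_filter(vol, sigma=config.sigma_voxels)
        vol = (vol - vol.mean()) / vol.std()
    return vol > config.z_threshold


def max_cluster_size(mask: np.ndarray, connectivity: int = 18) -> int:
    labels, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return 0
    return int(np.bincount(labels.reshape(-1))[1:].max())


def estimate_extent_threshold(config: MCConfig) -> MCThresholdResult:
    """Empirical max-cluster-size distribution and the minimal extent k with
    P(max >= k) < fwe_alpha."""
    rng = np.random.default_rng(config.seed)
    sizes = np.empty(config.n_iterations, dtype=np.int64)
    for i in range(config.n_iterations):
        sizes[i] = max_cluster_size(simulate_null_volume(config, rng), config.connectivity)
    for k in range(1, int(sizes.max()) + 2):
        fwe = float(np.mean(sizes >= k))
        if fwe < config.fwe_alpha:
            return MCThresholdResult(k, sizes, fwe, config)
    raise RuntimeError("unreachable: exceedance of max+1 is always 0")
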