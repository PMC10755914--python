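"""Gray-white boundary mapping: thresholds, binary boundary map, box density.

The per-subject boundary band is built from two intensity pools: voxels
holding more than 50% gray matter and voxels holding more than 50% white
matter (strict inequality; ties at exactly 0.5 are excluded).  With pool
mean m and sample standard deviation s (n-1 denominator, 2SD dispersion
terms):

    lower = m_GM + (2 s_GM) / 2 = m_GM + s_GM
    upper = m_WM - (2 s_WM) / 2 = m_WM - s_WM

Voxels whose intensity falls inside [lower, upper] (inclusive) and whose
combined GM+WM fraction exceeds 0.5 form the binary boundary map (gwBB).
Convolving gwBB with a normalized 5x5x5 box kernel (zero padding) yields
the boundary density map, read as the local boundary-tissue volume
fraction (gwBTV): multiply by the voxel volume for mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import TissueFractions
from .volio import Volume, check_common_space

__all__ = [
    "ThresholdPair",
    "BoundaryBinaryMap",
    "BoundaryDensityMap",
    "compute_thresholds",
    "compute_gwbb",
    "box_convolve",
]

#: fraction rule for "more than 50% volume" pool membership
POOL_FRACTION = 0.5


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper boundary band and the four pool statistics behind it."""

    gm_mean: float
    gm_2sd: float
    wm_mean: float
    wm_2sd: float

    def __post_init__(self) -> None:
        if self.gm_2sd < 0 or self.wm_2sd < 0:
            raise ValueError("2SD terms must be non-negative")

    @property
    def lower(self) -> float:
        return self.gm_mean + self.gm_2sd / 2.0

    @property
    def upper(self) -> float:
        return self.wm_mean - self.wm_2sd / 2.0

    @property
    def degenerate(self) -> bool:
        """True when the band is empty (lower >= upper); gwBB will be all-zero."""
        return self.lower >= self.upper


@dataclass
class BoundaryBinaryMap:
    """gwBB: 1 inside the boundary band on GM/WM tissue, 0 elsewhere."""

    data: Volume
    eligible_mask: np.ndarray
    thresholds: ThresholdPair

    def __post_init__(self) -> None:
        vals = np.unique(self.data.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("gwBB values must be 0/1")
        if self.data.data[~self.eligible_mask].any():
            raise ValueError("gwBB nonzero outside the eligible mask")


@dataclass
class BoundaryDensityMap:
    """Box-convolved gwBB: local boundary-tissue volume fraction in [0, 1]."""

    data: Volume
    kernel_size: int

    def __post_init__(self) -> None:
        d = self.data.data
        if d.min(initial=0.0) < -1e-12 or d.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("density values must lie in [0, 1]")


def compute_thresholds(t1: Volume, fractions: TissueFractions) -> ThresholdPair:
    """Per-subject boundary band from the >50%-GM and >50%-WM intensity pools.

    Raises if either pool has fewer than 2 voxels (the sample SD needs n>=2).
    A degenerate band (lower >= upper) is returned with a warning; the
    downstream gwBB is then empty.
    """
    check_common_space([t1, fractions.gm, fractions.wm])
    intens = np.asarray(t1.data, dtype=np.float64)
    gm_pool = intens[fractions.gm.data > POOL_FRACTION]
    wm_pool = intens[fractions.wm.data > POOL_FRACTION]
    if gm_pool.size < 2:
        raise ValueError(f"GM pool has {gm_pool.size} voxel(s); need >= 2")
    if wm_pool.size < 2:
        raise ValueError(f"WM pool has {wm_pool.size} voxel(s); need >= 2")
    thr = ThresholdPair(
        gm_mean=float(gm_pool.mean()),
        gm_2sd=float(2.0 * gm_pool.std(ddof=1)),
        wm_mean=float(wm_pool.mean()),
        wm_2sd=float(2.0 * wm_pool.std(ddof=1)),
    )
    if thr.degenerate:
        warnings.warn(
            f"degenerate band: lower {thr.lower:.4g} >= upper {thr.upper:.4g}; "
            "gwBB will be empty",
            RuntimeWarning,
        )
    return thr


def compute_gwbb(
    t1: Volume, fractions: TissueFractions, thr: ThresholdPair
) -> BoundaryBinaryMap:
    """Binary boundary map: band membership restricted to GM/WM tissue.

    Eligibility (the "location information" of segmented tissue) is
    f_GM + f_WM > 0.5, which keeps CSF and background voxels with
    band-range intensities out of the map.
    """
    check_common_space([t1, fractions.gm, fractions.wm])
    eligible = (fractions.gm.data + fractions.wm.data) > 0.5
    intens = np.asarray(t1.data, dtype=np.float64)
    data = (eligible & (intens >= thr.lower) & (intens <= thr.upper)).astype(np.float64)
    return BoundaryBinaryMap(data=t1.like(data), eligible_mask=eligible, thresholds=thr)


def box_convolve(gwbb: BoundaryBinaryMap, kernel_size: int = 5) -> BoundaryDensityMap:
    """Normalized box (mean) filter of gwBB with zero padding outside the grid.

    Each output voxel is the mean of gwBB over the centred
    kernel_size^3 neighbourhood; kernel weight 1/kernel_size^3 keeps values
    in [0, 1] and conserves total mass.  kernel_size must be odd; size 1 is
    the identity.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    density = ndimage.uniform_filter(
        np.asarray(gwbb.data.data, dtype=np.float64), size=kernel_size, mode="constant", cval=0.0
    )
    # clamp float dust from the separable moving sums
    np.clip(density, 0.0, 1.0, out=density)
    return BoundaryDensityMap(data=gwbb.data.like(density), kernel_size=kernel_size)
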