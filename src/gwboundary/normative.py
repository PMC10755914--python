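"""Control-cohort normative model, gwBZ maps and FWHM Gaussian smoothing.

The normative model is the voxelwise mean and sample SD of the convolved
boundary maps of the cognitively normal (CN) group.  A subject's gwBZ map is

    z = (individual - control mean) / control SD

on voxels where the control SD exceeds a small floor, zero elsewhere; the
sign convention makes boundary loss negative (a subject with less boundary
tissue than the control population scores below zero).

Smoothing uses a separable Gaussian parameterized by full width at half
maximum, sigma = FWHM / (2 sqrt(2 ln 2)), truncated at 4 sigma, normalized,
with reflective boundary handling, so constant inputs are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .boundary import BoundaryDensityMap
from .volio import Volume, check_common_space

__all__ = [
    "NormativeModel",
    "ZScoreMap",
    "SmoothingConfig",
    "FWHM_TO_SIGMA",
    "build_normative",
    "zscore",
    "gaussian_smooth",
]

#: sigma = FWHM * FWHM_TO_SIGMA
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SD_FLOOR = 1e-6


@dataclass
class NormativeModel:
    mean_map: Volume
    sd_map: Volume
    n_controls: int
    kernel_size: int
    sd_floor: float = SD_FLOOR

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("normative model needs >= 2 controls")
        if float(self.sd_map.data.min(initial=0.0)) < 0:
            raise ValueError("sd_map must be non-negative")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.sd_map.data > self.sd_floor


@dataclass
class ZScoreMap:
    data: Volume
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.data.data[~self.valid_mask].any():
            raise ValueError("z-scores nonzero outside the valid mask")


@dataclass(frozen=True)
class SmoothingConfig:
    fwhm_mm: float = 8.0
    truncate_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm * FWHM_TO_SIGMA


def build_normative(
    densities: list[BoundaryDensityMap], sd_floor: float = SD_FLOOR
) -> NormativeModel:
    """Voxelwise mean and sample SD (n-1) over control boundary-density maps."""
    if len(densities) < 2:
        raise ValueError(f"need >= 2 control maps, got {len(densities)}")
    kernels = {d.kernel_size for d in densities}
    if len(kernels) != 1:
        raise ValueError(f"mixed kernel sizes in control maps: {sorted(kernels)}")
    check_common_space([d.data for d in densities])
    stack = np.stack([np.asarray(d.data.data, dtype=np.float64) for d in densities])
    ref = densities[0].data
    return NormativeModel(
        mean_map=ref.like(stack.mean(axis=0)),
        sd_map=ref.like(stack.std(axis=0, ddof=1)),
        n_controls=len(densities),
        kernel_size=kernels.pop(),
        sd_floor=sd_floor,
    )


def zscore(subject: BoundaryDensityMap, model: NormativeModel) -> ZScoreMap:
    """gwBZ map: (individual - control mean) / control SD on the valid mask."""
    if subject.kernel_size != model.kernel_size:
        raise ValueError(
            f"kernel mismatch: subject {subject.kernel_size} vs model {model.kernel_size}"
        )
    check_common_space([subject.data, model.mean_map])
    valid = model.valid_mask
    z = np.zeros(subject.data.shape)
    z[valid] = (
        np.asarray(subject.data.data, dtype=np.float64)[valid] - model.mean_map.data[valid]
    ) / model.sd_map.data[valid]
    return ZScoreMap(data=subject.data.like(z), valid_mask=valid)


def gaussian_smooth(v: Volume, cfg: SmoothingConfig = SmoothingConfig()) -> Volume:
    """Separable Gaussian smoothing with per-axis sigma in voxels.

    sigma_vox = sigma_mm / voxel_size per axis; reflective boundaries and a
    normalized truncated kernel preserve constants exactly.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite voxels in smoothing input")
    sigma_vox = [cfg.sigma_mm / d for d in v.voxel_size_mm]
    out = ndimage.gaussian_filter(
        data, sigma=sigma_vox, mode="reflect", truncate=cfg.truncate_sigmas
    )
    return v.like(out)
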