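"""GM/WM/CSF partial-volume fractions and total intracranial volume.

Two routes provide tissue fractions: pass-through (fraction volumes supplied
as files, mirroring use of an external segmenter) and a built-in 3-class
univariate Gaussian-mixture EM on T1 intensities.  Components are assigned
to tissues by ascending mean intensity — CSF < GM < WM, the standard T1
contrast — and the per-voxel posterior responsibilities are read as
partial-volume fractions.

The EM is written out explicitly (quantile initialisation, free means,
variances and weights) so the per-iteration log-likelihood trace is
available; the trace is guaranteed non-decreasing, which downstream tests
assert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volio import Volume

__all__ = ["TissueFractions", "SegmentationConfig", "segment_gmm", "compute_tiv"]


@dataclass
class TissueFractions:
    """Per-voxel GM/WM/CSF fractions in [0, 1] on a shared grid."""

    gm: Volume
    wm: Volume
    csf: Volume
    converged: bool = True
    loglik_trace: list[float] = field(default_factory=list)
    component_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape}
        if len(shapes) != 1:
            raise ValueError(f"fraction grids disagree in shape: {shapes}")
        total = self.gm.data + self.wm.data + self.csf.data
        if float(total.max(initial=0.0)) > 1.0 + 1e-9:
            raise ValueError("gm+wm+csf exceeds 1 somewhere")
        for name, v in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if v.data.min(initial=0.0) < -1e-12 or v.data.max(initial=0.0) > 1 + 1e-9:
                raise ValueError(f"{name} fraction outside [0, 1]")

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.gm.data + self.wm.data + self.csf.data) > 0

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.gm.voxel_size_mm


@dataclass(frozen=True)
class SegmentationConfig:
    n_classes: int = 3
    tol: float = 1e-8
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _log_gauss(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def segment_gmm(
    t1: Volume, mask: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> TissueFractions:
    """Fit a 3-component univariate Gaussian mixture to in-mask intensities.

    Initialisation is deterministic (component means at the 1/6, 3/6, 5/6
    intensity quantiles, shared initial variance, equal weights), so the fit
    does not depend on ``config.seed``; the seed field is kept for API
    stability.  Fractions are the posterior responsibilities, zero outside
    the mask.  Non-convergence after ``max_iter`` warns and returns the
    current estimate flagged ``converged=False``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1.shape:
        raise ValueError("mask shape does not match volume")
    x = np.asarray(t1.data, dtype=np.float64)[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities inside mask")
    k = config.n_classes
    if k != 3:
        raise ValueError("segmentation is fixed at 3 tissue classes")
    if x.size < 3 * k:
        raise ValueError(f"only {x.size} in-mask voxels; need at least {3 * k}")

    mu = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    var = np.full(k, max(x.var(), 1e-12) / k)
    w = np.full(k, 1.0 / k)

    trace: list[float] = []
    converged = False
    resp = np.empty((x.size, k))
    for _ in range(config.max_iter):
        # E-step
        log_p = np.stack(
            [np.log(w[j]) + _log_gauss(x, mu[j], var[j]) for j in range(k)], axis=1
        )
        m = log_p.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_p - log_norm[:, None])
        if trace and abs(ll - trace[-1]) <= config.tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step
        nk = resp.sum(axis=0) + 1e-300
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-12)
    if not converged:
        warnings.warn(
            f"EM did not converge within {config.max_iter} iterations", RuntimeWarning
        )

    order = np.argsort(mu)  # ascending mean: CSF, GM, WM
    resp = resp[:, order]
    out = []
    for j in range(k):
        grid = np.zeros(t1.shape)
        grid[mask] = resp[:, j]
        out.append(t1.like(grid))
    csf_v, gm_v, wm_v = out
    return TissueFractions(
        gm=gm_v,
        wm=wm_v,
        csf=csf_v,
        converged=converged,
        loglik_trace=trace,
        component_means=mu[order],
    )


def compute_tiv(fractions: TissueFractions) -> float:
    """Total intracranial volume in cm^3: sum of all tissue fractions times
    the voxel volume."""
    total = fractions.gm.data + fractions.wm.data + fractions.csf.data
    return float(total.sum() * fractions.gm.voxel_volume_mm3 / 1000.0)
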