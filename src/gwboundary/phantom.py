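"""Synthetic brain phantoms and cohorts with known ground truth.

The phantom is a nested-ellipsoid brain: a white-matter core, a gray-matter
shell and a surrounding CSF layer, embedded in a common grid.  Partial-volume
tissue fractions are computed by supersampled ellipsoid membership, so the
gray-white interface has genuine subvoxel structure.  Disease is modelled
primarily as a collapse of the gray-white intensity contrast (the band
between the gray- and white-derived thresholds provably narrows as the GM-WM
intensity gap shrinks), with geometric boundary blur, GM-shell atrophy and
additive Gaussian noise as additional degradation knobs.

Cohorts attach the covariates the group statistics consume: age (entering
the subject table only, never the image geometry), a cognition score driven
negatively by contrast loss, and a fixed per-group clinical dementia rating.
A small per-subject global brain-scale jitter makes total intracranial
volume vary realistically across subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import TissueFractions, compute_tiv
from .volio import CohortManifest, ROIAtlas, Volume, write_atlas, write_volume

__all__ = [
    "PhantomSpec",
    "DiseaseSeverity",
    "GroupModel",
    "KmmseModel",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "make_toy_atlas",
    "default_cohort_spec",
]

GROUPS = ("CN", "MCI", "AD")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one phantom brain.

    ``intensities`` are nominal CSF/GM/WM signal levels in arbitrary units
    and must be strictly increasing (T1 contrast).  ``supersample`` is the
    per-axis subvoxel sampling factor for the partial-volume ground truth.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wm_semiaxes_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    gm_thickness_mm: float = 4.0
    csf_thickness_mm: float = 3.0
    intensities: tuple[float, float, float] = (40.0, 100.0, 160.0)  # CSF, GM, WM
    supersample: int = 3
    space_tag: str = "phantom-common"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel spacings must be positive")
        if any(a <= 0 for a in self.wm_semiaxes_mm):
            raise ValueError("WM semi-axes must be positive")
        if self.gm_thickness_mm <= 0:
            raise ValueError("gm_thickness_mm must be positive")
        if self.csf_thickness_mm < 0:
            raise ValueError("csf_thickness_mm must be non-negative")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        csf, gm, wm = self.intensities
        if not (csf < gm < wm):
            raise ValueError("intensities must be strictly increasing CSF < GM < WM")


@dataclass(frozen=True)
class DiseaseSeverity:
    """Degradation applied to one phantom.

    contrast_scale in (0, 1] multiplies the WM-GM intensity gap (1 = intact);
    boundary_blur_mm is the std-dev of a Gaussian blur of the noiseless
    intensity; atrophy_mm thins the GM shell (the vacated space becomes CSF);
    noise_sd is the additive Gaussian noise level in intensity units.
    """

    contrast_scale: float = 1.0
    boundary_blur_mm: float = 0.0
    atrophy_mm: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast_scale <= 1.0):
            raise ValueError("contrast_scale must be in (0, 1]")
        if min(self.boundary_blur_mm, self.atrophy_mm, self.noise_sd) < 0:
            raise ValueError("blur/atrophy/noise must be >= 0")


def _block_mean(a: np.ndarray, s: int, shape: tuple[int, int, int]) -> np.ndarray:
    if s == 1:
        return a.astype(np.float64)
    nx, ny, nz = shape
    return a.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))


def _fractions(spec: PhantomSpec, atrophy_mm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Supersampled GM/WM/CSF partial-volume fractions.

    The GM outer surface moves inward with atrophy; the brain's outer
    (CSF) surface stays fixed, so atrophy converts GM into CSF ex vacuo.
    """
    s = spec.supersample
    wm_ax = np.asarray(spec.wm_semiaxes_mm, dtype=float)
    gm_ax = wm_ax + (spec.gm_thickness_mm - atrophy_mm)
    br_ax = wm_ax + spec.gm_thickness_mm + spec.csf_thickness_mm

    # per-axis 1D squared coordinates for each shell, combined by broadcasting
    coords = []
    for ax in range(3):
        n, d = spec.grid_shape[ax], spec.voxel_size_mm[ax]
        centre = n * d / 2.0
        x = (np.arange(n * s) + 0.5) / s * d - centre
        coords.append(x)

    def inside(semi: np.ndarray) -> np.ndarray:
        qx = (coords[0] / semi[0]) ** 2
        qy = (coords[1] / semi[1]) ** 2
        qz = (coords[2] / semi[2]) ** 2
        return (qx[:, None, None] + qy[None, :, None] + qz[None, None, :]) <= 1.0

    in_wm = inside(wm_ax)
    in_gm = inside(gm_ax) & ~in_wm
    in_br = inside(br_ax)
    in_csf = in_br & ~in_gm & ~in_wm

    wm = _block_mean(in_wm, s, spec.grid_shape)
    gm = _block_mean(in_gm, s, spec.grid_shape)
    csf = _block_mean(in_csf, s, spec.grid_shape)
    return gm, wm, csf


def make_phantom(
    spec: PhantomSpec, severity: DiseaseSeverity, seed: int
) -> tuple[Volume, TissueFractions]:
    """Generate one phantom brain.

    The intensity is the fraction-weighted tissue mixture
    ``I = f_CSF*I_CSF + f_GM*I_GM' + f_WM*I_WM`` with the degraded gray level
    ``I_GM' = I_WM - contrast_scale*(I_WM - I_GM)``, then geometric blur, then
    seeded additive noise.  The returned fractions are the unblurred
    geometric ground truth: segmentation recovery is tested against geometry,
    not against the degraded image.
    """
    if severity.atrophy_mm >= spec.gm_thickness_mm:
        raise ValueError("GM shell eliminated: atrophy_mm >= gm_thickness_mm")
    gm, wm, csf = _fractions(spec, severity.atrophy_mm)
    i_csf, i_gm, i_wm = spec.intensities
    i_gm_eff = i_wm - severity.contrast_scale * (i_wm - i_gm)
    intensity = csf * i_csf + gm * i_gm_eff + wm * i_wm
    if severity.boundary_blur_mm > 0:
        sigma_vox = [severity.boundary_blur_mm / d for d in spec.voxel_size_mm]
        intensity = ndimage.gaussian_filter(intensity, sigma=sigma_vox, mode="nearest")
    if severity.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, severity.noise_sd, size=intensity.shape)
    vol = Volume(intensity, spec.voxel_size_mm, spec.space_tag)
    frac = TissueFractions(
        gm=vol.like(gm), wm=vol.like(wm), csf=vol.like(csf)
    )
    return vol, frac


def make_toy_atlas(spec: PhantomSpec, shell_mm: float = 2.0) -> ROIAtlas:
    """Three-ROI atlas tied to the nominal (disease-free) geometry.

    Label 1: boundary shell, voxels within +-``shell_mm`` of the nominal
    GM/WM interface (measured by offsetting the WM semi-axes); label 2: the
    rest of the GM shell; label 3: the rest of the WM core; 0: background.
    """
    wm_ax = np.asarray(spec.wm_semiaxes_mm, dtype=float)
    gm_ax = wm_ax + spec.gm_thickness_mm

    grids = np.meshgrid(
        *[
            (np.arange(n) + 0.5) * d - n * d / 2.0
            for n, d in zip(spec.grid_shape, spec.voxel_size_mm)
        ],
        indexing="ij",
    )

    def rho2(semi: np.ndarray) -> np.ndarray:
        return sum((g / a) ** 2 for g, a in zip(grids, semi))

    in_wm = rho2(wm_ax) <= 1.0
    in_gm_outer = rho2(gm_ax) <= 1.0
    shell = (rho2(wm_ax + shell_mm) <= 1.0) & (rho2(np.maximum(wm_ax - shell_mm, 1e-6)) > 1.0)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[in_wm] = 3
    labels[in_gm_outer & ~in_wm] = 2
    labels[shell] = 1
    vol = Volume(labels, spec.voxel_size_mm, spec.space_tag)
    return ROIAtlas(vol, {1: "boundary_shell", 2: "gm_shell", 3: "wm_core"})


@dataclass(frozen=True)
class GroupModel:
    """Per-group severity and age distributions."""

    severity: DiseaseSeverity
    contrast_scale_sd: float = 0.05
    age_mean: float = 72.0
    age_sd: float = 5.0


@dataclass(frozen=True)
class KmmseModel:
    """Cognition score model: intercept + slope * contrast loss + noise.

    Slope is negative on severity (contrast loss = 1 - contrast_scale), so
    more degraded boundaries mean lower scores; output clipped to [0, 30].
    """

    intercept: float = 27.4
    slope: float = -20.0
    noise_sd: float = 2.0
    clip: tuple[float, float] = (0.0, 30.0)


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: tuple[int, int, int] = (5, 5, 5)  # CN, MCI, AD
    severity_by_group: dict[str, GroupModel] = field(default_factory=dict)
    kmmse_model: KmmseModel = KmmseModel()
    cdr_by_group: tuple[float, float, float] = (0.0, 0.5, 1.0)
    brain_scale_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.severity_by_group:
            object.__setattr__(self, "severity_by_group", _default_group_models())
        missing = set(GROUPS) - set(self.severity_by_group)
        if any(n > 0 for n in self.n_per_group) and missing & {
            g for g, n in zip(GROUPS, self.n_per_group) if n > 0
        }:
            raise ValueError(f"severity_by_group missing groups: {sorted(missing)}")


def _default_group_models() -> dict[str, GroupModel]:
    """Study conditions: ordered boundary degradation CN < MCI < AD.

    Disease ordering is carried entirely by gray-white contrast collapse
    (1.0 / 0.8 / 0.6) plus GM atrophy; geometric blur is held constant
    across groups because blur widens the apparent interface and has no
    monotone relation to boundary-band occupancy.  Age distributions follow
    typical memory-clinic cohorts.
    """
    return {
        "CN": GroupModel(DiseaseSeverity(1.0, 0.3, 0.0, 2.0), 0.05, 71.8, 4.8),
        "MCI": GroupModel(DiseaseSeverity(0.8, 0.3, 0.3, 2.0), 0.05, 72.6, 5.1),
        "AD": GroupModel(DiseaseSeverity(0.6, 0.3, 0.6, 2.0), 0.05, 73.6, 7.7),
    }


def default_cohort_spec(n_cn: int = 5, n_mci: int = 5, n_ad: int = 5, seed: int = 0) -> CohortSpec:
    return CohortSpec(n_per_group=(n_cn, n_mci, n_ad), seed=seed)


def _subject_seed(root: int, index: int, stream: int) -> int:
    return int(np.random.SeedSequence([root, index, stream]).generate_state(1)[0] % (2**31))


def make_cohort(
    cohort: CohortSpec, spec: PhantomSpec, out_dir: str | Path | None = None
) -> CohortManifest:
    """Generate a full cohort: one phantom per subject plus the subject table.

    Deterministic given ``cohort.seed``: each subject's noise, covariates and
    severity jitter come from seeds derived with ``SeedSequence`` from the
    root seed and the subject index.  When ``out_dir`` is given, t1/gm/wm/csf
    volumes are written as uncompressed NIfTI per subject and the table as
    ``cohort.csv``; volumes are also kept in memory on the manifest.
    """
    rows = []
    volumes: dict[str, Volume] = {}
    fractions: dict[str, TissueFractions] = {}
    paths: dict[str, Path] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    idx = 0
    for group, n in zip(GROUPS, cohort.n_per_group):
        model = cohort.severity_by_group[group]
        for k in range(n):
            sid = f"{group}{k:03d}"
            rng = np.random.default_rng(_subject_seed(cohort.seed, idx, 0))
            base = model.severity
            contrast = float(
                np.clip(rng.normal(base.contrast_scale, model.contrast_scale_sd), 0.05, 1.0)
            )
            severity = dataclasses.replace(base, contrast_scale=contrast)
            scale = float(np.clip(rng.normal(1.0, cohort.brain_scale_sd), 0.94, 1.06))
            subj_spec = dataclasses.replace(
                spec,
                wm_semiaxes_mm=tuple(a * scale for a in spec.wm_semiaxes_mm),
                gm_thickness_mm=spec.gm_thickness_mm * scale,
                csf_thickness_mm=spec.csf_thickness_mm * scale,
            )
            age = float(rng.normal(model.age_mean, model.age_sd))
            km = cohort.kmmse_model
            kmmse = float(
                np.clip(
                    km.intercept + km.slope * (1.0 - contrast) + rng.normal(0.0, km.noise_sd),
                    *km.clip,
                )
            )
            vol, frac = make_phantom(subj_spec, severity, _subject_seed(cohort.seed, idx, 1))
            volumes[sid] = vol
            fractions[sid] = frac
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": round(age, 2),
                    "kmmse": round(kmmse, 2),
                    "cdr": cohort.cdr_by_group[GROUPS.index(group)],
                    "tiv": round(compute_tiv(frac), 4),
                    "contrast_scale": round(contrast, 6),
                    "boundary_blur_mm": severity.boundary_blur_mm,
                    "atrophy_mm": severity.atrophy_mm,
                    "brain_scale": round(scale, 6),
                }
            )
            if out is not None:
                prefix = out / sid
                write_volume(vol, f"{prefix}_t1.nii")
                write_volume(frac.gm.like(frac.gm.data.astype(np.float32)), f"{prefix}_gm.nii")
                write_volume(frac.wm.like(frac.wm.data.astype(np.float32)), f"{prefix}_wm.nii")
                write_volume(frac.csf.like(frac.csf.data.astype(np.float32)), f"{prefix}_csf.nii")
                paths[sid] = prefix
            idx += 1

    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out / "cohort.csv", index=False)
        write_atlas(make_toy_atlas(spec), out / "atlas.nii")
    return CohortManifest(table=table, volumes=volumes, fractions=fractions, paths=paths)
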