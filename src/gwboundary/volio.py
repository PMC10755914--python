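"""NIfTI volume I/O and the common-space contract.

All downstream stages assume spatially co-registered inputs: every volume
entering a cross-subject operation must share grid shape, voxel spacing and
space tag.  Geometry throughout the package is computed in voxel indices
scaled by spacing; no world-affine arithmetic is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "ROIAtlas",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "check_common_space",
]

#: relative tolerance for voxel-spacing equality across subjects
SPACING_RTOL = 1e-6

DEFAULT_SPACE = "common"


@dataclass
class Volume:
    """A 3D scalar grid in a named common space.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values.  Integer dtypes are preserved (atlases).
    voxel_size_mm : tuple of 3 floats
        Per-axis voxel spacing in millimetres; all entries positive.
    space_tag : str
        Identifier of the common space the grid lives in.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = DEFAULT_SPACE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacings must be positive, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid metadata and different data."""
        return Volume(data, self.voxel_size_mm, self.space_tag)


@dataclass
class ROIAtlas:
    """Integer-labelled ROI volume; label 0 is background."""

    labels: Volume
    name_map: dict[int, str]

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            raise ValueError("atlas labels must be integer-typed")
        present = set(np.unique(self.labels.data).tolist()) - {0}
        missing = present - set(self.name_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from name_map")

    @property
    def roi_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels.data).tolist()) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.labels.data == label


@dataclass
class CohortManifest:
    """Subject table plus per-subject volumes (in memory or on disk).

    ``table`` has one row per subject with columns subject_id, group, age,
    kmmse, cdr and the planted severity ground truth.  ``volumes`` and
    ``fractions`` map subject_id to the in-memory objects when the cohort
    was generated in memory; ``paths`` maps subject_id to the file prefix
    when it was written to disk.
    """

    table: "pandas.DataFrame"  # noqa: F821 - kept light; pandas imported by maker
    volumes: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.table["subject_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject ids in cohort table")
        bad = set(self.table["group"]) - {"CN", "MCI", "AD"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")


def _space_tag_from_header(img: nib.Nifti1Image) -> str:
    descrip = img.header["descrip"].tobytes().split(b"\x00", 1)[0].decode(errors="replace")
    return descrip or DEFAULT_SPACE


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI volume.

    Integer on-disk dtypes are preserved; the space tag is carried in the
    NIfTI ``descrip`` header field.  Raises on missing files, 4D images and
    non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D single-frame image, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        if n_bad:
            raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, _space_tag_from_header(img))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from its spacing."""
    path = Path(path)
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.voxel_size_mm)
    img.header["descrip"] = vol.space_tag.encode()[:79]
    nib.save(img, path)
    return path


def read_atlas(path: str | Path, name_map: dict[int, str] | None = None) -> ROIAtlas:
    vol = read_volume(path)
    if not np.issubdtype(vol.data.dtype, np.integer):
        data = vol.data
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: atlas volume is not integer-valued")
        vol = Volume(np.round(data).astype(np.int32), vol.voxel_size_mm, vol.space_tag)
    if name_map is None:
        name_map = {lab: f"roi{lab}" for lab in np.unique(vol.data) if lab != 0}
    return ROIAtlas(vol, dict(name_map))


def write_atlas(atlas: ROIAtlas, path: str | Path) -> Path:
    lab = atlas.labels
    return write_volume(Volume(lab.data.astype(np.int16), lab.voxel_size_mm, lab.space_tag), path)


def check_common_space(volumes: list[Volume]) -> None:
    """Verify all volumes share grid shape, spacing and space tag.

    Raises ``ValueError`` naming the first offending pair; silent on success.
    Spacing is compared with relative tolerance ``SPACING_RTOL``.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if v.shape != ref.shape:
            raise ValueError(
                f"common-space violation: volume 0 has shape {ref.shape}, "
                f"volume {i} has shape {v.shape}"
            )
        if not np.allclose(v.voxel_size_mm, ref.voxel_size_mm, rtol=SPACING_RTOL, atol=0):
            raise ValueError(
                f"common-space violation: volume 0 spacing {ref.voxel_size_mm} vs "
                f"volume {i} spacing {v.voxel_size_mm}"
            )
        if v.space_tag != ref.space_tag:
            raise ValueError(
                f"common-space violation: volume 0 space '{ref.space_tag}' vs "
                f"volume {i} space '{v.space_tag}'"
            )
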