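"""End-to-end pipeline: simulate -> boundary -> normative -> zmap -> stats.

Every stage reads its inputs from and writes its outputs to a run directory,
so stages can be re-run individually; a rerun with an identical config and
seed is bit-identical (volumes are written as uncompressed NIfTI and tables
with fixed float formatting).  A manifest listing every artifact with its
stage and SHA-256 checksum, plus a resolved copy of the configuration, is
written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bnd
from . import normative as nrm
from . import phantom as ph
from . import stats as gst
from .segmentation import TissueFractions
from .volio import Volume, read_atlas, read_volume, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "boundary", "normative", "zmap", "roi-stats", "voxel-stats", "classify")

#: Table-4-style feature sets evaluated per group pair in the classify stage
FEATURE_SETS = [
    ("gwbz",),
    ("gwbtv",),
    ("gwbz", "gwbtv"),
    ("gwbz", "kmmse"),
    ("gwbtv", "kmmse"),
    ("gwbz", "cdr"),
    ("gwbz", "gwbtv", "kmmse"),
    ("gwbz", "gwbtv", "cdr", "kmmse"),
]

PAIRS = [("CN", "MCI"), ("CN", "AD"), ("MCI", "AD")]


@dataclass
class PipelineConfig:
    """Run directory, cohort size and the analysis parameters.

    The analysis defaults are the pipeline's canonical settings: 5x5x5 box
    kernel, 8 mm FWHM smoothing, FDR alpha 0.01 with 100-voxel cluster
    extent under 18-connectivity, SD floor 1e-6.
    """

    out_dir: Path = Path("gwb_run")
    n_per_group: tuple[int, int, int] = (5, 5, 5)
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    supersample: int = 3
    kernel_size: int = 5
    fwhm_mm: float = 8.0
    fdr_alpha: float = 0.01
    min_extent: int = 100
    connectivity: int = 18
    sd_floor: float = 1e-6
    seed: int = 0
    loo: bool = False
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def phantom_spec(self) -> ph.PhantomSpec:
        return ph.PhantomSpec(
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=tuple(self.voxel_size_mm),
            supersample=self.supersample,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_per_group", "grid_shape", "voxel_size_mm", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _read_fractions(prefix: Path) -> TissueFractions:
    return TissueFractions(
        gm=read_volume(f"{prefix}_gm.nii"),
        wm=read_volume(f"{prefix}_wm.nii"),
        csf=read_volume(f"{prefix}_csf.nii"),
    )


def _cohort_table(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.out_dir / "simulate" / "cohort.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing cohort table {path}; run the 'simulate' stage first")
    return pd.read_csv(path)


def _density(cfg: PipelineConfig, sid: str) -> bnd.BoundaryDensityMap:
    path = cfg.out_dir / "boundary" / f"{sid}_gwbtv.nii"
    if not path.exists():
        raise FileNotFoundError(f"missing boundary density {path}; run 'boundary' first")
    return bnd.BoundaryDensityMap(data=read_volume(path), kernel_size=cfg.kernel_size)


def _f32(v: Volume) -> Volume:
    return v.like(np.asarray(v.data, dtype=np.float32))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = cfg.out_dir / "simulate"
    spec = cfg.phantom_spec()
    cohort = ph.CohortSpec(n_per_group=tuple(cfg.n_per_group), seed=cfg.seed)
    ph.make_cohort(cohort, spec, out_dir=out)
    return sorted(out.iterdir())


def stage_boundary(cfg: PipelineConfig) -> list[Path]:
    table = _cohort_table(cfg)
    sim = cfg.out_dir / "simulate"
    out = cfg.out_dir / "boundary"
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {}
    for sid in table["subject_id"]:
        t1 = read_volume(sim / f"{sid}_t1.nii")
        frac = _read_fractions(sim / sid)
        thr = bnd.compute_thresholds(t1, frac)
        gwbb = bnd.compute_gwbb(t1, frac, thr)
        dens = bnd.box_convolve(gwbb, kernel_size=cfg.kernel_size)
        write_volume(_f32(dens.data), out / f"{sid}_gwbtv.nii")
        thresholds[sid] = {
            "lower": round(thr.lower, 6),
            "upper": round(thr.upper, 6),
            "gm_mean": round(thr.gm_mean, 6),
            "gm_2sd": round(thr.gm_2sd, 6),
            "wm_mean": round(thr.wm_mean, 6),
            "wm_2sd": round(thr.wm_2sd, 6),
        }
    with open(out / "thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=1, sort_keys=True)
    return sorted(out.iterdir())


def stage_normative(cfg: PipelineConfig) -> list[Path]:
    table = _cohort_table(cfg)
    cn_ids = table.loc[table["group"] == "CN", "subject_id"].tolist()
    densities = [_density(cfg, sid) for sid in cn_ids]
    model = nrm.build_normative(densities, sd_floor=cfg.sd_floor)
    out = cfg.out_dir / "normative"
    out.mkdir(parents=True, exist_ok=True)
    write_volume(_f32(model.mean_map), out / "mean.nii")
    write_volume(_f32(model.sd_map), out / "sd.nii")
    with open(out / "meta.json", "w") as fh:
        json.dump(
            {
                "n_controls": model.n_controls,
                "kernel_size": model.kernel_size,
                "sd_floor": model.sd_floor,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return sorted(out.iterdir())


def _load_model(cfg: PipelineConfig) -> nrm.NormativeModel:
    out = cfg.out_dir / "normative"
    meta_path = out / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"missing normative model in {out}; run the 'normative' stage first"
        )
    with open(meta_path) as fh:
        meta = json.load(fh)
    return nrm.NormativeModel(
        mean_map=read_volume(out / "mean.nii"),
        sd_map=read_volume(out / "sd.nii"),
        n_controls=meta["n_controls"],
        kernel_size=meta["kernel_size"],
        sd_floor=meta["sd_floor"],
    )


def stage_zmap(cfg: PipelineConfig) -> list[Path]:
    table = _cohort_table(cfg)
    model = _load_model(cfg)
    smooth_cfg = nrm.SmoothingConfig(fwhm_mm=cfg.fwhm_mm)
    out = cfg.out_dir / "zmap"
    out.mkdir(parents=True, exist_ok=True)
    cn_ids = table.loc[table["group"] == "CN", "subject_id"].tolist()
    for sid, group in zip(table["subject_id"], table["group"]):
        dens = _density(cfg, sid)
        if cfg.loo and group == "CN" and len(cn_ids) > 2:
            others = [_density(cfg, other) for other in cn_ids if other != sid]
            subj_model = nrm.build_normative(others, sd_floor=cfg.sd_floor)
        else:
            subj_model = model
        z = nrm.zscore(dens, subj_model)
        write_volume(_f32(nrm.gaussian_smooth(z.data, smooth_cfg)), out / f"{sid}_gwbz.nii")
        write_volume(
            _f32(nrm.gaussian_smooth(dens.data, smooth_cfg)), out / f"{sid}_gwbtv.nii"
        )
    return sorted(out.iterdir())


def _roi_table(cfg: PipelineConfig) -> pd.DataFrame:
    """Subject x ROI x map-type mean values joined to the subject table."""
    table = _cohort_table(cfg)
    atlas = read_atlas(
        cfg.out_dir / "simulate" / "atlas.nii",
        {1: "boundary_shell", 2: "gm_shell", 3: "wm_core"},
    )
    zdir = cfg.out_dir / "zmap"
    if not zdir.exists():
        raise FileNotFoundError(f"missing z-maps in {zdir}; run the 'zmap' stage first")
    rows = []
    for _, rec in table.iterrows():
        sid = rec["subject_id"]
        for map_type in ("gwbz", "gwbtv"):
            vol = read_volume(zdir / f"{sid}_{map_type}.nii")
            means = gst.roi_means(vol, atlas)
            for lab, val in means.items():
                rows.append(
                    {
                        "subject_id": sid,
                        "group": rec["group"],
                        "age": rec["age"],
                        "kmmse": rec["kmmse"],
                        "cdr": rec["cdr"],
                        "tiv": rec["tiv"],
                        "map": map_type,
                        "roi": atlas.name_map[lab],
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


def stage_roi_stats(cfg: PipelineConfig) -> list[Path]:
    roi_tab = _roi_table(cfg)
    out = cfg.out_dir / "roi_stats"
    out.mkdir(parents=True, exist_ok=True)
    roi_tab.to_csv(out / "roi_values.csv", index=False, float_format="%.6g")

    comp_rows, corr_rows = [], []
    for (map_type, roi), sub in roi_tab.groupby(["map", "roi"], sort=True):
        sub = sub.sort_values("subject_id")
        y = sub["value"].to_numpy()
        cov = sub[["age", "tiv"]].to_numpy()
        res = gst.ancova_group(
            y, sub["group"].to_numpy(), cov, group_order=["CN", "MCI", "AD"]
        )
        stats_by_group = sub.groupby("group")["value"]
        row = {"map": map_type, "roi": roi, "F": round(res.f, 4), "p": res.p}
        for g in ("CN", "MCI", "AD"):
            row[f"{g}_mean"] = round(float(stats_by_group.mean().get(g, np.nan)), 6)
            row[f"{g}_sd"] = round(float(stats_by_group.std().get(g, np.nan)), 6)
        for pair, pp in res.posthoc.items():
            row[f"p_{pair[0]}_vs_{pair[1]}"] = pp
        comp_rows.append(row)

        age_r = gst.pearson_corr(sub["age"].to_numpy(), y)
        km_r = gst.partial_corr(sub["kmmse"].to_numpy(), y, cov)
        corr_rows.append(
            {
                "map": map_type,
                "roi": roi,
                "age_r": round(age_r.r, 4),
                "age_p": age_r.p,
                "kmmse_r": round(km_r.r, 4),
                "kmmse_p": km_r.p,
            }
        )
    pd.DataFrame(comp_rows).to_csv(out / "group_comparison.csv", index=False, float_format="%.6g")
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False, float_format="%.6g")
    return sorted(out.iterdir())


def stage_voxel_stats(cfg: PipelineConfig) -> list[Path]:
    table = _cohort_table(cfg)
    model = _load_model(cfg)
    zdir = cfg.out_dir / "zmap"
    out = cfg.out_dir / "voxel_stats"
    out.mkdir(parents=True, exist_ok=True)
    table = table.sort_values("subject_id").reset_index(drop=True)
    maps = [read_volume(zdir / f"{sid}_gwbz.nii") for sid in table["subject_id"]]
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "mci": (table["group"] == "MCI").astype(float),
            "ad": (table["group"] == "AD").astype(float),
            "age": table["age"].astype(float),
            "tiv": table["tiv"].astype(float),
        }
    )
    statmap = gst.voxel_glm(maps, design, ["mci", "ad"], mask=model.valid_mask)
    clusters = gst.fdr_cluster_filter(
        statmap, alpha=cfg.fdr_alpha, min_extent=cfg.min_extent, connectivity=cfg.connectivity
    )
    write_volume(_f32(statmap.stat), out / "group_F.nii")
    write_volume(_f32(statmap.p), out / "group_p.nii")
    ref = statmap.stat
    write_volume(
        Volume(clusters.mask.astype(np.int16), ref.voxel_size_mm, ref.space_tag),
        out / "group_sig_mask.nii",
    )
    clusters.table.to_csv(out / "clusters.csv", index=False, float_format="%.6g")
    return sorted(out.iterdir())


def stage_classify(cfg: PipelineConfig, roi: str = "boundary_shell") -> list[Path]:
    roi_tab = _roi_table(cfg)
    out = cfg.out_dir / "classify"
    out.mkdir(parents=True, exist_ok=True)
    wide = roi_tab[roi_tab["roi"] == roi].pivot_table(
        index=["subject_id", "group", "kmmse", "cdr"], columns="map", values="value"
    ).reset_index()
    rows = []
    for g0, g1 in PAIRS:
        sub = wide[wide["group"].isin([g0, g1])].sort_values("subject_id")
        y = (sub["group"] == g1).astype(int).to_numpy()
        for feats in FEATURE_SETS:
            X = sub[list(feats)].to_numpy()
            res = gst.logistic_roc(X, y)
            rows.append(
                {
                    "pair": f"{g0}_vs_{g1}",
                    "features": "+".join(feats),
                    "roi": roi,
                    "SE": round(res.sensitivity, 2),
                    "SP": round(res.specificity, 2),
                    "AUC": round(res.auc, 4),
                    "p": res.p,
                    "separable": res.separable,
                }
            )
    pd.DataFrame(rows).to_csv(out / "roc_table.csv", index=False, float_format="%.6g")
    return sorted(out.iterdir())


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "boundary": stage_boundary,
    "normative": stage_normative,
    "zmap": stage_zmap,
    "roi-stats": stage_roi_stats,
    "voxel-stats": stage_voxel_stats,
    "classify": stage_classify,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order and write the manifest.

    Returns the manifest: resolved config plus, per stage, every artifact
    with a path relative to the run directory and its SHA-256 checksum.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict[str, str]] = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        produced = _STAGE_FUNCS[stage](cfg)
        artifacts[stage] = {
            str(p.relative_to(cfg.out_dir)): _sha256(p) for p in produced if p.is_file()
        }
    manifest = {"config": cfg.to_dict(), "artifacts": artifacts}
    manifest["config"]["out_dir"] = "."  # keep the manifest location-independent
    with open(cfg.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(cfg.out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh, sort_keys=True)
    return manifest
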