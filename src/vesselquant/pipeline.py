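"""End-to-end orchestration: synthesize → separate → segment → measure →
aggregate → associate, with a YAML config, a run manifest, and fully
seeded, reproducible outputs.

Every stage is a pure function of (inputs, config, seed); two runs with
the same config produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .case_aggregation import aggregate_case, cases_to_frame, compute_icc
from .cohort_statistics import (
    NotEstimableError,
    cox_fit,
    design_matrix,
    dichotomize,
    km_logrank,
    spearman,
    subgroup_forest,
)
from .images import RGBImage
from .stain_separation import StainModel, default_stain_model, quantize_256, separate_image
from .synthetic_data import (
    LayoutInfeasibleError,
    generate_cohort,
    generate_vessel_layout,
    ground_truth_table,
    render_ihc_image,
)
from .vessel_morphometry import compute_image_metrics
from .vessel_segmentation import segment_image

log = logging.getLogger("vesselquant")

FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All pipeline parameters; everything is echoed to the run manifest."""

    seed: int
    out_dir: str
    resolution_px_per_um: float = 4.0
    # synthesis
    n_cases: int = 12
    cores_per_case: int = 3
    image_size_px: tuple[int, int] = (768, 768)
    n_vessels_per_core: int = 8  # Poisson mean; cores vary (floor 2)
    diameter_log_mean: float = float(np.log(10.0))
    diameter_log_sd: float = 0.30  # within-case spread
    case_diameter_log_sd: float = 0.30  # between-case heterogeneity
    sma_covered_fraction: float = 0.5
    noise_sd_od: float = 0.02
    n_stroma_patches: int = 2
    true_log_hr: float = float(np.log(3.0))
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.3
    # stains
    stain_vectors: dict = field(default_factory=dict)
    # segmentation
    threshold: int | str = 64
    despeckle_radius_px: int = 2
    enlarge_radius_px: int = 3
    smooth_radius_px: int = 2
    min_feret_floor_um: float = 4.0
    # morphometry
    ring_distance_px: int = 10
    stroma_threshold_od: float = 0.15
    od_max: float = 2.0
    fcv_cutoff_convention: str = "cohort_median"  # or "per_case_median"
    # aggregation / statistics
    aggregation_mode: str = "pooled"
    ties: str = "breslow"

    def stains(self) -> StainModel:
        if self.stain_vectors:
            return StainModel.from_dict(
                {k: tuple(v) for k, v in self.stain_vectors.items()}
            )
        return default_stain_model()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.image_size_px, list):
            cfg.image_size_px = tuple(cfg.image_size_px)
        if cfg.aggregation_mode not in ("pooled", "median_of_cores"):
            raise ConfigError(f"bad aggregation_mode {cfg.aggregation_mode!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def stage_synth(cfg: RunConfig, out: Path) -> dict:
    """Render per-core images + ground truth, and the clinical table."""
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    stains = cfg.stains()
    gt_frames = []
    rng = np.random.default_rng(cfg.seed)
    for i in range(cfg.n_cases):
        case = f"case_{i:04d}"
        # cases differ in typical vessel caliber (inter-tumor heterogeneity);
        # the cores of one case share that case-level mean
        case_mu = cfg.diameter_log_mean + float(
            rng.normal(0.0, cfg.case_diameter_log_sd)
        )
        # mural coverage is likewise a case-level trait
        case_covered = float(
            np.clip(rng.normal(cfg.sma_covered_fraction, 0.2), 0.0, 1.0)
        )
        for j in range(cfg.cores_per_case):
            n_vessels = max(2, int(rng.poisson(cfg.n_vessels_per_core)))
            layout = None
            for _ in range(20):  # dense draws can fail to pack; resample
                sub_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    layout = generate_vessel_layout(
                        n_vessels=n_vessels,
                        diameter_log_mean=case_mu,
                        diameter_log_sd=cfg.diameter_log_sd,
                        image_size_px=cfg.image_size_px,
                        resolution_px_per_um=cfg.resolution_px_per_um,
                        sma_covered_fraction=case_covered,
                        seed=sub_seed,
                        n_stroma_patches=cfg.n_stroma_patches,
                    )
                    break
                except LayoutInfeasibleError:
                    continue
            if layout is None:
                raise DataError(
                    f"could not synthesize a feasible layout for {case} core {j}"
                )
            img = render_ihc_image(
                layout, stains, noise_sd_od=cfg.noise_sd_od, seed=sub_seed
            )
            tifffile.imwrite(img_dir / f"{case}_core{j}.tiff", img.pixels)
            gt_frames.append(ground_truth_table(layout, case, f"core{j}"))
    gt = pd.concat(gt_frames, ignore_index=True)
    _write_csv(gt, out / "ground_truth_vessels.csv")

    true_sizes = gt.groupby("case_id")["diameter_um"].median().sort_index()
    clinical = generate_cohort(
        cfg.n_cases,
        true_log_hr=cfg.true_log_hr,
        baseline_hazard=cfg.baseline_hazard,
        censoring_rate=cfg.censoring_rate,
        seed=cfg.seed + 1,
        sizes_um=true_sizes.to_numpy(),
    )
    clinical["case_id"] = true_sizes.index
    _write_csv(clinical, out / "clinical.csv")
    return {"n_images": cfg.n_cases * cfg.cores_per_case}


def stage_measure(cfg: RunConfig, out: Path) -> dict:
    """Separate, segment and measure every image; write per-vessel and
    per-image tables."""
    img_dir = out / "images"
    paths = sorted(img_dir.glob("*.tiff"))
    if not paths:
        raise DataError("no inputs: image directory is empty")
    stains = cfg.stains()
    per_image_rows = []
    per_vessel_frames = []
    metrics_by_image = {}
    for path in paths:
        pixels = tifffile.imread(path)
        image = RGBImage(pixels, cfg.resolution_px_per_um)
        od_maps = separate_image(image.pixels, stains)
        cd34_layer = quantize_256(od_maps["cd34"], od_max=cfg.od_max)
        _, vessels = segment_image(
            cd34_layer,
            cfg.resolution_px_per_um,
            threshold=cfg.threshold,
            despeckle_radius_px=cfg.despeckle_radius_px,
            enlarge_radius_px=cfg.enlarge_radius_px,
            smooth_radius_px=cfg.smooth_radius_px,
            min_feret_floor_um=cfg.min_feret_floor_um,
        )
        m = compute_image_metrics(
            path.stem,
            vessels,
            od_maps["sma"],
            ring_distance_px=cfg.ring_distance_px,
            stroma_threshold_od=cfg.stroma_threshold_od,
        )
        metrics_by_image[path.stem] = m
        tbl = vessels.table.copy()
        tbl.insert(0, "image_id", path.stem)
        tbl["pv_od"] = m.pv_od
        per_vessel_frames.append(tbl)
        per_image_rows.append(
            {
                "image_id": path.stem,
                "n_vessels": m.n_vessels,
                "tissue_area_mm2": m.tissue_area_mm2,
                "vessel_density": m.vessel_density,
                "median_diameter_um": m.median_diameter_um,
                "pvi": m.pvi,
                "stromal_area_mm2": m.stromal_area_mm2,
                "stromal_od": m.stromal_sma_od_median,
            }
        )
    per_vessel = pd.concat(per_vessel_frames, ignore_index=True)
    _write_csv(per_vessel, out / "per_vessel.csv")
    _write_csv(pd.DataFrame(per_image_rows), out / "per_image.csv")
    # keep the in-memory bundles for aggregation within the same run
    return {"n_images": len(paths), "_metrics": metrics_by_image}


def stage_aggregate(cfg: RunConfig, out: Path, metrics_by_image: dict) -> dict:
    """Pool cores into case-level metrics; report inter-core ICC."""
    by_case: dict[str, list] = {}
    for image_id, m in metrics_by_image.items():
        case = image_id.rsplit("_core", 1)[0]
        by_case.setdefault(case, []).append(m)
    # cohort-level covered/uncovered cutoff over all vessels of all images
    all_pv = np.concatenate(
        [m.pv_od[~np.isnan(m.pv_od)] for ms in by_case.values() for m in ms]
    )
    cutoff = float(np.median(all_pv)) if all_pv.size else None
    cases = [
        aggregate_case(case, ms, mode=cfg.aggregation_mode, fcv_cutoff=cutoff)
        for case, ms in sorted(by_case.items())
    ]
    df = cases_to_frame(cases)
    _write_csv(df, out / "per_case.csv")

    per_core = pd.DataFrame(
        [
            {"case_id": image_id.rsplit("_core", 1)[0],
             "value": m.median_diameter_um}
            for image_id, m in metrics_by_image.items()
        ]
    )
    try:
        icc = compute_icc(per_core)
    except ValueError as exc:
        icc = {"error": str(exc)}
    (out / "icc.json").write_text(json.dumps(icc, indent=2, sort_keys=True) + "\n")
    return {"n_cases": len(cases), "fcv_cutoff": cutoff}


def stage_stats(cfg: RunConfig, out: Path) -> dict:
    """Dichotomize measured vessel size; KM/log-rank and Cox models."""
    per_case = pd.read_csv(out / "per_case.csv")
    clinical = pd.read_csv(out / "clinical.csv")
    df = per_case.merge(clinical, on="case_id", how="inner")
    df = df[~df["qc_excluded"].astype(bool)]
    if len(df) < 4:
        raise NotEstimableError("too few cases for cohort statistics")
    df["size_group"] = dichotomize(df["vessel_median_diameter_um"])

    results: dict = {}
    rho, p = spearman(df["vessel_median_diameter_um"], df["vessel_density"])
    results["spearman_size_vs_density"] = {"rho": rho, "p": p}
    try:
        km = km_logrank(df["time"], df["event"], df["size_group"])
        _write_csv(km["curves"], out / "km_curves.csv")
        results["logrank"] = {"chi2": km["chi2"], "p": km["p"]}
    except NotEstimableError as exc:
        results["logrank"] = {"error": str(exc)}
    x = (df["size_group"] == "high").astype(float).to_frame("size_high")
    try:
        uni = cox_fit(df["time"], df["event"], x, ties=cfg.ties)
        _write_csv(uni.table, out / "cox_univariable.csv")
        t = uni.table.iloc[0]
        results["cox_univariable"] = {
            "hr": t["hr"], "ci_low": t["ci_low"], "ci_high": t["ci_high"],
            "p": t["p"], "n": uni.n, "n_events": uni.n_events,
        }
    except (NotEstimableError, Exception) as exc:  # noqa: BLE001 - reported, not silenced
        results["cox_univariable"] = {"error": str(exc)}
    forest = subgroup_forest(
        df,
        "size_group",
        subgroups={
            "all": pd.Series(True, index=df.index),
            "ER_positive": df["er_status"] == "positive",
            "ER_negative": df["er_status"] == "negative",
        },
        ties=cfg.ties,
    )
    _write_csv(forest, out / "forest.csv")
    (out / "statistics.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n"
    )
    return {"stats": results}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Writes ``manifest.json`` with the echoed config, its hash, the seed
    and the package version, sufficient to re-run any stage in
    isolation.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("synthesizing %d cases x %d cores", cfg.n_cases, cfg.cores_per_case)
    stage_synth(cfg, out)
    log.info("measuring images")
    measured = stage_measure(cfg, out)
    log.info("aggregating cases")
    stage_aggregate(cfg, out, measured["_metrics"])
    log.info("cohort statistics")
    stage_stats(cfg, out)
    cfg_dict = cfg.to_dict()
    manifest = {
        "package": "vesselquant",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
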