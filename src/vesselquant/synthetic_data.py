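"""Synthetic dual-stain IHC images and survival cohorts with known truth.

Real slides for this kind of study are not publicly deposited, so every
downstream stage is exercised against simulated data whose ground truth
is known exactly:

* **Images** — vessels are elliptical annuli (an open lumen surrounded by
  a CD34+ endothelial wall 1.5–3 um thick), optionally broken into a
  C-shape by a small wall gap (the condition the mask-repair stage
  targets), optionally wrapped by an a-SMA+ mural ring.  Pixel colors
  follow forward Beer–Lambert mixing of the stain model, i.e. the exact
  inverse of color deconvolution.  Sub-capillary CD34+ distractors
  (single-cell-sized discs) exercise the size filter.
* **Cohorts** — per-case vessel median size is log-normal; disease-
  specific event times are exponential with a proportional-hazards
  dependence on the median-split size group, plus independent exponential
  censoring calibrated to a requested censoring fraction.

Same seed, same output, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .images import RGBImage
from .stain_separation import StainModel, default_stain_model, mix_od, od_to_rgb

#: endothelial wall thickness range, um (capillary to venule scale)
WALL_THICKNESS_RANGE_UM = (1.5, 3.0)
#: a-SMA mural ring thickness, um
SMA_RING_THICKNESS_UM = 2.0
#: chromogen OD deposited in vessel walls
CD34_WALL_OD = 1.0
#: mural-ring a-SMA OD for covered vs uncovered vessels
COVERED_RING_OD = 0.8
UNCOVERED_RING_OD = 0.05


class LayoutInfeasibleError(RuntimeError):
    """Could not place all objects without overlap within the retry budget."""


@dataclass
class Vessel:
    center_px: tuple[float, float]  # (row, col)
    lumen_diameter_um: float
    wall_thickness_um: float
    orientation_rad: float
    eccentricity: float
    has_sma_ring: bool
    sma_ring_od: float
    gap_px: float = 0.0  # 0 = closed wall; >0 = C-shaped wall gap width
    gap_angle_rad: float = 0.0

    def outer_diameter_um(self) -> float:
        """Outer minimal caliper diameter: lumen + both walls."""
        return self.lumen_diameter_um + 2.0 * self.wall_thickness_um


@dataclass
class Distractor:
    """Single CD34+ cell: a disc below the detector's 4 um size floor."""

    center_px: tuple[float, float]
    diameter_um: float


@dataclass
class StromaPatch:
    """a-SMA+ stromal blob (fibroblast-rich area), away from vessels."""

    center_px: tuple[float, float]
    radii_px: tuple[float, float]
    orientation_rad: float
    od: float


@dataclass
class GroundTruthLayout:
    image_size_px: tuple[int, int]
    resolution_px_per_um: float
    vessels: list[Vessel]
    distractors: list[Distractor] = field(default_factory=list)
    stroma_patches: list[StromaPatch] = field(default_factory=list)
    background_stroma_od: float = 0.02
    seed: int = 0


def _vessel_radii_px(v: Vessel, res: float) -> tuple[float, float, float, float]:
    """(a_lum, b_lum, a_out, b_out) semi-axes in px; b is the minor axis."""
    b_lum = 0.5 * v.lumen_diameter_um * res
    a_lum = b_lum / math.sqrt(1.0 - v.eccentricity**2)
    t = v.wall_thickness_um * res
    return a_lum, b_lum, a_lum + t, b_lum + t


def _bounding_radius_px(v: Vessel, res: float) -> float:
    a_out = _vessel_radii_px(v, res)[2]
    return a_out + (SMA_RING_THICKNESS_UM * res if v.has_sma_ring else 0.0)


def generate_vessel_layout(
    n_vessels: int,
    diameter_log_mean: float = math.log(10.0),
    diameter_log_sd: float = 0.45,
    image_size_px: tuple[int, int] = (1024, 1024),
    resolution_px_per_um: float = 4.0,
    sma_covered_fraction: float = 0.5,
    seed: int = 0,
    min_diameter_um: float = 4.0,
    eccentricity_max: float = 0.6,
    gap_fraction: float = 0.25,
    gap_px: float = 4.0,
    n_distractors: int | None = None,
    distractor_diameter_range_um: tuple[float, float] = (1.0, 3.0),
    n_stroma_patches: int = 0,
    stroma_patch_od: float = 0.4,
    background_stroma_od: float = 0.02,
    clearance_px: float = 12.0,
    max_retries: int = 2000,
) -> GroundTruthLayout:
    """Sample a non-overlapping vessel layout with known per-vessel truth.

    Lumen diameters are log-normal, floored at ``min_diameter_um`` (default
    4 um, the detector's size floor).  Exactly ``round(sma_covered_fraction
    * n_vessels)`` vessels carry an a-SMA mural ring.  A ``gap_fraction``
    of vessels get a C-shaped wall with a ``gap_px``-wide break.  Object
    bounding circles are kept ``clearance_px`` apart (and off the border)
    so that morphological repair cannot merge neighbors; placement failure
    after ``max_retries`` attempts per object raises
    :class:`LayoutInfeasibleError`.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    rng = np.random.default_rng(seed)
    res = resolution_px_per_um
    h, w = image_size_px
    if n_distractors is None:
        n_distractors = int(round(1.5 * n_vessels))

    n_covered = int(round(sma_covered_fraction * n_vessels))
    covered = np.zeros(n_vessels, dtype=bool)
    covered[rng.permutation(n_vessels)[:n_covered]] = True
    n_gapped = int(round(gap_fraction * n_vessels))
    gapped = np.zeros(n_vessels, dtype=bool)
    gapped[rng.permutation(n_vessels)[:n_gapped]] = True

    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)

    def _place(radius: float) -> tuple[float, float]:
        margin = radius + clearance_px
        if 2 * margin >= min(h, w):
            raise LayoutInfeasibleError(
                f"object of radius {radius:.1f}px cannot fit in {image_size_px}"
            )
        for _ in range(max_retries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(
                math.hypot(r - pr, c - pc) >= radius + prad + clearance_px
                for pr, pc, prad in placed
            ):
                placed.append((r, c, radius))
                return r, c
        raise LayoutInfeasibleError(
            f"layout infeasible: could not place object after {max_retries} retries"
        )

    vessels: list[Vessel] = []
    for i in range(n_vessels):
        d_lum = max(float(rng.lognormal(diameter_log_mean, diameter_log_sd)),
                    min_diameter_um)
        vessels.append(
            Vessel(
                center_px=(0.0, 0.0),
                lumen_diameter_um=d_lum,
                wall_thickness_um=float(rng.uniform(*WALL_THICKNESS_RANGE_UM)),
                orientation_rad=float(rng.uniform(0, math.pi)),
                eccentricity=float(rng.uniform(0, eccentricity_max)),
                has_sma_ring=bool(covered[i]),
                sma_ring_od=COVERED_RING_OD if covered[i] else UNCOVERED_RING_OD,
                gap_px=gap_px if gapped[i] else 0.0,
                gap_angle_rad=float(rng.uniform(0, 2 * math.pi)),
            )
        )
    # place largest objects first: greedy packing succeeds far more often
    # while leaving the sampled size distribution untouched
    radii = [_bounding_radius_px(v, res) for v in vessels]
    for i in sorted(range(n_vessels), key=lambda k: -radii[k]):
        vessels[i].center_px = _place(radii[i])

    distractors: list[Distractor] = []
    for _ in range(n_distractors):
        d = float(rng.uniform(*distractor_diameter_range_um))
        center = _place(0.5 * d * res)
        distractors.append(Distractor(center_px=center, diameter_um=d))

    patches: list[StromaPatch] = []
    for _ in range(n_stroma_patches):
        radii = (float(rng.uniform(10, 30)), float(rng.uniform(10, 30)))
        center = _place(max(radii))
        patches.append(
            StromaPatch(
                center_px=center,
                radii_px=radii,
                orientation_rad=float(rng.uniform(0, math.pi)),
                od=stroma_patch_od,
            )
        )

    return GroundTruthLayout(
        image_size_px=image_size_px,
        resolution_px_per_um=res,
        vessels=vessels,
        distractors=distractors,
        stroma_patches=patches,
        background_stroma_od=background_stroma_od,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------

def _window(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[slice, slice]:
    """Crop window slices covering a bounding circle, clipped to the image."""
    h, w = shape
    cr, cc = center
    r0, r1 = max(int(cr - radius) - 1, 0), min(int(cr + radius) + 2, h)
    c0, c1 = max(int(cc - radius) - 1, 0), min(int(cc + radius) + 2, w)
    return slice(r0, r1), slice(c0, c1)


def _local_frame(
    win: tuple[slice, slice], center: tuple[float, float], theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Window pixel coordinates rotated into the object's (u, v) frame."""
    rr, cc_idx = np.mgrid[win[0], win[1]]
    dy = rr - center[0]
    dx = cc_idx - center[1]
    u = math.cos(theta) * dx + math.sin(theta) * dy
    v = -math.sin(theta) * dx + math.cos(theta) * dy
    return u, v


def _ellipse(u: np.ndarray, v: np.ndarray, a: float, b: float) -> np.ndarray:
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_amount_maps(layout: GroundTruthLayout) -> dict[str, np.ndarray]:
    """Ground-truth per-stain OD amount maps ("cd34", "sma") for a layout."""
    h, w = layout.image_size_px
    res = layout.resolution_px_per_um
    cd34 = np.zeros((h, w))
    sma = np.zeros((h, w))
    vessel_zone = np.zeros((h, w), dtype=bool)  # walls + lumina + rings

    ring_t = SMA_RING_THICKNESS_UM * res
    for v in layout.vessels:
        a_lum, b_lum, a_out, b_out = _vessel_radii_px(v, res)
        win = _window((h, w), v.center_px, a_out + ring_t)
        u, vv = _local_frame(win, v.center_px, v.orientation_rad)
        outer = _ellipse(u, vv, a_out, b_out)
        lumen = _ellipse(u, vv, a_lum, b_lum)
        wall = outer & ~lumen
        if v.gap_px > 0:
            half = 0.5 * v.gap_px / a_out  # break width <= gap_px at the rim
            ang = np.arctan2(vv, u)
            diff = np.angle(np.exp(1j * (ang - v.gap_angle_rad)))
            wall &= ~(np.abs(diff) < half)
        cd34[win][wall] = CD34_WALL_OD
        ring = _ellipse(u, vv, a_out + ring_t, b_out + ring_t) & ~outer
        sma[win][ring] = v.sma_ring_od
        vessel_zone[win] |= outer | ring

    for d in layout.distractors:
        r_px = 0.5 * d.diameter_um * res
        win = _window((h, w), d.center_px, r_px)
        u, vv = _local_frame(win, d.center_px, 0.0)
        m = _ellipse(u, vv, r_px, r_px)
        cd34[win][m] = CD34_WALL_OD
        vessel_zone[win] |= m

    for p in layout.stroma_patches:
        win = _window((h, w), p.center_px, max(p.radii_px))
        u, vv = _local_frame(win, p.center_px, p.orientation_rad)
        m = _ellipse(u, vv, p.radii_px[0], p.radii_px[1])
        sma[win][m & ~vessel_zone[win]] = p.od

    if layout.background_stroma_od > 0:
        bg = ~vessel_zone & (sma == 0)
        sma[bg] = layout.background_stroma_od

    return {"cd34": cd34, "sma": sma}


def render_ihc_image(
    layout: GroundTruthLayout,
    stains: StainModel | None = None,
    noise_sd_od: float = 0.0,
    seed: int = 0,
    quantize: bool = True,
) -> RGBImage | np.ndarray:
    """Forward-render a layout to a transmitted-light RGB image.

    Per pixel, channel OD = sum of stain amounts times unit color vectors,
    plus (optionally) Gaussian OD noise of sd ``noise_sd_od``; intensity is
    ``255 * 10**(-OD)``, rounded and clipped to 8 bits when ``quantize``.
    With ``quantize=False`` the continuous float image is returned (no
    rounding), which inverts exactly under deconvolution at zero noise.
    """
    stains = stains or default_stain_model()
    if stains.n_stains < 2:
        raise ValueError("need >= 2 stains to render a dual-stain image")
    maps = render_amount_maps(layout)
    amounts = np.stack([maps[name] for name in stains.names], axis=-1)
    od = mix_od(amounts, stains)
    if noise_sd_od > 0:
        rng = np.random.default_rng(seed)
        od = np.clip(od + rng.normal(0.0, noise_sd_od, od.shape), 0.0, None)
    pixels = od_to_rgb(od, quantize=quantize)
    if not quantize:
        return pixels
    return RGBImage(pixels, layout.resolution_px_per_um)


def ground_truth_table(
    layout: GroundTruthLayout, case_id: str = "case", core_id: str = "core"
) -> pd.DataFrame:
    """Machine-readable per-vessel truth emitted alongside every image."""
    rows = [
        {
            "case_id": case_id,
            "core_id": core_id,
            "vessel_id": i + 1,
            "center_x": v.center_px[1],
            "center_y": v.center_px[0],
            "lumen_diameter_um": v.lumen_diameter_um,
            "wall_thickness_um": v.wall_thickness_um,
            "diameter_um": v.outer_diameter_um(),
            "covered_flag": int(v.has_sma_ring),
            "has_gap": int(v.gap_px > 0),
        }
        for i, v in enumerate(layout.vessels)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "core_id", "vessel_id", "center_x", "center_y",
            "lumen_diameter_um", "wall_thickness_um", "diameter_um",
            "covered_flag", "has_gap",
        ],
    )


# ---------------------------------------------------------------------------
# synthetic survival cohorts
# ---------------------------------------------------------------------------

_COVARIATE_LEVELS = {
    "age_group": (["<=60", ">60"], [0.5, 0.5]),
    "tumor_size_group": (["<=20mm", ">20mm"], [0.6, 0.4]),
    "grade": (["1", "2", "3"], [0.25, 0.45, 0.30]),
    "nodal_status": (["N0", "N1"], [0.65, 0.35]),
    "er_status": (["positive", "negative"], [0.85, 0.15]),
    "pr_status": (["positive", "negative"], [0.70, 0.30]),
    "her2_status": (["negative", "positive"], [0.88, 0.12]),
}


def _censoring_hazard(target: float, hazards: np.ndarray) -> float:
    """Exponential censoring rate giving the requested censoring fraction.

    For event hazard h and censoring hazard c, P(censored) = c / (c + h);
    the cohort-average probability is solved for c by root finding.
    """

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    lo, hi = 1e-12, 1e-12
    while frac(hi) < target:
        hi *= 10
        if hi > 1e12:  # pragma: no cover
            raise RuntimeError("censoring calibration failed")
    return brentq(lambda c: frac(c) - target, lo, hi)


def generate_cohort(
    n_cases: int,
    true_log_hr: float,
    baseline_hazard: float = 0.01,
    censoring_rate: float = 0.3,
    seed: int = 0,
    sizes_um: np.ndarray | None = None,
    size_log_mean: float = math.log(10.0),
    size_log_sd: float = 0.35,
) -> pd.DataFrame:
    """Simulate a cohort whose survival depends on vessel median size.

    Event times are exponential with hazard ``baseline_hazard *
    exp(true_log_hr)`` for cases above the cohort-median size and
    ``baseline_hazard`` otherwise; censoring is independent exponential,
    calibrated so the expected censored fraction equals
    ``censoring_rate``.  Clinical covariates are drawn independently of
    size (the null the study observed for clinicopathologic factors).

    ``sizes_um`` substitutes externally supplied per-case sizes (e.g.
    measured from synthetic images) for the log-normal draw.
    """
    if n_cases < 2:
        raise ValueError("need >= 2 cases")
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must be in [0, 1)")
    if not baseline_hazard > 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    if sizes_um is None:
        sizes = rng.lognormal(size_log_mean, size_log_sd, n_cases)
    else:
        sizes = np.asarray(sizes_um, dtype=float)
        if sizes.shape != (n_cases,):
            raise ValueError("sizes_um length must equal n_cases")
    high = sizes > np.median(sizes)
    hazards = baseline_hazard * np.exp(true_log_hr * high.astype(float))
    t_event = rng.exponential(1.0 / hazards)
    if censoring_rate > 0:
        c_haz = _censoring_hazard(censoring_rate, hazards)
        t_cens = rng.exponential(1.0 / c_haz, n_cases)
    else:
        t_cens = np.full(n_cases, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    df = pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(n_cases)],
            "size_um": sizes,
            "true_high": high.astype(int),
            "time": time,
            "event": event,
        }
    )
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        df[name] = rng.choice(levels, size=n_cases, p=probs)
    # molecular subtype, loosely consistent with ER/HER2 calls
    subtype = np.where(
        df["er_status"] == "positive",
        np.where(df["her2_status"] == "positive", "LumB_HER2pos", "LumA"),
        np.where(df["her2_status"] == "positive", "HER2", "TN"),
    )
    df["subtype"] = subtype
    df.attrs["true_log_hr"] = true_log_hr
    df.attrs["censoring_rate"] = censoring_rate
    df.attrs["seed"] = seed
    return df
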