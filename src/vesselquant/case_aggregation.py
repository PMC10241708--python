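"""Pooling of image-level results into case-level metrics, plus inter-core
concordance (ICC) for tissue-microarray replicates.

A TMA case is represented by up to three 1 mm cores; the default
aggregation treats the passing cores of one case as a single tissue
sample (vessel tables concatenated, areas summed) before any per-case
summary is taken.  An alternative median-of-cores mode summarizes each
core first and combines core summaries by median.  Cases whose cores all
fail QC are excluded, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vessel_morphometry import ImageMetrics, fraction_covered


@dataclass
class CaseMetrics:
    case_id: str
    n_cores_used: int
    qc_excluded: bool
    tissue_area_mm2: float | None = None
    n_vessels: int | None = None
    vessel_density: float | None = None
    vessel_median_diameter_um: float | None = None
    pvi: float | None = None
    fcv: float | None = None
    stromal_area_mm2: float | None = None
    stromal_sma_od_median: float | None = None
    aggregation_mode: str = "pooled"


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def _nanmedian(values: list[float | None]) -> float | None:
    arr = np.array([v for v in values if v is not None], dtype=float)
    return float(np.median(arr)) if arr.size else None


def aggregate_case(
    case_id: str,
    core_results: list[ImageMetrics],
    mode: str = "pooled",
    fcv_cutoff: float | None = None,
    qc_pass: list[bool] | None = None,
) -> CaseMetrics:
    """Combine the passing cores of one case into case-level metrics.

    ``pooled`` concatenates vessels and sums areas before computing
    density, median diameter, PVI (median of per-vessel perivascular
    ODs) and FCV; ``median_of_cores`` takes the median of per-core
    metrics.  ``fcv_cutoff`` is the cohort-level covered/uncovered
    cutoff; FCV is left unset without it.
    """
    if mode not in ("pooled", "median_of_cores"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if qc_pass is None:
        qc_pass = [True] * len(core_results)
    cores = [m for m, ok in zip(core_results, qc_pass) if ok]
    if not cores:
        return CaseMetrics(case_id, 0, True, aggregation_mode=mode)

    area = sum(m.tissue_area_mm2 for m in cores)
    n_vessels = sum(m.n_vessels for m in cores)
    diameters = np.concatenate([m.diameters_um for m in cores]) if n_vessels else np.array([])
    pv = np.concatenate([m.pv_od for m in cores]) if n_vessels else np.array([])
    pv = pv[~np.isnan(pv)] if pv.size else pv
    stromal_area = sum(m.stromal_area_mm2 for m in cores)

    if mode == "pooled":
        density = n_vessels / area
        med_diam = float(np.median(diameters)) if diameters.size else None
        pvi = float(np.median(pv)) if pv.size else None
        fcv = (
            fraction_covered(pv, fcv_cutoff)
            if (fcv_cutoff is not None and pv.size)
            else None
        )
        stro_pairs = [
            (m.stromal_sma_od_median, m.stromal_area_mm2)
            for m in cores
            if m.stromal_sma_od_median is not None and m.stromal_area_mm2 > 0
        ]
        if stro_pairs:
            vals = np.array([p[0] for p in stro_pairs])
            wts = np.array([p[1] for p in stro_pairs])
            stro_med = _weighted_median(vals, wts)
        else:
            stro_med = None
    else:
        density = _nanmedian([m.vessel_density for m in cores])
        med_diam = _nanmedian([m.median_diameter_um for m in cores])
        pvi = _nanmedian([m.pvi for m in cores])
        if fcv_cutoff is not None:
            per_core_fcv = [
                fraction_covered(m.pv_od[~np.isnan(m.pv_od)], fcv_cutoff)
                for m in cores
                if m.pv_od.size and (~np.isnan(m.pv_od)).any()
            ]
            fcv = _nanmedian(per_core_fcv)
        else:
            fcv = None
        stro_med = _nanmedian([m.stromal_sma_od_median for m in cores])

    return CaseMetrics(
        case_id=case_id,
        n_cores_used=len(cores),
        qc_excluded=False,
        tissue_area_mm2=area,
        n_vessels=n_vessels,
        vessel_density=density,
        vessel_median_diameter_um=med_diam,
        pvi=pvi,
        fcv=fcv,
        stromal_area_mm2=stromal_area,
        stromal_sma_od_median=stro_med,
        aggregation_mode=mode,
    )


def cases_to_frame(cases: list[CaseMetrics]) -> pd.DataFrame:
    """One row per case; metric columns are NaN for QC-excluded cases."""
    return pd.DataFrame([vars(c) for c in cases])


def compute_icc(per_core: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way random-effects ICC(1,1) with an F-based confidence interval.

    ``per_core`` is a long table with columns ``case_id`` and ``value``
    (one row per core).  Replicate cores are treated as interchangeable
    (agreement interpretation).  Unbalanced designs use the standard
    effective replicate count ``k0 = (N - sum(n_i^2)/N) / (n_cases - 1)``.
    """
    df = per_core.dropna(subset=["value"])
    counts = df.groupby("case_id")["value"].count()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise ValueError("ICC needs >= 2 cases with >= 2 cores each")
    df = df[df["case_id"].isin(counts.index)]
    n_cases = len(counts)
    n_total = int(counts.sum())
    grand = df["value"].mean()
    means = df.groupby("case_id")["value"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(
        ((df["value"] - df["case_id"].map(means)) ** 2).sum()
    )
    df_b = n_cases - 1
    df_w = n_total - n_cases
    msb = ss_between / df_b
    msw = ss_within / df_w
    k0 = (n_total - float((counts**2).sum()) / n_total) / df_b
    if msw == 0.0:  # replicates identical within every case
        return {
            "estimate": 1.0, "ci_low": 1.0, "ci_high": 1.0,
            "n_cases": n_cases, "n_cores": n_total,
            "model": "one-way random, ICC(1,1)",
        }
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    f_obs = msb / msw
    f_u = stats.f.ppf(1 - alpha / 2, df_b, df_w)
    f_l_crit = stats.f.ppf(1 - alpha / 2, df_w, df_b)
    fl = f_obs / f_u
    fu = f_obs * f_l_crit
    ci_low = (fl - 1) / (fl + k0 - 1)
    ci_high = (fu - 1) / (fu + k0 - 1)
    return {
        "estimate": float(icc),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "n_cases": n_cases,
        "n_cores": n_total,
        "model": "one-way random, ICC(1,1)",
    }
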