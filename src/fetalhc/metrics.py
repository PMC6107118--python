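"""Evaluation metrics and HC-based gestational-age estimation.

The agreement metrics compare a system (or second-observer) ellipse S
against the reference annotation R:

* DF  = HC_S - HC_R           (signed circumference difference, mm)
* ADF = |DF|                  (absolute difference, mm)
* HD  = max(h(S,R), h(R,S))   (symmetric Hausdorff distance between the
  two boundaries, with h(S,R) = max_s min_r ||s - r||, mm)
* DSC = 2 |A_S n A_R| / (|A_S| + |A_R|)  (Dice overlap of the filled
  ellipse regions on the pixel grid)

GA is estimated by inverting the median (P50) HC growth-curve track with
monotone linear interpolation; no extrapolation outside the chart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .core_io import (
    EllipseAnnotation,
    GrowthCurveTable,
    ScaledImage,
    ellipse_circumference,
    rasterize_ellipse,
)

__all__ = [
    "EvaluationRecord",
    "hc_difference",
    "hausdorff",
    "dice",
    "estimate_ga",
    "trimester_of",
    "evaluate_set",
]

TRIMESTER_EDGES_DAYS = (98.0, 196.0)  # 14+0 and 28+0 weeks


@dataclass(frozen=True)
class EvaluationRecord:
    """All per-image agreement numbers."""

    id: str
    df: float
    adf: float
    hd: float
    dsc: float
    ga_est: float
    ga_ref: float
    ga_diff: float
    trimester: int


def hc_difference(hc_s: float, hc_r: float) -> tuple[float, float]:
    """Signed and absolute circumference difference (system minus reference)."""
    if hc_s <= 0 or hc_r <= 0:
        raise ValueError("circumferences must be positive")
    df = hc_s - hc_r
    return df, abs(df)


def _as_points(obj, n_angles: int) -> np.ndarray:
    if isinstance(obj, EllipseAnnotation):
        return obj.boundary_points(n_angles)
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("point set must be a non-empty (n, 2) array")
    return pts


def hausdorff(s, r, n_angles: int = 270) -> float:
    """Symmetric Hausdorff distance (mm) between two boundaries.

    Inputs are (n, 2) point arrays or ellipses (discretized at
    ``n_angles`` boundary points).
    """
    sp = _as_points(s, n_angles)
    rp = _as_points(r, n_angles)
    return max(directed_hausdorff(sp, rp)[0], directed_hausdorff(rp, sp)[0])


def dice(ellipse_s: EllipseAnnotation, ellipse_r: EllipseAnnotation, grid: ScaledImage) -> float:
    """Dice overlap of the two filled ellipses rasterized on ``grid``."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty masks handled below
        ms = rasterize_ellipse(ellipse_s, grid, "filled")
        mr = rasterize_ellipse(ellipse_r, grid, "filled")
    denom = int(ms.sum()) + int(mr.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((ms & mr).sum()) / denom


def estimate_ga(hc: float, curve: GrowthCurveTable) -> float:
    """GA in days at which the median HC track equals ``hc`` (mm)."""
    return curve.invert("hc_p50", hc)


def trimester_of(ga_days: float) -> int:
    """Clinical trimester bins: T1 < 14+0 weeks <= T2 < 28+0 weeks <= T3."""
    if ga_days < TRIMESTER_EDGES_DAYS[0]:
        return 1
    if ga_days < TRIMESTER_EDGES_DAYS[1]:
        return 2
    return 3


def evaluate_set(
    predictions: dict[str, EllipseAnnotation],
    references: dict[str, EllipseAnnotation],
    curve: GrowthCurveTable,
    grids: dict[str, ScaledImage],
    ga_ref: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image records and a trimester-stratified mean +- SD summary.

    ``ga_ref`` supplies the reference GA per image (e.g. CRL-derived);
    when absent it is estimated from the reference HC.  Trimester
    assignment uses the reference GA.  Returns ``(records, summary)``
    DataFrames; the SD is the population SD (a single record reports 0).
    """
    ids = sorted(predictions)
    if set(ids) != set(references):
        raise ValueError("predictions and references must cover the same image ids")
    records = []
    for img_id in ids:
        es, er = predictions[img_id], references[img_id]
        hc_s = ellipse_circumference(es)
        hc_r = ellipse_circumference(er)
        df, adf = hc_difference(hc_s, hc_r)
        ga_e = estimate_ga(hc_s, curve)
        ga_r = ga_ref[img_id] if ga_ref is not None else estimate_ga(hc_r, curve)
        records.append(
            EvaluationRecord(
                id=img_id, df=df, adf=adf,
                hd=hausdorff(es, er),
                dsc=dice(es, er, grids[img_id]),
                ga_est=ga_e, ga_ref=ga_r, ga_diff=ga_e - ga_r,
                trimester=trimester_of(ga_r),
            )
        )
    rec_df = pd.DataFrame([vars(r) for r in records])
    metrics = ["df", "adf", "hd", "dsc", "ga_diff"]
    grouped = rec_df.groupby("trimester")[metrics]
    summary = pd.concat(
        {"mean": grouped.mean(), "sd": grouped.agg(lambda s: float(np.std(s)))}, axis=1
    )
    summary.columns = [f"{m}_{stat}" for stat, m in summary.columns]
    summary["n"] = grouped.size()
    return rec_df, summary.reset_index()
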