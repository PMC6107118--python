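"""Skull boundary extraction from a likelihood map.

The chain is: Hough-transform detection of the head center, a polar
resampling around that center, a first dynamic-programming (DP) pass on the
classifier likelihood that traces the skull *midline*, a second DP pass on
the radial derivative of the raw image that re-positions the path onto the
*outer* skull edge, selection of high-likelihood path points, and a direct
least-squares ellipse fit with a minimum-circumference plausibility filter.

Both DP passes find the exact minimal-cost path across the angle axis with
a bounded per-step radial jump; ties are broken toward the smaller radius,
then the smaller predecessor radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .classifier import LikelihoodMap
from .core_io import EllipseAnnotation, GrowthCurveTable, PipelineConfig, ScaledImage

__all__ = [
    "PolarMap",
    "RadialPath",
    "DetectionError",
    "FitError",
    "MIN_HC_MM",
    "EDGE_BAND_HALF_WIDTH_MM",
    "FIT_POINT_PERCENTILE",
    "radius_bounds",
    "hough_center",
    "polar_transform",
    "dp_shortest_path",
    "extract_skull_midline",
    "refine_outer_edge",
    "select_fit_points",
    "fit_ellipse_direct",
    "filter_ellipse",
]

MIN_HC_MM = 38.6
"""Smallest plausible head circumference (mm): the lower end of the
reference growth chart.  Fitted ellipses below it are rejected as noise."""

EDGE_BAND_HALF_WIDTH_MM = 2.0
"""Half-width of the search band of the edge-refinement DP around the
stage-1 midline path; the fetal skull is only a few mm thick."""

FIT_POINT_PERCENTILE = 0.05
"""Fraction of boundary points (highest classifier likelihood) kept for
the ellipse fit."""

_BAND_PENALTY = 1e9


class DetectionError(RuntimeError):
    """Raised when a detection stage finds nothing to work with."""


class FitError(RuntimeError):
    """Raised when the ellipse fit is degenerate."""


def radius_bounds(curve: GrowthCurveTable, ga_min: float, ga_max: float) -> tuple[float, float]:
    """Hough search-radius bounds (mm) for a GA window, from a growth chart.

    The lower bound is half the 3rd-percentile BPD at the window start; the
    upper bound is ``ceil(HC_P97 / pi - BPD_P97 / 2)`` at the window end
    (the largest half-extent an ellipse with that circumference and minor
    diameter can have).  Chart rows are linearly interpolated.
    """
    r_min = curve.lookup("bpd_p3", ga_min) / 2.0
    r_max = math.ceil(curve.lookup("hc_p97", ga_max) / math.pi - curve.lookup("bpd_p97", ga_max) / 2.0)
    return r_min, float(r_max)


def hough_center(lmap: LikelihoodMap, r_min: float, r_max: float) -> tuple[float, float]:
    """Center (x, y, mm) of the highest-scoring circle with radius in
    ``[r_min, r_max]``.

    Pixels above the 90th likelihood percentile vote for every center at
    (1 mm-quantized) distance r, on a 1 mm center grid with 1 mm radius
    steps.  The reported center is the vote-weighted centroid of the
    near-maximal accumulator cells (>= 80% of the peak, maximized over
    radius): on an elliptical ring the single best circle osculates one
    end of the major axis, biasing a plain argmax by up to a - b, while
    the near-maximal cells cluster symmetrically around the true center.
    Only the center is returned — the circle radius is discarded, because
    the skull is elliptical and the center merely seeds the polar
    transform.
    """
    if not r_min < r_max:
        raise ValueError("r_min must be < r_max")
    vals = lmap.values
    if vals.size == 0:
        raise DetectionError("empty likelihood map")
    thresh = np.percentile(vals, 90.0)
    sel = np.argwhere(vals > thresh)
    if len(sel) == 0:
        raise DetectionError("no likelihood pixel above the Hough threshold")
    ps = lmap.pixel_size
    h, w = vals.shape
    # vote image on the 1 mm center grid (centers at integer mm)
    x = (sel[:, 1] + 0.5) * ps
    y = (sel[:, 0] + 0.5) * ps
    ny = int(math.ceil(h * ps)) + 1
    nx = int(math.ceil(w * ps)) + 1
    votes = np.zeros((ny, nx))
    np.add.at(votes, (np.round(y).astype(int), np.round(x).astype(int)), 1.0)
    radii = np.arange(int(math.ceil(r_min)), int(math.floor(r_max)) + 1)
    if len(radii) == 0:
        radii = np.array([int(round(0.5 * (r_min + r_max)))])
    acc_max = np.full((ny, nx), -np.inf)
    for r in radii:
        d = np.arange(-r, r + 1)
        dx, dy = np.meshgrid(d, d)
        ring = (np.round(np.hypot(dx, dy)).astype(int) == r).astype(float)
        acc = np.round(signal.fftconvolve(votes, ring, mode="same"), 6)
        acc_max = np.maximum(acc_max, acc)
    peak = float(acc_max.max())
    if peak <= 0:
        raise DetectionError("Hough accumulator is empty")
    iy, ix = np.nonzero(acc_max >= 0.8 * peak)
    wgt = acc_max[iy, ix]
    return float((ix * wgt).sum() / wgt.sum()), float((iy * wgt).sum() / wgt.sum())


@dataclass(frozen=True)
class PolarMap:
    """A 2D map resampled onto (angle, radius) around a center.

    ``values[k, j]`` is the bilinear sample at angle ``2*pi*k / N_angles``
    (0 = +x axis, counterclockwise in the x-right / y-down frame) and
    radius ``radial_offset + j * s_dis_eff`` mm.  Samples beyond the image
    frame read zero.
    """

    values: np.ndarray  # (N_angles, N_radii)
    center: tuple[float, float]  # (x, y) mm
    radial_offset: float
    s_dis_eff: float

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_radii(self) -> int:
        return self.values.shape[1]

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * (2 * math.pi / self.n_angles)

    @property
    def radii(self) -> np.ndarray:
        return self.radial_offset + np.arange(self.n_radii) * self.s_dis_eff


def polar_transform(
    src: np.ndarray,
    pixel_size: float,
    center: tuple[float, float],
    n_angles: int,
    s_dis: float,
    radial_offset: float,
    r_stop: float,
) -> PolarMap:
    """Resample a 2D map onto polar coordinates around ``center`` (mm).

    ``s_dis = 0`` means native resolution (one sample per ``pixel_size``).
    ``N_radii = floor((r_stop - radial_offset) / s_dis_eff) + 1``.
    """
    src = np.asarray(src, dtype=np.float64)
    h, w = src.shape
    cx, cy = center
    if not (0 <= cx <= w * pixel_size and 0 <= cy <= h * pixel_size):
        raise ValueError(f"center {center} lies outside the image frame")
    if r_stop <= radial_offset:
        raise ValueError("r_stop must exceed radial_offset")
    s_eff = s_dis if s_dis > 0 else pixel_size
    n_radii = int(math.floor((r_stop - radial_offset) / s_eff)) + 1
    theta = np.arange(n_angles) * (2 * math.pi / n_angles)
    r = radial_offset + np.arange(n_radii) * s_eff
    x = cx + r[None, :] * np.cos(theta)[:, None]
    y = cy + r[None, :] * np.sin(theta)[:, None]
    rows = y / pixel_size - 0.5
    cols = x / pixel_size - 0.5
    vals = ndimage.map_coordinates(src, [rows, cols], order=1, mode="constant", cval=0.0)
    return PolarMap(vals, (float(cx), float(cy)), float(radial_offset), float(s_eff))


@dataclass(frozen=True)
class RadialPath:
    """One radius per polar angle, the DP output."""

    indices: np.ndarray  # radial sample index per angle
    pm: PolarMap

    @property
    def radii(self) -> np.ndarray:
        return self.pm.radial_offset + self.indices * self.pm.s_dis_eff

    @property
    def angles(self) -> np.ndarray:
        return self.pm.angles

    def points(self) -> np.ndarray:
        """(n, 2) Cartesian (x, y) mm points of the path."""
        cx, cy = self.pm.center
        r = self.radii
        th = self.angles
        return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def dp_shortest_path(pm: PolarMap, cost: np.ndarray, dp_step: int = 1) -> RadialPath:
    """Exact minimal-cost left-to-right path through a polar cost grid.

    One radial sample per angle row; consecutive samples differ by at most
    ``dp_step`` indices.  The path is open (no wrap-around constraint
    between the last and first angle).  Ties break toward the smaller
    radius, then the smaller predecessor radius.
    """
    cost = np.asarray(cost, dtype=np.float64)
    n_ang, n_rad = cost.shape
    if n_rad < dp_step + 1:
        raise ValueError("need at least dp_step + 1 radial samples")
    width = 2 * dp_step + 1
    dist = cost[0].copy()
    pred = np.empty((n_ang, n_rad), dtype=np.int32)
    for a in range(1, n_ang):
        padded = np.concatenate([np.full(dp_step, np.inf), dist, np.full(dp_step, np.inf)])
        win = np.lib.stride_tricks.sliding_window_view(padded, width)
        k = np.argmin(win, axis=1)  # first occurrence = smallest predecessor radius
        pred[a] = k + np.arange(n_rad) - dp_step
        dist = cost[a] + win[np.arange(n_rad), k]
    path = np.empty(n_ang, dtype=np.int64)
    path[-1] = int(np.argmin(dist))  # first occurrence = smallest radius
    for a in range(n_ang - 1, 0, -1):
        path[a - 1] = pred[a, path[a]]
    return RadialPath(path, pm)


def extract_skull_midline(
    lmap: LikelihoodMap, center: tuple[float, float], cfg: PipelineConfig
) -> RadialPath:
    """Stage-1 DP: trace the skull midline in the polar likelihood map.

    Cost is ``1 - likelihood``; radial sampling starts at the pipeline's
    radial offset (which hides small bright structures near the center) and
    extends to ``r_max`` at sampling distance ``S_dis``.
    """
    pm = polar_transform(
        lmap.values, lmap.pixel_size, center,
        cfg.n_angles, cfg.s_dis, cfg.radial_offset, cfg.r_max,
    )
    return dp_shortest_path(pm, 1.0 - pm.values, cfg.dp_step)


def refine_outer_edge(
    img: ScaledImage, center: tuple[float, float], midline: RadialPath, cfg: PipelineConfig
) -> RadialPath:
    """Stage-2 DP: re-position the midline path onto the outer skull edge.

    A polar transform of the raw image at native radial resolution (no
    downsampling) is differentiated radially (central differences, per mm);
    minimizing the signed derivative makes the path track the strongest
    bright-to-dark outward transition.  The search is confined to radii
    within +-2 mm of the stage-1 midline; the per-step radial jump bound is
    scaled so the stage-2 path can move as fast (in mm per angle step) as
    the stage-1 path could.
    """
    ps = img.pixel_size
    band = EDGE_BAND_HALF_WIDTH_MM
    r_lo = max(0.0, float(midline.radii.min()) - band - 2 * ps)
    r_hi = float(midline.radii.max()) + band + 2 * ps
    pm = polar_transform(img.pixels, ps, center, midline.pm.n_angles, 0.0, r_lo, r_hi)
    if pm.n_radii < 3:
        raise DetectionError("edge-refinement band too narrow for this image")
    # in-frame check: the band must intersect the image somewhere
    h, w = img.shape
    cx, cy = center
    pts_x = cx + midline.radii * np.cos(midline.angles)
    pts_y = cy + midline.radii * np.sin(midline.angles)
    inside = (pts_x >= 0) & (pts_x <= w * ps) & (pts_y >= 0) & (pts_y <= h * ps)
    if not inside.any():
        raise DetectionError("edge-refinement band lies entirely outside the image")
    deriv = np.gradient(pm.values, pm.s_dis_eff, axis=1)
    in_band = np.abs(pm.radii[None, :] - midline.radii[:, None]) <= band + 1e-9
    cost = deriv + np.where(in_band, 0.0, _BAND_PENALTY)
    step = max(1, int(math.ceil(midline.pm.s_dis_eff / pm.s_dis_eff)))
    return dp_shortest_path(pm, cost, step)


def select_fit_points(
    edge: RadialPath,
    lmap: LikelihoodMap,
    percentile: float = FIT_POINT_PERCENTILE,
    mode: str = "map",
) -> np.ndarray:
    """Keep the path points lying in the highest-likelihood percentile.

    ``mode='map'`` (the default used by the pipeline) keeps every path
    point whose sampled likelihood reaches the map-wide
    ``(1 - percentile)`` quantile — for the default 5% that is the top
    twentieth of the likelihood map.  Since the skull occupies only a few
    percent of the frame, this keeps most on-skull path points and drops
    excursions over background, which is what makes the subsequent conic
    fit well-conditioned.

    ``mode='rank'`` instead ranks the path's own points and keeps the top
    ``ceil(n * percentile)`` of them (ties break toward the smaller angle
    index).

    Either way at least 6 points — the conic-fit minimum — are retained,
    topping up by rank when the threshold passes fewer.  Returns an
    (n_keep, 2) array of (x, y) mm.
    """
    pts = edge.points()
    if len(pts) == 0:
        raise ValueError("empty path")
    rows = pts[:, 1] / lmap.pixel_size - 0.5
    cols = pts[:, 0] / lmap.pixel_size - 0.5
    lik = ndimage.map_coordinates(lmap.values, [rows, cols], order=1, mode="constant", cval=0.0)
    order = np.lexsort((np.arange(len(pts)), -lik))  # likelihood desc, angle asc
    floor = min(6, len(pts))
    if mode == "rank":
        n_keep = min(max(floor, int(math.ceil(len(pts) * percentile))), len(pts))
        keep = order[:n_keep]
    elif mode == "map":
        thresh = np.percentile(lmap.values, 100.0 * (1.0 - percentile))
        keep = np.where(lik >= thresh)[0]
        if len(keep) < floor:
            keep = order[:floor]
    else:
        raise ValueError(f"mode must be 'map' or 'rank', got {mode!r}")
    return pts[np.sort(keep)]


def _conic_to_geometric(coef: np.ndarray) -> EllipseAnnotation:
    A, B, C, D, E, F = coef
    disc = B * B - 4 * A * C
    if disc >= 0:
        raise FitError("fitted conic is not an ellipse")
    cx = (2 * C * D - B * E) / disc
    cy = (2 * A * E - B * D) / disc
    f0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    m = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(m)
    axes2 = -f0 / evals
    if np.any(axes2 <= 0):
        raise FitError("degenerate ellipse (non-positive axis)")
    axes = np.sqrt(axes2)
    i_major = int(np.argmax(axes))
    a, b = float(axes[i_major]), float(axes[1 - i_major])
    vx, vy = evecs[:, i_major]
    theta = math.atan2(vy, vx) % math.pi
    return EllipseAnnotation(float(cx), float(cy), a, b, theta)


def fit_ellipse_direct(points: np.ndarray) -> EllipseAnnotation:
    """Direct least-squares ellipse fit (ellipse-specific conic constraint).

    Solves the constrained conic least-squares problem whose quadratic
    constraint ``4AC - B^2 = 1`` guarantees an elliptical solution, using
    the numerically stable block decomposition; input points are centered
    and scaled first.  Needs at least 6 points in a non-degenerate
    configuration.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise FitError("need at least 6 (x, y) points")
    mean = pts.mean(axis=0)
    scale = float(pts.std())
    if scale <= 0:
        raise FitError("degenerate point configuration")
    x, y = ((pts - mean) / scale).T
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration (collinear points?)") from exc
    m = s1 + s2 @ t
    # premultiply by inv(C1), C1 the constraint matrix [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    evals, evecs = np.linalg.eig(m)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(ok) == 0:
        raise FitError("no elliptical solution (degenerate input)")
    a1 = np.real(evecs[:, ok[0]])
    coef_n = np.concatenate([a1, t @ a1])  # conic in normalized coordinates
    # un-normalize: substitute x -> (x - mx) / s
    A, B, C, D, E, F = coef_n
    s = scale
    mx, my = mean
    coef = np.array([
        A / s**2,
        B / s**2,
        C / s**2,
        -2 * A * mx / s**2 - B * my / s**2 + D / s,
        -B * mx / s**2 - 2 * C * my / s**2 + E / s,
        A * mx**2 / s**2 + B * mx * my / s**2 + C * my**2 / s**2 - D * mx / s - E * my / s + F,
    ])
    return _conic_to_geometric(coef)


def filter_ellipse(e: EllipseAnnotation, min_circumference: float = MIN_HC_MM) -> bool:
    """Accept an ellipse iff its circumference reaches the plausibility
    threshold (inclusive, default 38.6 mm)."""
    return e.circumference >= min_circumference - 1e-9
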