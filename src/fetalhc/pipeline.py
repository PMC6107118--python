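"""Measurement-system orchestration.

A *system* is a set of trained pipelines covering the pregnancy: system A
has a single pipeline for all trimesters, system B splits off the first
trimester (whose skull is not yet brightly ossified), and system C has one
pipeline per trimester.  At measurement time every pipeline of the system
runs on the image; among the candidates that produced a plausible ellipse,
the one whose stage-1 boundary trace has the highest median response on its
own classifier's likelihood map wins.  This selects the right trimester model
automatically — the trimester never needs to be known in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifier import (
    LikelihoodMap,
    SkullClassifier,
    predict_likelihood,
    sample_training_pixels,
    train_classifier,
)
from .core_io import EllipseAnnotation, PipelineConfig, ScaledImage, ellipse_circumference
from .extraction import (
    DetectionError,
    FitError,
    extract_skull_midline,
    filter_ellipse,
    fit_ellipse_direct,
    hough_center,
    refine_outer_edge,
    select_fit_points,
)

__all__ = [
    "CandidateResult",
    "MeasurementResult",
    "default_system",
    "run_pipeline",
    "median_boundary_likelihood",
    "select_best",
    "measure_hc",
    "train_system",
]

# Shipped per-pipeline defaults after parameter optimization.  GA windows in
# days (trimester cut-offs at 14+0 and 28+0 weeks); radii and distances in mm.
_GA = {"t1": (63, 97), "t2": (98, 195), "t3": (196, 294), "t23": (98, 294), "all": (63, 294)}

_DEFAULTS = {
    "A": [
        PipelineConfig("A-all", *_GA["all"], r_min=5, r_max=61, f_scales=(6, 20),
                       n_trees=10, d_min=0.0, s_dis=0.4, n_angles=270, radial_offset=0.0),
    ],
    "B": [
        PipelineConfig("B-t1", *_GA["t1"], r_min=5, r_max=18, f_scales=(2.5, 0.5, 11),
                       n_trees=10, d_min=0.2, s_dis=0.2, n_angles=270, radial_offset=0.0),
        PipelineConfig("B-t23", *_GA["t23"], r_min=12, r_max=61, f_scales=(7, 11),
                       n_trees=10, d_min=0.2, s_dis=0.4, n_angles=270, radial_offset=5.0),
    ],
    "C": [
        PipelineConfig("C-t1", *_GA["t1"], r_min=5, r_max=18, f_scales=(2.5, 0.5, 11),
                       n_trees=10, d_min=0.2, s_dis=0.2, n_angles=270, radial_offset=0.0),
        PipelineConfig("C-t2", *_GA["t2"], r_min=12, r_max=50, f_scales=(7,),
                       n_trees=10, d_min=0.1, s_dis=0.3, n_angles=270, radial_offset=5.0),
        PipelineConfig("C-t3", *_GA["t3"], r_min=34, r_max=61, f_scales=(9, 12),
                       n_trees=10, d_min=0.1, s_dis=0.5, n_angles=270, radial_offset=10.0),
    ],
}


def default_system(name: str) -> list[PipelineConfig]:
    """Shipped pipeline configurations for system ``'A'``, ``'B'`` or ``'C'``."""
    try:
        return list(_DEFAULTS[name.upper()])
    except KeyError:
        raise ValueError(f"unknown system {name!r}; expected 'A', 'B' or 'C'") from None


@dataclass
class CandidateResult:
    """Outcome of one pipeline on one image; failures are recorded, not raised."""

    pipeline: str
    ellipse: EllipseAnnotation | None = None
    score: float | None = None
    failure: str | None = None
    center: tuple[float, float] | None = None
    likelihood: LikelihoodMap | None = field(default=None, repr=False)
    midline: object = field(default=None, repr=False)
    edge: object = field(default=None, repr=False)

    @property
    def accepted(self) -> bool:
        return self.ellipse is not None and self.failure is None

    @property
    def hc(self) -> float | None:
        return ellipse_circumference(self.ellipse) if self.ellipse is not None else None


def median_boundary_likelihood(
    e: EllipseAnnotation, lmap: LikelihoodMap, n_angles: int = 270
) -> float:
    """Median likelihood sampled (bilinearly) at equally-spaced boundary
    points of the ellipse — the pipeline-selection score."""
    pts = e.boundary_points(n_angles)
    rows = pts[:, 1] / lmap.pixel_size - 0.5
    cols = pts[:, 0] / lmap.pixel_size - 0.5
    lik = ndimage.map_coordinates(lmap.values, [rows, cols], order=1, mode="constant", cval=0.0)
    return float(np.median(lik))


def run_pipeline(
    img: ScaledImage,
    cfg: PipelineConfig,
    model: SkullClassifier,
    score_on: str = "path",
) -> CandidateResult:
    """Run one pipeline end to end; any stage failure yields a failed
    candidate instead of an exception.

    ``score_on`` chooses what the selection score is the median likelihood
    of: the stage-1 DP path (default — the score rewards the classifier
    that actually drove the extraction) or the fitted ellipse boundary
    (``score_on='ellipse'``).
    """
    out = CandidateResult(pipeline=cfg.name)
    try:
        lmap = predict_likelihood(model, img)
        out.likelihood = lmap
        center = hough_center(lmap, cfg.r_min, cfg.r_max)
        out.center = center
        midline = extract_skull_midline(lmap, center, cfg)
        out.midline = midline
        edge = refine_outer_edge(img, center, midline, cfg)
        out.edge = edge
        points = select_fit_points(edge, lmap)
        ellipse = fit_ellipse_direct(points)
        if not filter_ellipse(ellipse):
            out.failure = (
                f"fitted circumference {ellipse_circumference(ellipse):.1f} mm "
                "below plausibility threshold"
            )
            return out
        out.ellipse = ellipse
        if score_on == "path":
            pts = midline.points()
            rows = pts[:, 1] / lmap.pixel_size - 0.5
            cols = pts[:, 0] / lmap.pixel_size - 0.5
            lik = ndimage.map_coordinates(lmap.values, [rows, cols], order=1,
                                          mode="constant", cval=0.0)
            out.score = float(np.median(lik))
        else:
            out.score = median_boundary_likelihood(ellipse, lmap, cfg.n_angles)
    except (DetectionError, FitError, ValueError) as exc:
        out.failure = f"{type(exc).__name__}: {exc}"
    return out


def select_best(candidates: list[CandidateResult]) -> CandidateResult:
    """The accepted candidate with the highest selection score.

    Ties go to the earlier candidate in the list (pipelines are ordered by
    trimester, so ties favor the lower trimester).  If nothing was
    accepted, a failure result summarizing all per-pipeline reasons is
    returned.
    """
    if not candidates:
        raise ValueError("no candidates")
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        reasons = "; ".join(f"{c.pipeline}: {c.failure}" for c in candidates)
        return CandidateResult(pipeline="none", failure=f"all pipelines failed ({reasons})")
    best = accepted[0]
    for c in accepted[1:]:
        if c.score > best.score:
            best = c
    return best


@dataclass
class MeasurementResult:
    """Final HC measurement with full provenance."""

    hc: float | None
    ellipse: EllipseAnnotation | None
    pipeline: str
    candidates: list[CandidateResult]
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


def measure_hc(
    img: ScaledImage,
    models: dict[str, SkullClassifier],
    configs: list[PipelineConfig] | None = None,
    system: str = "C",
) -> MeasurementResult:
    """End-to-end HC measurement: run every pipeline, pick the best ellipse.

    ``models`` maps pipeline names to trained classifiers; ``configs``
    defaults to the shipped configuration of ``system``.  Deterministic
    given the models and the image.
    """
    cfgs = configs if configs is not None else default_system(system)
    missing = [c.name for c in cfgs if c.name not in models]
    if missing:
        raise ValueError(f"missing trained models for pipelines {missing}")
    candidates = [run_pipeline(img, cfg, models[cfg.name]) for cfg in cfgs]
    best = select_best(candidates)
    if not best.accepted:
        return MeasurementResult(None, None, best.pipeline, candidates, failure=best.failure)
    return MeasurementResult(best.hc, best.ellipse, best.pipeline, candidates)


def train_system(
    images: list[ScaledImage],
    annotations: dict[str, EllipseAnnotation],
    ga_days: dict[str, float],
    configs: list[PipelineConfig] | None = None,
    system: str = "C",
    seed: int = 0,
) -> dict[str, SkullClassifier]:
    """Train one classifier per pipeline from annotated images.

    Each image trains every pipeline whose GA window contains the image's
    gestational age.  Sampling and forest training are reproducible from
    ``seed``.
    """
    cfgs = configs if configs is not None else default_system(system)
    models: dict[str, SkullClassifier] = {}
    for ci, cfg in enumerate(cfgs):
        merged = None
        for ii, img in enumerate(images):
            ga = ga_days[img.id]
            if not (cfg.ga_min <= ga <= cfg.ga_max):
                continue
            s = sample_training_pixels(
                img, annotations[img.id], cfg.d_min, cfg.f_scales,
                rng_seed=seed + 1009 * ci + 13 * ii,
            )
            merged = s if merged is None else merged.merged_with(s)
        if merged is None:
            raise ValueError(f"no training image falls in the GA window of {cfg.name!r}")
        models[cfg.name] = train_classifier(merged, cfg.n_trees, rng_seed=seed + ci, name=cfg.name)
    return models
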