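"""Domain types, file I/O and ellipse geometry.

Coordinate conventions
----------------------
Pixel indices are 0-based ``(row, col)``.  The physical frame is in
millimeters with its origin at the top-left *corner* of the image, x
pointing right and y pointing down.  Pixel ``(i, j)`` covers the physical
point ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` at its center.
All geometry (ellipse parameters, radii, distances) is expressed in mm and
converted to pixels only at the raster boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import special

__all__ = [
    "ScaledImage",
    "EllipseAnnotation",
    "GrowthCurveTable",
    "PipelineConfig",
    "read_scaled_image",
    "ellipse_circumference",
    "rasterize_ellipse",
    "load_growth_curve",
    "read_annotations",
    "write_annotations",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class LookupError_(KeyError):
    """Raised when a sidecar or annotation row is missing."""


@dataclass(frozen=True)
class ScaledImage:
    """A 2D grayscale ultrasound frame plus its physical pixel size.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Grayscale intensities, nominally 0-255.
    pixel_size : float
        Isotropic pixel edge length in mm; clinical scans range from
        roughly 0.05 mm (first trimester, zoomed) to 0.33 mm.
    id : str
        Identifier, typically the source filename stem.
    """

    pixels: np.ndarray
    pixel_size: float
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image intensities must be finite")
        if not (self.pixel_size > 0 and math.isfinite(self.pixel_size)):
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the frame in mm."""
        h, w = self.pixels.shape
        return (w * self.pixel_size, h * self.pixel_size)

    def flipped_horizontally(self) -> "ScaledImage":
        return ScaledImage(self.pixels[:, ::-1].copy(), self.pixel_size, self.id + "_hflip")


@dataclass(frozen=True)
class EllipseAnnotation:
    """Geometric ellipse in the physical (mm) frame.

    ``a >= b`` are the semi-axes and ``theta`` is the rotation of the major
    axis against the +x axis, normalized to ``[0, pi)``.  The perimeter of
    this ellipse is the head circumference (HC).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        a, b, theta = float(self.a), float(self.b), float(self.theta)
        if not (a > 0 and b > 0):
            raise ValidationError(f"semi-axes must be positive, got a={a}, b={b}")
        if b > a:  # keep a as the major semi-axis
            a, b = b, a
            theta = theta + math.pi / 2
        theta = theta % math.pi
        if theta >= math.pi:  # fmod of a tiny negative can round to pi itself
            theta = 0.0
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "theta", theta)

    @property
    def circumference(self) -> float:
        return ellipse_circumference(self)

    def boundary_points(self, n: int) -> np.ndarray:
        """``n`` points on the boundary, uniformly spaced in the parametric
        angle, as an (n, 2) array of (x, y) mm."""
        t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        ct, st = math.cos(self.theta), math.sin(self.theta)
        x = self.cx + self.a * np.cos(t) * ct - self.b * np.sin(t) * st
        y = self.cy + self.a * np.cos(t) * st + self.b * np.sin(t) * ct
        return np.column_stack([x, y])


def ellipse_circumference(e: EllipseAnnotation) -> float:
    """Perimeter of an ellipse in mm: ``4 a E(1 - (b/a)^2)`` with the
    complete elliptic integral of the second kind (machine precision for
    any aspect ratio)."""
    a, b = e.a, e.b
    return float(4.0 * a * special.ellipe(1.0 - (b / a) ** 2))


def rasterize_ellipse(e: EllipseAnnotation, img: ScaledImage, mode: str = "curve") -> np.ndarray:
    """Rasterize an ellipse onto the pixel grid of ``img``.

    ``mode='curve'`` marks a 1-px-wide, 8-connected closed boundary;
    ``mode='filled'`` marks interior plus boundary.  Returns a boolean mask
    of the image shape.  An ellipse entirely outside the frame yields an
    empty mask (with a warning).
    """
    if mode not in ("curve", "filled"):
        raise ValueError(f"mode must be 'curve' or 'filled', got {mode!r}")
    h, w = img.shape
    ps = img.pixel_size
    # implicit conic test at every pixel center
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = (jj + 0.5) * ps - e.cx
    y = (ii + 0.5) * ps - e.cy
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    mask = (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
    if mode == "curve":
        # innermost pixel layer: pixels with a 4-neighbor outside; this is a
        # 1-px-wide, 8-connected closed loop contained in the filled mask
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
        mask = mask & ~interior
    if not mask.any():
        import warnings

        warnings.warn(f"ellipse {e} lies entirely outside the image frame", stacklevel=2)
    return mask


def read_scaled_image(image_path: str | Path, sidecar: str | Path) -> ScaledImage:
    """Load an 8-bit grayscale PNG/TIFF plus its pixel size from a sidecar CSV.

    The sidecar must have columns ``filename,pixel_size_mm`` and a row whose
    filename matches the image's basename.  Color inputs are converted to
    luminance.
    """
    image_path = Path(image_path)
    table = pd.read_csv(sidecar)
    if not {"filename", "pixel_size_mm"} <= set(table.columns):
        raise ValidationError("sidecar CSV must have columns filename,pixel_size_mm")
    rows = table[table["filename"] == image_path.name]
    if rows.empty:
        raise LookupError_(f"no sidecar row for {image_path.name!r} in {sidecar}")
    pixel_size = float(rows.iloc[0]["pixel_size_mm"])
    if not pixel_size > 0:
        raise ValidationError(f"pixel size for {image_path.name!r} must be > 0, got {pixel_size}")
    with Image.open(image_path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return ScaledImage(arr, pixel_size, id=image_path.stem)


ANNOTATION_COLUMNS = ["id", "cx_mm", "cy_mm", "a_mm", "b_mm", "theta_rad"]


def read_annotations(csv: str | Path) -> dict[str, EllipseAnnotation]:
    """Read an annotation CSV (``id,cx_mm,cy_mm,a_mm,b_mm,theta_rad``)."""
    table = pd.read_csv(csv)
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"annotation CSV missing columns {sorted(missing)}")
    out: dict[str, EllipseAnnotation] = {}
    for _, row in table.iterrows():
        out[str(row["id"])] = EllipseAnnotation(
            float(row["cx_mm"]), float(row["cy_mm"]),
            float(row["a_mm"]), float(row["b_mm"]), float(row["theta_rad"]),
        )
    return out


def write_annotations(annotations: dict[str, EllipseAnnotation], csv: str | Path) -> None:
    rows = [
        {"id": k, "cx_mm": e.cx, "cy_mm": e.cy, "a_mm": e.a, "b_mm": e.b, "theta_rad": e.theta}
        for k, e in annotations.items()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(csv, index=False, float_format="%.12g")


GROWTH_COLUMNS = ["ga_days", "hc_p3", "hc_p50", "hc_p97", "bpd_p3", "bpd_p50", "bpd_p97"]


@dataclass(frozen=True)
class GrowthCurveTable:
    """Reference growth-curve table: GA (days) against HC and BPD percentiles (mm).

    All columns must be strictly increasing in GA (each percentile track is
    invertible) and the percentiles ordered P3 <= P50 <= P97 in every row.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(GROWTH_COLUMNS) - set(t.columns)
        if missing:
            raise ValidationError(f"growth curve missing columns {sorted(missing)}")
        t = t[GROWTH_COLUMNS].astype(float).reset_index(drop=True)
        for col in GROWTH_COLUMNS:
            if not np.all(np.diff(t[col].to_numpy()) > 0):
                raise ValidationError(f"growth-curve column {col!r} must be strictly increasing")
        for m in ("hc", "bpd"):
            if not ((t[f"{m}_p3"] <= t[f"{m}_p50"]).all() and (t[f"{m}_p50"] <= t[f"{m}_p97"]).all()):
                raise ValidationError(f"growth-curve percentiles out of order for {m!r}")
        object.__setattr__(self, "table", t)

    @property
    def ga_range(self) -> tuple[float, float]:
        ga = self.table["ga_days"].to_numpy()
        return float(ga[0]), float(ga[-1])

    def lookup(self, column: str, ga_days: float) -> float:
        """Linear interpolation of a percentile column at a GA in days."""
        ga = self.table["ga_days"].to_numpy()
        if not (ga[0] <= ga_days <= ga[-1]):
            raise ValueError(f"GA {ga_days} days outside table range [{ga[0]}, {ga[-1]}]")
        return float(np.interp(ga_days, ga, self.table[column].to_numpy()))

    def invert(self, column: str, value: float) -> float:
        """GA (days) at which the given column equals ``value``; no extrapolation."""
        col = self.table[column].to_numpy()
        ga = self.table["ga_days"].to_numpy()
        if not (col[0] <= value <= col[-1]):
            raise ValueError(f"value {value} outside {column!r} range [{col[0]}, {col[-1]}]")
        return float(np.interp(value, col, ga))


def load_growth_curve(csv: str | Path) -> GrowthCurveTable:
    """Load and validate a growth-curve CSV (see :data:`GROWTH_COLUMNS`)."""
    return GrowthCurveTable(pd.read_csv(csv))


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one measurement pipeline.

    Each pipeline covers a gestational-age window and carries the classifier
    and skull-extraction settings tuned for it: Haar feature scales
    ``F_scales`` (mm), forest size ``N_trees``, negative-sampling clearance
    ``d_min`` (mm), Hough radius bounds ``r_min``/``r_max`` (mm), polar
    sampling distance ``S_dis`` (mm, 0 = native pixel resolution), angle
    count ``N_angles``, the radial offset at which stage-1 polar sampling
    starts (mm), and the dynamic-programming step bound ``dp_step``
    (samples per angle step).
    """

    name: str
    ga_min: float
    ga_max: float
    r_min: float
    r_max: float
    f_scales: tuple[float, ...]
    n_trees: int = 10
    d_min: float = 0.0
    s_dis: float = 0.0
    n_angles: int = 270
    radial_offset: float = 0.0
    dp_step: int = 1

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValidationError(f"r_min must be < r_max, got {self.r_min} >= {self.r_max}")
        if self.s_dis < 0:
            raise ValidationError("S_dis must be >= 0")
        if self.n_angles < 8:
            raise ValidationError("N_angles must be >= 8")
        if not self.f_scales:
            raise ValidationError("F_scales must be non-empty")
        if self.radial_offset < 0:
            raise ValidationError("radial_offset must be >= 0")
        object.__setattr__(self, "f_scales", tuple(float(s) for s in self.f_scales))
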