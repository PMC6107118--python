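"""Synthetic ultrasound phantom generator.

Each phantom is a fetal-head look-alike: a bright elliptical skull annulus
(the ground-truth ellipse is its *outer* edge, matching the clinical
annotation protocol) over a darker brain interior and background, with
multiplicative speckle, optional acoustic shadow sectors that break the
ring, a fan-shaped field of view, a midline echo and bright distractor
blobs.  Trimester controls head size, pixel size, skull thickness and
ring contrast — first-trimester skulls are rendered faint, as they are
in clinical scans before ossification.

Speckle uses the fully-developed approximation: the squared magnitude of
a spatially smoothed complex Gaussian field (Rayleigh-like envelope),
applied multiplicatively.  It is a texture model, not a wave simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .core_io import EllipseAnnotation, ScaledImage, ellipse_circumference, write_annotations
from .growth import synthetic_growth_curve

__all__ = ["PhantomSpec", "PhantomSample", "render_phantom", "generate_dataset"]

PIXEL_SIZE_RANGE = (0.052, 0.326)  # mm, clinical scanner range

# per-trimester generation defaults: HC range (mm), pixel-size range (mm),
# skull thickness (mm), ring contrast multiplier
TRIMESTER_DEFAULTS = {
    1: {"hc": (48.0, 100.0), "px": (0.052, 0.11), "thickness": 1.2, "contrast": 0.35},
    2: {"hc": (120.0, 250.0), "px": (0.09, 0.22), "thickness": 2.2, "contrast": 1.0},
    3: {"hc": (258.0, 330.0), "px": (0.17, 0.326), "thickness": 3.0, "contrast": 1.0},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; rendering is deterministic per spec."""

    trimester: int
    shape: tuple[int, int]  # (H, W) px
    pixel_size: float  # mm
    ellipse: EllipseAnnotation  # ground truth = outer skull edge
    thickness: float = 2.0  # skull thickness, mm
    background: float = 35.0
    interior: float = 55.0
    skull: float = 175.0
    contrast: float = 1.0  # multiplier on the ring/interior contrast
    speckle: float = 0.5  # multiplicative speckle weight in [0, 1)
    speckle_scale_mm: float = 0.6
    shadow_sectors: tuple = ()  # (angle_lo, angle_hi, attenuation) radians
    fan: bool = True
    midline_echo: bool = True
    n_distractors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (PIXEL_SIZE_RANGE[0] <= self.pixel_size <= PIXEL_SIZE_RANGE[1]):
            raise ValueError(f"pixel_size {self.pixel_size} outside {PIXEL_SIZE_RANGE}")
        if self.thickness <= 0:
            raise ValueError("skull thickness must be positive")
        h, w = self.shape
        ext_x, ext_y = w * self.pixel_size, h * self.pixel_size
        e = self.ellipse
        if not (e.a <= e.cx <= ext_x - e.a and e.a <= e.cy <= ext_y - e.a):
            raise ValueError("ellipse (bounding circle) must lie inside the field of view")

    @classmethod
    def for_trimester(
        cls,
        trimester: int,
        seed: int,
        shape: tuple[int, int] = (540, 800),
        speckle: float = 0.5,
        fan: bool = True,
        n_distractors: int = 2,
        max_shadows: int = 2,
    ) -> "PhantomSpec":
        """Sample a realistic spec for one trimester, reproducibly.

        Head size and pixel size are drawn from the trimester's clinical
        range; when the requested frame is too small for the drawn head,
        the pixel size is raised (within the clinical range) and, if still
        necessary, the head shrunk until it fits with a margin.
        """
        if trimester not in TRIMESTER_DEFAULTS:
            raise ValueError("trimester must be 1, 2 or 3")
        d = TRIMESTER_DEFAULTS[trimester]
        rng = np.random.default_rng(seed)
        hc = rng.uniform(*d["hc"])
        q = rng.uniform(1.15, 1.35)  # major/minor axis ratio
        theta = rng.uniform(0, math.pi)
        min_dim = min(shape)
        margin = 10.0  # mm clearance to the frame border
        for _ in range(100):
            a = hc / math.pi * q / (1 + q)
            px_needed = (2 * a + margin) / min_dim
            px_lo = max(d["px"][0], px_needed)
            if px_lo <= d["px"][1]:
                break
            hc *= 0.95  # frame too small: shrink the head
        px = min(rng.uniform(px_lo, max(px_lo, d["px"][1])), PIXEL_SIZE_RANGE[1])
        ext_x, ext_y = shape[1] * px, shape[0] * px
        slack_x = max(0.0, ext_x / 2 - a - margin / 2)
        slack_y = max(0.0, ext_y / 2 - a - margin / 2)
        cx = ext_x / 2 + rng.uniform(-1, 1) * min(5.0, slack_x)
        cy = ext_y / 2 + rng.uniform(-1, 1) * min(5.0, slack_y)
        ell = EllipseAnnotation(cx, cy, a, a / q, theta)
        n_shadows = int(rng.integers(0, max_shadows + 1))
        sectors = []
        for _ in range(n_shadows):
            lo = rng.uniform(0, 2 * math.pi)
            sectors.append((lo, lo + rng.uniform(0.35, 0.7), rng.uniform(0.25, 0.5)))
        return cls(
            trimester=trimester,
            shape=tuple(shape),
            pixel_size=float(px),
            ellipse=ell,
            thickness=d["thickness"],
            contrast=d["contrast"],
            speckle=speckle,
            shadow_sectors=tuple(sectors),
            fan=fan,
            n_distractors=n_distractors,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def _elliptical_radius(spec: PhantomSpec):
    """Normalized elliptical radius rho at every pixel center (1 = outer edge),
    plus the polar angle around the ellipse center."""
    h, w = spec.shape
    ps = spec.pixel_size
    e = spec.ellipse
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = (jj + 0.5) * ps - e.cx
    y = (ii + 0.5) * ps - e.cy
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    rho = np.sqrt((u / e.a) ** 2 + (v / e.b) ** 2)
    phi = np.arctan2(y, x) % (2 * math.pi)
    return rho, phi, u, v


def render_phantom(spec: PhantomSpec) -> tuple[ScaledImage, EllipseAnnotation]:
    """Render a phantom; returns the image and its ground-truth annotation.

    Bit-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    ps = spec.pixel_size
    e = spec.ellipse
    rho, phi, u, v = _elliptical_radius(spec)

    # base tissue map: background / brain interior / skull annulus
    inner = EllipseAnnotation(e.cx, e.cy, max(e.a - spec.thickness, 0.3), max(e.b - spec.thickness, 0.2), e.theta)
    rho_in = np.sqrt((u / inner.a) ** 2 + (v / inner.b) ** 2)
    skull_mean = spec.interior + spec.contrast * (spec.skull - spec.interior)
    base = np.full((h, w), spec.background)
    base[rho <= 1.0] = spec.interior
    base[(rho <= 1.0) & (rho_in >= 1.0)] = skull_mean

    if spec.midline_echo:
        echo = (np.abs(v) <= 0.5) & (np.abs(u) <= 0.8 * inner.a) & (rho_in < 1.0)
        base[echo] = spec.interior + spec.contrast * 45.0

    for _ in range(spec.n_distractors):
        # bright blobs outside the head, e.g. uterine wall sections
        bx = rng.uniform(0.1, 0.9) * w * ps
        by = rng.uniform(0.1, 0.9) * h * ps
        brho = math.hypot(bx - e.cx, by - e.cy) / max(e.a, 1e-6)
        if brho < 1.3:  # too close to the head: skip, keep the draw count fixed
            continue
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        d2 = ((jj + 0.5) * ps - bx) ** 2 + ((ii + 0.5) * ps - by) ** 2
        base += 70.0 * np.exp(-d2 / (2 * 2.0**2))

    # acoustic shadows: attenuate the outer skull and everything beyond it
    for lo, hi, att in spec.shadow_sectors:
        in_sector = ((phi - lo) % (2 * math.pi)) <= ((hi - lo) % (2 * math.pi))
        ramp = np.clip((rho - 0.92) / 0.16, 0.0, 1.0)
        base = np.where(in_sector, base * (1.0 - att * ramp), base)

    base = ndimage.gaussian_filter(base, sigma=0.6)  # soften tissue boundaries

    if spec.speckle > 0:
        sigma_px = max(spec.speckle_scale_mm / ps, 0.5)
        f = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
        f = ndimage.gaussian_filter(f.real, sigma_px) + 1j * ndimage.gaussian_filter(f.imag, sigma_px)
        intensity = np.abs(f) ** 2
        intensity /= intensity.mean()
        base = base * ((1.0 - spec.speckle) + spec.speckle * intensity)

    if spec.fan:
        apex_x, apex_y = w * ps / 2.0, -15.0
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        dx = (jj + 0.5) * ps - apex_x
        dy = (ii + 0.5) * ps - apex_y
        ang = np.arctan2(dx, dy)  # 0 = straight down
        r = np.hypot(dx, dy)
        half = math.radians(55.0)
        r_fan = h * ps + 15.0 + 5.0
        base[(np.abs(ang) > half) | (r < 3.0) | (r > r_fan)] = 0.0

    img = ScaledImage(np.clip(np.round(base), 0, 255), ps, id=f"phantom_t{spec.trimester}_{spec.seed}")
    return img, e


@dataclass(frozen=True)
class PhantomSample:
    """One generated phantom with its ground truth and nominal GA."""

    image: ScaledImage
    annotation: EllipseAnnotation
    spec: PhantomSpec
    ga_days: float
    hc_mm: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hc_mm", ellipse_circumference(self.annotation))


def _trimester_counts(n: int, mix) -> list[int]:
    """Largest-remainder allocation of n phantoms over the three trimesters."""
    mix = np.asarray(mix, dtype=float)
    mix = mix / mix.sum()
    raw = n * mix
    counts = np.floor(raw).astype(int)
    rest = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[rest[i % 3]] += 1
    return counts.tolist()


def generate_dataset(
    n: int,
    trimester_mix=(1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    out_dir: str | Path | None = None,
    shape: tuple[int, int] = (540, 800),
    **spec_kwargs,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with the given trimester proportions.

    Each sample carries a nominal GA obtained by inverting the synthetic
    median growth curve at the phantom's true HC.  When ``out_dir`` is
    given, the dataset is written in the package's external formats:
    8-bit PNGs, a ``pixel_sizes.csv`` sidecar, a ``annotations.csv``
    ellipse table and a ``meta.csv`` with trimester and GA.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = _trimester_counts(n, trimester_mix)
    curve = synthetic_growth_curve()
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for trimester, count in zip((1, 2, 3), counts):
        for _ in range(count):
            sub = int(master.integers(0, 2**31 - 1))
            spec = PhantomSpec.for_trimester(trimester, sub, shape=shape, **spec_kwargs)
            img, ann = render_phantom(spec)
            hc = ellipse_circumference(ann)
            ga = curve.invert("hc_p50", float(np.clip(hc, *_hc50_range(curve))))
            samples.append(PhantomSample(img, ann, spec, ga))
    if out_dir is not None:
        _write_dataset(samples, Path(out_dir))
    return samples


def _hc50_range(curve) -> tuple[float, float]:
    col = curve.table["hc_p50"].to_numpy()
    return float(col[0]), float(col[-1])


def _write_dataset(samples: list[PhantomSample], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar, meta, annotations = [], [], {}
    for s in samples:
        fname = f"{s.image.id}.png"
        Image.fromarray(s.image.pixels.astype(np.uint8), mode="L").save(out_dir / fname)
        sidecar.append({"filename": fname, "pixel_size_mm": s.image.pixel_size})
        meta.append({"id": s.image.id, "trimester": s.spec.trimester,
                     "ga_days": s.ga_days, "hc_mm": s.hc_mm})
        annotations[s.image.id] = s.annotation
    pd.DataFrame(sidecar).to_csv(out_dir / "pixel_sizes.csv", index=False)
    pd.DataFrame(meta).to_csv(out_dir / "meta.csv", index=False)
    write_annotations(annotations, out_dir / "annotations.csv")
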