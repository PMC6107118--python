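"""Haar-like feature bank on integral images.

Twelve kernels are used: edge (horizontal/vertical), line
(horizontal/vertical), center-surround and checkerboard-rectangle families,
each in an upright and a 45-degree rotated orientation.  Edge and rectangle
kernels are 2x2 cell grids; line and center-surround kernels are 3x3.

Kernels are sized in millimeters so that responses are invariant to the
scan's pixel size: the upright kernel side is ``max(n, round(scale_mm /
pixel_size))`` rounded up to a multiple of the cell-grid size ``n``.
Rotated kernels keep the same physical cell side along the diagonal axes,
which makes their axis-aligned bounding box a factor sqrt(2) larger.

Responses are normalized to be independent of the kernel's pixel area:

    response = mean(intensity over positive cells) - mean(over negative cells)

where each mean uses the exact count of in-frame pixels under the cells
(cells partially outside the frame therefore average over their visible
part; a constant image yields exactly zero everywhere).

Sign conventions (fixed so tests are deterministic): edge kernels take the
top / right half positive; line and center-surround take the center
positive; the rectangle checkerboard takes the main-diagonal cells
positive.  Rotated kernels apply the same sign grid on the rotated axes
(u = down-right diagonal, v = down-left diagonal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ScaledImage

__all__ = [
    "HaarKernel",
    "KERNEL_BANK",
    "FeatureStack",
    "integral_image",
    "rotated_integral_image",
    "kernel_geometry",
    "haar_response",
    "feature_stack",
    "ImageSATs",
]


@dataclass(frozen=True)
class HaarKernel:
    """One Haar-like kernel: a small grid of +1/-1 cells."""

    family: str
    orientation: str  # "upright" | "rotated45"
    signs: tuple[tuple[int, ...], ...]

    @property
    def grid(self) -> int:
        return len(self.signs)

    @property
    def name(self) -> str:
        return f"{self.family}_{self.orientation}"


_SIGNS = {
    "edge_h": ((1, 1), (-1, -1)),
    "edge_v": ((-1, 1), (-1, 1)),
    "line_h": ((-1, -1, -1), (1, 1, 1), (-1, -1, -1)),
    "line_v": ((-1, 1, -1), (-1, 1, -1), (-1, 1, -1)),
    "center_surround": ((-1, -1, -1), (-1, 1, -1), (-1, -1, -1)),
    "rectangle": ((1, -1), (-1, 1)),
}

KERNEL_BANK: tuple[HaarKernel, ...] = tuple(
    HaarKernel(family, orientation, _SIGNS[family])
    for orientation in ("upright", "rotated45")
    for family in ("edge_h", "edge_v", "line_h", "line_v", "center_surround", "rectangle")
)
"""The full 12-kernel bank, upright families first, then rotated."""


def integral_image(img: np.ndarray) -> np.ndarray:
    """Summed-area table: ``sat[i, j] = sum(img[:i+1, :j+1])``."""
    img = np.asarray(img, dtype=np.float64)
    return img.cumsum(axis=0).cumsum(axis=1)


def _padded_sat(img: np.ndarray) -> np.ndarray:
    """SAT with a leading zero row/column so rectangle sums need no branches."""
    h, w = img.shape
    sat = np.zeros((h + 1, w + 1), dtype=np.float64)
    sat[1:, 1:] = integral_image(img)
    return sat


class RotatedSAT:
    """Summed-area table on the 45-degree lattice.

    Pixels ``(r, c)`` are embedded at ``(u, v) = (r + c, r - c + W - 1)``;
    a square cell rotated by 45 degrees in image space becomes an
    axis-aligned rectangle in (u, v), so its pixel sum costs four lookups.
    Positions outside the image read as zero.
    """

    def __init__(self, img: np.ndarray):
        img = np.asarray(img, dtype=np.float64)
        h, w = img.shape
        n = h + w - 1
        grid = np.zeros((n, n), dtype=np.float64)
        mask = np.zeros((n, n), dtype=np.float64)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        u = rr + cc
        v = rr - cc + (w - 1)
        grid[u, v] = img
        mask[u, v] = 1.0
        self.shape = (h, w)
        self._sat = _padded_sat(grid)
        self._msat = _padded_sat(mask)

    def uv_of_pixel(self, r, c):
        """(u, v) coordinates of pixel (r, c)."""
        w = self.shape[1]
        return r + c, r - c + (w - 1)

    def _rect(self, sat, u_lo, u_hi, v_lo, v_hi):
        n = sat.shape[0] - 1
        a = np.clip(u_lo, 0, n)
        b = np.clip(u_hi, 0, n)
        c = np.clip(v_lo, 0, n)
        d = np.clip(v_hi, 0, n)
        return sat[b, d] - sat[a, d] - sat[b, c] + sat[a, c]

    def cell_sum(self, u_lo, u_hi, v_lo, v_hi):
        """Pixel-intensity sum over the half-open (u, v) box
        ``[u_lo, u_hi) x [v_lo, v_hi)``; out-of-frame area contributes 0."""
        return self._rect(self._sat, u_lo, u_hi, v_lo, v_hi)

    def cell_count(self, u_lo, u_hi, v_lo, v_hi):
        """Exact number of in-frame pixels inside the (u, v) box."""
        return self._rect(self._msat, u_lo, u_hi, v_lo, v_hi)


def rotated_integral_image(img: np.ndarray) -> RotatedSAT:
    """Build the rotated summed-area table for 45-degree cell sums."""
    return RotatedSAT(img)


class ImageSATs:
    """Both integral images of one frame, computed once and shared."""

    def __init__(self, img: np.ndarray):
        img = np.asarray(img, dtype=np.float64)
        self.shape = img.shape
        self.sat = _padded_sat(img)
        self.rsat = RotatedSAT(img)


def _upright_side(scale_mm: float, pixel_size: float, grid: int) -> int:
    side = max(grid, int(math.floor(scale_mm / pixel_size + 0.5)))
    if side % grid:
        side += grid - side % grid
    return side


def kernel_geometry(kernel: HaarKernel, scale_mm: float, pixel_size: float) -> dict:
    """Pixel extents of each cell of a kernel at a physical scale.

    Returns a dict with the cell side and a list of
    ``(sign, (lo0, hi0, lo1, hi1))`` half-open boxes, expressed as offsets
    from the center pixel — in (row, col) for upright kernels and in
    (u, v) lattice coordinates for rotated ones (``space`` key says which).
    """
    if scale_mm <= 0:
        raise ValueError("scale_mm must be positive")
    n = kernel.grid
    t = _upright_side(scale_mm, pixel_size, n) // n
    if kernel.orientation == "upright":
        cell, space = t, "image"
    else:
        # same physical side along the 45-degree axes; one (u, v) lattice
        # step moves sqrt(2)/2 pixels, hence the sqrt(2) factor
        cell, space = max(1, int(math.floor(t * math.sqrt(2.0) + 0.5))), "uv"
    half = (n * cell) // 2
    boxes = []
    for gi in range(n):
        for gj in range(n):
            lo0 = -half + gi * cell
            lo1 = -half + gj * cell
            boxes.append((kernel.signs[gi][gj], (lo0, lo0 + cell, lo1, lo1 + cell)))
    return {"cell_px": cell, "space": space, "grid": n, "boxes": boxes}


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _response_map(sats: ImageSATs, kernel: HaarKernel, scale_mm: float, pixel_size: float) -> np.ndarray:
    """Normalized response of one kernel at one scale, at every pixel."""
    h, w = sats.shape
    geom = kernel_geometry(kernel, scale_mm, pixel_size)
    pos_sum = np.zeros((h, w))
    neg_sum = np.zeros((h, w))
    pos_cnt = np.zeros((h, w))
    neg_cnt = np.zeros((h, w))
    if geom["space"] == "image":
        rows = np.arange(h)
        cols = np.arange(w)
        for sign, (lo0, hi0, lo1, hi1) in geom["boxes"]:
            ra = np.clip(rows + lo0, 0, h)
            rb = np.clip(rows + hi0, 0, h)
            ca = np.clip(cols + lo1, 0, w)
            cb = np.clip(cols + hi1, 0, w)
            sat = sats.sat
            s = sat[rb][:, cb] - sat[ra][:, cb] - sat[rb][:, ca] + sat[ra][:, ca]
            cnt = (rb - ra)[:, None] * (cb - ca)[None, :]
            if sign > 0:
                pos_sum += s
                pos_cnt += cnt
            else:
                neg_sum += s
                neg_cnt += cnt
    else:
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        u0, v0 = sats.rsat.uv_of_pixel(rr, cc)
        for sign, (lo0, hi0, lo1, hi1) in geom["boxes"]:
            s = sats.rsat.cell_sum(u0 + lo0, u0 + hi0, v0 + lo1, v0 + hi1)
            cnt = sats.rsat.cell_count(u0 + lo0, u0 + hi0, v0 + lo1, v0 + hi1)
            if sign > 0:
                pos_sum += s
                pos_cnt += cnt
            else:
                neg_sum += s
                neg_cnt += cnt
    resp = _safe_div(pos_sum, pos_cnt) - _safe_div(neg_sum, neg_cnt)
    # a kernel with one sign group entirely outside the frame carries no
    # contrast information; define its response as zero
    return np.where((pos_cnt > 0) & (neg_cnt > 0), resp, 0.0)


def haar_response(
    sats: ImageSATs | np.ndarray,
    kernel: HaarKernel,
    scale_mm: float,
    pixel_size: float,
    at: tuple | None = None,
):
    """Normalized kernel response; the full (H, W) map, or the value at
    pixel ``at=(row, col)`` (arrays allowed)."""
    if not isinstance(sats, ImageSATs):
        sats = ImageSATs(sats)
    resp = _response_map(sats, kernel, scale_mm, pixel_size)
    if at is None:
        return resp
    r, c = at
    return resp[r, c]


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel feature values of shape (H, W, 12 * n_scales).

    Channel order is scales-major: channel ``s * 12 + k`` holds kernel
    ``KERNEL_BANK[k]`` at ``scales[s]``.
    """

    values: np.ndarray
    scales: tuple[float, ...]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def at(self, rows, cols) -> np.ndarray:
        """Feature matrix (n_points, n_channels) at the given pixels."""
        return self.values[np.asarray(rows), np.asarray(cols), :]

    @staticmethod
    def channel_names(scales) -> list[str]:
        return [f"{k.name}@{s:g}mm" for s in scales for k in KERNEL_BANK]


def feature_stack(img: ScaledImage, f_scales) -> FeatureStack:
    """Evaluate all 12 kernels at every pixel for every scale (mm)."""
    scales = tuple(float(s) for s in f_scales)
    if any(s <= 0 for s in scales):
        raise ValueError("feature scales must be positive")
    sats = ImageSATs(img.pixels)
    h, w = img.shape
    out = np.empty((h, w, 12 * len(scales)), dtype=np.float32)
    for si, s in enumerate(scales):
        for ki, k in enumerate(KERNEL_BANK):
            out[:, :, si * 12 + ki] = _response_map(sats, k, s, img.pixel_size)
    return FeatureStack(out, scales)
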