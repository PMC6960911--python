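"""Color-space conversions, thresholding, labeling and rectangle primitives.

Images are ``float64`` arrays in ``[0, 1]``, shape ``(H, W, 3)`` for RGB,
row-major with the origin at the top-left; pixel coordinates are 0-based
``(row, col)``.  The HSI color model used throughout places hue in
``[0, 2*pi]`` with the band ``[pi/2, pi]`` corresponding to green
vegetation, saturation in ``[0, 1]`` and intensity ``I = (R + G + B) / 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

__all__ = [
    "HSIImage",
    "Region",
    "RegionSet",
    "validate_rgb",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "hsi_to_rgb_unclipped",
    "rgb_to_lab",
    "otsu_threshold",
    "remove_small_components",
    "label_regions",
    "max_inner_rectangle",
]

TWO_PI = 2.0 * np.pi


class HSIImage(NamedTuple):
    """Hue/saturation/intensity planes of an image.

    ``hue`` is in radians in ``[0, 2*pi]`` (0 for achromatic pixels),
    ``sat`` in ``[0, 1]`` (0 where R=G=B) and ``intensity`` in ``[0, 1]``.
    Black pixels (I=0) have hue and saturation 0 by convention.
    """

    hue: np.ndarray
    sat: np.ndarray
    intensity: np.ndarray


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Coerce *img* to a float64 H×W×3 array in [0, 1] or raise ValueError."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB values must be finite")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB values must lie in [0, 1]")
    return arr


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert an RGB image to HSI.

    Uses the arithmetic-mean intensity ``I = (R+G+B)/3``, the classic
    ``S = 1 - 3*min(R,G,B)/(R+G+B)`` saturation (0 where I=0) and the
    arccos hue, reflected to ``[pi, 2*pi]`` where ``B > G``.
    """
    arr = validate_rgb(img)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    intensity = total / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(total > 0.0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0.0, total, 1.0), 0.0)
    sat = np.clip(sat, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = den > 1e-12
    ratio = np.zeros_like(num)
    np.divide(num, den, out=ratio, where=chromatic)
    theta = np.arccos(np.clip(ratio, -1.0, 1.0))
    hue = np.where(b > g, TWO_PI - theta, theta)
    hue = np.where(chromatic, hue, 0.0)

    return HSIImage(hue=hue, sat=sat, intensity=intensity)


def hsi_to_rgb(hsi: HSIImage) -> np.ndarray:
    """Invert :func:`rgb_to_hsi`; output clipped to [0, 1].

    The round trip rgb→hsi→rgb reproduces the input to within 1e-6
    wherever no clipping occurs.
    """
    return np.clip(hsi_to_rgb_unclipped(hsi), 0.0, 1.0)


def hsi_to_rgb_unclipped(hsi: HSIImage) -> np.ndarray:
    """Inverse HSI transform without the gamut clip (may leave [0, 1])."""
    h = np.mod(np.asarray(hsi.hue, dtype=np.float64), TWO_PI)
    s = np.asarray(hsi.sat, dtype=np.float64)
    i = np.asarray(hsi.intensity, dtype=np.float64)

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    third = TWO_PI / 3.0  # 120 degrees
    sixth = np.pi / 3.0  # 60 degrees

    def sector(hh: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # within one 120-degree sector: (low, mid-raising, remainder)
        with np.errstate(divide="ignore", invalid="ignore"):
            raised = i * (1.0 + s * np.cos(hh) / np.cos(sixth - hh))
        lowered = i * (1.0 - s)
        rest = 3.0 * i - raised - lowered
        return lowered, raised, rest

    sec0 = h < third
    sec1 = (h >= third) & (h < 2.0 * third)
    sec2 = h >= 2.0 * third

    lo, hi, rest = sector(h)
    b[sec0], r[sec0], g[sec0] = lo[sec0], hi[sec0], rest[sec0]
    lo, hi, rest = sector(h - third)
    r[sec1], g[sec1], b[sec1] = lo[sec1], hi[sec1], rest[sec1]
    lo, hi, rest = sector(h - 2.0 * third)
    g[sec2], b[sec2], r[sec2] = lo[sec2], hi[sec2], rest[sec2]

    return np.stack([r, g, b], axis=-1)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB → CIE L*a*b* (D65), returned as an H×W×3 array (L, a*, b*)."""
    arr = validate_rgb(img)
    return skcolor.rgb2lab(arr)


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold for a real-valued map.

    Values are min–max scaled onto *bins* histogram bins; every interior
    bin edge is scored by the between-class variance of the two-class
    split it induces and the best edge (smallest on ties) is mapped back
    to the original scale.  Pixels strictly above the returned threshold
    form the bright class.

    Raises
    ------
    ValueError
        If the input is constant ("degenerate histogram").
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("degenerate histogram: empty input")
    lo, hi = float(vals.min()), float(vals.max())
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("non-finite values")
    if hi <= lo:
        raise ValueError("degenerate histogram: constant input")

    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(p)[:-1]  # weight of bins < k for split index k=1..bins-1
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    mu0 = np.divide(mu[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(mu_t - mu[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2

    k = int(np.argmax(sigma_b)) + 1  # first maximum -> smallest threshold
    return float(edges[k])


@dataclass(frozen=True)
class Region:
    """One 8-connected foreground component."""

    label: int
    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive


@dataclass
class RegionSet:
    """Labeled connected components of a binary mask.

    ``label_map`` holds 0 for background and 1..N for regions;
    ``area_ratio`` is the foreground fraction *A* in percent and
    ``count`` the number of regions *N*.
    """

    label_map: np.ndarray
    regions: list[Region] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.regions)

    @property
    def area_ratio(self) -> float:
        """Foreground area as a percentage of the image area."""
        total = self.label_map.size
        fg = int(np.count_nonzero(self.label_map))
        return 100.0 * fg / total if total else 0.0

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def region_mask(self, label: int) -> np.ndarray:
        return self.label_map == label


def remove_small_components(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Drop 8-connected components with area strictly below *min_area* pixels."""
    m = np.asarray(mask, dtype=bool)
    lab = skmeasure.label(m, connectivity=2)
    if lab.max() == 0:
        return m.copy()
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def label_regions(mask: np.ndarray) -> RegionSet:
    """Label the 8-connected components of a boolean mask."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    lab = skmeasure.label(m, connectivity=2)
    regions = [
        Region(
            label=int(rp.label),
            area=int(rp.area),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            bbox=tuple(int(v) for v in rp.bbox),
        )
        for rp in skmeasure.regionprops(lab)
    ]
    return RegionSet(label_map=lab, regions=regions)


def max_inner_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned rectangle fully inside a boolean mask.

    Returns ``(min_row, min_col, max_row, max_col)`` with exclusive upper
    bounds.  Uses the row-histogram / monotone-stack method; ties are
    broken by the top-left-most corner (smallest ``min_row``, then
    smallest ``min_col``).
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise ValueError("empty region")

    h, w = m.shape
    heights = np.zeros(w, dtype=np.int64)
    best = (0, (0, 0, 0, 0))  # (area, (top, left, bottom, right))

    for r in range(h):
        heights = np.where(m[r], heights + 1, 0)
        # largest rectangle in histogram ending at row r
        stack: list[int] = []  # indices with increasing heights
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top_idx = stack.pop()
                ht = int(heights[top_idx])
                if ht == 0:
                    continue
                left = stack[-1] + 1 if stack else 0
                area = ht * (c - left)
                cand = (area, (r - ht + 1, left, r + 1, c))
                if area > best[0] or (
                    area == best[0] and cand[1][:2] < best[1][:2]
                ):
                    best = cand
            stack.append(c)
    return best[1]
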