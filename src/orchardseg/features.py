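"""Per-region descriptors: color moments, GLCM statistics and uniform LBP.

A region is described by 78 numbers:

* 14 color features — population mean and variance of R, G, B, hue,
  saturation, a* and b* over the full region mask (hue uses circular
  statistics since it is an angle);
* 5 GLCM statistics — contrast (CON), energy (ASM), entropy (ENT, base-10
  log), inverse difference moment (IDM) and correlation (COR) of the
  16-level, distance-1, 4-direction symmetric co-occurrence matrix;
* 59 uniform-LBP bins — 8-neighbor radius-1 local binary patterns with
  bilinear sampling; the 58 uniform patterns (at most two circular bit
  transitions) get individual bins ordered by ascending 8-bit code, all
  non-uniform patterns pool into the final bin; histogram normalized to 1.

Texture is computed on the HSI intensity plane so it does not duplicate
the color features.  At test time texture uses the region's maximum inner
rectangle; training patches use their full rectangle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .imaging import max_inner_rectangle, rgb_to_hsi, rgb_to_lab, validate_rgb

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "color_features",
    "quantize_gray",
    "glcm_features",
    "lbp_histogram",
    "region_feature_vector",
    "UnFeaturizableRegion",
]

logger = logging.getLogger(__name__)

GLCM_LEVELS = 16
_COLOR_CHANNELS = ("R", "G", "B", "H", "S", "a", "b")
_GLCM_STATS = ("CON", "ASM", "ENT", "IDM", "COR")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ch}" for ch in _COLOR_CHANNELS for stat in ("mean", "var")
) + tuple(f"glcm_{s}" for s in _GLCM_STATS) + tuple(f"lbp_{i:02d}" for i in range(59))


class UnFeaturizableRegion(ValueError):
    """Raised when a region is too small/degenerate to featurize."""


@dataclass
class FeatureVector:
    """A 78-dim region descriptor with an optional class label."""

    values: np.ndarray  # shape (78,)
    label: str | None = None  # "tree", "background" or None

    N_COLOR = 14
    N_GLCM = 5
    N_LBP = 59
    N_TOTAL = 78

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.N_TOTAL,):
            raise ValueError(f"feature vector must have {self.N_TOTAL} dims")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _circular_moments(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean in [0, 2*pi) and circular variance 1 − |mean resultant|."""
    c = np.cos(angles).mean()
    s = np.sin(angles).mean()
    mean = float(np.mod(np.arctan2(s, c), 2.0 * np.pi))
    var = float(1.0 - np.hypot(c, s))
    return mean, max(var, 0.0)


def color_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """14 color features over the masked pixels.

    Order: (mean, var) for R, G, B, H, S, a*, b*.  Variances are
    population variances; hue uses the circular mean and circular
    variance.  Requires at least two masked pixels.
    """
    arr = validate_rgb(img)
    m = np.asarray(mask, dtype=bool)
    if m.sum() < 2:
        raise UnFeaturizableRegion("color features need at least 2 pixels")
    hsi = rgb_to_hsi(arr)
    lab = rgb_to_lab(arr)

    out = []
    for plane in (arr[..., 0], arr[..., 1], arr[..., 2]):
        vals = plane[m]
        out.extend([vals.mean(), vals.var()])
    h_mean, h_var = _circular_moments(hsi.hue[m])
    out.extend([h_mean, h_var])
    s_vals = hsi.sat[m]
    out.extend([s_vals.mean(), s_vals.var()])
    for plane in (lab[..., 1], lab[..., 2]):
        vals = plane[m]
        out.extend([vals.mean(), vals.var()])
    return np.array(out, dtype=np.float64)


def quantize_gray(patch: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantize a real-valued patch to ``levels`` uniform min–max bins."""
    p = np.asarray(patch, dtype=np.float64)
    lo, hi = p.min(), p.max()
    if hi <= lo:
        return np.zeros(p.shape, dtype=np.uint8)
    q = np.floor((p - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


GLCM_ANGLES: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_features(
    gray: np.ndarray,
    levels: int = GLCM_LEVELS,
    angles: tuple[float, ...] = GLCM_ANGLES,
) -> np.ndarray:
    """Five GLCM statistics of a gray patch (CON, ASM, ENT, IDM, COR).

    The patch is quantized to ``levels`` gray levels; symmetric
    co-occurrences at distance 1 are accumulated over *angles* (default:
    the four directions 0°, 45°, 90°, 135°) and normalized to a single
    probability matrix G.  Entropy uses the base-10 logarithm with
    0·lg 0 := 0; correlation is 0 by convention when either marginal
    standard deviation vanishes.
    """
    patch = np.asarray(gray, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 2:
        raise UnFeaturizableRegion("GLCM needs a patch of at least 2x2 pixels")
    q = quantize_gray(patch, levels)
    mats = graycomatrix(
        q,
        distances=[1],
        angles=list(angles),
        levels=levels,
        symmetric=True,
        normed=False,
    )
    g = mats[:, :, 0, :].sum(axis=-1).astype(np.float64)
    g /= g.sum()

    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    con = float(np.sum((ii - jj) ** 2 * g))
    asm = float(np.sum(g**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        logg = np.where(g > 0, np.log10(np.where(g > 0, g, 1.0)), 0.0)
    ent = float(-np.sum(g * logg))
    idm = float(np.sum(g / (1.0 + (ii - jj) ** 2)))

    pi_marg = g.sum(axis=1)
    pj_marg = g.sum(axis=0)
    u_i = float(np.sum(i * pi_marg))
    v_j = float(np.sum(i * pj_marg))
    s_i = float(np.sqrt(np.sum((i - u_i) ** 2 * pi_marg)))
    s_j = float(np.sqrt(np.sum((i - v_j) ** 2 * pj_marg)))
    if s_i * s_j > 0:
        cor = float((np.sum(ii * jj * g) - u_i * v_j) / (s_i * s_j))
    else:
        cor = 0.0
    return np.array([con, asm, ent, idm, cor], dtype=np.float64)


# 8 neighbors at angles 2*pi*k/8, k=0..7, radius 1, offsets in (row, col);
# row axis points down so angle k maps to (sin, cos) like a standard circle
# traversed clockwise on screen.  Diagonals need bilinear sampling.
_LBP_OFFSETS = [
    (np.sin(2.0 * np.pi * k / 8.0), np.cos(2.0 * np.pi * k / 8.0)) for k in range(8)
]


def _uniform_code_table() -> np.ndarray:
    """Map each 8-bit LBP code to its histogram bin (58 uniform + pooled)."""
    table = np.full(256, 58, dtype=np.int64)
    uniform_codes = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        if transitions <= 2:
            uniform_codes.append(code)
    for bin_idx, code in enumerate(sorted(uniform_codes)):
        table[code] = bin_idx
    return table


_LBP_TABLE = _uniform_code_table()


def _bilinear_sample(patch: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sample patch interior points offset by (dy, dx) with bilinear weights."""
    h, w = patch.shape
    rows = np.arange(1, h - 1, dtype=np.float64)[:, None] + dy
    cols = np.arange(1, w - 1, dtype=np.float64)[None, :] + dx
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    r0 = np.clip(r0, 0, h - 2)
    c0 = np.clip(c0, 0, w - 2)
    p00 = patch[r0, c0]
    p01 = patch[r0, c0 + 1]
    p10 = patch[r0 + 1, c0]
    p11 = patch[r0 + 1, c0 + 1]
    return (
        p00 * (1 - fr) * (1 - fc)
        + p01 * (1 - fr) * fc
        + p10 * fr * (1 - fc)
        + p11 * fr * fc
    )


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Raw 8-bit LBP codes for the interior pixels of a gray patch.

    Neighbor k (weight 2**k) sits at angle 2*pi*k/8 on the radius-1
    circle; off-grid neighbors are sampled bilinearly.  A neighbor counts
    as 1 when its value is >= the center value.
    """
    patch = np.asarray(gray, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise UnFeaturizableRegion("LBP needs a patch of at least 3x3 pixels")
    center = patch[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dy, dx) in enumerate(_LBP_OFFSETS):
        # snap near-integer offsets to the grid to avoid interpolation noise
        if abs(dy - round(dy)) < 1e-9 and abs(dx - round(dx)) < 1e-9:
            ry, rx = int(round(dy)), int(round(dx))
            neigh = patch[1 + ry : patch.shape[0] - 1 + ry, 1 + rx : patch.shape[1] - 1 + rx]
        else:
            neigh = _bilinear_sample(patch, dy, dx)
        codes |= (neigh >= center - 1e-12).astype(np.int64) << k
    return codes


def lbp_histogram(gray: np.ndarray) -> np.ndarray:
    """59-bin normalized uniform-LBP histogram of a gray patch.

    Invariant to adding a constant to every pixel and, more generally, to
    any strictly increasing gray-level transform.
    """
    codes = lbp_codes(gray)
    bins = _LBP_TABLE[codes.ravel()]
    hist = np.bincount(bins, minlength=59).astype(np.float64)
    return hist / hist.sum()


def region_feature_vector(
    img: np.ndarray,
    mask: np.ndarray,
    mode: str = "inner_rect",
    label: str | None = None,
) -> FeatureVector:
    """Full 78-dim descriptor for one region of an image.

    Color features use the full region mask.  Texture (GLCM + LBP) uses
    the HSI intensity plane restricted to the region's maximum inner
    rectangle (``mode='inner_rect'``, test time) or to the region's
    bounding rectangle (``mode='full_mask'``, training patches whose mask
    is the whole rectangle).

    Raises
    ------
    UnFeaturizableRegion
        If the texture window is smaller than 3x3 pixels.
    """
    if mode not in ("inner_rect", "full_mask"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = validate_rgb(img)
    m = np.asarray(mask, dtype=bool)

    color = color_features(arr, m)
    intensity = arr.mean(axis=-1)

    if mode == "inner_rect":
        top, left, bottom, right = max_inner_rectangle(m)
    else:
        rows, cols = np.nonzero(m)
        top, left, bottom, right = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
    window = intensity[top:bottom, left:right]
    if min(window.shape) < 3:
        raise UnFeaturizableRegion(
            f"texture window {window.shape} smaller than 3x3; region excluded"
        )
    glcm = glcm_features(window)
    lbp = lbp_histogram(window)
    return FeatureVector(values=np.concatenate([color, glcm, lbp]), label=label)
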