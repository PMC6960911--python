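"""Retinex-enhanced re-extraction for weedy scenes, with the switch rule.

When weeds cover much of the ground they share the crowns' green hue, so a
purely chromatic threshold merges crowns and weeds into one huge foreground
blob ("under-extraction").  The under-extraction judgement rule (UEJR)
detects this from the extracted foreground ratio *A* and region count *N*;
flagged scenes are re-extracted with a multi-scale retinex (MSR)
reflectance image, the 2G−R−B excess-green index, and a grayscale
closing / white top-hat / opening cascade that keeps crown-scale bright
structures while suppressing the broad weed field, followed by Otsu
binarization, per-component convex hulls and small-area exclusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .imaging import (
    RegionSet,
    label_regions,
    otsu_threshold,
    remove_small_components,
    validate_rgb,
)

__all__ = [
    "MsrParams",
    "UejrThresholds",
    "uejr_is_under_extracted",
    "msr_reflectance",
    "chromatic_2grb",
    "extract_rois_emsrcm",
]


@dataclass(frozen=True)
class MsrParams:
    """Multi-scale retinex parameters.

    ``sigmas`` are the Gaussian surround scales in pixels (the conventional
    small/medium/large triple for full-resolution aerial frames); weights
    must sum to 1; ``epsilon`` guards the logarithms.
    """

    sigmas: tuple[float, float, float] = (15.0, 80.0, 250.0)
    weights: tuple[float, float, float] = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigmas must be non-negative")
        if not math.isclose(sum(self.weights), 1.0, rel_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class UejrThresholds:
    """Under-extraction thresholds: area ratio percent T_A and region count T_N."""

    t_a: float = 45.0
    t_n: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.t_a < 100.0:
            raise ValueError("t_a must be in (0, 100)")
        if self.t_n < 1:
            raise ValueError("t_n must be >= 1")


def uejr_is_under_extracted(
    regions: RegionSet, thresholds: UejrThresholds = UejrThresholds()
) -> bool:
    """True iff the preliminary extraction looks under-extracted.

    Fires when the foreground area ratio exceeds ``T_A`` percent (weeds
    absorbed into the foreground) or the region count falls below ``T_N``
    (independent crowns merged together).
    """
    return regions.area_ratio > thresholds.t_a or regions.count < thresholds.t_n


def msr_reflectance(img: np.ndarray, params: MsrParams = MsrParams()) -> np.ndarray:
    """Multi-scale retinex reflectance image M.

    Per channel i: ``R_i = sum_j W_j [log(S_i + eps) − log(S_i ⊗ G_j + eps)]``
    and ``M_i = exp(R_i)``, with unit-sum Gaussian surrounds ``G_j`` and
    reflect padding at the borders.  A global multiplicative illumination
    change cancels in the log difference (exactly as eps → 0), and a
    constant image maps to M ≡ 1.
    """
    arr = validate_rgb(img)
    eps = params.epsilon
    out = np.empty_like(arr)
    for i in range(3):
        chan = arr[..., i]
        log_s = np.log(chan + eps)
        r = np.zeros_like(chan)
        for w, sigma in zip(params.weights, params.sigmas):
            if sigma <= 0:
                blurred = chan  # delta-kernel limit
            else:
                blurred = ndi.gaussian_filter(chan, sigma=sigma, mode="reflect")
            r += w * (log_s - np.log(blurred + eps))
        out[..., i] = np.exp(r)
    return out


def chromatic_2grb(img: np.ndarray) -> np.ndarray:
    """Excess-green index ``2G − R − B`` (= (G−R) + (G−B)) per pixel."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 array, got shape {arr.shape}")
    return 2.0 * arr[..., 1] - arr[..., 0] - arr[..., 2]


def _disk(radius: int):
    # decomposed footprint: large-radius grayscale morphology in linear time
    return skmorph.disk(radius, decomposition="sequence")


def extract_rois_emsrcm(
    img: np.ndarray,
    params: MsrParams = MsrParams(),
    closing_radius: int = 20,
    tophat_radius: int = 24,
    opening_radius: int = 20,
    min_area_frac: float = 0.0005,
) -> RegionSet:
    """Re-extract candidate tree regions from a weedy scene.

    Pipeline: MSR reflectance → 2G−R−B map → grayscale closing (disk
    ``closing_radius``) → white top-hat (disk ``tophat_radius``) →
    grayscale opening (disk ``opening_radius``) → Otsu binarization →
    per-component convex hull fill → small-area exclusion → labeling.

    The closing removes dark speckle inside crowns, the top-hat keeps
    bright structures narrower than its disk (crowns) while flattening the
    broad weed field, and the opening erases residual bright grains
    smaller than crown scale.  Convex hulls restore crown edges eroded by
    the large-radius morphology.
    """
    m = msr_reflectance(img, params)
    chrom = chromatic_2grb(m)
    chrom = skmorph.closing(chrom, _disk(closing_radius))
    chrom = skmorph.white_tophat(chrom, _disk(tophat_radius))
    chrom = skmorph.opening(chrom, _disk(opening_radius))
    try:
        thr = otsu_threshold(chrom)
    except ValueError:
        warnings.warn("degenerate chromatic map; returning empty region set", stacklevel=2)
        return label_regions(np.zeros(chrom.shape, dtype=bool))
    mask = chrom > thr
    if mask.any():
        # one hull pass per component; hulls of nearby components may
        # overlap, in which case the merged region is no longer convex
        mask = skmorph.convex_hull_object(mask, connectivity=2)
    mask = remove_small_components(mask, mask.size * min_area_frac)
    return label_regions(mask)
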