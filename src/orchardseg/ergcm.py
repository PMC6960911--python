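"""Primary RoI extraction via the relative G−R chromatic map.

Tree crowns have G > R while soil and withered grass have R ≳ G, so the
difference ``G − R`` separates vegetation from background — but its
magnitude scales with the local brightness.  Dividing by the HSI intensity
gives the *relative* chromatic index ``im = (G − R) / I`` which is exactly
invariant to a multiplicative illumination change.  The map is thresholded
with Otsu's method and cleaned morphologically.
"""

from __future__ import annotations

import warnings

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

__all__ = ["relative_gr_map", "clean_mask_ergcm", "extract_rois_ergcm"]

MIN_AREA_FRAC: float = 0.0005  # exclude components below 0.05% of the image
DISK_RADIUS: int = 5


def relative_gr_map(img: np.ndarray) -> np.ndarray:
    """Per-pixel relative G−R chromatic index ``(G − R) / I`` (0 where I = 0)."""
    arr = validate_rgb(img)
    g_minus_r = arr[..., 1] - arr[..., 0]
    intensity = arr.mean(axis=-1)
    out = np.zeros_like(g_minus_r)
    np.divide(g_minus_r, intensity, out=out, where=intensity > 0)
    return out


def clean_mask_ergcm(
    mask: np.ndarray, min_area_frac: float = MIN_AREA_FRAC, disk_radius: int = DISK_RADIUS
) -> np.ndarray:
    """Morphological cleanup of a raw vegetation mask.

    In order: (1) exclude components smaller than ``min_area_frac`` of the
    image area, (2) binary closing with a disk of ``disk_radius`` pixels to
    smooth jagged edges, (3) fill interior holes.
    """
    m = np.asarray(mask, dtype=bool)
    m = remove_small_components(m, m.size * min_area_frac)
    footprint = skmorph.disk(disk_radius)
    m = skmorph.closing(m, footprint)
    m = ndi.binary_fill_holes(m)
    return m


def extract_rois_ergcm(
    img: np.ndarray,
    min_area_frac: float = MIN_AREA_FRAC,
    disk_radius: int = DISK_RADIUS,
) -> RegionSet:
    """Extract candidate tree regions from an (illumination-compensated) image.

    Pipeline: relative G−R map → Otsu threshold (keep pixels above) →
    small-area exclusion → disk closing → hole filling → 8-connected
    labeling.  A chromatically constant image (degenerate Otsu histogram)
    yields an empty region set with a warning.
    """
    chrom = relative_gr_map(img)
    try:
        thr = otsu_threshold(chrom)
    except ValueError:
        warnings.warn("degenerate chromatic map; returning empty region set", stacklevel=2)
        return label_regions(np.zeros(chrom.shape, dtype=bool))
    mask = chrom > thr
    mask = clean_mask_ergcm(mask, min_area_frac=min_area_frac, disk_radius=disk_radius)
    return label_regions(mask)
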