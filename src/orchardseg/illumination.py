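"""Selective illumination compensation for under-lit orchard imagery.

Nadir UAV images of orchards are often dominated by bright soil while the
tree crowns sit in shadow, so global histogram equalization spends most of
its dynamic range on the background.  SRIHE (selective region intensity
histogram equalization) instead equalizes the intensity histogram only over
the green-hue pixel set ``S_g = {p : pi/2 <= H(p) <= pi}``, leaving hue,
saturation and all non-green pixels untouched.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .imaging import HSIImage, hsi_to_rgb, hsi_to_rgb_unclipped, rgb_to_hsi, validate_rgb

__all__ = [
    "GREEN_HUE_RANGE",
    "green_selection_mask",
    "equalize_intensity",
    "srihe",
    "global_he",
    "classify_brightness",
    "BRIGHTNESS_THRESHOLD",
]

logger = logging.getLogger(__name__)

GREEN_HUE_RANGE: tuple[float, float] = (np.pi / 2.0, np.pi)
BRIGHTNESS_THRESHOLD: float = 0.3
HE_BINS: int | None = None  # exact empirical CDF by default


def green_selection_mask(
    hsi: HSIImage, hue_range: tuple[float, float] = GREEN_HUE_RANGE
) -> np.ndarray:
    """Boolean mask of pixels whose hue lies in the green band (inclusive)."""
    lo, hi = hue_range
    return (hsi.hue >= lo) & (hsi.hue <= hi)


def equalize_intensity(
    intensity: np.ndarray, mask: np.ndarray | None = None, bins: int | None = None
) -> np.ndarray:
    """Histogram-equalize an intensity plane over *mask* (default: all pixels).

    The transfer function is the cumulative distribution of the masked
    pixels (the probability integral transform).  With ``bins=None`` the
    exact empirical CDF of the continuous values is used, which makes the
    mapping *exactly* idempotent — ranks map to ranks; with an integer
    ``bins`` the plane is first quantized to that many gray levels and
    idempotence holds up to one level.  A constant masked plane is
    returned unchanged, as are all pixels outside the mask.
    """
    inten = np.asarray(intensity, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(inten, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return inten.copy()

    vals = inten[mask]
    if bins is None:
        sorted_vals = np.sort(vals)
        if sorted_vals[0] == sorted_vals[-1]:
            return inten.copy()
        mapped = np.searchsorted(sorted_vals, vals, side="right") / vals.size
    else:
        levels = np.clip((vals * (bins - 1)).round().astype(np.int64), 0, bins - 1)
        hist = np.bincount(levels, minlength=bins).astype(np.float64)
        if np.count_nonzero(hist) <= 1:
            return inten.copy()
        transfer = np.cumsum(hist) / hist.sum()
        mapped = transfer[levels]

    out = inten.copy()
    out[mask] = mapped
    return out


def srihe(img: np.ndarray, hue_range: tuple[float, float] = GREEN_HUE_RANGE, bins: int | None = HE_BINS) -> np.ndarray:
    """Selective region intensity histogram equalization.

    Equalizes the intensity histogram restricted to the green-hue set
    ``S_g``, keeps hue and saturation and all pixels outside ``S_g``
    unchanged, and converts back to RGB (clipped to gamut).  If ``S_g``
    is empty the input is returned unchanged.
    """
    arr = validate_rgb(img)
    hsi = rgb_to_hsi(arr)
    sg = green_selection_mask(hsi, hue_range)
    if not sg.any():
        return arr.copy()

    new_i = equalize_intensity(hsi.intensity, sg, bins=bins)
    raw = hsi_to_rgb_unclipped(HSIImage(hue=hsi.hue, sat=hsi.sat, intensity=new_i))
    out, adjusted = _fit_gamut_by_desaturation(raw, new_i)
    if adjusted > 0:
        logger.info("srihe: %.2f%% of pixels desaturated into gamut", 100.0 * adjusted)
    return out


def _fit_gamut_by_desaturation(raw: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, float]:
    """Bring out-of-gamut RGB into [0, 1] while preserving hue and intensity.

    At fixed hue and intensity the HSI inverse is linear in saturation
    (every channel is ``I + S * f(H)`` with the f summing to 0), so
    shrinking each offending pixel's chroma by a scalar keeps both I and
    H exact — unlike a hard clip, which silently changes the equalized
    intensities.
    """
    i = intensity[..., None]
    delta = raw - i
    alpha = np.ones_like(raw)
    over = raw > 1.0
    np.divide(1.0 - i + 0 * raw, delta, out=alpha, where=over)
    under = raw < 0.0
    np.divide(i + 0 * raw, -delta, out=alpha, where=under)
    scale = np.clip(alpha.min(axis=-1), 0.0, 1.0)
    out = i + scale[..., None] * delta
    adjusted = float(np.mean(scale < 1.0))
    return np.clip(out, 0.0, 1.0), adjusted


def global_he(img: np.ndarray, bins: int | None = HE_BINS) -> np.ndarray:
    """Global histogram equalization of the full intensity plane.

    Baseline for SRIHE: the transfer function is built from the whole
    image histogram, so a bright background dominates the mapping.
    """
    arr = validate_rgb(img)
    hsi = rgb_to_hsi(arr)
    new_i = equalize_intensity(hsi.intensity, None, bins=bins)
    return hsi_to_rgb(HSIImage(hue=hsi.hue, sat=hsi.sat, intensity=new_i))


def classify_brightness(
    img: np.ndarray, threshold: float = BRIGHTNESS_THRESHOLD
) -> str:
    """Classify a scene as insufficient ('IB') or sufficient ('SB') brightness.

    The mean intensity ``I_A`` over the green-hue foreground set is
    compared against *threshold* (default 0.3): IB if strictly below,
    SB otherwise.  An image with no green pixels is reported SB with a
    warning.
    """
    arr = validate_rgb(img)
    hsi = rgb_to_hsi(arr)
    sg = green_selection_mask(hsi)
    if not sg.any():
        warnings.warn("no green-hue pixels; brightness condition defaults to SB", stacklevel=2)
        return "SB"
    i_a = float(hsi.intensity[sg].mean())
    return "IB" if i_a < threshold else "SB"
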