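"""Image and mask readers/writers (JPEG/PNG/TIFF via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask", "write_label_map"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as float64 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def write_image(path: str | Path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask/label PNG; nonzero pixels are foreground."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def read_label_map(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.int64)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)).save(path)


def write_label_map(path: str | Path, label_map: np.ndarray) -> None:
    lab = np.asarray(label_map)
    if lab.max() > 255:
        raise ValueError("label map has more than 255 regions; use 16-bit storage")
    Image.fromarray(lab.astype(np.uint8)).save(path)
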