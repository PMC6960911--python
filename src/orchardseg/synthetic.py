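"""Synthetic orchard scene generator with exact ground truth.

Renders nadir views of a citrus orchard: dark-green textured crowns
(lumpy-edged ellipses) planted on a jittered grid (commercial orchards are
laid out in rows), a brown soil / withered-grass background, and green weed
patches whose total coverage is driven to a target fraction.  Crowns carry coarse
multiplicative mottling (leaf clumps); weeds carry finer-grained texture,
which is what the retinex/top-hat re-extraction chain exploits.  A global
brightness factor produces under-lit (IB) versus well-lit (SB) scenes.

Every scene is deterministic given its seed, and the generator returns the
per-tree masks, the weed mask and the brightness/weed-coverage condition
labels recomputed from the rendered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

from .illumination import classify_brightness, green_selection_mask
from .imaging import rgb_to_hsi

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "generate_patch",
    "generate_dataset",
    "save_dataset",
    "classify_wcc_fraction",
    "STRATA",
]

STRATA: tuple[tuple[str, str], ...] = (
    ("IB", "SWCR"),
    ("IB", "MWCR"),
    ("IB", "LWCR"),
    ("SB", "SWCR"),
    ("SB", "MWCR"),
    ("SB", "LWCR"),
)

# green coverage fraction (crowns + weeds) targeted per weed-coverage class;
# class cutoffs are 35% and 60%, targets sit comfortably inside each band
WCC_TARGETS: dict[str, float] = {"SWCR": 0.25, "MWCR": 0.47, "LWCR": 0.70}

# brightness factor per brightness class; IB must push the mean green-pixel
# intensity below the 0.3 cutoff, SB must stay above it
BC_FACTORS: dict[str, float] = {"IB": 0.55, "SB": 1.0}

# width of the weed-free ring around crowns per weed-coverage class: the
# coverage classes reflect orchard-floor management intensity, so heavily
# invaded orchards lack the mowed/shaded strip and weeds encroach the crowns
WCC_MARGINS: dict[str, int] = {"SWCR": 7, "MWCR": 5, "LWCR": 3}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic orchard scene."""

    height: int = 200
    width: int = 200
    n_trees: int = 30
    crown_radius: tuple[float, float] = (7.0, 11.0)
    crown_lumpiness: float = 0.15  # radial boundary irregularity (fraction of radius)
    crown_color: tuple[float, float, float] = (0.24, 0.62, 0.20)
    crown_color_jitter: float = 0.03
    soil_color: tuple[float, float, float] = (0.46, 0.36, 0.22)
    weed_color: tuple[float, float, float] = (0.30, 0.60, 0.22)
    green_coverage: float = 0.25  # target crown+weed fraction of the image
    crown_texture_sigma: float = 3.0  # coarse leaf-clump mottling scale (px)
    crown_texture_amp: float = 0.22
    weed_texture_sigma: float = 0.7  # fine grass-blade texture scale (px)
    weed_texture_amp: float = 0.20
    weed_blob_sigma: float = 9.0  # spatial scale of weed patches (px)
    weed_margin: int = 7  # mowed/shaded ring around crowns kept free of weeds (px)
    crown_gap: float = 6.0  # minimum soil gap between neighboring crowns (px)
    soil_texture_sigma: float = 4.0
    soil_texture_amp: float = 0.12
    brightness: float = 1.0  # global multiplicative illumination factor
    blur_sigma: float = 0.6
    noise_sigma: float = 0.008
    seed: int = 0

    @classmethod
    def for_stratum(cls, bc: str, wcc: str, seed: int = 0, **overrides) -> "SceneSpec":
        """Spec whose coverage/brightness target the given condition stratum."""
        if bc not in BC_FACTORS or wcc not in WCC_TARGETS:
            raise ValueError(f"unknown stratum ({bc}, {wcc})")
        overrides.setdefault("weed_margin", WCC_MARGINS[wcc])
        return cls(
            green_coverage=WCC_TARGETS[wcc],
            brightness=BC_FACTORS[bc],
            seed=seed,
            **overrides,
        )


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene."""

    tree_masks: list[np.ndarray]  # pairwise disjoint boolean masks
    tree_mask: np.ndarray  # union of crowns
    weed_mask: np.ndarray
    centroids: list[tuple[float, float]]
    bc: str  # brightness condition recomputed from the rendered image
    wcc: str  # weed-coverage condition recomputed from the rendered image
    green_fraction: float  # rendered green-hue pixel fraction


def classify_wcc_fraction(a_fraction: float) -> str:
    """Weed-coverage class from a green-area fraction (cutoffs 0.35, 0.60)."""
    if a_fraction < 0.35:
        return "SWCR"
    if a_fraction < 0.60:
        return "MWCR"
    return "LWCR"


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-std Gaussian-filtered white noise."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = ndi.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _mottle(rng: np.random.Generator, shape: tuple[int, int], sigma: float, amp: float) -> np.ndarray:
    """Multiplicative texture field around 1, clipped away from zero."""
    return np.clip(1.0 + amp * _smooth_noise(rng, shape, sigma), 0.2, 1.8)


def _place_crowns(spec: SceneSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint elliptical crown masks on a jittered planting grid."""
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.crown_radius
    aspect = h / w
    rows = int(np.ceil(np.sqrt(spec.n_trees * aspect)))
    cols = int(np.ceil(spec.n_trees / rows))
    cell_h, cell_w = h / rows, w / cols
    half = min(cell_h, cell_w) / 2.0
    margin = spec.crown_gap / 2.0
    lump = 1.0 + (0.2 if spec.crown_lumpiness > 0 else 0.0)  # max radial bump
    if half <= r_hi * lump + margin:
        raise ValueError(
            f"infeasible packing: {spec.n_trees} crowns of radius up to {r_hi} "
            f"with gap {spec.crown_gap} do not fit a {h}x{w} scene"
        )

    cells = [(r, c) for r in range(rows) for c in range(cols)]
    order = rng.permutation(len(cells))[: spec.n_trees]
    yy, xx = np.mgrid[0:h, 0:w]
    masks = []
    for idx in order:
        gr, gc = cells[idx]
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0.0, np.pi)
        jitter = max(half - max(a, b) * lump - margin, 0.0)
        cy = (gr + 0.5) * cell_h + rng.uniform(-jitter, jitter)
        cx = (gc + 0.5) * cell_w + rng.uniform(-jitter, jitter)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rad = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        if spec.crown_lumpiness > 0:
            # lumpy (non-convex) boundary: low-order radial harmonics emulate
            # the irregular outline of a real canopy
            phi = np.arctan2(v, u)
            bump = np.zeros_like(phi)
            for kh in range(2, 6):
                bump += rng.normal(0.0, 1.0) * np.cos(kh * phi) + rng.normal(
                    0.0, 1.0
                ) * np.sin(kh * phi)
            bump *= spec.crown_lumpiness / np.sqrt(8.0)
            boundary = 1.0 + np.clip(bump, -0.3, 0.2)
        else:
            boundary = 1.0
        masks.append(rad <= boundary)
    return masks


def _weed_mask(
    spec: SceneSpec, rng: np.random.Generator, crown_union: np.ndarray
) -> np.ndarray:
    """Weed patches outside the crowns hitting the green-coverage target."""
    total = crown_union.size
    crown_frac = crown_union.sum() / total
    weed_frac = max(spec.green_coverage - crown_frac, 0.0)
    if weed_frac <= 0.0:
        return np.zeros_like(crown_union)
    # canopy shade suppresses grass at the crown edge: weeds keep a small
    # soil ring around every crown
    if spec.weed_margin > 0:
        excluded = ndi.binary_dilation(
            crown_union, structure=ndi.generate_binary_structure(2, 2), iterations=spec.weed_margin
        )
    else:
        excluded = crown_union
    # blobby patch field: threshold smooth noise at the quantile that yields
    # the required fraction among plantable pixels
    blobs = _smooth_noise(rng, crown_union.shape, sigma=spec.weed_blob_sigma)
    open_frac = weed_frac / max(1.0 - excluded.mean(), 1e-9)
    open_frac = min(open_frac, 1.0)
    cutoff = np.quantile(blobs[~excluded], 1.0 - open_frac)
    return (blobs > cutoff) & ~excluded


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one orchard scene and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    tree_masks = _place_crowns(spec, rng)
    crown_union = np.logical_or.reduce(tree_masks) if tree_masks else np.zeros((h, w), bool)
    weed_mask = _weed_mask(spec, rng, crown_union)

    img = np.empty((h, w, 3))
    soil_tex = _mottle(rng, (h, w), spec.soil_texture_sigma, spec.soil_texture_amp)
    img[:] = np.asarray(spec.soil_color) * soil_tex[..., None]

    crown_tex = _mottle(rng, (h, w), spec.crown_texture_sigma, spec.crown_texture_amp)
    for mask in tree_masks:
        jitter = 1.0 + rng.uniform(-spec.crown_color_jitter, spec.crown_color_jitter, 3)
        color = np.clip(np.asarray(spec.crown_color) * jitter, 0.0, 1.0)
        img[mask] = color * crown_tex[mask, None]

    weed_tex = _mottle(rng, (h, w), spec.weed_texture_sigma, spec.weed_texture_amp)
    img[weed_mask] = np.asarray(spec.weed_color) * weed_tex[weed_mask, None]

    img *= spec.brightness
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0), mode="reflect")
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    hsi = rgb_to_hsi(img)
    green = green_selection_mask(hsi)
    green_fraction = float(green.mean())
    truth = SceneTruth(
        tree_masks=tree_masks,
        tree_mask=crown_union,
        weed_mask=weed_mask,
        centroids=[
            (float(np.nonzero(m)[0].mean()), float(np.nonzero(m)[1].mean()))
            for m in tree_masks
        ],
        bc=classify_brightness(img),
        wcc=classify_wcc_fraction(green_fraction),
        green_fraction=green_fraction,
    )
    return img, truth


def generate_patch(kind: str, size: int = 64, brightness: float = 1.0, seed: int = 0) -> np.ndarray:
    """Render a uniform training patch of crown, soil or weed texture.

    These emulate the manually marked training rectangles: ``tree``
    patches are positive samples, ``soil`` and ``weed`` patches negative.
    """
    spec = SceneSpec(brightness=brightness, seed=seed)
    rng = np.random.default_rng(seed)
    shape = (size, size)
    if kind == "tree":
        jit = 1.0 + rng.uniform(-spec.crown_color_jitter, spec.crown_color_jitter, 3)
        base = np.clip(np.asarray(spec.crown_color) * jit, 0, 1)
        tex = _mottle(rng, shape, spec.crown_texture_sigma, spec.crown_texture_amp)
    elif kind == "soil":
        base = np.asarray(spec.soil_color)
        tex = _mottle(rng, shape, spec.soil_texture_sigma, spec.soil_texture_amp)
    elif kind == "weed":
        base = np.asarray(spec.weed_color)
        tex = _mottle(rng, shape, spec.weed_texture_sigma, spec.weed_texture_amp)
    else:
        raise ValueError(f"unknown patch kind {kind!r}")
    img = base * tex[..., None] * brightness
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0), mode="reflect")
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    n_per_stratum: int,
    strata: tuple[tuple[str, str], ...] = STRATA,
    seed: int = 0,
    **overrides,
) -> tuple[list[tuple[SceneSpec, np.ndarray, SceneTruth]], pd.DataFrame]:
    """Balanced scene set across condition strata with a manifest table.

    Per-scene seeds are spawned reproducibly from the master seed.  The
    manifest records the intended stratum and the conditions recomputed
    from the rendered pixels.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(strata) * n_per_stratum)
    scenes = []
    rows = []
    k = 0
    for bc, wcc in strata:
        for i in range(n_per_stratum):
            scene_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            spec = SceneSpec.for_stratum(bc, wcc, seed=scene_seed, **overrides)
            img, truth = generate_scene(spec)
            scenes.append((spec, img, truth))
            rows.append(
                {
                    "scene_id": f"{bc}_{wcc}_{i:03d}",
                    "bc_target": bc,
                    "wcc_target": wcc,
                    "bc_rendered": truth.bc,
                    "wcc_rendered": truth.wcc,
                    "green_fraction": truth.green_fraction,
                    "n_trees": len(truth.tree_masks),
                    "seed": scene_seed,
                }
            )
    return scenes, pd.DataFrame(rows)


def save_dataset(
    scenes: list[tuple[SceneSpec, np.ndarray, SceneTruth]],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write images/ (PNG), truth/ (label PNGs) and manifest.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for (spec, img, truth), sid in zip(scenes, manifest["scene_id"]):
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out / "images" / f"{sid}.png")
        label = np.zeros(img.shape[:2], dtype=np.uint8)
        for idx, m in enumerate(truth.tree_masks, start=1):
            label[m] = idx
        Image.fromarray(label).save(out / "truth" / f"{sid}_trees.png")
        Image.fromarray((truth.weed_mask * 255).astype(np.uint8)).save(
            out / "truth" / f"{sid}_weeds.png"
        )
    manifest.to_csv(out / "manifest.csv", index=False)
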