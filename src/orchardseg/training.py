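"""Train the region classifier on labeled crops of synthetic scenes.

Emulates the manual training-rectangle protocol: training samples are
taken from illumination-compensated scenes — every true crown becomes a
positive sample (color over the crown mask, texture over its maximum
inner rectangle, exactly as at test time), and negative samples are
rectangles drawn fully inside the weed field or the bare soil, with
weed negatives outnumbering soil negatives four to one.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .classifier import SvmModel, train_linear_svm
from .emsrcm import chromatic_2grb
from .features import FeatureVector, UnFeaturizableRegion, region_feature_vector
from .illumination import srihe
from .synthetic import STRATA, generate_dataset

__all__ = ["scene_training_features", "train_on_synthetic_scenes"]

NEG_RECT = 12  # side of negative sample rectangles (px)
WEED_SOIL_RATIO = 4  # weed negatives per soil negative


def _rects_inside(
    mask: np.ndarray,
    side: int,
    rng: np.random.Generator,
    k: int,
    saliency: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Top-left corners of up to *k* disjoint side×side rects inside *mask*.

    With a *saliency* map, half the rectangles are taken where the map is
    largest (hard examples near the decision boundary) and half at random;
    otherwise all are random.
    """
    eroded = ndi.minimum_filter(mask.astype(np.uint8), size=side, mode="constant") > 0
    # minimum_filter is centered; shift to top-left corner coordinates
    rows, cols = np.nonzero(eroded)
    if rows.size == 0:
        return []
    half = side // 2
    order = list(rng.permutation(rows.size))
    if saliency is not None:
        smooth = ndi.uniform_filter(np.asarray(saliency, dtype=float), size=side)
        ranked = list(np.argsort(-smooth[rows, cols], kind="stable"))
        # alternate hard (high-saliency) and random candidates
        order = [i for pair in zip(ranked, order) for i in pair]
    taken: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(rows[idx]) - half, int(cols[idx]) - half
        if r < 0 or c < 0 or r + side > mask.shape[0] or c + side > mask.shape[1]:
            continue
        if any(abs(r - tr) < side and abs(c - tc) < side for tr, tc in taken):
            continue
        taken.append((r, c))
        if len(taken) >= k:
            break
    return taken


def scene_training_features(
    n_scenes_per_stratum: int = 2,
    n_samples: int = 200,
    seed: int = 0,
) -> list[FeatureVector]:
    """Balanced labeled feature vectors cropped from compensated scenes.

    Half the samples are positive crowns; negatives mix weed and soil
    rectangles (4:1).  Samples are drawn evenly across the brightness ×
    weed-coverage strata and subsampled reproducibly to *n_samples*.
    """
    rng = np.random.default_rng(seed)
    scenes, _ = generate_dataset(n_scenes_per_stratum, strata=STRATA, seed=seed)

    positives: list[FeatureVector] = []
    weed_negs: list[FeatureVector] = []
    soil_negs: list[FeatureVector] = []
    for _, img, truth in scenes:
        comp = srihe(img)
        for crown in truth.tree_masks:
            try:
                positives.append(
                    region_feature_vector(comp, crown, mode="inner_rect", label="tree")
                )
            except UnFeaturizableRegion:
                continue
        soil_mask = ~truth.tree_mask & ~truth.weed_mask
        # the greenest weed patches sit closest to the crown class; sample
        # half the weed negatives there so the SVM sees the hard boundary
        excess_green = chromatic_2grb(comp)
        for store, mask, k, sal in (
            (weed_negs, truth.weed_mask, 6, excess_green),
            (soil_negs, soil_mask, 3, None),
        ):
            for r, c in _rects_inside(mask, NEG_RECT, rng, k, saliency=sal):
                rect_mask = np.zeros(mask.shape, dtype=bool)
                rect_mask[r : r + NEG_RECT, c : c + NEG_RECT] = True
                store.append(
                    region_feature_vector(comp, rect_mask, mode="full_mask", label="background")
                )

    n_pos = n_samples // 2
    n_soil = max((n_samples - n_pos) // (WEED_SOIL_RATIO + 1), 1)
    n_weed = n_samples - n_pos - n_soil

    def pick(pool: list[FeatureVector], k: int) -> list[FeatureVector]:
        if len(pool) <= k:
            return pool
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    feats = pick(positives, n_pos) + pick(weed_negs, n_weed) + pick(soil_negs, n_soil)
    return feats


def train_on_synthetic_scenes(
    n_scenes_per_stratum: int = 2,
    n_samples: int = 200,
    seed: int = 0,
    c: float = 1.0,
) -> SvmModel:
    """Train the linear SVM on scene-cropped samples (the default trainer)."""
    feats = scene_training_features(
        n_scenes_per_stratum=n_scenes_per_stratum, n_samples=n_samples, seed=seed
    )
    model = train_linear_svm(feats, c=c, seed=seed)
    model.metadata["n_scenes_per_stratum"] = n_scenes_per_stratum
    return model
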