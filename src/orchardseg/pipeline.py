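"""End-to-end segmentation: pre-processing, extraction switch, SVM filter.

The flow is: selective illumination compensation (SRIHE) → chromatic
extraction with the relative G−R map (ERGCM) → under-extraction check
(UEJR) → if flagged, retinex re-extraction (EMSRCM) → per-region
feature vectors → linear-SVM confirmation that drops background-scored
regions.  Every run records provenance: which backend produced the final
regions and every threshold used.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ergcm as _ergcm
from . import emsrcm as _emsrcm
from .classifier import SvmModel, classify_regions
from .features import UnFeaturizableRegion, region_feature_vector
from .illumination import classify_brightness, green_selection_mask, srihe
from .imaging import RegionSet, label_regions, rgb_to_hsi, validate_rgb
from .synthetic import classify_wcc_fraction

__all__ = ["PipelineConfig", "SegmentationResult", "segment_image", "classify_conditions"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable knobs of the segmentation pipeline.

    Defaults are sized for full-resolution UAV frames where crowns span
    hundreds of pixels; spatial parameters (morphology radii, MSR sigmas)
    should be scaled proportionally for smaller imagery.
    """

    green_hue_range: tuple[float, float] = (float(np.pi / 2), float(np.pi))
    he_bins: int | None = None  # None = exact empirical-CDF equalization
    min_area_frac: float = 0.0005
    ergcm_disk_radius: int = 5
    msr_sigmas: tuple[float, float, float] = (15.0, 80.0, 250.0)
    closing_radius: int = 20
    tophat_radius: int = 24
    opening_radius: int = 20
    uejr_t_a: float = 45.0
    uejr_t_n: int = 20
    svm_c: float = 1.0
    match_iou: float = 0.5
    seed: int = 0

    @classmethod
    def for_synthetic_scenes(cls, **overrides) -> "PipelineConfig":
        """Spatial parameters scaled to the synthetic scenes (~9 px crowns).

        The full-scale radii and retinex scales target frames where a
        crown spans hundreds of pixels.  At the synthetic scale the
        edge-smoothing closing shrinks to 1 px, the top-hat disk matches
        the typical crown radius (10 px), the opening erases weed-scale
        bright grains but spares the smallest crowns (5 px), and the
        retinex surround triple becomes (2, 10, 30) px.
        """
        defaults = dict(
            ergcm_disk_radius=3,
            msr_sigmas=(2.0, 10.0, 30.0),
            closing_radius=1,
            tophat_radius=10,
            opening_radius=5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def msr_params(self) -> _emsrcm.MsrParams:
        return _emsrcm.MsrParams(sigmas=tuple(self.msr_sigmas))

    def uejr_thresholds(self) -> _emsrcm.UejrThresholds:
        return _emsrcm.UejrThresholds(t_a=self.uejr_t_a, t_n=self.uejr_t_n)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["green_hue_range"] = list(self.green_hue_range)
        d["msr_sigmas"] = list(self.msr_sigmas)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("green_hue_range", "msr_sigmas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SegmentationResult:
    """Final regions with per-region labels/scores and run provenance."""

    regions: RegionSet  # regions surviving the SVM filter (or all, if disabled)
    candidate_regions: RegionSet  # regions from the extraction backend
    labels: list[str]  # per candidate region
    scores: np.ndarray  # per candidate region, signed SVM decision score
    provenance: dict

    @property
    def tree_mask(self) -> np.ndarray:
        return self.regions.mask


def segment_image(
    img: np.ndarray,
    model: SvmModel | None,
    cfg: PipelineConfig = PipelineConfig(),
    use_svm: bool = True,
) -> SegmentationResult:
    """Segment tree crowns in one image.

    With ``use_svm=False`` (or ``model=None``) every extracted candidate
    region passes unfiltered — the ablation the evaluation module
    compares against.  Un-featurizable regions (texture window below 3×3)
    are logged and treated as background.
    """
    arr = validate_rgb(img)
    compensated = srihe(arr, hue_range=cfg.green_hue_range, bins=cfg.he_bins)

    prelim = _ergcm.extract_rois_ergcm(
        compensated, min_area_frac=cfg.min_area_frac, disk_radius=cfg.ergcm_disk_radius
    )
    under = _emsrcm.uejr_is_under_extracted(prelim, cfg.uejr_thresholds())
    if under:
        # the retinex stage is itself an (exact) multiplicative-illumination
        # normalizer, so re-extraction starts from the original image: a
        # second brightness compensation is redundant and the equalization
        # distorts the chromatic contrast the 2G-R-B index relies on
        candidates = _emsrcm.extract_rois_emsrcm(
            arr,
            params=cfg.msr_params(),
            closing_radius=cfg.closing_radius,
            tophat_radius=cfg.tophat_radius,
            opening_radius=cfg.opening_radius,
            min_area_frac=cfg.min_area_frac,
        )
        backend = "EMSRCM"
    else:
        candidates = prelim
        backend = "ERGCM"

    provenance = {
        "backend": backend,
        "uejr_fired": bool(under),
        "prelim_area_ratio": prelim.area_ratio,
        "prelim_count": prelim.count,
        "uejr_t_a": cfg.uejr_t_a,
        "uejr_t_n": cfg.uejr_t_n,
        "svm_used": bool(use_svm and model is not None),
        "config": cfg.to_dict(),
        "dropped_unfeaturizable": [],
    }

    if not (use_svm and model is not None):
        return SegmentationResult(
            regions=candidates,
            candidate_regions=candidates,
            labels=["tree"] * candidates.count,
            scores=np.full(candidates.count, np.nan),
            provenance=provenance,
        )

    feats = []
    keepable = []
    for region in candidates.regions:
        rmask = candidates.region_mask(region.label)
        try:
            feats.append(region_feature_vector(compensated, rmask, mode="inner_rect"))
            keepable.append(region.label)
        except UnFeaturizableRegion as exc:
            logger.info("region %d dropped: %s", region.label, exc)
            provenance["dropped_unfeaturizable"].append(region.label)

    labels_by_region = {lab: "background" for lab in (r.label for r in candidates.regions)}
    scores_by_region = {lab: float("nan") for lab in labels_by_region}
    if feats:
        pred_labels, pred_scores = classify_regions(model, feats)
        for lab, pl, sc in zip(keepable, pred_labels, pred_scores):
            labels_by_region[lab] = pl
            scores_by_region[lab] = float(sc)

    keep = {lab for lab, pl in labels_by_region.items() if pl == "tree"}
    final_mask = np.isin(candidates.label_map, sorted(keep)) if keep else np.zeros(
        candidates.label_map.shape, dtype=bool
    )
    final = label_regions(final_mask)
    return SegmentationResult(
        regions=final,
        candidate_regions=candidates,
        labels=[labels_by_region[r.label] for r in candidates.regions],
        scores=np.array([scores_by_region[r.label] for r in candidates.regions]),
        provenance=provenance,
    )


def classify_conditions(img: np.ndarray) -> tuple[str, str]:
    """Brightness (IB/SB) and weed-coverage (SWCR/MWCR/LWCR) conditions.

    The green-area fraction A is the green-hue pixel fraction; cutoffs
    are A < 35% SWCR, 35% ≤ A < 60% MWCR, A ≥ 60% LWCR.
    """
    arr = validate_rgb(img)
    hsi = rgb_to_hsi(arr)
    a_fraction = float(green_selection_mask(hsi).mean())
    return classify_brightness(arr), classify_wcc_fraction(a_fraction)
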