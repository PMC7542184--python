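"""Areas, percentages, and the two cellularity equations.

Two denominators coexist in marrow histomorphometry. The pathologists'
convention relates the hematopoietic area to the hematopoietic-plus-
adipocytic area only (Eq. 1), while the compartment percentages use the
total marrow area Ma.Ar (Eq. 2):

    cellularity (Eq. 1)      = H / (H + A)
    % hematopoietic (Eq. 2)  = 100 · H / Ma.Ar

Since H + A ≤ Ma.Ar, Eq. 2 never exceeds Eq. 1 (×100). Undefined ratios
(zero denominators) propagate as NA, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adipocytes import AdipocyteGhost, SizeHistogram, size_distribution
from .config import AnalysisConfig
from .io_formats import RegionMasks
from .segmentation import CompartmentLabelMap, Label


class InconsistentResultError(RuntimeError):
    """Internal consistency violation between ghost list and label map."""


@dataclass
class QuantResult:
    """All reported quantities for one image (areas in μm²)."""

    image: str = ""
    mode: str = "marrow"
    tissue_area: float = 0.0
    artifact_area: float = 0.0
    bone_area: float = 0.0
    marrow_area: float = 0.0
    hematopoietic_area: float = 0.0
    adipocyte_area: float = 0.0
    interstitium_area: float = 0.0
    undetected_area: float = 0.0
    cellularity_eq1: float | None = None
    pct_hematopoietic: float | None = None
    pct_adiposity: float | None = None
    pct_interstitium: float | None = None
    pct_undetected: float | None = None
    pct_bone_of_tissue: float | None = None  # user-interpretable (ROI-dependent)
    adipocyte_count: int = 0
    mean_adipocyte_area: float | None = None
    histogram: SizeHistogram | None = None
    pixel_counts: dict = field(default_factory=dict)


def areas(labels: CompartmentLabelMap,
          region_masks: RegionMasks | None = None) -> dict[str, float]:
    """Per-compartment areas (μm²) plus raw pixel counts.

    The excluded area splits into outside-tissue versus artifact when region
    masks are available.
    """
    ps2 = labels.pixel_size ** 2
    counts = labels.counts()
    out = {
        "bone_area": counts[Label.BONE] * ps2,
        "hematopoietic_area": counts[Label.HEMATO] * ps2,
        "adipocyte_area": counts[Label.ADIPO] * ps2,
        "interstitium_area": counts[Label.INTERSTITIUM] * ps2,
        "undetected_area": counts[Label.UNDETECTED] * ps2,
        "marrow_area": (counts[Label.HEMATO] + counts[Label.ADIPO]
                        + counts[Label.INTERSTITIUM] + counts[Label.UNDETECTED]) * ps2,
        "pixel_counts": {lab.name: n for lab, n in counts.items()},
    }
    if region_masks is not None:
        tissue_px = int(region_masks.tissue_mask.sum())
        artifact_px = int((region_masks.artifact_mask & region_masks.tissue_mask).sum())
        out["tissue_area"] = tissue_px * ps2
        out["artifact_area"] = artifact_px * ps2
        out["pixel_counts"]["TISSUE"] = tissue_px
        out["pixel_counts"]["ARTIFACT"] = artifact_px
    return out


def cellularity_eq1(hematopoietic_area: float, adipocyte_area: float) -> float | None:
    """H / (H + A); NA (None) when the denominator is zero."""
    denom = hematopoietic_area + adipocyte_area
    if denom <= 0:
        return None
    return hematopoietic_area / denom


def pct_of_marrow(compartment_area: float, marrow_area: float) -> float | None:
    """100 · compartment / Ma.Ar; NA (None) when Ma.Ar is zero."""
    if marrow_area <= 0:
        return None
    return 100.0 * compartment_area / marrow_area


def summarize(labels: CompartmentLabelMap, ghosts: list[AdipocyteGhost],
              region_masks: RegionMasks | None, cfg: AnalysisConfig,
              image_name: str = "") -> QuantResult:
    """Aggregate a composed label map and measured ghosts into a QuantResult.

    Verifies the pixel identity between the retained ghosts and the ADIPO
    compartment: the two are produced by the same pipeline and any
    discrepancy indicates an internal error.
    """
    a = areas(labels, region_masks)
    retained = [g for g in ghosts if g.retained]
    retained_px = sum(g.pixel_count for g in retained)
    adipo_px = a["pixel_counts"]["ADIPO"]
    if retained_px != adipo_px:
        raise InconsistentResultError(
            f"retained ghost pixels ({retained_px}) != ADIPO compartment pixels "
            f"({adipo_px})"
        )
    ma = a["marrow_area"]
    count = len(retained)
    hist = size_distribution(retained, cfg.bin_width, upper=cfg.max_adipocyte_area)
    tissue_area = a.get("tissue_area", 0.0)
    return QuantResult(
        image=image_name,
        mode=cfg.mode,
        tissue_area=tissue_area,
        artifact_area=a.get("artifact_area", 0.0),
        bone_area=a["bone_area"],
        marrow_area=ma,
        hematopoietic_area=a["hematopoietic_area"],
        adipocyte_area=a["adipocyte_area"],
        interstitium_area=a["interstitium_area"],
        undetected_area=a["undetected_area"],
        cellularity_eq1=cellularity_eq1(a["hematopoietic_area"], a["adipocyte_area"]),
        pct_hematopoietic=pct_of_marrow(a["hematopoietic_area"], ma),
        pct_adiposity=pct_of_marrow(a["adipocyte_area"], ma),
        pct_interstitium=pct_of_marrow(a["interstitium_area"], ma),
        pct_undetected=pct_of_marrow(a["undetected_area"], ma),
        pct_bone_of_tissue=(100.0 * a["bone_area"] / tissue_area
                            if tissue_area > 0 else None),
        adipocyte_count=count,
        mean_adipocyte_area=(sum(g.area for g in retained) / count if count else None),
        histogram=hist,
        pixel_counts=a["pixel_counts"],
    )
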