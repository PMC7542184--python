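"""Compartment segmentation of the analysis region.

Inside the user-defined tissue boundaries (minus artifacts) five mutually
exclusive compartments are produced, in fixed priority order:

    BONE > HEMATO > ADIPO > INTERSTITIUM > UNDETECTED

Bone is identified first (eosin-dense, texturally flat matrix); subtracting
its dilation from the analysis region yields the total marrow area (Ma.Ar).
Nucleated cells form the hematopoietic mask; near-background "void" pixels
are adipocyte-ghost candidates (fragmented and filtered downstream); the
remaining eosinophilic signal (RBCs plus serous infiltrate) is
interstitium/microvasculature; anything left in Ma.Ar is the undetected
area, so the four marrow compartments always sum exactly to Ma.Ar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .config import AnalysisConfig, require_pixel_size

logger = logging.getLogger("marrowquant")


class Label(IntEnum):
    EXCLUDED = 0
    BONE = 1
    HEMATO = 2
    ADIPO = 3
    INTERSTITIUM = 4
    UNDETECTED = 5


# Operator constants (OD units and μm); exposed here rather than in the user
# config because they parameterize the segmentation operators themselves.
BONE_HEMA_MAX_OD = 0.20          # bone matrix carries little hematoxylin
BONE_TEXTURE_WINDOW_UM = 5.0     # local-variance window (nuclear scale)
BONE_TEXTURE_MAX_OD = 0.06       # max local std of smoothed eosin over bone
MORPH_CLOSING_RADIUS_UM = 2.0
#: the texture criterion is undefined within half a window of the matrix
#: boundary; confirmed bone is re-grown this far into intensity-qualified rim
BONE_RIM_RECLAIM_UM = BONE_TEXTURE_WINDOW_UM / 2 + 1.5
MIN_NUCLEUS_AREA_UM2 = 10.0
GHOST_OPENING_RADIUS_UM = 1.0
INTERSTITIUM_EOSIN_FLOOR_OD = 0.08
#: ghost "void" pixels are near background by definition; when the marrow
#: carries several stained populations Otsu can split between them instead,
#: so the void threshold is capped just above the interstitium floor
VOID_MAX_OD = 0.12
DEGENERATE_OD_RANGE = 0.05       # below this spread a threshold is meaningless


def disk_selem(radius_um: float, pixel_size: float) -> np.ndarray | None:
    """Disk structuring element; radii in μm, rounded to ≥ 1 px (0 → None)."""
    if radius_um <= 0:
        return None
    return morphology.disk(max(1, round(radius_um / pixel_size)))


def _sigma_px(cfg: AnalysisConfig) -> float:
    return cfg.smoothing_sigma / require_pixel_size(cfg)


def _smooth(arr: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    return ndi.gaussian_filter(arr, sigma=_sigma_px(cfg))


def _otsu(values: np.ndarray) -> float | None:
    """Otsu threshold over the given values; None when degenerate."""
    if values.size < 2:
        return None
    if float(values.max() - values.min()) < DEGENERATE_OD_RANGE:
        return None
    return float(filters.threshold_otsu(values))


def _fill_small_holes(mask: np.ndarray, max_px: int) -> np.ndarray:
    """Fill enclosed holes below *max_px* (a cortical ring must not have its
    entire marrow cavity 'filled' as if it were matrix porosity)."""
    holes = ndi.binary_fill_holes(mask) & ~mask
    if not holes.any():
        return mask
    lab, n = ndi.label(holes)
    sizes = np.bincount(lab.ravel())
    small = np.zeros(n + 1, bool)
    small[1:] = sizes[1:] <= max_px
    return mask | small[lab]


def _local_std(arr: np.ndarray, window_px: int) -> np.ndarray:
    size = max(3, window_px | 1)  # odd window
    mean = ndi.uniform_filter(arr, size)
    sq = ndi.uniform_filter(arr * arr, size)
    return np.sqrt(np.clip(sq - mean * mean, 0.0, None))


@dataclass
class CompartmentLabelMap:
    """Per-pixel compartment labels over the full image frame."""

    labels: np.ndarray  # int8, values from Label
    pixel_size: float

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    def counts(self) -> dict[Label, int]:
        flat = np.bincount(self.labels.ravel(), minlength=6)
        return {lab: int(flat[int(lab)]) for lab in Label}

    @property
    def marrow_mask(self) -> np.ndarray:
        return (self.labels >= int(Label.HEMATO)) & (self.labels <= int(Label.UNDETECTED))


# ---------------------------------------------------------------------------

def segment_bone(stains, analysis_mask: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Cortical + trabecular bone: eosin-dense, hematoxylin-poor, flat texture.

    The eosin map is smoothed and Otsu-thresholded within the analysis
    region; pixels must also be hematoxylin-poor and texturally flat at
    nuclear scale (local std of smoothed eosin), which separates bone matrix
    from the equally eosin-bright but speckled RBC lakes. Morphological
    closing, hole filling and a minimum object size finish the mask; a final
    guarded dilation reclaims boundary pixels the texture criterion eroded.
    An empty mask is valid (e.g. trephine-like inputs).
    """
    ps = require_pixel_size(cfg)
    eosin = _smooth(stains.eosin, cfg)
    hema = _smooth(stains.hema, cfg)

    if cfg.threshold_method == "fixed" and cfg.fixed_od_thresholds:
        thr = cfg.fixed_od_thresholds.get("eosin")
    else:
        thr = _otsu(eosin[analysis_mask]) if analysis_mask.any() else None
    if thr is None:
        return np.zeros_like(analysis_mask)

    eosin_dense = (eosin >= thr) & (hema < BONE_HEMA_MAX_OD) & analysis_mask
    flat = _local_std(eosin, round(BONE_TEXTURE_WINDOW_UM / ps)) <= BONE_TEXTURE_MAX_OD
    bone = eosin_dense & flat

    closing = disk_selem(MORPH_CLOSING_RADIUS_UM, ps)
    bone = morphology.closing(bone, closing) & analysis_mask
    max_hole_px = int(round(4 * cfg.min_bone_object_area / ps**2))
    bone = _fill_small_holes(bone, max_hole_px)
    min_px = int(round(cfg.min_bone_object_area / ps**2))
    if min_px > 1:
        bone = morphology.remove_small_objects(bone, max_size=min_px - 1)
    # texture is undefined across the matrix boundary; reclaim the rim that
    # passes the intensity tests and touches confirmed bone
    rim = morphology.dilation(bone, disk_selem(BONE_RIM_RECLAIM_UM, ps)) & eosin_dense
    bone = _fill_small_holes(bone | rim, max_hole_px) & analysis_mask
    return bone


def marrow_mask(analysis_mask: np.ndarray, bone_mask: np.ndarray,
                cfg: AnalysisConfig) -> np.ndarray:
    """Total marrow area: analysis region minus the dilated bone mask.

    The dilation ring (endosteal lining suppression) is excluded from all
    marrow compartments and from Ma.Ar itself.
    """
    ps = require_pixel_size(cfg)
    selem = disk_selem(cfg.bone_dilation_radius, ps)
    dilated = morphology.dilation(bone_mask, selem) if selem is not None else bone_mask
    return analysis_mask & ~dilated


def segment_hematopoietic(stains, ma_mask: np.ndarray, cfg: AnalysisConfig) -> np.ndarray:
    """Nucleated-cell mask within the marrow area.

    The hematoxylin map is smoothed and Otsu-thresholded within Ma.Ar;
    detections are closed (2 μm) so densely packed nuclei merge into a
    contiguous cellularity mask, and sub-nuclear specks (< 10 μm²) are
    dropped. A degenerate (near-constant) hematoxylin channel yields an
    empty mask with a warning.
    """
    ps = require_pixel_size(cfg)
    hema = _smooth(stains.hema, cfg)
    if cfg.threshold_method == "fixed" and cfg.fixed_od_thresholds:
        thr = cfg.fixed_od_thresholds.get("hema")
    else:
        thr = _otsu(hema[ma_mask]) if ma_mask.any() else None
    if thr is None:
        logger.warning("degenerate hematoxylin channel: empty hematopoietic mask")
        return np.zeros_like(ma_mask)
    mask = (hema >= thr) & ma_mask
    mask = morphology.closing(mask, disk_selem(MORPH_CLOSING_RADIUS_UM, ps)) & ma_mask
    min_px = int(round(MIN_NUCLEUS_AREA_UM2 / ps**2))
    if min_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    return mask


def candidate_ghost_mask(stains, ma_mask: np.ndarray, hemato_mask: np.ndarray,
                         cfg: AnalysisConfig) -> np.ndarray:
    """Near-background "void" pixels: adipocyte-ghost candidates.

    Within Ma ∖ hemato, pixels whose total chromatic density (hematoxylin +
    eosin) falls below an Otsu threshold computed on that same region are
    candidate ghost interiors. Holes are filled and a light (1 μm) opening
    detaches membrane remnants. When the region is monochrome the mean
    decides: an all-void region is all candidates, an all-stained region
    (e.g. fully hemorrhagic marrow) has none.
    """
    ps = require_pixel_size(cfg)
    region = ma_mask & ~hemato_mask
    if not region.any():
        return np.zeros_like(ma_mask)
    total = stains.total
    if cfg.threshold_method == "fixed" and cfg.fixed_od_thresholds:
        thr = cfg.fixed_od_thresholds.get("void")
    else:
        thr = _otsu(total[region])
        if thr is not None:
            thr = min(thr, VOID_MAX_OD)
    if thr is None:
        mean = float(total[region].mean())
        if mean < 2 * INTERSTITIUM_EOSIN_FLOOR_OD:
            return region.copy()
        return np.zeros_like(ma_mask)
    candidates = (total <= thr) & region
    candidates = ndi.binary_fill_holes(candidates) & region
    opening = disk_selem(GHOST_OPENING_RADIUS_UM, ps)
    candidates = morphology.opening(candidates, opening) & region
    return candidates


def segment_interstitium(stains, remaining_mask: np.ndarray,
                         cfg: AnalysisConfig,
                         eosin_floor: float = INTERSTITIUM_EOSIN_FLOOR_OD) -> np.ndarray:
    """Eosinophilic remainder: RBC lakes and pale serous infiltrate.

    Any remaining pixel with eosin OD at or above a low fixed floor is
    interstitium/microvasculature; pixels at background white stay
    unattributed.
    """
    eosin = _smooth(stains.eosin, cfg)
    return (eosin >= eosin_floor) & remaining_mask


def compose(analysis_mask: np.ndarray, bone: np.ndarray, hemato: np.ndarray,
            ghosts: np.ndarray, interstitium: np.ndarray,
            cfg: AnalysisConfig, marrow: np.ndarray | None = None) -> CompartmentLabelMap:
    """Assemble the label map under the fixed priority order.

    ``ghosts`` is the retained adipocyte mask. Pixels outside the analysis
    region — and inside the bone dilation ring — are EXCLUDED; marrow pixels
    claimed by nothing are UNDETECTED. Rejected ghost candidates are
    expected to have been routed by the caller through the interstitium
    test (eosin floor), so they revert there or to UNDETECTED naturally.
    """
    shapes = {analysis_mask.shape, bone.shape, hemato.shape, ghosts.shape,
              interstitium.shape}
    if len(shapes) != 1:
        raise ValueError(f"mask dimension mismatch: {sorted(shapes)}")
    if marrow is None:
        marrow = marrow_mask(analysis_mask, bone, cfg)
    labels = np.zeros(analysis_mask.shape, dtype=np.int8)
    labels[marrow] = int(Label.UNDETECTED)
    labels[interstitium & marrow] = int(Label.INTERSTITIUM)
    labels[ghosts & marrow] = int(Label.ADIPO)
    labels[hemato & marrow] = int(Label.HEMATO)
    labels[bone & analysis_mask] = int(Label.BONE)
    return CompartmentLabelMap(labels=labels, pixel_size=require_pixel_size(cfg))
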