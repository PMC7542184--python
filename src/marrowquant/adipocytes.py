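"""Adipocyte-ghost fragmentation, morphometry, filtering and binning.

Delipidated adipocytes appear as white voids bounded by thin eosinophilic
membranes. The candidate void mask is fragmented into individual ghosts by
a marker-controlled watershed on the inverted Euclidean distance transform,
with the eosin (membrane) signal added to the flooding surface so
fragmentation lines prefer stained membranes. Ghosts are then measured
(area, perimeter, circularity) and filtered by the configured size /
circularity / edge rules; retained ghosts define the adiposity compartment
and the size distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg

from .config import AnalysisConfig, require_pixel_size

logger = logging.getLogger("marrowquant")

#: depth (μm) of h-maxima suppression on the distance transform; prevents
#: over-seeding of slightly lumpy ghosts. Advanced parameter.
H_MAXIMA_DEPTH_UM = 1.5
#: weight (μm per OD unit) of the membrane signal on the watershed surface.
MEMBRANE_WEIGHT_UM_PER_OD = 4.0

REJECTION_REASONS = ("too_small", "too_large", "low_circularity", "edge")


@dataclass
class AdipocyteGhost:
    """One fragmented ghost with its morphometry and filtering outcome."""

    id: int
    area: float              # μm²
    perimeter: float         # μm
    circularity: float       # 4πA/P², clamped to [0, 1]
    centroid: tuple[float, float]  # (x, y) pixels
    edge_touching: bool
    pixel_count: int
    retained: bool = True
    rejection_reason: str | None = None


# ---------------------------------------------------------------------------
# fragmentation

def fragment_ghosts(candidates: np.ndarray, membrane_signal: np.ndarray,
                    cfg: AnalysisConfig,
                    h_depth_um: float = H_MAXIMA_DEPTH_UM,
                    membrane_weight: float = MEMBRANE_WEIGHT_UM_PER_OD) -> np.ndarray:
    """Split the candidate void mask into individually labeled ghosts.

    Seeds are the h-maxima of the Euclidean distance transform (depth
    *h_depth_um*); the flooding surface is the inverted distance transform
    plus the smoothed membrane signal scaled by *membrane_weight*, so ridges
    of eosin attract the fragmentation lines. Candidate components whose
    relief is too shallow to seed keep their own label, so the output labels
    always partition the candidate mask. Fully deterministic.
    """
    candidates = np.asarray(candidates, bool)
    if not candidates.any():
        return np.zeros(candidates.shape, dtype=np.int32)
    ps = require_pixel_size(cfg)
    edt = ndi.distance_transform_edt(candidates) * ps
    peaks = morphology.h_maxima(edt, h_depth_um)
    markers, _ = ndi.label(peaks)
    sigma = cfg.smoothing_sigma / ps
    surface = -edt + membrane_weight * ndi.gaussian_filter(membrane_signal, sigma)
    labels = skseg.watershed(surface, markers=markers, mask=candidates).astype(np.int32)
    orphan = candidates & (labels == 0)
    if orphan.any():  # components with no surviving maximum
        extra, n = ndi.label(orphan)
        labels[orphan] = extra[orphan] + labels.max()
    return labels


# ---------------------------------------------------------------------------
# morphometry

def _contour_perimeter(mask: np.ndarray, smoothing_px: float = 1.0) -> float:
    """Sub-pixel perimeter: marching-squares contour of the smoothed mask."""
    padded = np.pad(mask.astype(float), 4)
    smoothed = ndi.gaussian_filter(padded, smoothing_px)
    total = 0.0
    for contour in measure.find_contours(smoothed, 0.5):
        deltas = np.diff(contour, axis=0)
        total += float(np.sqrt((deltas**2).sum(axis=1)).sum())
    return total


def estimate_perimeter(mask: np.ndarray, pixel_size: float) -> float:
    """Perimeter in μm.

    The smoothed-contour estimate is accurate for compact shapes but can
    vanish on sub-resolution ones (1-px lines, specks); the Crofton estimate
    serves as a lower-bound guard there. The larger of the two is returned,
    which biases circularity conservatively downward.
    """
    contour = _contour_perimeter(mask)
    crofton = float(measure.perimeter_crofton(mask, directions=4))
    return max(contour, crofton) * pixel_size


def circularity_of(area_um2: float, perimeter_um: float) -> float:
    """4πA/P² clamped to [0, 1]; 1 for a perfect disk. 0 when degenerate."""
    if perimeter_um <= 0:
        return 0.0
    return float(np.clip(4.0 * np.pi * area_um2 / perimeter_um**2, 0.0, 1.0))


def _edge_proximity(analysis_mask: np.ndarray) -> np.ndarray:
    """Pixels 4-adjacent to an excluded pixel or the image border."""
    padded = np.pad(analysis_mask, 1, constant_values=False)
    outside = ~padded
    near = ndi.binary_dilation(outside, structure=ndi.generate_binary_structure(2, 1))
    return near[1:-1, 1:-1]


def measure_ghost(region_mask: np.ndarray, pixel_size: float,
                  ghost_id: int = 1, analysis_mask: np.ndarray | None = None) -> AdipocyteGhost:
    """Morphometry of a single ghost component."""
    region_mask = np.asarray(region_mask, bool)
    count = int(region_mask.sum())
    if count == 0:
        raise ValueError("empty ghost component")
    area = count * pixel_size**2
    perimeter = estimate_perimeter(region_mask, pixel_size)
    rows, cols = np.nonzero(region_mask)
    centroid = (float(cols.mean()), float(rows.mean()))
    if analysis_mask is None:
        analysis_mask = np.ones(region_mask.shape, bool)
    edge = bool((region_mask & _edge_proximity(analysis_mask)).any())
    return AdipocyteGhost(
        id=ghost_id, area=area, perimeter=perimeter,
        circularity=circularity_of(area, perimeter),
        centroid=centroid, edge_touching=edge, pixel_count=count,
    )


def measure_ghosts(label_map: np.ndarray, pixel_size: float,
                   analysis_mask: np.ndarray | None = None) -> list[AdipocyteGhost]:
    """Measure every labeled ghost in scan-order of label ids."""
    label_map = np.asarray(label_map)
    if analysis_mask is None:
        analysis_mask = np.ones(label_map.shape, bool)
    near_edge = _edge_proximity(analysis_mask)
    ghosts = []
    for region in measure.regionprops(label_map):
        sl = region.slice
        sub = label_map[sl] == region.label
        count = int(region.area)
        area = count * pixel_size**2
        perimeter = estimate_perimeter(sub, pixel_size)
        r0, c0 = region.centroid
        edge = bool((sub & near_edge[sl]).any())
        ghosts.append(AdipocyteGhost(
            id=int(region.label), area=area, perimeter=perimeter,
            circularity=circularity_of(area, perimeter),
            centroid=(float(c0), float(r0)), edge_touching=edge,
            pixel_count=count,
        ))
    return ghosts


# ---------------------------------------------------------------------------
# filtering and binning

def filter_ghosts(ghosts: list[AdipocyteGhost], cfg: AnalysisConfig
                  ) -> tuple[list[AdipocyteGhost], list[AdipocyteGhost]]:
    """Apply the size / circularity / edge retention rules (bounds inclusive).

    The rejection reason records the first failed test, in the order
    size-low, size-high, circularity, edge.
    """
    retained, rejected = [], []
    for g in ghosts:
        reason = None
        if g.area < cfg.min_adipocyte_area:
            reason = "too_small"
        elif g.area > cfg.max_adipocyte_area:
            reason = "too_large"
        elif g.circularity < cfg.min_circularity:
            reason = "low_circularity"
        elif cfg.exclude_edges and g.edge_touching:
            reason = "edge"
        g.retained = reason is None
        g.rejection_reason = reason
        (retained if g.retained else rejected).append(g)
    return retained, rejected


def retained_mask(label_map: np.ndarray, ghosts: list[AdipocyteGhost]) -> np.ndarray:
    """Boolean mask of pixels belonging to retained ghosts."""
    ids = [g.id for g in ghosts if g.retained]
    if not ids:
        return np.zeros(label_map.shape, bool)
    return np.isin(label_map, ids)


@dataclass
class SizeHistogram:
    """Half-open bins [k·w, (k+1)·w) of retained-ghost areas (μm²)."""

    bin_width: float
    edges: np.ndarray     # len nbins+1
    counts: np.ndarray    # int, len nbins
    frequencies: np.ndarray  # counts / total (zeros when empty)


def size_distribution(ghosts, bin_width: float, upper: float | None = None) -> SizeHistogram:
    """Bin retained ghost areas; counts always sum to the input count.

    Areas at or above *upper* land in the last bin (they have already passed
    the maximum-size filter, so this only guards the exact boundary).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    areas = np.asarray([
        g.area if hasattr(g, "area") else float(g)
        for g in ghosts
        if not hasattr(g, "retained") or g.retained
    ], dtype=float)
    if upper is None:
        upper = float(areas.max()) + bin_width if areas.size else bin_width
    nbins = max(1, int(np.ceil(upper / bin_width)))
    edges = np.arange(nbins + 1) * bin_width
    counts = np.zeros(nbins, dtype=int)
    if areas.size:
        idx = np.clip(np.floor(areas / bin_width).astype(int), 0, nbins - 1)
        counts = np.bincount(idx, minlength=nbins)
    total = counts.sum()
    freqs = counts / total if total else np.zeros(nbins)
    return SizeHistogram(bin_width=float(bin_width), edges=edges,
                         counts=counts, frequencies=freqs)
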