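"""Forward-rendered H&E-like sections with pixel-level ground truth.

Two builders make the rest of the package testable without any slide scans:

``generate_marrow_section``
    A whole-bone-like section: cortical ring and trabeculae (eosin-dense,
    texturally flat), a packed nucleated-cell territory, non-overlapping
    adipocyte ghosts (white interiors wrapped in thin eosinophilic
    membranes, optionally with one rim nucleus), RBC lakes and a serous
    wash, plus thin empty strips that remain unattributed. Target
    compartment fractions of the marrow area are enforced by construction
    plus rejection resampling (±3 points).

``generate_adipose_sheet``
    An extramedullary white-adipose sheet: a Voronoi-like tiling of ghosts
    sharing membrane walls, sparse stromal nuclei, surrounded by an
    eosinophilic stroma margin. A configurable fraction of walls can be
    given central gaps (membrane erasure) to stress hypo/hyper-fragmentation.

Rendering composes per-pixel stain concentrations and inverts Beer–Lambert:
``I_c = white_c · 10^(−OD_c)`` with optional additive Gaussian intensity
noise. All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import morphology

from .io_formats import (ARTIFACT, BACKGROUND, TISSUE, AnnotationPolygon,
                         AnnotationSet, CalibratedImage)
from .segmentation import Label
from .stain import StainVectors


logger = logging.getLogger("marrowquant")


class SyntheticError(RuntimeError):
    pass


# Rendered stain concentrations (OD units along the respective stain vector)
BONE_EOSIN, BONE_HEMA = 0.75, 0.05
MEMBRANE_EOSIN = 0.50
SEROUS_EOSIN = 0.20
RBC_PLASMA_EOSIN, RBC_CORE_EOSIN = 0.30, 0.65
NUCLEUS_HEMA, NUCLEUS_EOSIN = 0.90, 0.05
CYTOPLASM_EOSIN, CYTOPLASM_HEMA = 0.15, 0.05
STROMA_EOSIN = 0.25
RIM_NUCLEUS_RADIUS_UM = 2.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic section (all lengths μm)."""

    dims: tuple[int, int] = (384, 384)
    pixel_size: float = 1.0
    # marrow compartment targets, as fractions of the marrow area Ma.Ar;
    # interstitium defaults to the remainder
    frac_hemato: float = 0.50
    frac_adipo: float = 0.20
    frac_undetected: float = 0.05
    frac_interstitium: float | None = None
    cortical_ring: bool = True
    ring_thickness_um: float = 22.0
    trabecula_count: int = 3
    ghost_radius_mean_um: float = 13.0
    ghost_radius_sigma: float = 0.18      # lognormal sigma of ln(radius)
    nucleus_radius_um: float = 3.0
    nucleus_spacing_um: float = 6.0   # near-confluent, as in mouse marrow
    membrane_thickness_um: float = 1.5
    rim_nucleus_prob: float = 0.5
    noise_sd: float = 3.0                 # additive Gaussian, intensity units
    white_reference: tuple[float, float, float] = (242.0, 240.0, 244.0)
    seed: int = 0
    # adipose-sheet parameters
    ghost_count: int = 200
    membrane_gap_fraction: float = 0.0    # fraction of walls given central gaps
    sheet_margin_um: float = 24.0

    def __post_init__(self):
        fr = [self.frac_hemato, self.frac_adipo, self.frac_undetected]
        if self.frac_interstitium is not None:
            fr.append(self.frac_interstitium)
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise SyntheticError("compartment fractions must be ≥ 0 and sum ≤ 1")

    @property
    def interstitium_target(self) -> float:
        if self.frac_interstitium is not None:
            return self.frac_interstitium
        return 1.0 - self.frac_hemato - self.frac_adipo - self.frac_undetected


@dataclass
class GroundTruth:
    """Pixel-level truth for one rendered section."""

    labels: np.ndarray            # int8, same alphabet as CompartmentLabelMap
    ghost_labels: np.ndarray      # int32, one positive id per true ghost
    ghost_table: pd.DataFrame     # id, area_um2, centroid_x, centroid_y
    realized_fractions: dict[str, float]
    pixel_size: float

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)


# ---------------------------------------------------------------------------
# forward rendering

def forward_stain_render(hema: np.ndarray, eosin: np.ndarray,
                         vectors: StainVectors | None = None,
                         white=(242.0, 240.0, 244.0),
                         noise_sd: float = 0.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Render concentration maps to 8-bit RGB via I = white·10^(−M·c)."""
    vectors = vectors or StainVectors.h_and_e()
    od = (np.asarray(hema, float)[..., None] * vectors.hematoxylin
          + np.asarray(eosin, float)[..., None] * vectors.eosin)
    intensity = np.asarray(white, float) * 10.0 ** (-od)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# placement helpers

def _disk_patch(yc: float, xc: float, radius: float, shape: tuple[int, int]):
    """Boolean disk patch and its slice, or None when it crosses the frame."""
    r_out = int(np.ceil(radius))
    y0, x0 = int(round(yc)), int(round(xc))
    if y0 - r_out < 0 or x0 - r_out < 0 or y0 + r_out + 1 > shape[0] or x0 + r_out + 1 > shape[1]:
        return None
    sl = (slice(y0 - r_out, y0 + r_out + 1), slice(x0 - r_out, x0 + r_out + 1))
    yy, xx = np.ogrid[sl]
    disk = (yy - yc) ** 2 + (xx - xc) ** 2 <= radius ** 2
    return sl, disk


def _paint_disk(target: np.ndarray, yc, xc, radius, value=True) -> np.ndarray | None:
    patch = _disk_patch(yc, xc, radius, target.shape)
    if patch is None:
        return None
    sl, disk = patch
    target[sl][disk] = value
    return disk


# ---------------------------------------------------------------------------
# marrow sections

def _build_marrow(spec: SyntheticSpec, rng: np.random.Generator):
    h, w = spec.dims
    ps = spec.pixel_size

    border = max(2, round(4 / ps))
    tissue = np.zeros((h, w), bool)
    tissue[border:h - border, border:w - border] = True
    tissue_poly = np.array([(border, border), (w - border, border),
                            (w - border, h - border), (border, h - border)], float)

    # --- bone: cortical ring plus trabecular ellipses
    bone = np.zeros((h, w), bool)
    if spec.cortical_ring:
        ring_px = max(1, round(spec.ring_thickness_um / ps))
        cavity = morphology.erosion(tissue, morphology.disk(ring_px))
        bone |= tissue & ~cavity
    else:
        cavity = tissue.copy()
    inner = morphology.erosion(cavity, morphology.disk(max(1, round(14 / ps))))
    inner_coords = np.argwhere(inner)
    for _ in range(spec.trabecula_count):
        if not len(inner_coords):
            break
        r0, c0 = inner_coords[rng.integers(len(inner_coords))]
        a = rng.uniform(8, 12) / ps
        b = rng.uniform(18, 30) / ps
        rr, cc = skdraw.ellipse(r0, c0, a, b, shape=(h, w),
                                rotation=rng.uniform(0, np.pi))
        trab = np.zeros((h, w), bool)
        trab[rr, cc] = True
        bone |= trab & morphology.erosion(cavity, morphology.disk(3))

    ma_truth = tissue & ~bone
    ma_count = int(ma_truth.sum())
    clearance = morphology.dilation(bone, morphology.disk(max(1, round(3 / ps))))
    free = ma_truth & ~clearance

    # --- unattributed strips (thin, white); the first doubles as the
    # Background annotation, so at least one is always placed. Strips are
    # confined to a compact band at the top of the cavity so they do not
    # fragment the ghost-placement zone.
    strips = np.zeros((h, w), bool)
    strip_polys: list[np.ndarray] = []
    blocked = ~free
    target_u_px = spec.frac_undetected * ma_count
    strip_w = max(2, round(4 / ps))
    free_rows = np.nonzero(free.any(axis=1))[0]
    band_top = int(free_rows[0]) + 2
    placed_u = 0
    attempts = 0
    band_h0 = int(np.ceil(target_u_px / max(0.5 * (w - 8), 1))) + 6
    while (placed_u < target_u_px or not strip_polys) and attempts < 1200:
        attempts += 1
        band_h = band_h0 + attempts // 30  # widen gently when crowded
        length = round(rng.uniform(60, 90) / ps)
        sh, sw = strip_w, length
        lo = max(4, band_top)
        hi = min(band_top + band_h, h - sh - 4)
        if hi <= lo or w - sw - 4 <= 4:
            continue
        r0 = int(rng.integers(lo, hi))
        c0 = int(rng.integers(4, w - sw - 4))
        pad = 1
        window = blocked[r0 - pad:r0 + sh + pad, c0 - pad:c0 + sw + pad]
        if window.any():
            continue
        strips[r0:r0 + sh, c0:c0 + sw] = True
        blocked[r0 - pad:r0 + sh + pad, c0 - pad:c0 + sw + pad] = True
        strip_polys.append(np.array([(c0, r0), (c0 + sw, r0),
                                     (c0 + sw, r0 + sh), (c0, r0 + sh)], float))
        placed_u += sh * sw
    if not strip_polys:
        return None

    # --- adipocyte ghosts across the whole free cavity (interspersed with
    # the nucleated territory, as in real marrow)
    strips_d = morphology.dilation(strips, morphology.disk(2))
    zone_strict = free & ~strips_d
    zone_loose = ma_truth & ~strips_d
    interiors = np.zeros((h, w), bool)
    membranes = np.zeros((h, w), bool)
    ghost_labels = np.zeros((h, w), np.int32)
    ghost_rows = []
    target_a_px = spec.frac_adipo * ma_count
    t_px = max(1, round(spec.membrane_thickness_um / ps))
    if target_a_px > 0:
        zone_px = int(zone_strict.sum())
        p_needed = target_a_px / max(zone_px, 1)
        if p_needed > 0.78:
            return None
        r0 = spec.ghost_radius_mean_um / ps
        # adjacent ghosts may share a membrane wall: the separation footprint
        # is r + t/2, so centre distances stay ≥ r1 + r2 + t. Sites form
        # minimally spaced hex lattices; a shuffled subset is used until the
        # area target is met, so sparse sections stay spatially uniform. At
        # high packing, jitter and size spread shrink to protect capacity,
        # and further lattice passes at smaller radii fill the boundary bands
        # the full-size lattice cannot reach.
        dense = p_needed > 0.45
        jitter = 0.0 if dense else 2.5
        sigma_r = min(spec.ghost_radius_sigma, 0.06) if dense else spec.ghost_radius_sigma
        occupancy = np.zeros((h, w), bool)
        placed_a = 0

        def try_place(yc, xc, radius) -> bool:
            nonlocal placed_a
            if np.pi * radius ** 2 * ps ** 2 < 130:
                return False
            r_out = int(np.ceil(radius + t_px))
            y0, x0 = int(round(yc)), int(round(xc))
            if (y0 - r_out < 0 or x0 - r_out < 0
                    or y0 + r_out + 1 > h or x0 + r_out + 1 > w):
                return False
            sl = (slice(y0 - r_out, y0 + r_out + 1),
                  slice(x0 - r_out, x0 + r_out + 1))
            yy, xx = np.ogrid[sl]
            d2 = (yy - yc) ** 2 + (xx - xc) ** 2
            sep = d2 <= (radius + t_px / 2) ** 2
            mem = d2 <= (radius + t_px) ** 2
            inter_d = d2 <= radius ** 2
            if (mem & ~zone_loose[sl]).any() or (sep & occupancy[sl]).any():
                return False
            if (inter_d & ~zone_strict[sl]).any():
                return False
            occupancy[sl][sep] = True
            gid = len(ghost_rows) + 1
            interiors[sl][inter_d] = True
            ghost_labels[sl][inter_d] = gid
            membranes[sl][mem & ~inter_d] = True
            ghost_rows.append({"id": gid, "yc": yc, "xc": xc, "r": radius})
            placed_a += int(inter_d.sum())
            return True

        def lattice_pass(r_pass: float) -> None:
            s = 2 * r_pass + t_px + 1
            ys = np.arange(rng.uniform(0, s), h, s * 0.866)
            x_origin = rng.uniform(0, s)
            sites = []
            for i, yc in enumerate(ys):
                offset = (s / 2) if i % 2 else 0.0
                for xc in np.arange(x_origin + offset, w, s):
                    sites.append((yc, xc))
            for idx in rng.permutation(len(sites)):
                if placed_a >= target_a_px:
                    return
                yc, xc = sites[idx]
                yc += rng.uniform(-jitter, jitter)
                xc += rng.uniform(-jitter, jitter)
                r_top = r_pass if dense else 1.3 * r_pass
                r_nom = float(np.clip(r_pass * np.exp(rng.normal(0, sigma_r)),
                                      0.6 * r_pass, r_top))
                # mild shrink only: a site that cannot take ~a full ghost is
                # left empty so a later, finer lattice can use the space
                for scale in (1.0, 0.92, 0.85):
                    if try_place(yc, xc, r_nom * scale):
                        break

        # at high adiposity marrow adipocytes hypertrophy, so dense sections
        # start from a larger lattice (which also packs more efficiently)
        radii = [2.0 * r0, 1.4 * r0, r0, 0.75 * r0, 0.55 * r0] if dense else [r0, 0.75 * r0]
        for k, r_pass in enumerate(radii):
            if k and placed_a >= target_a_px - 0.02 * ma_count:
                break
            lattice_pass(max(r_pass, 7.0 / ps))
            logger.debug("ghost lattice r=%.1f: %d ghosts, %d px of %d target (zone %d px)",
                         r_pass, len(ghost_rows), placed_a, int(target_a_px), zone_px)
        if placed_a < target_a_px - 0.02 * ma_count:
            # greedy maximal-disk gap fill: repeatedly place a ghost at the
            # deepest point of the remaining free space
            blocked_extra = np.zeros((h, w), bool)
            for _ in range(500):
                if placed_a >= target_a_px:
                    break
                free_sp = zone_strict & ~occupancy & ~blocked_extra
                edt_free = ndi.distance_transform_edt(free_sp)
                depth = float(edt_free.max())
                r_fit = min(depth - 1.5, 1.4 * r0)
                if np.pi * r_fit ** 2 * ps ** 2 < 130:
                    break
                yc, xc = np.unravel_index(int(np.argmax(edt_free)), edt_free.shape)
                if not try_place(float(yc), float(xc), r_fit):
                    blocked_extra[yc, xc] = True  # avoid re-picking a dead spot
            logger.debug("ghost gap-fill: %d ghosts, %d px of %d target",
                         len(ghost_rows), placed_a, int(target_a_px))

    # --- hematopoietic territory: topmost rows of what the ghosts left free.
    # Slivers too narrow to hold a nucleus are opened away (they render as
    # cytoplasm-only and belong to the interstitium).
    target_h_px = spec.frac_hemato * ma_count
    hemato_zone = np.zeros((h, w), bool)
    if target_h_px > 0:
        avail = free & ~strips_d & ~interiors & ~membranes
        avail = morphology.opening(avail, morphology.disk(max(1, round(2 / ps))))
        cum = np.cumsum(avail.sum(axis=1))
        if cum[-1] < target_h_px:
            logger.debug("hemato territory infeasible: %d available of %d target",
                         int(cum[-1]), int(target_h_px))
            return None
        r_cut = int(np.searchsorted(cum, target_h_px))
        hemato_zone = avail
        hemato_zone[r_cut + 1:, :] = False

    # --- rim nuclei (adipocyte nuclei at the ghost membrane)
    rim_nuclei = np.zeros((h, w), bool)
    for row in ghost_rows:
        if rng.random() >= spec.rim_nucleus_prob:
            continue
        theta = rng.uniform(0, 2 * np.pi)
        ny = row["yc"] + row["r"] * np.sin(theta)
        nx = row["xc"] + row["r"] * np.cos(theta)
        patch = _disk_patch(ny, nx, RIM_NUCLEUS_RADIUS_UM / ps, (h, w))
        if patch is None:
            continue
        sl, disk = patch
        rim_nuclei[sl] |= disk & ma_truth[sl] & ~strips[sl] & ~hemato_zone[sl]
    interiors &= ~rim_nuclei
    membranes &= ~rim_nuclei
    membranes &= ~interiors  # shared-wall rounding must never stain an interior
    ghost_labels[rim_nuclei] = 0

    # --- RBC lakes in the remaining interstitium
    remaining = ma_truth & ~hemato_zone & ~strips & ~interiors & ~membranes & ~rim_nuclei
    rbc_blob = np.zeros((h, w), bool)
    rbc_core = np.zeros((h, w), bool)
    blob_seed_region = morphology.erosion(remaining, morphology.disk(2))
    blob_coords = np.argwhere(blob_seed_region)
    for _ in range(2 + int(rng.integers(0, 3))):
        if not len(blob_coords):
            break
        r0, c0 = blob_coords[rng.integers(len(blob_coords))]
        a, b = rng.uniform(12, 22), rng.uniform(15, 28)
        rr, cc = skdraw.ellipse(r0, c0, a / ps, b / ps, shape=(h, w),
                                rotation=rng.uniform(0, np.pi))
        blob = np.zeros((h, w), bool)
        blob[rr, cc] = True
        blob &= remaining
        rbc_blob |= blob
        # speckled texture: discoid RBCs on plasma
        spacing = 6.0 / ps
        for yc in np.arange(rng.uniform(0, spacing), h, spacing):
            for xc in np.arange(rng.uniform(0, spacing), w, spacing):
                patch = _disk_patch(yc + rng.uniform(-1, 1), xc + rng.uniform(-1, 1),
                                    2.5 / ps, (h, w))
                if patch is None:
                    continue
                sl, disk = patch
                if (disk & blob[sl]).any():
                    rbc_core[sl] |= disk & blob[sl]

    # --- concentration maps
    e = np.zeros((h, w))
    hmap = np.zeros((h, w))
    interstitium_truth = ma_truth & ~hemato_zone & ~strips & ~interiors & ~rim_nuclei
    e[interstitium_truth] = SEROUS_EOSIN
    e[membranes] = MEMBRANE_EOSIN
    e[rbc_blob] = RBC_PLASMA_EOSIN
    e[rbc_core] = RBC_CORE_EOSIN
    e[bone] = BONE_EOSIN
    hmap[bone] = BONE_HEMA
    if hemato_zone.any():
        e[hemato_zone] = CYTOPLASM_EOSIN
        hmap[hemato_zone] = CYTOPLASM_HEMA
        spacing = spec.nucleus_spacing_um / ps
        nr = spec.nucleus_radius_um / ps
        rows_idx, cols_idx = np.nonzero(hemato_zone)
        rmin, rmax = rows_idx.min(), rows_idx.max()
        cmin, cmax = cols_idx.min(), cols_idx.max()
        for yc in np.arange(rmin + rng.uniform(0, spacing), rmax + 1, spacing):
            for xc in np.arange(cmin + rng.uniform(0, spacing), cmax + 1, spacing):
                patch = _disk_patch(yc + rng.uniform(-1.0, 1.0),
                                    xc + rng.uniform(-1.0, 1.0), nr, (h, w))
                if patch is None:
                    continue
                sl, disk = patch
                nucleus = disk & hemato_zone[sl]
                hmap[sl][nucleus] = NUCLEUS_HEMA
                e[sl][nucleus] = NUCLEUS_EOSIN
    hmap[rim_nuclei] = NUCLEUS_HEMA
    e[rim_nuclei] = NUCLEUS_EOSIN

    pixels = forward_stain_render(hmap, e, white=spec.white_reference,
                                  noise_sd=spec.noise_sd, rng=rng)

    # --- ground truth
    labels = np.zeros((h, w), np.int8)
    labels[interstitium_truth] = int(Label.INTERSTITIUM)
    labels[strips] = int(Label.UNDETECTED)
    labels[interiors] = int(Label.ADIPO)
    labels[hemato_zone | rim_nuclei] = int(Label.HEMATO)
    labels[bone] = int(Label.BONE)

    table_rows = []
    ps2 = ps ** 2
    for row in ghost_rows:
        sel = ghost_labels == row["id"]
        n = int(sel.sum())
        if n == 0:
            continue
        rr, cc = np.nonzero(sel)
        table_rows.append({"id": row["id"], "area_um2": n * ps2,
                           "centroid_x": float(cc.mean()),
                           "centroid_y": float(rr.mean())})
    ghost_table = pd.DataFrame(table_rows,
                               columns=["id", "area_um2", "centroid_x", "centroid_y"])

    realized = {
        "hemato": float((labels == int(Label.HEMATO)).sum()) / ma_count,
        "adipo": float((labels == int(Label.ADIPO)).sum()) / ma_count,
        "interstitium": float((labels == int(Label.INTERSTITIUM)).sum()) / ma_count,
        "undetected": float((labels == int(Label.UNDETECTED)).sum()) / ma_count,
    }
    targets = {
        "hemato": spec.frac_hemato, "adipo": spec.frac_adipo,
        "interstitium": spec.interstitium_target,
        "undetected": spec.frac_undetected,
    }
    if any(abs(realized[k] - targets[k]) > 0.03 for k in realized):
        logger.debug("rejecting draw: realized %s vs targets %s",
                     {k: round(v, 3) for k, v in realized.items()},
                     {k: round(v, 3) for k, v in targets.items()})
        return None

    image = CalibratedImage(pixels=pixels, pixel_size=ps, source_path="synthetic:marrow")
    truth = GroundTruth(labels=labels, ghost_labels=ghost_labels,
                        ghost_table=ghost_table, realized_fractions=realized,
                        pixel_size=ps)
    annotations = AnnotationSet(polygons=[
        AnnotationPolygon(class_label=TISSUE, rings=[tissue_poly]),
        AnnotationPolygon(class_label=BACKGROUND, rings=[strip_polys[0]]),
    ])
    return image, truth, annotations


def generate_marrow_section(spec: SyntheticSpec, seed: int | None = None):
    """Render a marrow section; returns (image, ground truth, annotations).

    Fraction targets are met by construction where possible and enforced by
    rejection resampling (new sub-seed) otherwise; irreconcilable targets
    (e.g. adiposity beyond the packing limit) raise :class:`SyntheticError`.
    """
    base = spec.seed if seed is None else seed
    for attempt in range(6):
        rng = np.random.default_rng(base + 9973 * attempt)
        built = _build_marrow(spec, rng)
        if built is not None:
            return built
    raise SyntheticError(
        "infeasible packing: could not realize the requested compartment "
        f"fractions (hemato={spec.frac_hemato}, adipo={spec.frac_adipo}, "
        f"undetected={spec.frac_undetected}) within tolerance"
    )


# ---------------------------------------------------------------------------
# adipose sheets

def generate_adipose_sheet(spec: SyntheticSpec, seed: int | None = None):
    """Render a Voronoi-like adipose sheet; returns (image, ground truth).

    Exactly ``spec.ghost_count`` truth ghosts are produced. With
    ``membrane_gap_fraction`` > 0, that fraction of the shared walls gets a
    central gap (the erased pixels join the adjacent ghost interiors), which
    merges neighbouring candidate regions — the hypo/hyper-fragmentation
    stressor.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.dims
    ps = spec.pixel_size
    n = spec.ghost_count
    margin = max(2, round(spec.sheet_margin_um / ps))
    sheet = np.zeros((h, w), bool)
    sheet[margin:h - margin, margin:w - margin] = True

    # jittered grid sites; surplus sites are deleted so exactly n remain
    nx = max(1, round(np.sqrt(n * (w - 2 * margin) / max(h - 2 * margin, 1))))
    ny = int(np.ceil(n / nx))
    sx = (w - 2 * margin) / nx
    sy = (h - 2 * margin) / ny
    jitter = 0.18 * min(sx, sy)
    sites = []
    for i in range(ny):
        for j in range(nx):
            yc = margin + (i + 0.5) * sy + rng.uniform(-jitter, jitter)
            xc = margin + (j + 0.5) * sx + rng.uniform(-jitter, jitter)
            sites.append((yc, xc))
    sites = np.asarray(sites)
    if len(sites) > n:
        keep = rng.permutation(len(sites))[:n]
        sites = sites[np.sort(keep)]

    rows_idx, cols_idx = np.nonzero(sheet)
    _, nearest = cKDTree(sites).query(np.column_stack([rows_idx, cols_idx]))
    cells = np.zeros((h, w), np.int32)
    cells[rows_idx, cols_idx] = nearest + 1

    # walls: pixels whose 4-neighbourhood holds a different label (label 0 =
    # stroma, so the sheet rim is walled too)
    membranes = np.zeros((h, w), bool)
    wall_px: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for axis in (0, 1):
        b = np.roll(cells, -1, axis=axis)
        valid = np.ones((h, w), bool)
        if axis == 0:
            valid[-1, :] = False
        else:
            valid[:, -1] = False
        diff = valid & (cells != b)
        membranes |= diff & (cells > 0)
        membranes |= np.roll(diff & (b > 0), 1, axis=axis)  # facing side
        rr, cc = np.nonzero(diff & (cells > 0) & (b > 0))
        for r0, c0 in zip(rr, cc):
            la, lb = int(cells[r0, c0]), int(b[r0, c0])
            key = (min(la, lb), max(la, lb))
            # record both faces of the wall so a gap truly opens it
            facing = (r0 + 1, c0) if axis == 0 else (r0, c0 + 1)
            wall_px.setdefault(key, []).extend([(r0, c0), facing])

    # thicker membranes when requested resolution demands it
    t_px = round(spec.membrane_thickness_um / ps)
    if t_px > 2:
        membranes = morphology.dilation(
            membranes, morphology.disk(int(np.ceil((t_px - 2) / 2))))
        membranes &= cells > 0

    # membrane erasure: central gaps in a fraction of internal walls. At most
    # one wall per cell is opened — degradation is patchy, and this keeps
    # merges pairwise (junction blow-outs would pool many cells into one
    # basin no watershed could resolve).
    if spec.membrane_gap_fraction > 0 and wall_px:
        keys = sorted(wall_px)
        quota = int(round(spec.membrane_gap_fraction * len(keys)))
        affected: set[int] = set()
        chosen = []
        for ki in rng.permutation(len(keys)):
            if len(chosen) >= quota:
                break
            i_cell, j_cell = keys[ki]
            if i_cell in affected or j_cell in affected:
                continue
            affected.update((i_cell, j_cell))
            chosen.append(keys[ki])
        for key in chosen:
            px = np.asarray(wall_px[key])
            centre = px.mean(axis=0)
            d = np.sqrt(((px - centre) ** 2).sum(axis=1))
            # open the central ~40% of the wall, leaving stubs whose neck the
            # downstream watershed can still fragment on
            gap = px[d <= np.quantile(d, 0.4)]
            membranes[gap[:, 0], gap[:, 1]] = False

    membranes &= cells > 0
    interiors = (cells > 0) & ~membranes

    # sparse stromal nuclei at membrane junctions
    nuclei = np.zeros((h, w), bool)
    mem_coords = np.argwhere(membranes)
    for _ in range(max(1, n // 12)):
        if not len(mem_coords):
            break
        r0, c0 = mem_coords[rng.integers(len(mem_coords))].astype(float)
        _paint_disk(nuclei, r0, c0, RIM_NUCLEUS_RADIUS_UM / ps)
    interiors &= ~nuclei
    membranes &= ~nuclei

    ghost_labels = np.where(interiors, cells, 0).astype(np.int32)

    e = np.full((h, w), STROMA_EOSIN)
    hmap = np.zeros((h, w))
    e[membranes] = MEMBRANE_EOSIN
    e[interiors] = 0.0
    hmap[nuclei] = NUCLEUS_HEMA
    e[nuclei] = NUCLEUS_EOSIN

    pixels = forward_stain_render(hmap, e, white=spec.white_reference,
                                  noise_sd=spec.noise_sd, rng=rng)

    labels = np.full((h, w), int(Label.INTERSTITIUM), np.int8)
    labels[interiors] = int(Label.ADIPO)
    labels[nuclei] = int(Label.HEMATO)

    ps2 = ps ** 2
    table_rows = []
    for gid in range(1, len(sites) + 1):
        sel = ghost_labels == gid
        count = int(sel.sum())
        if count == 0:
            continue
        rr, cc = np.nonzero(sel)
        table_rows.append({"id": gid, "area_um2": count * ps2,
                           "centroid_x": float(cc.mean()),
                           "centroid_y": float(rr.mean())})
    ghost_table = pd.DataFrame(table_rows,
                               columns=["id", "area_um2", "centroid_x", "centroid_y"])

    total = h * w
    realized = {
        "hemato": float(nuclei.sum()) / total,
        "adipo": float(interiors.sum()) / total,
        "interstitium": float((labels == int(Label.INTERSTITIUM)).sum()) / total,
        "undetected": 0.0,
    }
    image = CalibratedImage(pixels=pixels, pixel_size=ps, source_path="synthetic:sheet")
    truth = GroundTruth(labels=labels, ghost_labels=ghost_labels,
                        ghost_table=ghost_table, realized_fractions=realized,
                        pixel_size=ps)
    return image, truth


def recovery_sweep_specs(n_sections: int = 20, seed: int = 0) -> list[SyntheticSpec]:
    """Study conditions for the measured-versus-truth recovery sweep.

    Truth adiposity is swept over 0–60% of Ma.Ar with hematopoietic content
    varied reciprocally (pathologist-style cellularity spans ~0–100%),
    mirroring the red-to-yellow marrow range. High-adiposity sections carry
    a single trabecula, as in distal (yellow-marrow) sites.
    """
    specs = []
    for i in range(n_sections):
        a = 0.6 * i / max(n_sections - 1, 1)
        budget = max(0.0, 0.88 - 1.28 * a)  # space the ghost packing leaves
        c = (0.3, 0.6, 0.9)[i % 3]
        specs.append(SyntheticSpec(
            seed=seed + i,
            frac_adipo=round(a, 3),
            frac_hemato=round(c * budget, 3),
            frac_undetected=0.03,
            trabecula_count=1 if a >= 0.45 else 3,
        ))
    return specs


# ---------------------------------------------------------------------------
# ghost matching (evaluation helper)

def match_ghosts(truth: GroundTruth, measured_labels: np.ndarray) -> pd.DataFrame:
    """Match truth ghosts to measured labels by maximum pixel overlap.

    Returns one row per truth ghost: truth id/area, best-overlapping
    measured label (0 = unmatched), measured pixel area and the relative
    area error (NaN when unmatched).
    """
    t = truth.ghost_labels.ravel()
    m = np.asarray(measured_labels).ravel()
    sel = t > 0
    t, m = t[sel], m[sel]
    nt = int(truth.ghost_labels.max())
    nm = int(measured_labels.max())
    pair = t.astype(np.int64) * (nm + 1) + m
    counts = np.bincount(pair, minlength=(nt + 1) * (nm + 1)).reshape(nt + 1, nm + 1)
    measured_sizes = np.bincount(np.asarray(measured_labels).ravel(),
                                 minlength=nm + 1)
    ps2 = truth.pixel_size ** 2
    rows = []
    for _, trow in truth.ghost_table.iterrows():
        tid = int(trow["id"])
        overlaps = counts[tid]
        best = int(np.argmax(overlaps[1:]) + 1) if overlaps[1:].any() else 0
        m_area = float(measured_sizes[best] * ps2) if best else np.nan
        err = abs(m_area - trow["area_um2"]) / trow["area_um2"] if best else np.nan
        rows.append({"truth_id": tid, "truth_area_um2": trow["area_um2"],
                     "measured_label": best, "measured_area_um2": m_area,
                     "rel_area_error": err})
    return pd.DataFrame(rows)
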