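"""Calibrated image and annotation I/O, result tables, mask overlays.

Images are flat RGB TIFF or PNG; pixel calibration comes from TIFF
resolution tags or an explicit override. Annotations are a GeoJSON
FeatureCollection whose features carry a classification name (the dialect
QuPath exports): "Tissue Boundaries", "Artifacts"/"Artifact", "Background".
Coordinates are pixel units, origin top-left, x = column, y = row; a pixel
belongs to a polygon iff its centre (col+0.5, row+0.5) is inside under the
even-odd rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

logger = logging.getLogger("marrowquant")


class ImageError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


# Annotation classes
TISSUE = "TissueBoundaries"
ARTIFACT = "Artifact"
BACKGROUND = "Background"

_CLASS_ALIASES = {
    "tissueboundaries": TISSUE,
    "tissueboundary": TISSUE,
    "artifact": ARTIFACT,
    "artifacts": ARTIFACT,
    "background": BACKGROUND,
}


@dataclass
class CalibratedImage:
    """8-bit RGB image with physical pixel calibration (μm/pixel)."""

    pixels: np.ndarray
    pixel_size: float
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageError("expected an H×W×3 RGB image")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageError("empty image")
        if not self.pixel_size > 0:
            raise ImageError("pixel_size must be > 0")

    @property
    def dims(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class AnnotationPolygon:
    """One classed polygon: class label plus one or more vertex rings.

    Additional rings are interpreted under the even-odd rule, so interior
    rings behave as holes.
    """

    class_label: str
    rings: list[np.ndarray]


@dataclass
class AnnotationSet:
    polygons: list[AnnotationPolygon] = field(default_factory=list)

    def of_class(self, label: str) -> list[AnnotationPolygon]:
        return [p for p in self.polygons if p.class_label == label]


@dataclass
class RegionMasks:
    """Rasterized user annotations. analysis = tissue ∖ artifacts."""

    tissue_mask: np.ndarray
    artifact_mask: np.ndarray
    background_mask: np.ndarray

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.tissue_mask & ~self.artifact_mask


# ---------------------------------------------------------------------------
# image loading / writing

def _pixel_size_from_tiff(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        xres = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        per_unit = num / den
        unit_value = getattr(unit.value, "value", unit.value) if unit else 2
        if unit_value == 3:  # pixels per centimetre
            return 1e4 / per_unit
        if unit_value == 2:  # pixels per inch
            return 25400.0 / per_unit
        return None


def load_image(path: str | Path, pixel_size_override: float | None = None) -> CalibratedImage:
    """Read a TIFF/PNG as a calibrated RGB image.

    Pixel size is taken from TIFF resolution tags when present, otherwise
    from the override; it is an error to have neither.
    """
    path = Path(path)
    if not path.exists():
        raise ImageError(f"cannot read image: {path} does not exist")
    suffix = path.suffix.lower()
    pixel_size = None
    try:
        if suffix in (".tif", ".tiff"):
            pixels = tifffile.imread(path)
            pixel_size = _pixel_size_from_tiff(path)
        else:
            with PILImage.open(path) as im:
                pixels = np.asarray(im.convert("RGB") if im.mode == "RGB" else im)
    except ImageError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise ImageError(f"unreadable image {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ImageError(f"{path}: expected an RGB image, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise ImageError(f"{path}: expected 8-bit channels, got {pixels.dtype}")
    if pixel_size_override is not None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise ImageError(f"{path}: pixel size unknown (no calibration tags, no override)")
    return CalibratedImage(pixels=pixels, pixel_size=float(pixel_size), source_path=str(path))


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated TIFF with resolution tags (pixels per centimetre)."""
    ppcm = 1e4 / image.pixel_size
    tifffile.imwrite(
        Path(path), image.pixels,
        resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        photometric="rgb",
    )


# ---------------------------------------------------------------------------
# annotations

def _classification_name(props: dict) -> str | None:
    cls = props.get("classification")
    if isinstance(cls, dict) and "name" in cls:
        return str(cls["name"])
    if isinstance(cls, str):
        return cls
    if "name" in props:
        return str(props["name"])
    return None


def _normalize_class(name: str) -> str | None:
    key = "".join(name.lower().split()).replace("_", "").replace("-", "")
    return _CLASS_ALIASES.get(key)


def _rings_from_geometry(geom: dict) -> list[list[np.ndarray]]:
    """Return a list of polygons, each a list of rings (Nx2 float arrays)."""
    gtype = geom.get("type")
    if gtype == "Polygon":
        coord_sets = [geom["coordinates"]]
    elif gtype == "MultiPolygon":
        coord_sets = geom["coordinates"]
    else:
        raise AnnotationError(f"unsupported geometry type {gtype!r}")
    polygons = []
    for rings in coord_sets:
        arrays = [np.asarray(r, dtype=float) for r in rings]
        polygons.append(arrays)
    return polygons


def load_annotations(path: str | Path, dims: tuple[int, int],
                     mode: str = "marrow") -> AnnotationSet:
    """Read classed polygons from a GeoJSON FeatureCollection.

    Features are mapped case- and whitespace-insensitively onto the three
    classes; other classes are ignored with a warning. Vertices are clipped
    to the image bounds. Requires at least one Tissue Boundaries feature in
    marrow mode.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"malformed GeoJSON {path}: {exc}") from exc
    features = doc.get("features")
    if doc.get("type") != "FeatureCollection" or features is None:
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    h, w = dims
    out: list[AnnotationPolygon] = []
    for feat in features:
        props = feat.get("properties") or {}
        raw_name = _classification_name(props)
        if raw_name is None:
            logger.warning("annotation feature without classification ignored")
            continue
        label = _normalize_class(raw_name)
        if label is None:
            logger.warning("annotation class %r ignored", raw_name)
            continue
        for rings in _rings_from_geometry(feat["geometry"]):
            clipped = []
            for ring in rings:
                if ring.ndim != 2 or ring.shape[0] < 3:
                    raise AnnotationError("polygon ring with fewer than 3 vertices")
                if (ring[:, 0].max() <= 0 or ring[:, 0].min() >= w
                        or ring[:, 1].max() <= 0 or ring[:, 1].min() >= h):
                    logger.warning("polygon ring entirely outside image bounds")
                ring = ring.copy()
                ring[:, 0] = np.clip(ring[:, 0], 0, w)
                ring[:, 1] = np.clip(ring[:, 1], 0, h)
                clipped.append(ring)
            out.append(AnnotationPolygon(class_label=label, rings=clipped))
    annset = AnnotationSet(polygons=out)
    if mode == "marrow" and not annset.of_class(TISSUE):
        raise AnnotationError("no Tissue Boundaries annotation (required in marrow mode)")
    return annset


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    display = {TISSUE: "Tissue Boundaries", ARTIFACT: "Artifacts", BACKGROUND: "Background"}
    features = []
    for poly in annotations.polygons:
        coords = [np.asarray(r, dtype=float).tolist() for r in poly.rings]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": coords},
            "properties": {"classification": {"name": display[poly.class_label]}},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


# ---------------------------------------------------------------------------
# rasterization (even-odd rule, pixel-centre containment)

def _evenodd_mask(rings: list[np.ndarray], dims: tuple[int, int]) -> np.ndarray:
    """Vectorized crossing-number fill over all rings of one polygon."""
    h, w = dims
    yc = np.arange(h) + 0.5
    xc = np.arange(w) + 0.5
    crossings = np.zeros((h, w), dtype=np.int32)
    for ring in rings:
        pts = np.asarray(ring, dtype=float)
        if len(pts) and not np.array_equal(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[:1]])
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            if y1 == y2:
                continue  # horizontal edge: no crossing with a horizontal ray
            straddles = (y1 <= yc) != (y2 <= yc)
            if not straddles.any():
                continue
            x_int = x1 + (yc - y1) * (x2 - x1) / (y2 - y1)
            crossings += (straddles[:, None] & (xc[None, :] < x_int[:, None]))
    return (crossings % 2).astype(bool)


def rasterize(annotations: AnnotationSet, dims: tuple[int, int]) -> RegionMasks:
    """Rasterize classed polygons into tissue / artifact / background masks.

    Each polygon is filled under the even-odd rule (holes and
    self-intersections behave as in vector graphics); polygons of the same
    class are unioned. Background is clipped to the tissue region when a
    tissue polygon exists.
    """
    masks = {TISSUE: np.zeros(dims, bool), ARTIFACT: np.zeros(dims, bool),
             BACKGROUND: np.zeros(dims, bool)}
    for poly in annotations.polygons:
        m = _evenodd_mask(poly.rings, dims)
        if not m.any():
            logger.warning("polygon of class %s contributes no pixels", poly.class_label)
        masks[poly.class_label] |= m
    tissue, artifact, background = masks[TISSUE], masks[ARTIFACT], masks[BACKGROUND]
    if tissue.any() and (background & ~tissue).any():
        logger.warning("Background annotation extends outside Tissue Boundaries; clipped")
        background &= tissue
    return RegionMasks(tissue_mask=tissue, artifact_mask=artifact,
                       background_mask=background)


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = [
    "image", "mode",
    "tissue_area_um2", "artifact_area_um2", "bone_area_um2", "marrow_area_um2",
    "hematopoietic_area_um2", "adipocyte_area_um2", "interstitium_area_um2",
    "undetected_area_um2",
    "pct_hematopoietic", "pct_adiposity", "pct_interstitium", "pct_undetected",
    "cellularity_eq1", "adipocyte_count", "mean_adipocyte_area_um2",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float) and np.isnan(value):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def results_row(result) -> dict:
    """Map a QuantResult onto the results-TSV column contract."""
    return {
        "image": result.image, "mode": result.mode,
        "tissue_area_um2": result.tissue_area,
        "artifact_area_um2": result.artifact_area,
        "bone_area_um2": result.bone_area,
        "marrow_area_um2": result.marrow_area,
        "hematopoietic_area_um2": result.hematopoietic_area,
        "adipocyte_area_um2": result.adipocyte_area,
        "interstitium_area_um2": result.interstitium_area,
        "undetected_area_um2": result.undetected_area,
        "pct_hematopoietic": result.pct_hematopoietic,
        "pct_adiposity": result.pct_adiposity,
        "pct_interstitium": result.pct_interstitium,
        "pct_undetected": result.pct_undetected,
        "cellularity_eq1": result.cellularity_eq1,
        "adipocyte_count": result.adipocyte_count,
        "mean_adipocyte_area_um2": result.mean_adipocyte_area,
    }


def write_results(results, path: str | Path) -> None:
    """Write one or more quantification results as tab-separated text.

    Floats are written at full precision so a parse round-trip is
    numerically identical; undefined values are ``NA``.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    lines = ["\t".join(RESULT_COLUMNS)]
    for res in results:
        row = results_row(res)
        lines.append("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return df


GHOST_COLUMNS = ["id", "area_um2", "perimeter_um", "circularity",
                 "centroid_x", "centroid_y", "edge_touching"]


def write_ghost_table(ghosts, path: str | Path) -> None:
    """CSV of retained adipocyte ghosts (header only when none retained)."""
    rows = [
        {
            "id": g.id, "area_um2": g.area, "perimeter_um": g.perimeter,
            "circularity": g.circularity,
            "centroid_x": g.centroid[0], "centroid_y": g.centroid[1],
            "edge_touching": g.edge_touching,
        }
        for g in ghosts if g.retained
    ]
    lines = [",".join(GHOST_COLUMNS)]
    for row in rows:
        lines.append(",".join(_fmt(row[c]) for c in GHOST_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# overlays

# Fixed compartment palette: bone green, nucleated cells violet, adipocyte
# ghosts yellow, interstitium/microvasculature pink, undetected grey.
OVERLAY_COLORS = {
    1: (0, 170, 0),       # BONE
    2: (148, 0, 211),     # HEMATO
    3: (255, 215, 0),     # ADIPO
    4: (255, 105, 180),   # INTERSTITIUM
    5: (128, 128, 128),   # UNDETECTED
}
OVERLAY_ALPHA = 0.5


def write_overlay(image: CalibratedImage, labels, path: str | Path) -> None:
    """Blend the compartment label map over the source image and save a PNG.

    Excluded pixels are left untinted, so an all-excluded map reproduces the
    input image exactly.
    """
    arr = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    out = image.pixels.astype(float).copy()
    for value, color in OVERLAY_COLORS.items():
        sel = arr == value
        if sel.any():
            out[sel] = (1 - OVERLAY_ALPHA) * out[sel] + OVERLAY_ALPHA * np.asarray(color, float)
    PILImage.fromarray(np.clip(np.round(out), 0, 255).astype(np.uint8)).save(Path(path))


def write_label_tiff(labels, path: str | Path, pixel_size: float | None = None) -> None:
    """8-bit label image (0=EXCLUDED … 5=UNDETECTED)."""
    arr = np.asarray(labels.labels if hasattr(labels, "labels") else labels).astype(np.uint8)
    kwargs = {}
    if pixel_size is None and hasattr(labels, "pixel_size"):
        pixel_size = labels.pixel_size
    if pixel_size:
        ppcm = 1e4 / pixel_size
        kwargs = dict(resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
    tifffile.imwrite(Path(path), arr, **kwargs)
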