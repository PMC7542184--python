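"""Optical-density conversion and H&E colour deconvolution.

Brightfield H&E absorbance is approximately linear in optical density
(Beer–Lambert): ``OD_c = log10(white_c / I_c)`` per channel, where the white
reference is estimated from a user-annotated background region inside the
ROI. Stains mix linearly in OD space, so per-pixel hematoxylin/eosin
concentrations are recovered by inverting a 3×3 stain matrix whose columns
are unit OD vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("marrowquant")


class StainError(ValueError):
    """Raised for degenerate stain bases or missing background."""


#: OD values are clipped to [0, OD_MAX]; 8-bit data cannot resolve more.
OD_MAX = 3.0

# Standard published H&E OD triplets (widely used community defaults);
# user-overridable via StainVectors.h_and_e(hema=..., eosin=...).
DEFAULT_HEMATOXYLIN = (0.65, 0.70, 0.29)
DEFAULT_EOSIN = (0.07, 0.99, 0.11)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not n > 0:
        raise StainError(f"{name} stain vector has zero norm")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Orthonormal-ish OD basis: hematoxylin, eosin and a residual channel."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    residual: np.ndarray

    @classmethod
    def h_and_e(cls, hema=None, eosin=None, residual=None) -> "StainVectors":
        h = _unit(hema if hema is not None else DEFAULT_HEMATOXYLIN, "hematoxylin")
        e = _unit(eosin if eosin is not None else DEFAULT_EOSIN, "eosin")
        if residual is None:
            r = np.cross(h, e)
            if np.linalg.norm(r) < 1e-8:
                raise StainError("hematoxylin and eosin vectors are collinear")
            r = r / np.linalg.norm(r)
        else:
            r = _unit(residual, "residual")
        vs = cls(h, e, r)
        vs.matrix()  # validate invertibility eagerly
        return vs

    def matrix(self) -> np.ndarray:
        """3×3 matrix with stain vectors as columns; validated invertible."""
        m = np.stack([self.hematoxylin, self.eosin, self.residual], axis=1)
        if np.linalg.cond(m) > 1e8:
            pairs = {
                ("hematoxylin", "eosin"): abs(float(self.hematoxylin @ self.eosin)),
                ("hematoxylin", "residual"): abs(float(self.hematoxylin @ self.residual)),
                ("eosin", "residual"): abs(float(self.eosin @ self.residual)),
            }
            a, b = max(pairs, key=pairs.get)
            raise StainError(f"singular stain matrix: {a} and {b} are (near-)parallel")
        return m


@dataclass
class StainMaps:
    """Per-pixel stain concentrations (OD units) plus the white reference."""

    hema: np.ndarray
    eosin: np.ndarray
    residual: np.ndarray
    white_reference: np.ndarray

    @property
    def total(self) -> np.ndarray:
        """Hematoxylin + eosin concentration — a chromatic density proxy."""
        return self.hema + self.eosin


def estimate_white_reference(
    image,
    background_mask: np.ndarray,
    mode: str = "marrow",
    analysis_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel median intensity over the annotated background region.

    The median is robust to dust specks and debris inside the annotation.
    An empty background is an error in marrow mode; in adipo mode the
    99th-percentile intensity of the analysis region is used instead (ghost
    interiors are near-white, so the bright tail is a serviceable stand-in).
    Channels are floored at 1 so the subsequent log is finite.
    """
    pixels = np.asarray(image.pixels if hasattr(image, "pixels") else image)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.any():
        white = np.median(pixels[background_mask].reshape(-1, 3), axis=0)
    elif mode == "adipo":
        region = analysis_mask if analysis_mask is not None else np.ones(pixels.shape[:2], bool)
        if not region.any():
            raise StainError("empty analysis region: cannot estimate white reference")
        white = np.percentile(pixels[region].reshape(-1, 3), 99, axis=0)
        logger.warning(
            "no Background annotation: falling back to 99th-percentile "
            "intensity of the analysis region, white=%s", np.round(white, 1)
        )
    else:
        raise StainError("Background annotation required in marrow mode")
    return np.maximum(white.astype(float), 1.0)


def rgb_to_od(pixels: np.ndarray, white_reference: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to optical density against the white reference.

    ``OD_c = log10(white_c / max(I_c, 1))``, clipped to [0, OD_MAX]. OD is 0
    at the white reference and increases monotonically with absorbance.
    """
    white = np.asarray(white_reference, dtype=float)
    if not np.all(white > 0):
        raise StainError("white reference must be positive")
    intensity = np.maximum(np.asarray(pixels, dtype=float), 1.0)
    od = np.log10(white / intensity)
    return np.clip(od, 0.0, OD_MAX)


def deconvolve(od: np.ndarray, vectors: StainVectors,
               white_reference: np.ndarray | None = None) -> StainMaps:
    """Unmix an OD image into per-stain concentration maps.

    Solves ``od = M·c`` per pixel (M columns = stain vectors) and clips
    negative components to zero.
    """
    m = vectors.matrix()
    inv = np.linalg.inv(m)
    conc = np.asarray(od, dtype=float) @ inv.T
    conc = np.clip(conc, 0.0, None)
    white = (np.full(3, 255.0) if white_reference is None
             else np.asarray(white_reference, dtype=float))
    return StainMaps(
        hema=conc[..., 0], eosin=conc[..., 1], residual=conc[..., 2],
        white_reference=white,
    )


def unmix_image(image, background_mask, vectors: StainVectors | None = None,
                mode: str = "marrow", analysis_mask=None) -> StainMaps:
    """Convenience: white reference → OD → deconvolution in one call."""
    vectors = vectors or StainVectors.h_and_e()
    white = estimate_white_reference(image, background_mask, mode=mode,
                                     analysis_mask=analysis_mask)
    pixels = image.pixels if hasattr(image, "pixels") else image
    od = rgb_to_od(pixels, white)
    return deconvolve(od, vectors, white_reference=white)
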