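"""Tunable analysis parameters, in physical units.

Every numeric field is expressed in micrometres (or μm²); conversion to
pixels happens only inside the segmentation steps, via ``pixel_size``.
Two parameter presets exist: ``marrow`` (whole-bone marrow sections) and
``adipo`` (extramedullary adipose sheets, the stand-alone adipocyte
workflow).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


MODES = ("marrow", "adipo")
THRESHOLD_METHODS = ("otsu", "fixed")


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameter set for one analysis run.

    Parameters
    ----------
    mode:
        ``"marrow"`` for bone sections (bone mask, marrow compartments) or
        ``"adipo"`` for extramedullary adipose tissue (no bone step).
    min_adipocyte_area, max_adipocyte_area:
        Retention window for adipocyte ghosts, μm². Boundaries inclusive.
    min_circularity:
        Minimum 4πA/P² of a retained ghost, in [0, 1].
    exclude_edges:
        Reject ghosts touching the image border or an excluded region.
    bin_width:
        Size-distribution bin width, μm².
    pixel_size:
        μm per pixel. ``None`` until supplied by image metadata or the user.
    bone_dilation_radius:
        Endosteal exclusion ring dilated around the bone mask, μm.
    smoothing_sigma:
        Gaussian smoothing applied to stain maps before thresholding, μm.
    min_bone_object_area:
        Smallest object kept in the bone mask, μm².
    threshold_method:
        ``"otsu"`` (adaptive, computed within the analysis region) or
        ``"fixed"`` (user-supplied OD thresholds).
    fixed_od_thresholds:
        Optional per-stain OD thresholds, e.g. ``{"hema": 0.3, "eosin": 0.4,
        "void": 0.1}``; consulted only when ``threshold_method == "fixed"``.
    """

    mode: str = "marrow"
    min_adipocyte_area: float = 120.0
    max_adipocyte_area: float = 5000.0
    min_circularity: float = 0.3
    exclude_edges: bool = False
    bin_width: float = 250.0
    pixel_size: float | None = None
    bone_dilation_radius: float = 2.0
    smoothing_sigma: float = 1.0
    min_bone_object_area: float = 500.0
    threshold_method: str = "otsu"
    fixed_od_thresholds: dict[str, float] | None = None

    def with_(self, **changes: Any) -> "AnalysisConfig":
        return validate_config(dataclasses.replace(self, **changes))


# Recommended presets. The adipocyte filters are the published recommended
# values per mode; the remaining operator parameters are this package's
# documented defaults (see docs/methods.md).
_PRESETS: dict[str, dict[str, Any]] = {
    "marrow": dict(
        mode="marrow",
        min_adipocyte_area=120.0,
        max_adipocyte_area=5000.0,
        min_circularity=0.3,
        exclude_edges=False,
    ),
    "adipo": dict(
        mode="adipo",
        min_adipocyte_area=300.0,
        max_adipocyte_area=2500.0,
        min_circularity=0.0,
        exclude_edges=True,
    ),
}


def default_config(mode: str) -> AnalysisConfig:
    """Return the recommended parameter set for *mode*.

    ``pixel_size`` is left unset; it must come from image metadata or the
    user before segmentation.
    """
    if mode not in _PRESETS:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    return AnalysisConfig(**_PRESETS[mode])


def validate_config(cfg: AnalysisConfig) -> AnalysisConfig:
    """Return *cfg* unchanged if all invariants hold.

    Raises :class:`ConfigError` naming the first violated invariant.
    """
    if cfg.mode not in MODES:
        raise ConfigError(f"unknown mode {cfg.mode!r}; expected one of {MODES}")
    if not cfg.min_adipocyte_area > 0:
        raise ConfigError("min_adipocyte_area must be > 0")
    if cfg.min_adipocyte_area >= cfg.max_adipocyte_area:
        raise ConfigError("min_adipocyte_area ≥ max_adipocyte_area")
    if not 0.0 <= cfg.min_circularity <= 1.0:
        raise ConfigError("min_circularity outside [0, 1]")
    if not cfg.bin_width > 0:
        raise ConfigError("bin_width must be > 0")
    if cfg.pixel_size is not None and not cfg.pixel_size > 0:
        raise ConfigError("pixel_size must be > 0")
    if cfg.bone_dilation_radius < 0:
        raise ConfigError("bone_dilation_radius must be ≥ 0")
    if not cfg.smoothing_sigma > 0:
        raise ConfigError("smoothing_sigma must be > 0")
    if not cfg.min_bone_object_area >= 0:
        raise ConfigError("min_bone_object_area must be ≥ 0")
    if cfg.threshold_method not in THRESHOLD_METHODS:
        raise ConfigError(
            f"unknown threshold_method {cfg.threshold_method!r}; "
            f"expected one of {THRESHOLD_METHODS}"
        )
    if cfg.threshold_method == "fixed" and not cfg.fixed_od_thresholds:
        raise ConfigError("threshold_method 'fixed' requires fixed_od_thresholds")
    return cfg


def require_pixel_size(cfg: AnalysisConfig) -> float:
    if cfg.pixel_size is None:
        raise ConfigError("pixel size unknown: supply image calibration or pixel_size")
    return cfg.pixel_size


# Flat key/value (TOML) serialization. Keys carry unit suffixes so a config
# file is self-describing.
_FILE_KEYS: dict[str, str] = {
    "mode": "mode",
    "min_adipocyte_area_um2": "min_adipocyte_area",
    "max_adipocyte_area_um2": "max_adipocyte_area",
    "min_circularity": "min_circularity",
    "exclude_edges": "exclude_edges",
    "bin_width_um2": "bin_width",
    "pixel_size_um": "pixel_size",
    "bone_dilation_radius_um": "bone_dilation_radius",
    "smoothing_sigma_um": "smoothing_sigma",
    "min_bone_object_area_um2": "min_bone_object_area",
    "threshold_method": "threshold_method",
}
_FIELD_TO_KEY = {v: k for k, v in _FILE_KEYS.items()}


def config_to_file_dict(cfg: AnalysisConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, field in _FILE_KEYS.items():
        value = getattr(cfg, field)
        if value is not None:
            out[key] = value
    return out


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    """Write *cfg* as a flat TOML-style key/value file."""
    lines = []
    for key, value in config_to_file_dict(cfg).items():
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, str):
            rendered = f'"{value}"'
        else:
            rendered = repr(float(value))
        lines.append(f"{key} = {rendered}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(
    path: str | Path | None = None,
    mode: str | None = None,
    **overrides: Any,
) -> AnalysisConfig:
    """Build a validated config from mode defaults, an optional file, and
    explicit overrides (in increasing precedence).

    *overrides* use field names (``min_adipocyte_area=...``); ``None`` values
    are ignored so CLI plumbing can pass unset flags straight through.
    """
    file_vals: dict[str, Any] = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())
        for key, value in raw.items():
            if key not in _FILE_KEYS:
                raise ConfigError(f"unknown config key {key!r}")
            file_vals[_FILE_KEYS[key]] = value
    effective_mode = mode or overrides.get("mode") or file_vals.get("mode", "marrow")
    cfg = default_config(effective_mode)
    merged = {**file_vals, **{k: v for k, v in overrides.items() if v is not None}}
    merged["mode"] = effective_mode
    cfg = dataclasses.replace(cfg, **merged)
    return validate_config(cfg)
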