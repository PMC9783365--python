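"""Pipeline configuration: YAML with schema validation and full defaults.

Defaults reproduce the processing parameters the pipeline was designed
around: 2-D map smoothing sigma 5 px, Savitzky–Golay order 5 / window
151 px, exposure saturation target 0.95, and the full-scale 4096x3000
sensor geometry with a 500 px illumination decay length.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .exceptions import ValidationError

DEFAULTS: dict = {
    "frame": {
        "height_px": 3000,
        "width_px": 4096,
        "bit_depth": 16,
    },
    "illumination": {
        "peak_intensity": 60000.0,
        "decay_length_px": 500.0,
    },
    "phantom": {
        "thread_depth_um": 200.0,
        "contrast_gain": 0.05,
        "depth_decay_um": 300.0,
        "blur_sigma_px_per_um_depth": 0.1,
        "pixel_pitch_um": 3.45 / 3.75,
    },
    "noise": {
        "kind": "gaussian",
        "sigma_fraction_of_peak": 0.005,
    },
    "reconstruction": {
        "smoothing_sigma_px": 5.0,
    },
    "profile": {
        "savgol_poly_order": 5,
        "savgol_window_px": 151,
    },
    "calibration": {
        "saturation_target": 0.95,
    },
}

_VALIDATORS = {
    ("frame", "height_px"): lambda v: int(v) > 0,
    ("frame", "width_px"): lambda v: int(v) > 0,
    ("frame", "bit_depth"): lambda v: int(v) > 0,
    ("illumination", "peak_intensity"): lambda v: float(v) > 0,
    ("illumination", "decay_length_px"): lambda v: float(v) > 0,
    ("phantom", "thread_depth_um"): lambda v: float(v) >= 0,
    ("phantom", "contrast_gain"): lambda v: float(v) > 0,
    ("phantom", "depth_decay_um"): lambda v: float(v) > 0,
    ("phantom", "blur_sigma_px_per_um_depth"): lambda v: float(v) >= 0,
    ("phantom", "pixel_pitch_um"): lambda v: float(v) > 0,
    ("noise", "kind"): lambda v: v in ("none", "gaussian", "shot"),
    ("noise", "sigma_fraction_of_peak"): lambda v: float(v) >= 0,
    ("reconstruction", "smoothing_sigma_px"): lambda v: float(v) >= 0,
    ("profile", "savgol_poly_order"): lambda v: int(v) >= 0,
    ("profile", "savgol_window_px"): lambda v: int(v) % 2 == 1 and int(v) > 1,
    ("calibration", "saturation_target"): lambda v: 0 < float(v) <= 1,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration, merged over the full defaults.

    An empty or absent file yields the defaults. Unknown sections or keys
    raise a validation error naming them; known keys are type/range checked.
    """
    merged = copy.deepcopy(DEFAULTS)
    overrides: dict = {}
    if path is not None:
        text = Path(path).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, dict):
            raise ValidationError("configuration root must be a mapping")

    unknown = []
    for section, entries in overrides.items():
        if section not in DEFAULTS:
            unknown.append(section)
            continue
        if not isinstance(entries, dict):
            raise ValidationError(f"section {section!r} must be a mapping")
        for key in entries:
            if key not in DEFAULTS[section]:
                unknown.append(f"{section}.{key}")
    if unknown:
        raise ValidationError(f"unknown configuration keys: {', '.join(sorted(unknown))}")

    for section, entries in overrides.items():
        for key, value in entries.items():
            check = _VALIDATORS.get((section, key))
            try:
                ok = check(value) if check else True
            except (TypeError, ValueError):
                ok = False
            if not ok:
                raise ValidationError(f"invalid value for {section}.{key}: {value!r}")
            merged[section][key] = type(DEFAULTS[section][key])(value) \
                if not isinstance(value, type(DEFAULTS[section][key])) else value
    return merged
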