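"""Cross-sections, Savitzky–Golay filtering, and deflection detection.

An absorbing structure shows up in an SP-DRI ratio map as a local
*deflection*: the profile departs from its baseline near 1, dipping where
the structure sits in the numerator frame. Profiles through the map are
smoothed with a Savitzky–Golay filter (local least-squares polynomial fits,
default order 5 over a 151 px window) before the deflection is quantified.

Baseline is the profile median — robust against a single deflection — and
amplitude is the largest absolute departure from it inside a border-excluded
interior, because division artifacts concentrate near mask edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DetectionError, ValidationError
from .model import Profile, ReflectanceFrame, SpdriMap

SAVGOL_POLY_ORDER = 5
SAVGOL_WINDOW_PX = 151


@dataclass(frozen=True)
class Deflection:
    """Quantified departure of a profile from its baseline."""

    position_px: int
    amplitude: float
    baseline: float
    polarity: str  # "dip" (below baseline) or "peak" (above)

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("amplitude must be nonnegative")
        if self.polarity not in ("dip", "peak"):
            raise ValidationError(f"polarity must be 'dip' or 'peak', got {self.polarity!r}")


def extract_cross_section(
    source: SpdriMap | ReflectanceFrame | np.ndarray,
    axis: str,
    fixed_coordinate_px: int,
) -> Profile:
    """Row (axis='x') or column (axis='y') at a fixed coordinate.

    For a ratio map, invalid pixels are carried as NaN so downstream
    filtering and detection can skip them.
    """
    if isinstance(source, SpdriMap):
        arr = source.masked_ratio()
    elif isinstance(source, ReflectanceFrame):
        arr = np.asarray(source.pixels, dtype=float)
    else:
        arr = np.asarray(source, dtype=float)
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    c = int(fixed_coordinate_px)
    n_rows, n_cols = arr.shape
    if axis == "x":
        if not 0 <= c < n_rows:
            raise IndexError(f"row {c} outside [0, {n_rows})")
        values = arr[c, :]
    else:
        if not 0 <= c < n_cols:
            raise IndexError(f"column {c} outside [0, {n_cols})")
        values = arr[:, c]
    return Profile(values=values.copy(), axis=axis, fixed_coordinate_px=c)


def _savgol_segment(seg: np.ndarray, poly_order: int, window: int) -> np.ndarray:
    """Savitzky–Golay on one contiguous finite segment, shrinking the
    window (keeping it odd) when the segment is shorter than requested."""
    n = seg.size
    if n >= window:
        return savgol_filter(seg, window_length=window, polyorder=poly_order, mode="interp")
    win = n if n % 2 == 1 else n - 1
    if win <= 1:
        return seg.copy()
    order = min(poly_order, win - 1)
    return savgol_filter(seg, window_length=win, polyorder=order, mode="interp")


def savgol_profile(
    profile: Profile,
    poly_order: int = SAVGOL_POLY_ORDER,
    frame_length_px: int = SAVGOL_WINDOW_PX,
) -> Profile:
    """Savitzky–Golay smoothing of a profile (default: order 5, 151 px).

    Local least-squares polynomial fits of the given order over a sliding
    window; polynomials of degree <= ``poly_order`` are reproduced exactly.
    NaN (masked) samples are preserved and excluded: each contiguous run of
    finite samples is filtered on its own, with the window shrunk on runs
    shorter than ``frame_length_px``.
    """
    if frame_length_px % 2 == 0:
        raise ValidationError(f"frame_length_px must be odd, got {frame_length_px}")
    if frame_length_px <= poly_order:
        raise ValidationError("frame_length_px must exceed poly_order")
    if profile.length < frame_length_px:
        raise ValidationError(
            f"profile length {profile.length} is shorter than the filter "
            f"window {frame_length_px}"
        )
    values = profile.values
    out = np.full_like(values, np.nan)
    finite = np.isfinite(values)
    # contiguous finite runs
    edges = np.flatnonzero(np.diff(finite.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges + 1, values.size]
    for lo, hi in zip(starts, stops):
        if finite[lo]:
            out[lo:hi] = _savgol_segment(values[lo:hi], poly_order, frame_length_px)
    return Profile(values=out, axis=profile.axis, fixed_coordinate_px=profile.fixed_coordinate_px)


def detect_deflection(profile: Profile, exclusion_border_px: int = 0) -> Deflection:
    """Largest absolute departure from the median baseline.

    The baseline is the median of the whole (finite) profile; the extremum
    is searched only in a border-excluded interior: samples within
    ``exclusion_border_px`` of the profile ends *or of any masked (NaN)
    run* are ignored, because division and filter edge artifacts
    concentrate at mask edges. A sensible border is the shift magnitude
    plus the Savitzky–Golay half-window.
    """
    b = int(exclusion_border_px)
    if b < 0:
        raise ValidationError("exclusion_border_px must be nonnegative")
    if profile.length <= 2 * b:
        raise ValidationError(
            f"profile of length {profile.length} has no interior for "
            f"border {b}"
        )
    values = profile.values
    finite = np.isfinite(values)
    if not finite.any():
        raise DetectionError("profile has no finite samples")
    baseline = float(np.median(values[finite]))
    allowed = finite.copy()
    if b:
        # erode the finite mask: a sample survives only if its whole
        # b-neighbourhood is finite and inside the profile
        pad = np.r_[np.zeros(b, dtype=bool), finite, np.zeros(b, dtype=bool)]
        windows = np.lib.stride_tricks.sliding_window_view(pad, 2 * b + 1)
        allowed = windows.all(axis=1)
    if not allowed.any():
        raise DetectionError("border-excluded interior has no finite samples")
    dev = np.where(allowed, np.abs(values - baseline), -np.inf)
    idx = int(np.argmax(dev))
    value = values[idx]
    return Deflection(
        position_px=idx,
        amplitude=float(dev[idx]),
        baseline=baseline,
        polarity="dip" if value < baseline else "peak",
    )


def raw_vs_spdri_contrast(
    raw_profile: Profile,
    spdri_profile: Profile,
    exclusion_border_px: int = 0,
) -> tuple[float, float]:
    """Relative deflection amplitude (amplitude / baseline) of each profile.

    Puts the raw diffuse-reflectance cross-section and the ratio-map
    cross-section on a common, unitless percentage-style scale so their
    structure contrast can be compared directly.
    """
    out = []
    for p in (raw_profile, spdri_profile):
        d = detect_deflection(p, exclusion_border_px)
        if d.baseline == 0:
            raise ValidationError("zero baseline: relative amplitude undefined")
        out.append(d.amplitude / abs(d.baseline))
    return out[0], out[1]
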