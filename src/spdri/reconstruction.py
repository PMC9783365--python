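"""The SP-DRI core: shift-align two frames and divide pixelwise.

Two diffuse-reflectance frames are acquired with the light source at two
slightly shifted positions but an otherwise identical scene. Translating one
frame so the two source positions coincide makes the illumination cones
overlap exactly, while the subsurface structure content is mutually
displaced. Pixelwise division then cancels the cone (both operands carry
the same illumination profile) and exposes absorbing structures as local
departures of the ratio from 1 — once below 1 where the structure sits in
the numerator frame, once above 1 at its displaced copy.

Design choices: shifts are integer-pixel (LED position differences are
rounded); pixels translated out of the overlap are masked invalid rather
than zero-filled; zero-denominator pixels are invalidated rather than
epsilon-padded, since real 16-bit data can contain true zeros far from the
cone; the frame of the lower-numbered LED is the numerator, so the sign of
a deflection is interpretable.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .model import LedSpec, ReflectanceFrame, SpdriMap

DEFAULT_SMOOTHING_SIGMA_PX = 5.0


def compute_shift(led_a: LedSpec, led_b: LedSpec) -> tuple[str, int]:
    """Shift axis and signed integer shift between two same-side LEDs.

    Long-side LEDs shift the frames in x, short-side LEDs in y;
    ``shift_px = round(position_a - position_b)``.
    """
    if led_a.side != led_b.side:
        raise ValidationError(
            f"LED #{led_a.led_id} ({led_a.side.value}) and LED #{led_b.led_id} "
            f"({led_b.side.value}) are on different sides; the shift axis is undefined"
        )
    shift = int(round(led_a.position_px - led_b.position_px))
    return led_a.side.shift_axis, shift


def align_frames(
    frame_a: ReflectanceFrame,
    frame_b: ReflectanceFrame,
    shift_axis: str,
    shift_px: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Translate frame_b so the two source positions coincide.

    frame_b is shifted by ``shift_px`` along ``shift_axis``; frame_a is
    returned untouched. Pixels translated in from outside the frame are
    marked invalid in the returned boolean mask.
    """
    if frame_a.pixels.shape != frame_b.pixels.shape:
        raise ValidationError("frames must share their shape to be aligned")
    if shift_axis not in ("x", "y"):
        raise ValidationError(f"shift_axis must be 'x' or 'y', got {shift_axis!r}")
    a = np.asarray(frame_a.pixels, dtype=float)
    b = np.asarray(frame_b.pixels, dtype=float)
    # numpy axis: 0 = rows = y, 1 = columns = x
    axis = 1 if shift_axis == "x" else 0
    extent = b.shape[axis]
    if abs(shift_px) >= extent:
        raise ValidationError(
            f"|shift| = {abs(shift_px)} px leaves no overlap along {shift_axis} "
            f"(frame extent {extent} px)"
        )
    shifted = np.zeros_like(b)
    mask = np.zeros(b.shape, dtype=bool)
    s = int(shift_px)
    src = [slice(None), slice(None)]
    dst = [slice(None), slice(None)]
    if s >= 0:
        dst[axis] = slice(s, extent)
        src[axis] = slice(0, extent - s)
    else:
        dst[axis] = slice(0, extent + s)
        src[axis] = slice(-s, extent)
    shifted[tuple(dst)] = b[tuple(src)]
    mask[tuple(dst)] = True
    return a, shifted, mask


def spdri_divide(
    aligned_a: np.ndarray,
    aligned_b: np.ndarray,
    valid_mask: np.ndarray,
    shift_axis: str = "x",
    shift_px: int = 0,
    source_leds: tuple[int, int] | None = None,
    min_counts: float = 0.0,
) -> SpdriMap:
    """Divide the aligned numerator by the aligned denominator, pixelwise.

    The ratio is defined wherever the overlap mask is true and the
    denominator is positive; zero-denominator pixels are dropped from the
    mask. ``source_leds`` records operand order (numerator, denominator).

    ``min_counts`` optionally raises the validity floor: pixels where either
    operand falls below it are masked out. Far from the illumination cone
    both operands approach the noise floor and their ratio is meaningless;
    thresholding at a few noise sigmas restricts the map to the adequately
    illuminated region. The default (0) keeps the plain b > 0 rule.
    """
    a = np.asarray(aligned_a, dtype=float)
    b = np.asarray(aligned_b, dtype=float)
    mask = np.asarray(valid_mask, dtype=bool)
    if not (a.shape == b.shape == mask.shape):
        raise ValidationError("operands and mask must share their shape")
    floor = max(float(min_counts), 0.0)
    mask = mask & (b > floor) & (a > floor)
    if not mask.any():
        raise ValidationError("empty valid region: nothing to divide")
    ratio = np.full(a.shape, np.nan)
    np.divide(a, b, out=ratio, where=mask)
    return SpdriMap(
        ratio=ratio,
        valid_mask=mask,
        shift_axis=shift_axis,
        shift_px=int(shift_px),
        source_leds=source_leds,
    )


def smooth_map(spdri_map: SpdriMap, sigma_px: float = DEFAULT_SMOOTHING_SIGMA_PX) -> SpdriMap:
    """Gaussian-smooth the ratio map inside its valid mask.

    Invalid pixels are excluded from the kernel support: the smoothed value
    at p is ``conv(ratio * mask) / conv(mask)`` at p, i.e. the kernel is
    renormalized over the valid neighbourhood, so masked-out pixels never
    leak into the result. ``sigma_px = 0`` returns the map unchanged.
    """
    if sigma_px < 0:
        raise ValidationError(f"sigma_px must be nonnegative, got {sigma_px}")
    if sigma_px == 0:
        return spdri_map
    mask = spdri_map.valid_mask
    filled = np.where(mask, spdri_map.ratio, 0.0)
    num = gaussian_filter(filled, sigma=sigma_px, mode="constant", cval=0.0)
    den = gaussian_filter(mask.astype(float), sigma=sigma_px, mode="constant", cval=0.0)
    smoothed = np.full(spdri_map.ratio.shape, np.nan)
    np.divide(num, den, out=smoothed, where=mask & (den > 0))
    return SpdriMap(
        ratio=smoothed,
        valid_mask=mask & (den > 0),
        shift_axis=spdri_map.shift_axis,
        shift_px=spdri_map.shift_px,
        source_leds=spdri_map.source_leds,
    )


def run_spdri(
    frame_a: ReflectanceFrame,
    frame_b: ReflectanceFrame,
    led_a: LedSpec,
    led_b: LedSpec,
    sigma_px: float = DEFAULT_SMOOTHING_SIGMA_PX,
    min_counts: float = 0.0,
) -> SpdriMap:
    """Full reconstruction: compute shift, align, divide, smooth.

    The frame of the lower-numbered LED is used as the numerator regardless
    of argument order; metadata on the returned map records the LED pair,
    shift axis and shift. ``min_counts`` is forwarded to the division stage.
    """
    if led_b.led_id < led_a.led_id:
        frame_a, frame_b = frame_b, frame_a
        led_a, led_b = led_b, led_a
    shift_axis, shift_px = compute_shift(led_a, led_b)
    a, b, mask = align_frames(frame_a, frame_b, shift_axis, shift_px)
    raw = spdri_divide(
        a, b, mask, shift_axis, shift_px,
        source_leds=(led_a.led_id, led_b.led_id), min_counts=min_counts,
    )
    return smooth_map(raw, sigma_px)
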