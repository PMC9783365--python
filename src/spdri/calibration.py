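"""System calibration: LED localization and exposure adjustment.

LED positions are found by fitting a Gaussian (with constant offset) to a
cross-section through the illumination cone at the frame edge; the fitted
center is reported as the LED position. The cone itself decays
exponentially, not Gaussian — the Gaussian is nevertheless an adequate
position estimator, and the fit quality (R²) is reported so the caller can
reject bad localizations.

Exposure calibration scales the camera exposure so that the brightest
region of the frame — operationalized as the 99.9th-percentile pixel, which
is robust to isolated hot pixels — lands at a target fraction (default 95%)
of the saturation ceiling, assuming counts linear in exposure time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateProfileError, FitError, ValidationError
from .model import GaussianFitResult, Profile, ReflectanceFrame

#: Percentile defining the "brightest region" pixel level.
ROBUST_PEAK_PERCENTILE = 99.9
#: Default saturation target as a fraction of the bit-depth ceiling.
DEFAULT_TARGET_FRACTION = 0.95


@dataclass(frozen=True)
class ExposureCalibration:
    """Result of exposure calibration for one LED/phantom combination."""

    led_id: int | None
    phantom_label: str | None
    exposure_ms: float
    achieved_peak_fraction: float

    def __post_init__(self):
        if self.exposure_ms <= 0:
            raise ValidationError("exposure_ms must be positive")
        if not (0 < self.achieved_peak_fraction <= 1):
            raise ValidationError("achieved_peak_fraction must lie in (0, 1]")


def _gaussian(u, amplitude, center, sigma, offset):
    return amplitude * np.exp(-((u - center) ** 2) / (2.0 * sigma**2)) + offset


def fit_led_position(profile: Profile) -> GaussianFitResult:
    """Locate an LED by least-squares Gaussian fit to a cross-section.

    Fits ``a * exp(-(u - mu)^2 / (2 sigma^2)) + c`` to the profile values
    (NaN samples excluded) and reports the center ``mu`` as the LED
    position, together with the fit quality R² = 1 - SSres/SStot computed
    on the raw profile.

    Raises
    ------
    DegenerateProfileError
        If the profile is shorter than 10 samples or constant.
    FitError
        If the optimizer does not converge; carries the last residual.
    """
    u_all = np.arange(profile.length, dtype=float)
    finite = np.isfinite(profile.values)
    u, y = u_all[finite], profile.values[finite]
    if u.size < 10:
        raise DegenerateProfileError(
            f"profile has {u.size} usable samples; need at least 10"
        )
    if np.ptp(y) == 0:
        raise DegenerateProfileError("constant profile: Gaussian fit is degenerate")

    p0 = [float(np.max(y) - np.min(y)), float(u[np.argmax(y)]),
          profile.length / 4.0, float(np.min(y))]
    try:
        popt, _ = curve_fit(_gaussian, u, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        residual = float(np.sum((y - _gaussian(u, *p0)) ** 2))
        raise FitError(f"Gaussian fit did not converge: {exc}", residual) from exc

    amplitude, center, sigma, offset = popt
    residuals = y - _gaussian(u, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return GaussianFitResult(
        center_px=float(center),
        amplitude=float(abs(amplitude)),
        sigma_px=float(abs(sigma)),
        offset=float(offset),
        r_squared=1.0 - ss_res / ss_tot,
    )


def robust_peak(frame: ReflectanceFrame) -> float:
    """Brightest-region pixel level: the 99.9th-percentile pixel value."""
    return float(np.percentile(frame.pixels, ROBUST_PEAK_PERCENTILE))


def calibrate_exposure(
    reference: ReflectanceFrame,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    phantom_label: str | None = None,
) -> ExposureCalibration:
    """Exposure time that puts the robust peak at ``target_fraction`` of saturation.

    Assumes pixel counts strictly linear in exposure time:
    ``new_exposure = exposure * target_fraction * ceiling / robust_peak``.
    The achieved peak fraction is recomputed on the reference rescaled by
    the exposure ratio (clipped at the ceiling).

    If the reference's robust peak is already clipped at the ceiling, the
    true peak is unknowable from the frame; a warning is issued and the
    exposure is halved iteratively until the predicted peak is unclipped.
    """
    if not (0 < target_fraction <= 1):
        raise ValidationError("target_fraction must lie in (0, 1]")
    peak = robust_peak(reference)
    if peak <= 0:
        raise ValidationError("cannot calibrate exposure on an all-zero frame")
    ceiling = float(reference.saturation)

    exposure = reference.exposure_ms
    if peak >= ceiling:
        while peak >= ceiling:
            warnings.warn(
                "robust peak is saturated; halving exposure", stacklevel=2
            )
            exposure *= 0.5
            peak *= 0.5

    new_exposure = exposure * (target_fraction * ceiling) / peak
    rescaled = np.clip(reference.pixels * (new_exposure / reference.exposure_ms), 0, ceiling)
    achieved = float(np.percentile(rescaled, ROBUST_PEAK_PERCENTILE)) / ceiling
    return ExposureCalibration(
        led_id=reference.led_id,
        phantom_label=phantom_label,
        exposure_ms=new_exposure,
        achieved_peak_fraction=achieved,
    )


def depth_window_filter(
    depth_um: float, low_um: float = 150.0, high_um: float = 300.0
) -> bool:
    """True iff a structure depth falls inside the accepted window (inclusive).

    Only structures within this depth band are analyzed; the defaults match
    the band over which the phantom measurements are valid.
    """
    if low_um > high_um:
        raise ValidationError(f"low_um ({low_um}) exceeds high_um ({high_um})")
    return bool(low_um <= depth_um <= high_um)
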