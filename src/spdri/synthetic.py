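"""Synthetic phantom-frame generator with known ground truth.

Emulates the measurement situation the reconstruction operates on: an
illumination cone with exponential radial decay injected at an edge LED
position, an embedded absorbing thread that locally attenuates the diffuse
reflectance, and sensor noise. Because the generator knows the ground truth
(thread mask, attenuation amplitude, shift geometry), every downstream stage
can be tested quantitatively without instrument data.

The illumination model is a single-exponential radial decay — a deliberate
phenomenological stand-in for full photon transport, sufficient because the
reconstruction cancels the cone by division whatever its exact shape.
Thread contrast follows a Beer–Lambert-inspired saturating law: the local
attenuation amplitude is

    A = 1 - exp(-g * D * exp(-z / zeta))

with ``D`` the thread diameter (μm), ``z`` its depth (μm), ``g`` a contrast
gain per μm of diameter, and ``zeta`` the depth scale over which contrast
decays. A increases monotonically with diameter and decreases with depth,
the two qualitative behaviours the synthetic data must reproduce. Depth
additionally blurs the thread image (scattering), modelled as a Gaussian
blur whose sigma grows linearly with depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .model import (
    DEFAULT_HEIGHT_PX,
    DEFAULT_WIDTH_PX,
    LedSpec,
    ReflectanceFrame,
    clamp_to_bit_depth,
)

#: Default peak illumination in counts at the source position (16-bit scale).
DEFAULT_PEAK_INTENSITY = 60000.0
#: Default 1/e decay length of the illumination cone, px.
DEFAULT_DECAY_LENGTH_PX = 500.0
#: Default camera pixel pitch at the object plane, μm/px
#: (3.45 μm sensor pixel over 3.75x system magnification).
DEFAULT_PIXEL_PITCH_UM = 3.45 / 3.75


@dataclass(frozen=True)
class IlluminationModel:
    """Exponential-decay light cone centered at an edge LED position."""

    led: LedSpec
    peak_intensity: float = DEFAULT_PEAK_INTENSITY
    decay_length_px: float = DEFAULT_DECAY_LENGTH_PX

    def __post_init__(self):
        if self.peak_intensity <= 0:
            raise ValidationError("peak_intensity must be positive")
        if self.decay_length_px <= 0:
            raise ValidationError("decay_length_px must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground truth for one synthetic phantom.

    ``thread_path`` is an ordered polyline of (x, y) control points in pixel
    coordinates; the thread is rasterized with a width of
    ``thread_diameter_um / pixel_pitch_um`` pixels.
    """

    thread_path: tuple[tuple[float, float], ...]
    thread_diameter_um: float = 10.0
    thread_depth_um: float = 200.0
    contrast_gain: float = 0.05
    depth_decay_um: float = 300.0
    blur_sigma_px_per_um_depth: float = 0.1
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self):
        object.__setattr__(
            self, "thread_path", tuple((float(x), float(y)) for x, y in self.thread_path)
        )
        if self.thread_diameter_um <= 0:
            raise ValidationError("thread_diameter_um must be positive")
        if self.thread_depth_um < 0:
            raise ValidationError("thread_depth_um must be nonnegative")
        if self.contrast_gain <= 0 or self.depth_decay_um <= 0:
            raise ValidationError("contrast_gain and depth_decay_um must be positive")
        if self.blur_sigma_px_per_um_depth < 0:
            raise ValidationError("blur_sigma_px_per_um_depth must be nonnegative")
        if self.pixel_pitch_um <= 0:
            raise ValidationError("pixel_pitch_um must be positive")

    @property
    def attenuation_amplitude(self) -> float:
        """Peak fractional absorption A = 1 - exp(-g D exp(-z/zeta))."""
        return 1.0 - np.exp(
            -self.contrast_gain
            * self.thread_diameter_um
            * np.exp(-self.thread_depth_um / self.depth_decay_um)
        )

    @property
    def thread_radius_px(self) -> float:
        return 0.5 * self.thread_diameter_um / self.pixel_pitch_um

    @property
    def blur_sigma_px(self) -> float:
        return self.blur_sigma_px_per_um_depth * self.thread_depth_um


@dataclass(frozen=True)
class NoiseModel:
    """Seeded sensor-noise model; identical seed+parameters reproduce bits.

    ``gaussian`` adds zero-mean additive read noise of ``sigma_counts``;
    ``shot`` draws Poisson counts scaled by ``scale`` electrons per count.
    """

    kind: str = "gaussian"
    sigma_counts: float = 0.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "shot"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma_counts < 0 or self.scale <= 0:
            raise ValidationError("sigma_counts must be >= 0 and scale > 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return signal
        if self.kind == "gaussian":
            return signal + rng.normal(0.0, self.sigma_counts, size=signal.shape)
        # shot: Poisson statistics on scaled counts
        return rng.poisson(np.maximum(signal, 0.0) * self.scale) / self.scale


def render_light_cone(
    model: IlluminationModel,
    height_px: int = DEFAULT_HEIGHT_PX,
    width_px: int = DEFAULT_WIDTH_PX,
    exposure_ms: float = 100.0,
) -> ReflectanceFrame:
    """Render the illumination cone of a single LED.

    Pixel value is ``peak * exp(-r / decay_length)`` with ``r`` the Euclidean
    distance from the LED's edge position; strictly radially decreasing.
    """
    x0, y0 = model.led.edge_xy(height_px, width_px)
    yy = np.arange(height_px, dtype=float)[:, None]
    xx = np.arange(width_px, dtype=float)[None, :]
    r = np.hypot(xx - x0, yy - y0)
    pixels = model.peak_intensity * np.exp(-r / model.decay_length_px)
    return ReflectanceFrame(
        pixels=pixels, exposure_ms=exposure_ms, led_id=model.led.led_id
    )


def rasterize_thread_mask(
    path_pts: np.ndarray, radius_px: float, height_px: int, width_px: int
) -> np.ndarray:
    """Boolean mask of pixels within ``radius_px`` of the thread polyline."""
    pts = np.asarray(path_pts, dtype=float)
    mask = np.zeros((height_px, width_px), dtype=bool)
    r = max(radius_px, 0.0)
    pad = int(np.ceil(r)) + 1
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        xlo = max(int(np.floor(min(x1, x2))) - pad, 0)
        xhi = min(int(np.ceil(max(x1, x2))) + pad + 1, width_px)
        ylo = max(int(np.floor(min(y1, y2))) - pad, 0)
        yhi = min(int(np.ceil(max(y1, y2))) + pad + 1, height_px)
        if xlo >= xhi or ylo >= yhi:
            continue
        yy = np.arange(ylo, yhi, dtype=float)[:, None]
        xx = np.arange(xlo, xhi, dtype=float)[None, :]
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0.0:
            dist = np.hypot(xx - x1, yy - y1)
        else:
            t = np.clip(((xx - x1) * dx + (yy - y1) * dy) / seg_len2, 0.0, 1.0)
            dist = np.hypot(xx - (x1 + t * dx), yy - (y1 + t * dy))
        mask[ylo:yhi, xlo:xhi] |= dist <= r
    return mask


def render_thread_attenuation(
    spec: PhantomSpec, height_px: int = DEFAULT_HEIGHT_PX, width_px: int = DEFAULT_WIDTH_PX
) -> np.ndarray:
    """Multiplicative attenuation map in (0, 1] for an embedded thread.

    ``attenuation = 1 - A * blur(mask)`` with A the spec's closed-form
    amplitude and the rasterized thread mask blurred by the depth-dependent
    sigma. Control points outside the frame are clipped with a warning.
    """
    pts = np.asarray(spec.thread_path, dtype=float)
    if pts.shape[0] < 2:
        raise ValidationError("thread_path needs at least 2 control points")
    if (
        pts[:, 0].min() < 0
        or pts[:, 0].max() > width_px - 1
        or pts[:, 1].min() < 0
        or pts[:, 1].max() > height_px - 1
    ):
        warnings.warn(
            "thread path extends outside the frame; clipping control points",
            stacklevel=2,
        )
        pts = pts.copy()
        pts[:, 0] = np.clip(pts[:, 0], 0, width_px - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, height_px - 1)

    mask = rasterize_thread_mask(pts, spec.thread_radius_px, height_px, width_px)
    soft = mask.astype(float)
    if spec.blur_sigma_px > 0:
        soft = gaussian_filter(soft, sigma=spec.blur_sigma_px, mode="constant")
    return 1.0 - spec.attenuation_amplitude * np.clip(soft, 0.0, 1.0)


def loop_thread_path(
    n_loops: int,
    loop_height_px: float,
    spacing_px: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Serpentine polyline emulating the hairpin pattern of capillary loops.

    Each loop is a hairpin rising ``loop_height_px`` from the baseline at
    ``origin``; consecutive legs are ``spacing_px`` apart. Deterministic for
    fixed arguments.
    """
    if n_loops < 1:
        raise ValidationError("n_loops must be >= 1")
    if loop_height_px <= 0 or spacing_px <= 0:
        raise ValidationError("loop_height_px and spacing_px must be positive")
    x0, y0 = origin
    pts = [(x0, y0)]
    for i in range(n_loops):
        xl = x0 + 2 * i * spacing_px
        xr = xl + spacing_px
        pts += [(xl, y0 - loop_height_px), (xr, y0 - loop_height_px), (xr, y0)]
        if i + 1 < n_loops:
            pts.append((xr + spacing_px, y0))
    return np.asarray(pts, dtype=float)


def generate_frame_pair(
    spec: PhantomSpec,
    led_a: LedSpec,
    led_b: LedSpec,
    illum: dict | None = None,
    noise: NoiseModel = NoiseModel(kind="none"),
    height_px: int = DEFAULT_HEIGHT_PX,
    width_px: int = DEFAULT_WIDTH_PX,
    exposure_ms: float = 100.0,
) -> tuple[ReflectanceFrame, ReflectanceFrame]:
    """Generate the two-frame acquisition the reconstruction consumes.

    Each frame is ``cone(led) * attenuation(spec)`` plus a noise realization;
    the phantom (thread) is identical across the pair, only the active LED
    differs — mirroring the serial one-LED-one-frame protocol. Both LEDs
    must sit on the same frame edge (same shift axis).

    ``illum`` optionally overrides ``peak_intensity`` / ``decay_length_px``.
    """
    if led_a.side != led_b.side:
        raise ValidationError(
            "LEDs must be on the same side; mixed-axis shifts are unsupported"
        )
    illum = dict(illum or {})
    unknown = set(illum) - {"peak_intensity", "decay_length_px"}
    if unknown:
        raise ValidationError(f"unknown illumination parameters: {sorted(unknown)}")

    attenuation = render_thread_attenuation(spec, height_px, width_px)
    rng = np.random.default_rng(noise.seed)
    frames = []
    for led in (led_a, led_b):
        cone = render_light_cone(
            IlluminationModel(led=led, **illum), height_px, width_px, exposure_ms
        )
        signal = cone.pixels * attenuation
        noisy = np.maximum(noise.apply(signal, rng), 0.0)
        frame = ReflectanceFrame(
            pixels=noisy, exposure_ms=exposure_ms, led_id=led.led_id
        )
        frames.append(clamp_to_bit_depth(frame))
    return frames[0], frames[1]
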