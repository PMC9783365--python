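"""Core domain types, coordinate conventions, and calibration-table I/O.

Coordinate convention used throughout the package: 0-based integer pixel
indices, ``x`` indexes columns, ``y`` indexes rows, origin at the top-left
of the frame. LEDs sit on two edges of the imaging field: *long-side* LEDs
are distributed along the x axis on the last row of the frame, *short-side*
LEDs along the y axis on the last column. Cross-sections through the raw
frames at those edge rows/columns pass through the illumination sources.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ValidationError

#: Default sensor extent in pixels (columns x rows).
DEFAULT_WIDTH_PX = 4096
DEFAULT_HEIGHT_PX = 3000


class Side(str, enum.Enum):
    """Which frame edge an LED sits on.

    ``LONG_AXIS`` sources are positioned along x (bottom edge row); a shift
    between two of them displaces the frames in x. ``SHORT_AXIS`` sources
    are positioned along y (right edge column) and shift in y.
    """

    LONG_AXIS = "long_axis"
    SHORT_AXIS = "short_axis"

    @property
    def shift_axis(self) -> str:
        return "x" if self is Side.LONG_AXIS else "y"


@dataclass(frozen=True)
class LedSpec:
    """One illumination source: edge side, axis position, optical power.

    ``exposure_ms_by_phantom`` maps a phantom label (e.g. ``"10um"``) to the
    camera exposure time calibrated for that phantom.
    """

    led_id: int
    side: Side
    position_px: float
    intensity_uW: float
    exposure_ms_by_phantom: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.position_px < 0:
            raise ValidationError(
                f"LED #{self.led_id}: position_px must be nonnegative, "
                f"got {self.position_px}"
            )
        if self.intensity_uW <= 0:
            raise ValidationError(
                f"LED #{self.led_id}: intensity_uW must be positive, "
                f"got {self.intensity_uW}"
            )
        for label, exp in self.exposure_ms_by_phantom.items():
            if exp <= 0:
                raise ValidationError(
                    f"LED #{self.led_id}: exposure for phantom {label!r} "
                    f"must be positive, got {exp}"
                )

    def edge_xy(self, height_px: int, width_px: int) -> tuple[float, float]:
        """Pixel coordinates (x, y) of the source on the frame edge."""
        if self.side is Side.LONG_AXIS:
            return (self.position_px, float(height_px - 1))
        return (float(width_px - 1), self.position_px)


@dataclass
class ReflectanceFrame:
    """A single diffuse-reflectance acquisition: one frame per active LED.

    ``pixels`` is a 2-D nonnegative intensity matrix; values are bounded by
    the sensor saturation ceiling ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    exposure_ms: float
    led_id: int | None = None
    bit_depth: int = 16

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"pixels must be a 2-D matrix, got ndim={self.pixels.ndim}"
            )
        if self.exposure_ms <= 0:
            raise ValidationError(
                f"exposure_ms must be positive, got {self.exposure_ms}"
            )
        if self.pixels.size and float(np.min(self.pixels)) < 0:
            raise ValidationError("pixel intensities must be nonnegative")
        if self.pixels.size and float(np.max(self.pixels)) > self.saturation:
            raise ValidationError(
                f"pixel intensities exceed saturation {self.saturation} "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def saturation(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def clamp_to_bit_depth(frame: ReflectanceFrame) -> ReflectanceFrame:
    """Clip pixel values into ``[0, 2**bit_depth - 1]``.

    Values already in range are returned unchanged (bitwise).
    """
    clipped = np.clip(frame.pixels, 0, 2 ** frame.bit_depth - 1)
    return replace(frame, pixels=clipped)


@dataclass
class SpdriMap:
    """Ratio image from shift-align + pixelwise division.

    ``ratio`` is finite and positive wherever ``valid_mask`` is true;
    pixels translated out of the overlap, or with a zero denominator, are
    masked invalid and carry NaN.
    """

    ratio: np.ndarray
    valid_mask: np.ndarray
    shift_axis: str
    shift_px: int
    source_leds: tuple[int, int] | None = None

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.ratio.shape != self.valid_mask.shape:
            raise ValidationError("ratio and valid_mask shapes differ")
        if self.shift_axis not in ("x", "y"):
            raise ValidationError(f"shift_axis must be 'x' or 'y', got {self.shift_axis!r}")
        valid = self.ratio[self.valid_mask]
        if valid.size and not (np.all(np.isfinite(valid)) and np.all(valid > 0)):
            raise ValidationError("ratio must be finite and positive where valid")

    def masked_ratio(self) -> np.ndarray:
        """Ratio with invalid pixels set to NaN."""
        out = np.where(self.valid_mask, self.ratio, np.nan)
        return out


@dataclass
class Profile:
    """A 1-D cross-section at a fixed row or column.

    ``axis`` is the direction the profile runs along: ``"x"`` means a row
    (fixed y coordinate), ``"y"`` means a column (fixed x coordinate).
    Masked/invalid pixels are carried as NaN.
    """

    values: np.ndarray
    axis: str
    fixed_coordinate_px: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.axis not in ("x", "y"):
            raise ValidationError(f"axis must be 'x' or 'y', got {self.axis!r}")

    @property
    def length(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GaussianFitResult:
    """Least-squares Gaussian fit a*exp(-(u-mu)^2/(2 sigma^2)) + c."""

    center_px: float
    amplitude: float
    sigma_px: float
    offset: float
    r_squared: float

    def __post_init__(self):
        if self.sigma_px <= 0:
            raise ValidationError(f"sigma_px must be positive, got {self.sigma_px}")
        if self.r_squared > 1 + 1e-12:
            raise ValidationError(f"r_squared cannot exceed 1, got {self.r_squared}")


# ---------------------------------------------------------------------------
# Calibration table I/O (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["led_id", "side", "position_px", "intensity_uW"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".json")


def read_calibration_table(path: str | Path) -> list[LedSpec]:
    """Read a calibration table (CSV plus JSON sidecar) into LedSpec rows.

    The CSV holds one row per LED with columns ``led_id, side, position_px,
    intensity_uW`` and one exposure column per phantom. The sidecar maps
    phantom labels to those column names; without a sidecar, every column
    named ``exposure_ms_<label>`` is taken as phantom ``<label>``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"calibration table not found: {path}")
    df = pd.read_csv(path)
    for col in _BASE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"calibration table missing required column {col!r}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        label_to_col: dict[str, str] = json.loads(sidecar.read_text())["exposure_columns"]
        for label, col in label_to_col.items():
            if col not in df.columns:
                raise FormatError(
                    f"sidecar names exposure column {col!r} (phantom {label!r}) "
                    f"absent from the CSV"
                )
    else:
        label_to_col = {
            c.removeprefix("exposure_ms_"): c
            for c in df.columns
            if c.startswith("exposure_ms_")
        }

    leds = []
    for _, row in df.iterrows():
        side_raw = str(row["side"])
        try:
            side = Side(side_raw)
        except ValueError:
            raise FormatError(
                f"unknown side {side_raw!r} in column 'side' "
                f"(expected 'long_axis' or 'short_axis')"
            ) from None
        exposures = {
            label: float(row[col])
            for label, col in label_to_col.items()
            if pd.notna(row[col])
        }
        leds.append(
            LedSpec(
                led_id=int(row["led_id"]),
                side=side,
                position_px=float(row["position_px"]),
                intensity_uW=float(row["intensity_uW"]),
                exposure_ms_by_phantom=exposures,
            )
        )
    return leds


def write_calibration_table(leds: list[LedSpec], path: str | Path) -> None:
    """Write LedSpec rows as CSV + JSON sidecar; inverse of the reader."""
    path = Path(path)
    labels: list[str] = []
    for led in leds:
        for label in led.exposure_ms_by_phantom:
            if label not in labels:
                labels.append(label)
    records = []
    for led in leds:
        rec = {
            "led_id": led.led_id,
            "side": led.side.value,
            "position_px": led.position_px,
            "intensity_uW": led.intensity_uW,
        }
        for label in labels:
            rec[f"exposure_ms_{label}"] = led.exposure_ms_by_phantom.get(label, np.nan)
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=_BASE_COLUMNS + [f"exposure_ms_{l}" for l in labels])
    df.to_csv(path, index=False)
    sidecar = {"exposure_columns": {l: f"exposure_ms_{l}" for l in labels}}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def table1_path() -> Path:
    """Path to the bundled instrument calibration table (six LEDs)."""
    return Path(__file__).parent / "data" / "table1.csv"


def load_instrument_leds() -> list[LedSpec]:
    """The bundled six-LED instrument geometry and calibrated exposures."""
    return read_calibration_table(table1_path())


# ---------------------------------------------------------------------------
# TIFF frame I/O
# ---------------------------------------------------------------------------

def write_frame_tiff(frame: ReflectanceFrame, path: str | Path) -> None:
    """Write a frame as a single-page 16-bit grayscale TIFF.

    Float pixel data is rounded to the nearest integer count.
    """
    data = np.clip(np.rint(frame.pixels), 0, frame.saturation).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        metadata={"exposure_ms": frame.exposure_ms, "led_id": frame.led_id},
    )


def read_frame_tiff(
    path: str | Path,
    exposure_ms: float | None = None,
    led_id: int | None = None,
    bit_depth: int = 16,
) -> ReflectanceFrame:
    """Read a single-page grayscale TIFF as a ReflectanceFrame.

    Exposure and LED identity are taken from the TIFF metadata written by
    :func:`write_frame_tiff` unless overridden.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.pages[0].asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if exposure_ms is None:
        exposure_ms = float(meta.get("exposure_ms", 0) or 0)
        if exposure_ms <= 0:
            raise FormatError(
                f"{path}: no exposure_ms metadata; pass exposure_ms explicitly"
            )
    if led_id is None:
        led_id = meta.get("led_id")
        led_id = int(led_id) if led_id is not None else None
    return ReflectanceFrame(
        pixels=data.astype(float), exposure_ms=exposure_ms, led_id=led_id,
        bit_depth=bit_depth,
    )
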